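"""Shared fixtures: phantoms and pipeline runs reused across test modules.

Expensive end-to-end products are session-scoped so the acceptance-grade
checks and the unit-level checks share one reconstruction.
"""

import numpy as np
import pytest

import dynqsm
from dynqsm.config import (AcquisitionParams, InversionConfig, RunConfig)
from dynqsm.phantom import tissue_concentration_series


@pytest.fixture(scope="session")
def phantom48():
    return dynqsm.build_phantom((48, 48, 48), seed=1)


@pytest.fixture(scope="session")
def params50():
    return AcquisitionParams(n_timepoints=50)


@pytest.fixture(scope="session")
def run48_noiseless():
    """Noiseless 48^3 x 50 end-to-end run (moderate size, no drift)."""
    cfg = RunConfig(grid_shape=(48, 48, 48), phantom_seed=1, noise_seed=2,
                    noise_sd=0.0,
                    acquisition=AcquisitionParams(n_timepoints=50),
                    inversion=InversionConfig(method="tkd"))
    return cfg, dynqsm.run_pipeline(cfg)


@pytest.fixture(scope="session")
def run64_noiseless():
    """Full-scale noiseless run: 64^3 grid, 70 time points as acquired."""
    cfg = RunConfig(grid_shape=(64, 64, 64), phantom_seed=1, noise_seed=2,
                    noise_sd=0.0,
                    acquisition=AcquisitionParams(n_timepoints=70),
                    inversion=InversionConfig(method="tkd"))
    return cfg, dynqsm.run_pipeline(cfg)


def true_window_delta_chi(phantom, blood, physio, windows, region,
                          chi_mol=308.0):
    """Ground-truth post-minus-pre susceptibility change of a region (ppm)."""
    conc = tissue_concentration_series(phantom, blood, physio)
    nt = conc.shape[-1]
    vox = conc[phantom.masks[region]]
    d = vox[:, windows.post_slice(nt)].mean() - vox[:, windows.pre_slice()].mean()
    return chi_mol / 1000.0 * float(d)
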
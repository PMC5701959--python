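"""Validated parameter objects shared across the pipeline.

All times are seconds, fields in tesla, susceptibilities in ppm unless a
field name says otherwise.  Time-point indices quoted in configuration are
1-based inclusive, matching the convention of the acquisition protocol
("time points 5-14"); array code converts to 0-based slices internally.
"""

from __future__ import annotations

from typing import Literal, Tuple

from pydantic import BaseModel, Field, model_validator

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_PROTON = 2.675e8


class AcquisitionParams(BaseModel):
    """Gradient-echo DSC acquisition parameters.

    Defaults mirror a 3 T single-shot GRE-EPI perfusion protocol:
    TE = 29 ms, 70 dynamics at 1.24 s temporal resolution.
    """

    te: float = Field(default=0.029, gt=0, description="echo time (s)")
    b0: float = Field(default=3.0, gt=0, description="main field (T)")
    gamma: float = Field(default=GAMMA_PROTON, gt=0,
                         description="gyromagnetic ratio (rad s^-1 T^-1)")
    n_timepoints: int = Field(default=70, ge=20)
    dt: float = Field(default=1.24, gt=0, description="temporal resolution (s)")
    voxel_size: Tuple[float, float, float] = (1.72, 1.72, 1.72)
    b0_drift_rate: float = Field(
        default=0.0, description="global field drift (ppb per time point)")

    @model_validator(mode="after")
    def _check_voxels(self) -> "AcquisitionParams":
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        return self

    @property
    def phase_per_ppm(self) -> float:
        """Phase accrued at TE by a 1 ppm field offset (rad)."""
        return self.gamma * self.b0 * self.te * 1e-6

    @property
    def times(self):
        import numpy as np

        return np.arange(self.n_timepoints) * self.dt


class PhysioConstants(BaseModel):
    """Physiological constants entering the blood-volume formula."""

    rho: float = Field(default=1.04, gt=0, description="brain density (g/mL)")
    hct_lv: float = Field(default=0.45, description="large-vessel hematocrit")
    hct_sv: float = Field(default=0.25, description="small-vessel hematocrit")
    chi_mol: float = Field(default=308.0, gt=0,
                           description="CA molar susceptibility (ppm/M)")

    @model_validator(mode="after")
    def _check_hct(self) -> "PhysioConstants":
        if not (0 < self.hct_sv < self.hct_lv < 1):
            raise ValueError("require 0 < hct_sv < hct_lv < 1")
        return self

    @property
    def hct_ratio(self) -> float:
        """(1 - Hct_LV) / (1 - Hct_SV), the large-to-small vessel correction."""
        return (1.0 - self.hct_lv) / (1.0 - self.hct_sv)


class InversionConfig(BaseModel):
    """Dipole-inversion settings.

    ``lam`` weights the data-fidelity term of the morphology-enabled
    inversion; larger values trust the measured field more and yield
    sharper (less smoothed) susceptibility maps.
    """

    lam: float = Field(default=300.0, gt=0)
    method: Literal["medi_like", "tkd"] = "medi_like"
    tkd_threshold: float = Field(default=0.10, gt=0, le=1.0 / 3.0)
    tkd_psf_correction: bool = False
    max_iter: int = Field(default=30, ge=1)
    tol: float = Field(default=1e-3, gt=0)
    edge_percentile: float = Field(
        default=70.0, gt=0, lt=100,
        description="magnitude-gradient percentile above which voxels are "
                    "treated as edges and excluded from the smoothness penalty")
    irls_outer: int = Field(default=5, ge=1)


class ReferenceConfig(BaseModel):
    """Thresholds of the CSF reference-pixel selection criteria."""

    thresh_range: float = Field(default=10.0, gt=0, le=100.0,
                                description="% of candidate ROI kept by the "
                                            "magnitude signal-range criterion")
    thresh_tailpeak: float = Field(default=30.0, ge=0, lt=100.0,
                                   description="% of candidates discarded for "
                                               "extreme tail-to-peak ratios")
    n_tail: int = Field(default=5, ge=1)
    n_peak: int = Field(default=5, ge=1)


class SteadyStateWindows(BaseModel):
    """Baseline and steady-state averaging windows (1-based inclusive)."""

    pre_window: Tuple[int, int] = (5, 14)
    post_window: int = Field(default=7, ge=1,
                             description="number of final time points "
                                         "averaged for the post-CA state")

    @model_validator(mode="after")
    def _check(self) -> "SteadyStateWindows":
        lo, hi = self.pre_window
        if not (1 <= lo <= hi):
            raise ValueError("pre_window must be 1-based increasing")
        return self

    def pre_slice(self) -> slice:
        lo, hi = self.pre_window
        return slice(lo - 1, hi)

    def post_slice(self, n_timepoints: int) -> slice:
        lo, hi = self.pre_window
        if n_timepoints - self.post_window <= hi:
            raise ValueError("post window overlaps the baseline window")
        return slice(n_timepoints - self.post_window, n_timepoints)


class RunConfig(BaseModel):
    """Fully-resolved configuration of one pipeline run.

    Round-trips losslessly through JSON; every run persists the resolved
    config (with its seeds) next to its outputs so results can be
    regenerated exactly.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    phantom_seed: int = 0
    noise_seed: int = 0
    noise_sd: float = Field(default=0.0, ge=0)
    peak_conc: float = Field(default=5.0, gt=0,
                             description="peak blood CA concentration (mM)")
    peak_to_tail_ratio: float = Field(default=9.0, gt=1)
    acquisition: AcquisitionParams = AcquisitionParams()
    physio: PhysioConstants = PhysioConstants()
    inversion: InversionConfig = InversionConfig()
    reference: ReferenceConfig = ReferenceConfig()
    windows: SteadyStateWindows = SteadyStateWindows()
    pdf_max_iter: int = Field(default=60, ge=1)
    pdf_tol: float = Field(default=5e-3, gt=0)
    erode_regions: int = Field(default=1, ge=0,
                               description="erosion (voxels) of WM/GM masks "
                                           "before regional averaging")
    relaxivity_erode: int = Field(
        default=2, ge=0,
        description="erosion (voxels) of the whole-brain tissue ROI for the "
                    "relaxivity fit; mask-edge voxels of susceptibility maps "
                    "are unreliable")

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.model_validate_json(text)
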
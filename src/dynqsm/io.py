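"""NIfTI / CSV / JSON input-output and run persistence.

Magnitude and phase travel as two 4D NIfTI files with a shared affine;
masks as 3D integer-label NIfTI; everything scalar (configuration, seeds,
regional results, diagnostics) as JSON or CSV sidecars so a run can be
audited and regenerated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np

from .config import AcquisitionParams, RunConfig
from .kernels import wrap_phase
from .phantom import DynamicSeries

_MASK_LABELS = {"csf": 1, "wm": 2, "gm": 3, "vessel": 4, "outer_csf": 5}


def _affine(params: AcquisitionParams) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = params.voxel_size
    return aff


def write_series(series: DynamicSeries, magnitude_path, phase_path) -> None:
    aff = _affine(series.params)
    nib.save(nib.Nifti1Image(series.magnitude.astype(np.float32), aff),
             str(magnitude_path))
    nib.save(nib.Nifti1Image(series.phase.astype(np.float32), aff),
             str(phase_path))


def read_series(magnitude_path, phase_path,
                params: AcquisitionParams,
                phase_units: str = "auto") -> DynamicSeries:
    """Load and validate a magnitude/phase pair.

    ``phase_units``: 'rad', 'deg' or 'auto'.  The auto heuristic flags
    phase stored in degrees when values exceed the wrapped radian range
    but stay within +-360.  Phase is re-wrapped to (-pi, pi] regardless,
    covering scanner conventions that store [0, 2*pi) or [-pi, pi].
    """
    mag_img = nib.load(str(magnitude_path))
    pha_img = nib.load(str(phase_path))
    mag = np.asarray(mag_img.dataobj, dtype=np.float64)
    pha = np.asarray(pha_img.dataobj, dtype=np.float64)
    if mag.shape != pha.shape:
        raise ValueError(f"magnitude shape {mag.shape} != phase shape "
                         f"{pha.shape}")
    if mag.ndim != 4:
        raise ValueError("expected 4D volumes (x, y, z, t)")
    if mag.shape[-1] != params.n_timepoints:
        raise ValueError(
            f"time dimension {mag.shape[-1]} does not match configured "
            f"n_timepoints {params.n_timepoints}")
    if mag_img.affine is None or pha_img.affine is None:
        raise ValueError("missing affine")

    amax = np.abs(pha).max()
    if phase_units == "auto":
        phase_units = "deg" if (amax > 2 * np.pi + 1e-3
                                and amax <= 360.0 + 1e-3) else "rad"
    if phase_units == "deg":
        pha = np.deg2rad(pha)
    elif phase_units != "rad":
        raise ValueError(f"unknown phase_units '{phase_units}'")
    pha = wrap_phase(pha)
    return DynamicSeries(magnitude=mag, phase=pha, params=params)


def write_masks(masks: Dict[str, np.ndarray], path,
                params: AcquisitionParams) -> None:
    """Tissue-class masks as one integer-label volume (brain implied)."""
    labels = np.zeros(next(iter(masks.values())).shape, dtype=np.int16)
    for name, lab in _MASK_LABELS.items():
        if name in masks:
            labels[np.asarray(masks[name], dtype=bool)] = lab
    nib.save(nib.Nifti1Image(labels, _affine(params)), str(path))


def read_masks(path) -> Dict[str, np.ndarray]:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    masks = {name: labels == lab for name, lab in _MASK_LABELS.items()}
    # the vein is not part of the brain (processing) mask
    masks["brain"] = (labels > 0) & (labels != _MASK_LABELS["vessel"])
    masks["head"] = labels > 0
    return masks


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def write_run(outdir, config: RunConfig, results: Dict) -> Path:
    """Persist one pipeline run: NIfTI volumes, CSV tables, JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.acquisition
    aff = _affine(params)
    phantom = results["phantom"]

    write_series(results["products"].series, outdir / "magnitude.nii",
                 outdir / "phase.nii")
    write_masks(phantom.masks, outdir / "masks.nii", params)
    nib.save(nib.Nifti1Image(phantom.cbv_map.astype(np.float32), aff),
             str(outdir / "true_cbv.nii"))
    nib.save(nib.Nifti1Image(results["chi_shifted"].chi.astype(np.float32),
                             aff), str(outdir / "chi_shifted.nii"))
    nib.save(nib.Nifti1Image(results["concentration"].astype(np.float32),
                             aff), str(outdir / "concentration.nii"))

    results["selection"].to_frame().to_csv(outdir / "csf_reference.csv",
                                           index=False)
    rows = []
    for method_key in ("cbv", "cbv_dr2s"):
        for region, res in results[method_key].items():
            rows.append({"region": region, "method": res.method,
                         "delta_tissue": res.delta_tissue,
                         "delta_blood": res.delta_blood, "cbv": res.cbv})
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "cbv_regional.csv", index=False)

    fit = results["relaxivity"]
    sidecar = {
        "config": json.loads(config.to_json()),
        "config_hash": config_hash(config),
        "blood_curve": {
            "times": results["blood"].times.tolist(),
            "concentration_mM": results["blood"].concentration.tolist(),
        },
        "delta_chi_blood_ppm": results["delta_chi_blood"],
        "relaxivity": {"slope": fit.slope, "intercept": fit.intercept,
                       "r": fit.r, "n_points": fit.n_points},
        "unwrap_residues": results["products"].unwrapped
                           .diagnostics["residues"].tolist(),
        "pdf_residual": results["products"].local_field
                        .diagnostics["pdf_residual"].tolist(),
    }
    (outdir / "run.json").write_text(json.dumps(sidecar, indent=2))
    return outdir
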
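"""CSF reference-pixel selection and per-time-point offset correction.

QSM maps and unfiltered phase images carry an arbitrary, time-varying
offset (PDF/inversion null space plus scanner B0 drift), so susceptibility
values at different time points are only comparable after shifting to a
reference that the contrast agent does not reach.  Ventricular CSF serves
as that reference.  Three criteria pick reliable CSF pixels:

1. candidates must lie in the ventricular CSF region of interest;
2. their magnitude time curve must show a small range (max - min) during
   the bolus passage — ``thresh_range`` % of the ROI with the smallest
   range is kept;
3. using each candidate alone as reference, the shifted whole-brain mean
   susceptibility curve must show a tail-to-peak ratio similar to the
   other candidates — the ``thresh_tailpeak`` % with the most extreme
   ratios (half from each side) is discarded.  This rejects pixels hit by
   pulsation/computation artefacts that would distort the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict

import numpy as np
import pandas as pd

from .config import ReferenceConfig
from .phantom import DynamicSeries
from .qsm import FieldSeries, SusceptibilitySeries

#: Baseline window, time points 5-14 (1-based inclusive), used everywhere.
BASELINE_SLICE = slice(4, 14)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ReferenceSelection:
    """The selected CSF reference pixels and the diagnostics behind them."""

    pixel_indices: np.ndarray  # (n, 3) voxel indices
    per_pixel_signal_range: np.ndarray
    per_pixel_tailpeak_ratio: np.ndarray
    config: ReferenceConfig
    diagnostics: Dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pixel_indices) < 1:
            raise ValueError("reference selection must contain >= 1 pixel")

    def __len__(self) -> int:
        return len(self.pixel_indices)

    def extract(self, series_4d: np.ndarray) -> np.ndarray:
        """Curves of the selected pixels, shape (n, t)."""
        i, j, k = self.pixel_indices.T
        return series_4d[i, j, k, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.pixel_indices[:, 0],
            "y": self.pixel_indices[:, 1],
            "z": self.pixel_indices[:, 2],
            "signal_range": self.per_pixel_signal_range,
            "tailpeak_ratio": self.per_pixel_tailpeak_ratio,
        })


def candidate_roi(masks: Dict[str, np.ndarray]) -> np.ndarray:
    """Ventricular CSF candidate voxels, shape (n, 3).

    The phantom's ground-truth CSF label stands in for the manually drawn
    lateral-ventricle ROI of a real study.
    """
    csf = np.asarray(masks["csf"], dtype=bool)
    if not csf.any():
        raise ValueError("CSF mask is empty")
    return np.argwhere(csf)


def filter_by_signal_range(series: DynamicSeries, roi: np.ndarray,
                           cfg: ReferenceConfig) -> np.ndarray:
    """Keep the ``thresh_range`` % of ROI pixels with the smallest magnitude
    signal range (rank order; ties broken by voxel index)."""
    if len(roi) == 0:
        raise ValueError("candidate ROI is empty")
    i, j, k = np.asarray(roi).T
    curves = series.magnitude[i, j, k, :]
    rng = curves.max(axis=1) - curves.min(axis=1)
    keep = max(1, _round_half_up(cfg.thresh_range / 100.0 * len(roi)))
    flat = np.ravel_multi_index((i, j, k), series.magnitude.shape[:3])
    order = np.lexsort((flat, rng))
    return np.asarray(roi)[order[:keep]]


def peak_window(magnitude: np.ndarray, brain_mask: np.ndarray,
                n_peak: int = 5) -> slice:
    """The ``n_peak`` time points including and surrounding the whole-brain
    mean-magnitude minimum (bolus peak), clipped at the series ends."""
    curve = magnitude[brain_mask].mean(axis=0)
    nt = curve.shape[0]
    if nt < n_peak:
        raise ValueError("series shorter than the peak window")
    tmin = int(np.argmin(curve))
    start = int(np.clip(tmin - n_peak // 2, 0, nt - n_peak))
    return slice(start, start + n_peak)


def filter_by_tailpeak(chi_series: SusceptibilitySeries,
                       magnitude: DynamicSeries, candidates: np.ndarray,
                       brain_mask: np.ndarray,
                       cfg: ReferenceConfig) -> ReferenceSelection:
    """Apply the tail-to-peak criterion and assemble the final selection.

    For each candidate used alone as reference, the whole-brain mean
    susceptibility curve is shifted by that candidate's curve and the
    baseline-referenced ratio (tail mean - baseline)/(peak mean -
    baseline) is computed; the ``thresh_tailpeak`` % most extreme ratios
    (half high, half low, counts rounded half-up) are discarded.
    """
    candidates = np.asarray(candidates)
    if len(candidates) == 0:
        raise ValueError("no candidates to filter")
    nt = chi_series.n_timepoints
    pw = peak_window(magnitude.magnitude, brain_mask, cfg.n_peak)
    tail = slice(nt - cfg.n_tail, nt)

    brain_curve = chi_series.chi[brain_mask].mean(axis=0)
    i, j, k = candidates.T
    cand_curves = chi_series.chi[i, j, k, :]
    shifted = brain_curve[None, :] - cand_curves
    base = shifted[:, BASELINE_SLICE].mean(axis=1)
    peak_amp = shifted[:, pw].mean(axis=1) - base
    tail_amp = shifted[:, tail].mean(axis=1) - base
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = tail_amp / peak_amp

    n = len(candidates)
    n_drop = _round_half_up(cfg.thresh_tailpeak / 2.0 / 100.0 * n)
    if 2 * n_drop >= n:
        raise ValueError(
            "tail-to-peak criterion discarded every candidate; "
            "lower thresh_tailpeak")
    order = np.argsort(ratios, kind="stable")
    kept = np.sort(order[n_drop:n - n_drop] if n_drop else order)

    mag_curves = magnitude.magnitude[i, j, k, :]
    sig_range = mag_curves.max(axis=1) - mag_curves.min(axis=1)
    table = pd.DataFrame({
        "x": i, "y": j, "z": k,
        "signal_range": sig_range,
        "tailpeak_ratio": ratios,
        "retained": np.isin(np.arange(n), kept),
    })
    return ReferenceSelection(
        pixel_indices=candidates[kept],
        per_pixel_signal_range=sig_range[kept],
        per_pixel_tailpeak_ratio=ratios[kept],
        config=cfg,
        diagnostics={"candidates": table, "peak_window": pw},
    )


def select_reference(series: DynamicSeries, chi_series: SusceptibilitySeries,
                     masks: Dict[str, np.ndarray],
                     cfg: ReferenceConfig) -> ReferenceSelection:
    """Run all three criteria in order."""
    roi = candidate_roi(masks)
    cand = filter_by_signal_range(series, roi, cfg)
    return filter_by_tailpeak(chi_series, series, cand,
                              np.asarray(masks["brain"], dtype=bool), cfg)


def _shift_curve(values_4d: np.ndarray, selection: ReferenceSelection):
    ref = selection.extract(values_4d).mean(axis=0)
    base = ref[BASELINE_SLICE].mean()
    return ref - base  # per-time-point correction scalar


def shift_susceptibility(chi_series: SusceptibilitySeries,
                         selection: ReferenceSelection) -> SusceptibilitySeries:
    """Shift every time point so the reference CSF curve is flat at its
    baseline level; spatial differences at fixed t are preserved."""
    correction = _shift_curve(chi_series.chi, selection)
    chi = chi_series.chi - correction[None, None, None, :]
    return SusceptibilitySeries(chi=chi, mask=chi_series.mask,
                                reference_state="csf_shifted")


def shift_phase(field: FieldSeries,
                selection: ReferenceSelection) -> FieldSeries:
    """Apply the same scalar-per-time-point correction to unwrapped,
    unfiltered phase (B0-drift correction for vessel measurements)."""
    if field.stage != "unwrapped":
        raise ValueError("phase shifting expects the unwrapped, unfiltered "
                         "phase series")
    correction = _shift_curve(field.values, selection)
    diag = dict(field.diagnostics)
    diag["csf_correction"] = correction
    return FieldSeries(values=field.values - correction[None, None, None, :],
                       mask=field.mask, stage=field.stage, unit=field.unit,
                       diagnostics=diag)
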
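"""Contrast-agent concentration, relaxation-rate change and steady-state CBV.

Core relations (chi in ppm, concentrations in mM, CBV in mL/100 g):

* concentration from susceptibility:  [CA] = (chi - chi0) / chi_mol
* relaxation change from magnitude:   dR2* = -(1/TE) ln(S / S0)
* steady-state blood volume:
      CBV = 100 (1/rho) (1 - Hct_LV)/(1 - Hct_SV) * dchi_tissue/dchi_blood
  and the analogous expression with dR2* in place of dchi, which is only
  unbiased when tissue and blood share the same relaxivity.

The blood susceptibility change is measured from drift-corrected,
*unfiltered* phase in a draining-vein ROI via the infinite-cylinder
relation, because PDF-filtered maps are unreliable at the brain edge
where the vein runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Tuple

import numpy as np
from scipy import ndimage, stats

from .config import AcquisitionParams, PhysioConstants, SteadyStateWindows
from .kernels import wrap_phase
from .phantom import DynamicSeries, Phantom
from .qsm import FieldSeries, SusceptibilitySeries, cylinder_susceptibility


@dataclass
class VesselROI:
    """Pixels inside the draining vein and its angle to B0 (rad)."""

    pixel_indices: np.ndarray  # (n, 3)
    theta: float = 0.0

    def __post_init__(self) -> None:
        if len(self.pixel_indices) < 1:
            raise ValueError("vessel ROI needs at least one pixel")


@dataclass
class CBVResult:
    region: str
    delta_tissue: float
    delta_blood: float
    cbv: float
    method: Literal["qsm", "dr2s"]

    def __post_init__(self) -> None:
        if not np.isfinite(self.cbv):
            raise ValueError("CBV is not finite")


@dataclass
class RelaxivityFit:
    slope: float  # r2* (mM^-1 s^-1)
    intercept: float  # s^-1
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("relaxivity fit needs >= 3 points")


def default_vessel_roi(phantom: Phantom, n_pixels: int = 3) -> VesselROI:
    """``n_pixels`` voxels at the axis of the phantom's vein cylinder,
    taken at the mid-slice along B0 (deepest inside the vessel)."""
    idx = np.argwhere(phantom.masks["vessel"])
    if len(idx) == 0:
        raise ValueError("vessel mask is empty")
    zc = int(np.median(idx[:, 2]))
    in_slice = idx[idx[:, 2] == zc]
    center = in_slice[:, :2].mean(axis=0)
    d = np.linalg.norm(in_slice[:, :2] - center, axis=1)
    pick = in_slice[np.argsort(d)[:n_pixels]]
    return VesselROI(pixel_indices=pick, theta=phantom.vessel_angle)


def concentration_from_susceptibility(
        chi_shifted: SusceptibilitySeries, windows: SteadyStateWindows,
        physio: PhysioConstants) -> np.ndarray:
    """Voxelwise concentration (mM) from a CSF-shifted susceptibility series.

    chi0 is the per-voxel mean over the baseline window; the factor 1000
    converts M to mM given chi in ppm and chi_mol in ppm/M.
    """
    if chi_shifted.reference_state != "csf_shifted":
        raise ValueError("concentration requires a CSF-shifted series; "
                         "apply shift_susceptibility first")
    chi0 = chi_shifted.chi[..., windows.pre_slice()].mean(axis=-1)
    return (chi_shifted.chi - chi0[..., None]) / physio.chi_mol * 1000.0


def delta_r2star(series: DynamicSeries,
                 windows: SteadyStateWindows) -> np.ndarray:
    """Voxelwise dR2* (s^-1); NaN flags voxels with non-positive signal."""
    s0 = series.magnitude[..., windows.pre_slice()].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = series.magnitude / s0[..., None]
        out = -np.log(ratio) / series.params.te
    bad = (series.magnitude <= 0) | (s0[..., None] <= 0)
    out[bad] = np.nan
    return out


def window_delta(series_4d: np.ndarray, windows: SteadyStateWindows,
                 mask: np.ndarray | None = None,
                 erode: int = 0) -> float:
    """post-window mean minus pre-window mean, averaged over ``mask``.

    ``erode`` shrinks the region mask to reduce boundary partial-volume
    contamination of the regional mean.
    """
    nt = series_4d.shape[-1]
    if mask is None:
        pre = np.nanmean(series_4d[..., windows.pre_slice()])
        post = np.nanmean(series_4d[..., windows.post_slice(nt)])
        return float(post - pre)
    mask = np.asarray(mask, dtype=bool)
    if erode:
        eroded = ndimage.binary_erosion(mask, iterations=erode)
        if eroded.any():
            mask = eroded
    vox = series_4d[mask]
    pre = np.nanmean(vox[:, windows.pre_slice()])
    post = np.nanmean(vox[:, windows.post_slice(nt)])
    return float(post - pre)


def blood_delta_chi(phase_corrected: FieldSeries, vessel: VesselROI,
                    windows: SteadyStateWindows,
                    params: AcquisitionParams) -> float:
    """Blood susceptibility change (ppm) from drift-corrected vein phase.

    Window-mean vessel phase is converted per window through the
    infinite-cylinder relation; the difference post - pre is returned.
    """
    if phase_corrected.unit != "rad":
        raise ValueError("vessel phase must be in rad (unfiltered phase)")
    i, j, k = np.asarray(vessel.pixel_indices).T
    curves = phase_corrected.values[i, j, k, :]
    nt = curves.shape[-1]
    # Vein phase can exceed pi against its surroundings at high CA
    # concentration, where spatial unwrapping of the sub-voxel jump is
    # ambiguous by 2*pi*k.  Re-wrapping each pixel's curve around its own
    # baseline removes that ambiguity, since the CA-induced deviation
    # within the measurement windows stays below pi.
    base = curves[:, windows.pre_slice()].mean(axis=1, keepdims=True)
    curves = base + wrap_phase(curves - base)
    phi_pre = float(curves[:, windows.pre_slice()].mean())
    phi_post = float(curves[:, windows.post_slice(nt)].mean())
    chi_pre = cylinder_susceptibility(phi_pre, vessel.theta, params)
    chi_post = cylinder_susceptibility(phi_post, vessel.theta, params)
    return chi_post - chi_pre


def cbv_qsm(delta_chi_tissue: float, delta_chi_blood: float,
            physio: PhysioConstants, region: str = "tissue") -> CBVResult:
    """Steady-state CBV (mL/100 g) from susceptibility differences."""
    if delta_chi_blood == 0:
        raise ValueError("blood susceptibility difference is zero")
    cbv = (100.0 / physio.rho) * physio.hct_ratio \
        * (delta_chi_tissue / delta_chi_blood)
    return CBVResult(region=region, delta_tissue=delta_chi_tissue,
                     delta_blood=delta_chi_blood, cbv=cbv, method="qsm")


def cbv_dr2s(dr2s_tissue: float, dr2s_blood: float,
             physio: PhysioConstants, region: str = "tissue") -> CBVResult:
    """Steady-state CBV from dR2* differences (relaxivity-biased variant)."""
    if dr2s_blood == 0:
        raise ValueError("blood dR2* difference is zero")
    cbv = (100.0 / physio.rho) * physio.hct_ratio * (dr2s_tissue / dr2s_blood)
    return CBVResult(region=region, delta_tissue=dr2s_tissue,
                     delta_blood=dr2s_blood, cbv=cbv, method="dr2s")


def cbv_map_qsm(chi_shifted: SusceptibilitySeries, delta_chi_blood: float,
                windows: SteadyStateWindows,
                physio: PhysioConstants) -> np.ndarray:
    """Voxelwise CBV map (mL/100 g) using the common blood denominator."""
    if delta_chi_blood == 0:
        raise ValueError("blood susceptibility difference is zero")
    nt = chi_shifted.n_timepoints
    pre = chi_shifted.chi[..., windows.pre_slice()].mean(axis=-1)
    post = chi_shifted.chi[..., windows.post_slice(nt)].mean(axis=-1)
    return (100.0 / physio.rho) * physio.hct_ratio \
        * (post - pre) / delta_chi_blood * chi_shifted.mask


def fit_relaxivity(dr2s_series: np.ndarray, conc_series: np.ndarray,
                   mask: np.ndarray, windows: SteadyStateWindows,
                   first_timepoint: int = 15) -> RelaxivityFit:
    """Tissue relaxivity r2* as the OLS slope of dR2* against [CA].

    Whole-mask means of both quantities are pooled from ``first_timepoint``
    (1-based) to the end of the series; earlier points are excluded (1-4:
    signal not yet in steady acquisition; 5-14: they define zero by
    construction).
    """
    mask = np.asarray(mask, dtype=bool)
    nt = dr2s_series.shape[-1]
    sel = slice(first_timepoint - 1, nt)
    x = np.nanmean(conc_series[mask][:, sel], axis=0)
    y = np.nanmean(dr2s_series[mask][:, sel], axis=0)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 pooled points for the relaxivity fit")
    if np.ptp(x) == 0:
        raise ValueError("concentration is constant; relaxivity undefined")
    res = stats.linregress(x, y)
    return RelaxivityFit(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r=float(res.rvalue), n_points=int(x.size))


def _round_half_up(x: float, decimals: int) -> float:
    f = 10.0**decimals
    return float(np.floor(x * f + 0.5) / f)


def theory_expected_values(
        peak_conc_range: Tuple[float, float] = (5.0, 10.0),
        peak_to_tail_ratio: float = 9.0,
        literature_cbv: Dict[str, float] | None = None,
        physio: PhysioConstants | None = None) -> Dict[str, Dict]:
    """Expected steady-state concentration and susceptibility changes.

    From an assumed peak blood concentration range and a peak-to-tail
    concentration ratio: blood tail concentration = peak/ratio, blood
    dchi = conc * chi_mol; tissue dchi follows by inverting the CBV
    relation with literature blood-volume values; tissue concentration is
    tissue dchi / chi_mol.  Reported roundings: 2 decimals for blood dchi
    (ppm), 3 decimals for tissue dchi (ppm).
    """
    if peak_to_tail_ratio <= 1:
        raise ValueError("peak_to_tail_ratio must exceed 1")
    physio = physio or PhysioConstants()
    literature_cbv = literature_cbv or {"wm": 1.91, "gm": 3.85}
    lo, hi = peak_conc_range
    out: Dict[str, Dict] = {}
    blood_conc = (lo / peak_to_tail_ratio, hi / peak_to_tail_ratio)
    blood_dchi = tuple(c * physio.chi_mol / 1000.0 for c in blood_conc)
    out["blood"] = {
        "conc_mM": blood_conc,
        "delta_chi_ppm": blood_dchi,
        "conc_mM_rounded": tuple(_round_half_up(c, 1) for c in blood_conc),
        "delta_chi_ppm_rounded": tuple(
            _round_half_up(c, 2) for c in blood_dchi),
    }
    for region, cbv in literature_cbv.items():
        factor = (cbv / 100.0) * physio.rho / physio.hct_ratio
        dchi = tuple(factor * b for b in blood_dchi)
        conc = tuple(d / physio.chi_mol * 1000.0 for d in dchi)
        out[region] = {
            "conc_mM": conc,
            "delta_chi_ppm": dchi,
            "conc_mM_rounded": tuple(_round_half_up(c, 2) for c in conc),
            "delta_chi_ppm_rounded": tuple(
                _round_half_up(d, 3) for d in dchi),
        }
    return out
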
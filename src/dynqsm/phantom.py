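"""Digital brain phantom with a contrast-agent bolus passage.

The phantom is an ellipsoidal "brain" containing a white-matter core, a
grey-matter shell, two ventricle-like CSF cavities and a straight
draining-vein cylinder running parallel to B0 near the posterior surface
(a stand-in for the superior sagittal sinus).  A gamma-variate bolus with
one recirculation echo and a steady-state tail drives a known blood-volume
map, and the dynamic complex MRI signal is synthesised with the same
dipole forward model that the reconstruction inverts: susceptibility ->
field -> phase at TE, and compartment-specific T2* decay for the
magnitude.  Everything downstream can therefore be checked against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .config import AcquisitionParams, PhysioConstants
from .kernels import dipole_kernel, apply_kernel, wrap_phase

#: Number of leading time points with strictly zero contrast agent.
N_BASELINE = 14

# Compartment constants (ppm, s^-1, a.u.).  Susceptibilities are relative
# to CSF; venous blood is strongly paramagnetic, myelinated WM slightly
# diamagnetic.
_CHI0 = {"csf": 0.0, "wm": -0.03, "gm": 0.02, "vessel": 0.27}
_R2S0 = {"csf": 1.0, "wm": 19.0, "gm": 16.0, "vessel": 30.0}
_S0 = {"csf": 1.0, "wm": 0.70, "gm": 0.85, "vessel": 0.90}
#: Literature steady-state blood volume (mL/100 g).
_CBV = {"wm": 1.91, "gm": 3.85}


@dataclass
class Phantom:
    """Ground-truth maps for one synthetic subject."""

    masks: Dict[str, np.ndarray]
    chi0_map: np.ndarray
    cbv_map: np.ndarray
    r2s0_map: np.ndarray
    s0_map: np.ndarray
    r2s_tissue_relaxivity: float = 85.0
    r2s_blood_relaxivity: float = 30.0
    vessel_angle: float = 0.0

    def __post_init__(self) -> None:
        for name in ("brain", "wm", "gm", "csf", "vessel"):
            if name not in self.masks:
                raise ValueError(f"missing mask '{name}'")
        tissue = ["wm", "gm", "csf", "vessel"]
        if "outer_csf" in self.masks:
            tissue.append("outer_csf")
        stack = np.stack([self.masks[m] for m in tissue])
        if stack.sum(axis=0).max() > 1:
            raise ValueError("tissue-class masks overlap")
        if np.any(self.cbv_map[self.masks["csf"]] != 0):
            raise ValueError("CBV must vanish in CSF")

    @property
    def shape(self):
        return self.chi0_map.shape

    def true_cbv(self, region: str) -> float:
        return float(np.mean(self.cbv_map[self.masks[region]]))


@dataclass
class BloodCurve:
    """Whole-blood contrast-agent concentration over the dynamic series."""

    times: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must match")

    @property
    def peak(self) -> float:
        return float(self.concentration.max())

    def tail_mean(self, n_tail: int = 5) -> float:
        return float(self.concentration[-n_tail:].mean())


@dataclass
class DynamicSeries:
    """Paired 4D magnitude and wrapped-phase volumes, time on the last axis."""

    magnitude: np.ndarray
    phase: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.ndim != 4:
            raise ValueError("expected 4D (x, y, z, t) arrays")
        if self.phase.size and (self.phase.max() > np.pi
                                or self.phase.min() <= -np.pi):
            raise ValueError("phase must be wrapped to (-pi, pi]")

    @property
    def n_timepoints(self) -> int:
        return self.magnitude.shape[-1]


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return acc <= 1.0


def build_phantom(grid_shape=(64, 64, 64), seed: int = 0) -> Phantom:
    """Construct the ground-truth phantom on an isotropic grid.

    Per-subject variability (CBV scale, baseline susceptibility jitter) is
    drawn deterministically from ``seed``, so distinct seeds act as
    distinct subjects while the geometry stays fixed.

    Raises
    ------
    ValueError
        If any grid dimension is below 32 (compartments no longer fit).
    """
    nx, ny, nz = grid_shape
    if min(grid_shape) < 32:
        raise ValueError("grid too small: each dimension must be >= 32")
    rng = np.random.default_rng(seed)

    # Brain spans ~60% of the FOV: the dipole field decays as r^-3 and the
    # FFT convolution is periodic, so a generous margin keeps wrap-around
    # contamination of the forward/inverse model negligible.
    center = np.array([nx / 2, ny / 2, nz / 2])
    brain_ax = np.array([0.30 * nx, 0.33 * ny, 0.315 * nz])
    brain = _ellipsoid(grid_shape, center, brain_ax)
    # Subarachnoid CSF layer between the cortex and the mask boundary, as
    # under a generously drawn processing mask in vivo.  Keeping the
    # cortical sources interior to the mask matters: background-field
    # removal treats field components attributable to sources at or
    # beyond the boundary as background.
    cortex_outer = _ellipsoid(grid_shape, center, 0.90 * brain_ax)
    inner = _ellipsoid(grid_shape, center, 0.58 * brain_ax)
    outer_csf = brain & ~cortex_outer

    vent_ax = np.array([0.041 * nx, 0.113 * ny, 0.075 * nz])
    csf = np.zeros(grid_shape, dtype=bool)
    for dx in (-0.0825 * nx, 0.0825 * nx):
        csf |= _ellipsoid(grid_shape, center + np.array([dx, 0, 0]), vent_ax)
    csf &= inner

    # Straight cylinder parallel to B0 (z) hugging the posterior brain
    # surface like the superior sagittal sinus: it touches the brain-mask
    # edge but lies outside it, as the dural sinus lies outside the pial
    # surface.  Spanning the full z extent makes the FFT-periodic cylinder
    # effectively infinite, so the closed-form interior field holds.
    radius = max(1.6, 0.028 * min(nx, ny))
    vy = center[1] + brain_ax[1] + radius + 1.0
    if vy + radius >= ny:
        raise ValueError("grid too small: vessel cylinder exceeds the FOV")
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cyl2d = (xx - center[0]) ** 2 + (yy - vy) ** 2 <= radius**2
    vessel = np.repeat(cyl2d[:, :, None], nz, axis=2)
    if not vessel.any():
        raise ValueError("grid too small: vessel cylinder is empty")

    wm = inner & ~csf
    gm = cortex_outer & ~inner

    chi0 = np.zeros(grid_shape)
    cbv = np.zeros(grid_shape)
    r2s0 = np.full(grid_shape, 0.0)
    s0 = np.zeros(grid_shape)

    # Between-subject blood-volume spread matching the ~40% coefficient of
    # variation reported for healthy cohorts.
    cbv_scale = float(np.exp(rng.normal(0.0, 0.35)))
    chi_jit = rng.normal(0.0, 0.002, size=3)
    for i, name in enumerate(("wm", "gm", "vessel")):
        mask = {"wm": wm, "gm": gm, "vessel": vessel}[name]
        chi0[mask] = _CHI0[name] + chi_jit[i]
        r2s0[mask] = _R2S0[name]
        s0[mask] = _S0[name]
    for m in (csf, outer_csf):
        chi0[m] = _CHI0["csf"]
        r2s0[m] = _R2S0["csf"]
        s0[m] = _S0["csf"]
    cbv[wm] = _CBV["wm"] * cbv_scale
    cbv[gm] = _CBV["gm"] * cbv_scale

    # Pure-blood voxels: the blood-volume value Eq.-style arithmetic would
    # assign to a 100% blood compartment.
    physio = PhysioConstants()
    cbv[vessel] = 100.0 * physio.hct_ratio / physio.rho

    masks = {"brain": brain, "wm": wm, "gm": gm, "csf": csf,
             "outer_csf": outer_csf, "vessel": vessel,
             "head": brain | vessel}
    return Phantom(masks=masks, chi0_map=chi0, cbv_map=cbv,
                   r2s0_map=r2s0, s0_map=s0)


def simulate_blood_curve(params: AcquisitionParams, peak_conc: float = 5.0,
                         peak_to_tail_ratio: float = 9.0,
                         seed: int = 0) -> BloodCurve:
    """Gamma-variate first pass + recirculation echo + steady-state plateau.

    The first ``N_BASELINE`` samples are exactly zero, the maximum equals
    ``peak_conc`` and the late tail converges to
    ``peak_conc / peak_to_tail_ratio``.  ``seed`` jitters the bolus shape
    (gamma-variate shape/scale, +-5%) without touching those contracts.
    """
    if peak_conc <= 0:
        raise ValueError("peak_conc must be positive")
    if peak_to_tail_ratio <= 1:
        raise ValueError("peak_to_tail_ratio must exceed 1")
    rng = np.random.default_rng(seed)
    alpha = 3.0 * (1 + rng.uniform(-0.05, 0.05))
    beta = 1.5 * (1 + rng.uniform(-0.05, 0.05))

    t = params.times
    tau = t - N_BASELINE * params.dt
    active = tau > 0
    tau_a = tau[active]

    def gv(x, a, b):
        x = np.maximum(x, 0.0)
        with np.errstate(invalid="ignore"):
            out = (x / (a * b)) ** a * np.exp(a - x / b)
        return np.where(x > 0, out, 0.0)

    first = gv(tau_a, alpha, beta)
    recirc = 0.25 * gv(tau_a - 10.0, 3.0, 3.0)
    shape = first + recirc
    plateau = (peak_conc / peak_to_tail_ratio) * (1.0 - np.exp(-tau_a / 6.0))

    amp = peak_conc
    for _ in range(4):  # fixed point: max of total == peak_conc
        total = amp * shape + plateau
        i = int(np.argmax(total))
        amp = (peak_conc - plateau[i]) / shape[i]
    conc = np.zeros_like(t)
    conc[active] = amp * shape + plateau
    return BloodCurve(times=t, concentration=conc)


def tissue_concentration_series(phantom: Phantom, blood: BloodCurve,
                                physio: PhysioConstants) -> np.ndarray:
    """Per-voxel contrast-agent concentration (mM), shape (x, y, z, t).

    Tissue scales the blood curve by its blood-volume fraction with the
    small-vessel hematocrit correction; vessel voxels carry the whole-blood
    curve directly; CSF and background stay at zero.
    """
    frac = (phantom.cbv_map / 100.0) * physio.rho / physio.hct_ratio
    frac = frac * (phantom.masks["wm"] | phantom.masks["gm"])
    conc = frac[..., None] * blood.concentration[None, None, None, :]
    conc[phantom.masks["vessel"], :] = blood.concentration
    return conc


def simulate_series(phantom: Phantom, blood: BloodCurve,
                    params: AcquisitionParams, physio: PhysioConstants,
                    noise_sd: float = 0.0, seed: int = 0) -> DynamicSeries:
    """Synthesise the dynamic complex acquisition and return magnitude/phase.

    Per time point: susceptibility = chi0 + chi_mol * [CA]; the field is the
    dipole convolution of that map plus a global drift of
    ``params.b0_drift_rate`` ppb per time point; phase = gamma*B0*TE*field
    wrapped to (-pi, pi]; magnitude decays as exp(-TE*(R2*0 + r2* [CA]))
    with the tissue relaxivity in parenchyma and the blood relaxivity in
    the vessel.  Complex Gaussian noise of sd ``noise_sd * s0`` (per voxel)
    is added before magnitude/phase extraction, so magnitude noise is
    Rician and phase noise scales inversely with local SNR.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if params.n_timepoints <= N_BASELINE:
        raise ValueError("series too short for the baseline window")
    rng = np.random.default_rng(seed)
    conc = tissue_concentration_series(phantom, blood, physio)
    kernel = dipole_kernel(phantom.shape, params.voxel_size)
    ppm_per_mm = physio.chi_mol / 1000.0

    relax = np.where(phantom.masks["vessel"],
                     phantom.r2s_blood_relaxivity,
                     phantom.r2s_tissue_relaxivity)
    nt = params.n_timepoints
    mag = np.empty(phantom.shape + (nt,), dtype=np.float64)
    pha = np.empty_like(mag)
    noise_scale = noise_sd * phantom.s0_map
    for it in range(nt):
        chi_t = phantom.chi0_map + ppm_per_mm * conc[..., it]
        field = apply_kernel(chi_t, kernel)
        field = field + params.b0_drift_rate * it / 1000.0
        phase_true = params.phase_per_ppm * field
        r2s = phantom.r2s0_map + relax * conc[..., it]
        mag_true = phantom.s0_map * np.exp(-params.te * r2s)
        sig = mag_true * np.exp(1j * phase_true)
        if noise_sd > 0:
            sig = sig + noise_scale * (rng.standard_normal(phantom.shape)
                                       + 1j * rng.standard_normal(phantom.shape))
        mag[..., it] = np.abs(sig)
        pha[..., it] = wrap_phase(np.angle(sig))
    return DynamicSeries(magnitude=mag, phase=pha, params=params)
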
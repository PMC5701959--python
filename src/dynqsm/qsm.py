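"""Dynamic QSM reconstruction: wrapped phase -> susceptibility maps.

Stages, applied per time point:

1. quality-guided phase unwrapping (:mod:`dynqsm.unwrap`);
2. background-field removal by projection onto dipole field (PDF):
   susceptibility sources restricted to the mask exterior are fitted by
   magnitude-weighted least squares and their field subtracted, leaving
   the local field of interior sources;
3. regularised dipole inversion, either a morphology-enabled
   (edge-preserving, L1) inversion or thresholded k-space division (TKD);
4. the closed-form infinite-cylinder phase -> susceptibility relation for
   vessel measurements on unfiltered phase.

The absolute level of the inverted maps is arbitrary (the dipole kernel
has no DC response); downstream code must shift them to a CSF reference
before values at different time points are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Literal

import numpy as np

from .config import AcquisitionParams, InversionConfig
from .kernels import (apply_kernel, dipole_kernel, gradient_adjoint,
                      gradient_forward)
from .phantom import DynamicSeries
from .unwrap import unwrap_3d


@dataclass
class FieldSeries:
    """4D field-map series with an explicit processing stage."""

    values: np.ndarray  # (x, y, z, t)
    mask: np.ndarray
    stage: Literal["unwrapped", "background-removed"]
    unit: Literal["rad", "ppm"] = "rad"
    diagnostics: Dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite field values inside mask")

    def in_ppm(self, params: AcquisitionParams) -> "FieldSeries":
        if self.unit == "ppm":
            return self
        return FieldSeries(values=self.values / params.phase_per_ppm,
                           mask=self.mask, stage=self.stage, unit="ppm",
                           diagnostics=dict(self.diagnostics))


@dataclass
class SusceptibilitySeries:
    """4D susceptibility maps (ppm); values meaningful only inside mask."""

    chi: np.ndarray
    mask: np.ndarray
    reference_state: Literal["unshifted", "csf_shifted"] = "unshifted"

    @property
    def n_timepoints(self) -> int:
        return self.chi.shape[-1]


def unwrap_phase(series: DynamicSeries, mask: np.ndarray) -> FieldSeries:
    """Unwrap every time point of a wrapped-phase series inside ``mask``.

    Residue voxels (neighbourhoods still inconsistent after unwrapping)
    are counted per time point in ``diagnostics['residues']`` instead of
    being corrected interactively.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    nt = series.n_timepoints
    out = np.empty_like(series.phase)
    residues = np.zeros(nt, dtype=int)
    for it in range(nt):
        res = unwrap_3d(series.phase[..., it], mask,
                        magnitude=series.magnitude[..., it])
        out[..., it] = res.phase
        residues[it] = res.n_residues
    return FieldSeries(values=out, mask=mask, stage="unwrapped", unit="rad",
                       diagnostics={"residues": residues})


def temporal_align(field: FieldSeries,
                   baseline: slice = slice(4, 14)) -> FieldSeries:
    """Re-wrap each voxel's unwrapped-phase time curve around its baseline.

    Spatial unwrapping is independent per time point, so each frame can
    carry local (and global) 2*pi*k offsets relative to the baseline
    frames — at high contrast-agent concentration the vein's phase jump
    against its surroundings is spatially undersampled and cannot be
    resolved within a frame.  Because the true temporal phase excursion
    within the measurement windows stays below pi per voxel, wrapping the
    deviation from the per-voxel baseline mean removes those offsets.
    This replaces the interactive 2*pi corrections a human operator would
    apply.  Frames near the bolus peak may retain errors in the vein,
    where the true excursion itself exceeds pi; the steady-state windows
    avoid them.
    """
    if field.unit != "rad" or field.stage != "unwrapped":
        raise ValueError("temporal alignment applies to unwrapped phase "
                         "in rad")
    from .kernels import wrap_phase

    base = field.values[..., baseline].mean(axis=-1, keepdims=True)
    vals = base + wrap_phase(field.values - base)
    diag = dict(field.diagnostics)
    diag["temporal_aligned"] = True
    return FieldSeries(values=vals, mask=field.mask, stage=field.stage,
                       unit="rad", diagnostics=diag)


def _normalised_weight(magnitude: np.ndarray, mask: np.ndarray) -> np.ndarray:
    w = np.where(mask, magnitude, 0.0)
    inside = w[mask]
    if inside.size == 0 or inside.mean() == 0:
        raise ValueError("magnitude weighting is identically zero in mask")
    return w / inside.mean()


def _pdf_fit_one(f: np.ndarray, mask: np.ndarray, exterior: np.ndarray,
                 w2: np.ndarray, kernel: np.ndarray, max_iter: int,
                 tol: float):
    """Early-stopped CG fit of exterior sources to one field volume.

    Returns (background_field, relative_residual, n_iterations).  Early
    stopping is deliberate: run to convergence, the unconstrained
    exterior basis can also mimic (and remove) the harmonic part of the
    field generated by sources inside the mask, so the iteration count
    acts as the regulariser, as in published implementations.

    The mask-mean of the field is removed before fitting (and never
    subtracted from the data): a spatially uniform offset carries no
    information about sources and must stay in the null component.
    """
    f = f - f[mask].mean() * mask
    b = exterior * apply_kernel(w2 * f, kernel)

    def normal_op(x):
        return exterior * apply_kernel(w2 * apply_kernel(x * exterior,
                                                         kernel), kernel)

    x = np.zeros_like(f)
    r = b.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    b_norm = np.sqrt(rs) + 1e-30
    n_it = 0
    while np.sqrt(rs) / b_norm >= tol and n_it < max_iter:
        ap = normal_op(p)
        alpha = rs / (float(np.vdot(p, ap).real) + 1e-30)
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.vdot(r, r).real)
        p = r + (rs_new / rs) * p
        rs = rs_new
        n_it += 1
    return apply_kernel(x * exterior, kernel), np.sqrt(rs) / b_norm, n_it


def remove_background_pdf(field: FieldSeries, mask: np.ndarray,
                          magnitude: np.ndarray | None = None,
                          max_iter: int = 60, tol: float = 5e-3,
                          voxel_size=(1.0, 1.0, 1.0),
                          max_modes: int = 8,
                          baseline: slice = slice(4, 14)) -> FieldSeries:
    """Projection onto dipole field for a dynamic field series.

    Susceptibility sources restricted to the mask exterior are fitted by
    magnitude-weighted least squares (conjugate gradients on the normal
    equations, early-stopped) and their field is subtracted; the local
    field of interior sources is retained.

    The fit is nonlinear in its input when early-stopped, so running it
    frame by frame would remove slightly different components from
    different frames and corrupt post-minus-pre differences.  Two
    measures make the removal act as one fixed linear projection on the
    dynamic content: (1) the baseline-window mean field is processed
    separately from the baseline-subtracted dynamic remainder, so the
    large static anatomy does not steer what is removed from the
    contrast-agent-induced changes; (2) the dynamic remainder, which is
    low-rank in time (a bolus mode plus noise), is factorised by a
    temporal SVD, the fit runs once per retained mode, and the per-frame
    background is the corresponding linear combination — at a fraction
    of the per-frame cost.

    ``baseline`` selects the frames averaged for the static part.
    """
    if field.stage != "unwrapped":
        raise ValueError("PDF expects an unwrapped field series")
    mask = np.asarray(mask, dtype=bool)
    exterior = ~mask
    shape = mask.shape
    kernel = dipole_kernel(shape, voxel_size)
    if magnitude is None:
        w = mask.astype(float)
    else:
        w = _normalised_weight(magnitude, mask)
    w2 = w * w

    nt = field.values.shape[-1]
    flat = (field.values * mask[..., None]).reshape(-1, nt)
    # The mask-mean of each frame carries no source information (uniform
    # offsets are in the dipole null space and the downstream CSF shift
    # re-references every frame): remove it explicitly so the result is
    # exactly invariant to uniform field offsets.
    col_means = flat[mask.reshape(-1), :].mean(axis=0)
    flat = flat - col_means[None, :] * mask.reshape(-1, 1)
    if nt > 1 and flat[:, baseline].shape[1] > 0:
        base = flat[:, baseline].mean(axis=1)
    else:
        base = flat[:, 0]
    bg_base, res_base, it_base = _pdf_fit_one(base.reshape(shape), mask,
                                              exterior, w2, kernel,
                                              max_iter, tol)
    background = np.broadcast_to(bg_base.reshape(-1, 1), flat.shape).copy()
    mode_residuals = [res_base]
    mode_iters = [it_base]
    keep = 0
    if nt > 1:
        dyn = flat - base[:, None]
        u, s, vt = np.linalg.svd(dyn, full_matrices=False)
        keep = min(max_modes, int((s > 1e-9 * (s[0] + 1e-30)).sum()))
        for m in range(keep):
            mode = (u[:, m] * s[m]).reshape(shape)
            bg, res, n_it = _pdf_fit_one(mode, mask, exterior, w2, kernel,
                                         max_iter, tol)
            background += bg.reshape(-1, 1) * vt[m][None, :]
            mode_residuals.append(res)
            mode_iters.append(n_it)
    local = (flat - background).reshape(field.values.shape) \
        * mask[..., None]
    mode_residuals = np.asarray(mode_residuals)
    mode_iters = np.asarray(mode_iters)
    diag = dict(field.diagnostics)
    diag.update(pdf_residual=mode_residuals, pdf_iterations=mode_iters,
                pdf_converged=mode_residuals < tol, pdf_rank=keep)
    return FieldSeries(values=local, mask=mask, stage="background-removed",
                       unit=field.unit, diagnostics=diag)


def morphology_mask(magnitude: np.ndarray, mask: np.ndarray,
                    edge_percentile: float = 70.0) -> np.ndarray:
    """Binary smoothness mask: 1 where the magnitude gradient is weak.

    Voxels whose gradient magnitude exceeds the given percentile (within
    the brain mask) are treated as anatomical edges and excluded from the
    smoothness penalty, so real boundaries are not blurred away.
    """
    g = gradient_forward(magnitude.astype(float))
    gmag = np.sqrt((g**2).sum(axis=0))
    thr = np.percentile(gmag[mask], edge_percentile)
    return (gmag <= thr) & mask


def _tkd_kernel(kernel: np.ndarray, threshold: float) -> np.ndarray:
    sign = np.where(kernel >= 0, 1.0, -1.0)
    return sign * np.maximum(np.abs(kernel), threshold)


def invert_dipole(local_field: FieldSeries, magnitude: np.ndarray,
                  mask: np.ndarray, cfg: InversionConfig,
                  params: AcquisitionParams | None = None,
                  voxel_size=(1.0, 1.0, 1.0)) -> SusceptibilitySeries:
    """Per-time-point dipole inversion of a background-removed field series.

    ``tkd`` divides by the truncated kernel (fast, linear); an optional
    point-spread correction rescales by the mean kernel attenuation so
    region means are approximately unbiased.  ``medi_like`` minimises

        lam * ||W (D chi - f)||^2 + || M grad chi ||_1

    by iteratively reweighted least squares with conjugate-gradient inner
    solves; W is the normalised magnitude, M the morphology mask.  Larger
    ``lam`` trusts the data more and yields higher tissue contrast.
    """
    if local_field.stage != "background-removed":
        raise ValueError("inversion expects a background-removed field")
    fs = local_field if local_field.unit == "ppm" else local_field.in_ppm(
        _require_params(params))
    mask = np.asarray(mask, dtype=bool)
    if not np.all(np.isfinite(fs.values[mask])):
        raise ValueError("non-finite field values inside mask")
    kernel = dipole_kernel(mask.shape, voxel_size)
    nt = fs.values.shape[-1]
    chi = np.empty_like(fs.values)

    if cfg.method == "tkd":
        dt = _tkd_kernel(kernel, cfg.tkd_threshold)
        gain = kernel / dt
        gain.flat[0] = 0.0
        scale = float(gain.mean()) if cfg.tkd_psf_correction else 1.0
        for it in range(nt):
            fk = np.fft.fftn(fs.values[..., it] * mask)
            x = np.fft.ifftn(fk / dt).real / scale
            chi[..., it] = np.where(mask, x, 0.0)
        return SusceptibilitySeries(chi=chi, mask=mask,
                                    reference_state="unshifted")

    w = _normalised_weight(magnitude, mask)
    w2 = w * w
    m_edge = morphology_mask(magnitude, mask, cfg.edge_percentile)
    mf = m_edge.astype(float)
    eps = 1e-6
    for it in range(nt):
        f = fs.values[..., it] * mask
        atb = cfg.lam * apply_kernel(w2 * f, kernel)
        x = np.zeros(mask.shape)
        for _outer in range(cfg.irls_outer):
            g = gradient_forward(x) * mf
            u = 1.0 / np.sqrt(g**2 + eps)

            def hess(v):
                data = cfg.lam * apply_kernel(w2 * apply_kernel(v, kernel),
                                              kernel)
                reg = gradient_adjoint(gradient_forward(v) * mf * u)
                return data + reg

            r = atb - hess(x)
            p = r.copy()
            rs = float(np.vdot(r, r).real)
            rs0 = rs
            for _inner in range(cfg.max_iter):
                if rs <= cfg.tol**2 * rs0:
                    break
                ap = hess(p)
                alpha = rs / (float(np.vdot(p, ap).real) + 1e-30)
                x = x + alpha * p
                r = r - alpha * ap
                rs_new = float(np.vdot(r, r).real)
                p = r + (rs_new / rs) * p
                rs = rs_new
        chi[..., it] = np.where(mask, x, 0.0)
    return SusceptibilitySeries(chi=chi, mask=mask,
                                reference_state="unshifted")


def _require_params(params: AcquisitionParams | None) -> AcquisitionParams:
    if params is None:
        raise ValueError("field series is in rad; acquisition parameters "
                         "are required to convert to ppm")
    return params


def cylinder_susceptibility(phase_shift: float, theta: float,
                            params: AcquisitionParams,
                            epsilon: float = 0.05) -> float:
    """Susceptibility (ppm) of an infinite cylinder from its interior phase.

    chi = 6 phi / (gamma TE (3 cos^2 theta - 1) B0), with theta the angle
    between cylinder axis and B0.  Near the magic angle the denominator
    vanishes and the relation is undefined.
    """
    geom = 3.0 * np.cos(theta) ** 2 - 1.0
    if abs(geom) <= epsilon:
        raise ValueError(
            f"theta={theta:.4f} rad is within epsilon of the magic angle; "
            "the cylinder relation degenerates (3cos^2(theta)-1 ~ 0)")
    return float(6.0 * phase_shift / (geom * params.phase_per_ppm))
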
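"""Fourier dipole kernel and small field/phase helpers.

The unit dipole response in k-space is D(k) = 1/3 - kz^2/|k|^2 with the
z axis along B0, defined on the continuous frequency coordinates of the
FFT grid; D(0) := 0, i.e. the spatially uniform field component is
demodulated away.  The same kernel object is used by the forward phantom
simulation, the background-field fit and the dipole inversion, so forward
and inverse models are exactly consistent.
"""

from __future__ import annotations

import numpy as np


def dipole_kernel(shape, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """D(k) on the FFT grid of ``shape``, B0 along the last (z) axis."""
    kx = np.fft.fftfreq(shape[0], d=voxel_size[0])
    ky = np.fft.fftfreq(shape[1], d=voxel_size[1])
    kz = np.fft.fftfreq(shape[2], d=voxel_size[2])
    kx, ky, kz = np.meshgrid(kx, ky, kz, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kz**2 / k2
    d[0, 0, 0] = 0.0
    return d


def forward_field(chi_map: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
                  kernel: np.ndarray | None = None) -> np.ndarray:
    """Field perturbation (same units as ``chi_map``) from a susceptibility map.

    Linear, shift-covariant dipole convolution via FFT; the output has zero
    spatial mean over the FOV (D(0) = 0 convention).
    """
    chi_map = np.asarray(chi_map)
    if not np.all(np.isfinite(chi_map)):
        raise ValueError("chi_map must be finite")
    if kernel is None:
        kernel = dipole_kernel(chi_map.shape, voxel_size)
    return np.fft.ifftn(kernel * np.fft.fftn(chi_map)).real


def apply_kernel(vol: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT-multiply ``vol`` by a precomputed real k-space kernel."""
    return np.fft.ifftn(kernel * np.fft.fftn(vol)).real


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap into (-pi, pi]."""
    return np.pi - np.mod(np.pi - phase, 2.0 * np.pi)


def gradient_forward(vol: np.ndarray) -> np.ndarray:
    """Forward-difference gradient, shape (3, *vol.shape), periodic edges."""
    g = np.empty((3,) + vol.shape, dtype=vol.dtype)
    for ax in range(3):
        g[ax] = np.roll(vol, -1, axis=ax) - vol
    return g


def gradient_adjoint(g: np.ndarray) -> np.ndarray:
    """Adjoint (negative divergence) of :func:`gradient_forward`."""
    out = np.zeros(g.shape[1:], dtype=g.dtype)
    for ax in range(3):
        out += np.roll(g[ax], 1, axis=ax) - g[ax]
    return out
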
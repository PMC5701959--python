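"""Quality-guided region-growing phase unwrapping.

Voxels are unwrapped in order of a quality score so that reliable
(low-noise, spatially coherent) regions are resolved first and errors in
noisy voxels cannot propagate inward.  Quality is the local coherence of
the wrapped phase gradient weighted by the magnitude image, so low-signal
voxels rank last.  Each connected component of the mask is unwrapped
independently and keeps its own arbitrary 2*pi*k offset — the absolute
phase level carries no information downstream.

Voxels whose unwrapped value still jumps by more than pi against an
already-unwrapped neighbour are flagged as residues rather than silently
accepted; callers decide what to do with them.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .kernels import wrap_phase

_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                     (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass
class UnwrapResult:
    phase: np.ndarray
    residue_mask: np.ndarray

    @property
    def n_residues(self) -> int:
        return int(self.residue_mask.sum())


def quality_map(phase: np.ndarray, magnitude: np.ndarray | None = None,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Higher = unwrap earlier.  Coherence of wrapped second differences,
    multiplied by the (normalised) magnitude when available."""
    rough = np.zeros_like(phase)
    for ax in range(3):
        fwd = wrap_phase(np.roll(phase, -1, axis=ax) - phase)
        bwd = wrap_phase(phase - np.roll(phase, 1, axis=ax))
        rough += (fwd - bwd) ** 2
    q = 1.0 / (np.sqrt(rough) + 1e-6)
    if magnitude is not None:
        m = magnitude / (magnitude.max() + 1e-30)
        q = q * (m + 1e-3)
    if mask is not None:
        q = np.where(mask, q, 0.0)
    return q


def _has_wraps(phase: np.ndarray, mask: np.ndarray) -> bool:
    """True if any within-mask neighbour difference reaches +-pi."""
    for ax in range(3):
        d = np.diff(phase, axis=ax)
        both = np.logical_and(np.take(mask, range(mask.shape[ax] - 1), axis=ax),
                              np.take(mask, range(1, mask.shape[ax]), axis=ax))
        if np.any(np.abs(d[both]) >= np.pi):
            return True
    return False


def unwrap_3d(phase: np.ndarray, mask: np.ndarray,
              magnitude: np.ndarray | None = None) -> UnwrapResult:
    """Unwrap one wrapped 3D phase volume inside ``mask``.

    Returns the unwrapped phase (input values outside the mask) and a
    boolean residue mask of voxels whose neighbourhood is inconsistent
    even after unwrapping.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    # Fast path: no neighbour difference reaches pi, so region growing
    # would never add a 2*pi offset and the output equals the input.
    if not _has_wraps(phase, mask):
        return UnwrapResult(phase=phase.copy(),
                            residue_mask=np.zeros_like(mask))

    quality = quality_map(phase, magnitude, mask)
    out = phase.astype(np.float64).copy()
    visited = ~mask  # outside-mask voxels are never touched
    shape = phase.shape
    two_pi = 2.0 * np.pi

    order = np.argsort(quality[mask])[::-1]
    seeds = np.argwhere(mask)[order]
    counter = 0
    heap: list = []

    def push_neighbors(idx):
        nonlocal counter
        x, y, z = idx
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            nx, ny, nz = x + dx, y + dy, z + dz
            if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2] and not visited[nx, ny, nz]):
                counter += 1
                heapq.heappush(heap, (-quality[nx, ny, nz], counter,
                                      (nx, ny, nz), (x, y, z)))

    for seed in seeds:
        s = tuple(seed)
        if visited[s]:
            continue
        visited[s] = True  # seed keeps its wrapped value (free 2*pi*k)
        push_neighbors(s)
        while heap:
            _, _, v, ref = heapq.heappop(heap)
            if visited[v]:
                continue
            visited[v] = True
            out[v] = out[v] + two_pi * np.round((out[ref] - out[v]) / two_pi)
            push_neighbors(v)

    residue = np.zeros(shape, dtype=bool)
    for ax in range(3):
        d = np.abs(np.diff(out, axis=ax)) > np.pi
        both = np.logical_and(
            np.take(mask, range(mask.shape[ax] - 1), axis=ax),
            np.take(mask, range(1, mask.shape[ax]), axis=ax))
        bad = d & both
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, shape[ax] - 1)
        hi[ax] = slice(1, shape[ax])
        residue[tuple(lo)] |= bad
        residue[tuple(hi)] |= bad
    return UnwrapResult(phase=out, residue_mask=residue)
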
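"""Forward model: per-atom Gaussian mixture with a uniform background.

An atom contributes intensity ``Z_i · exp(-|v - x_i|² / B_i²)`` at a voxel
centre ``v``; the simulated map is the sum over atoms plus a uniform
background term ``E`` that absorbs intensity not explained by any atom.
Each atom's contribution is truncated to a sphere of radius
``cutoff_sigma · B_i`` (exactly zero outside), which also defines the
voxel support used by the maximisation step and by support-restricted
scores.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .grid import DensityMap
from .models import Atom, AtomicModel

log = logging.getLogger(__name__)

__all__ = [
    "GMMState",
    "ResponsibilityField",
    "atom_intensity",
    "simulate_map",
    "responsibilities",
    "support_mask",
]


def atom_intensity(atom: Atom, point: np.ndarray) -> float:
    """Gaussian intensity of one atom at a real-space point (Å).

    ``Z · exp(-|v - x|² / B²)`` — the width convention used throughout:
    B is the length scale of the exponent without an extra factor 2.
    """
    r2 = float(np.sum((np.asarray(point, dtype=np.float64) - atom.position) ** 2))
    return atom.atomic_number * np.exp(-r2 / atom.bwidth**2)


@dataclasses.dataclass
class GMMState:
    """An atomic model plus the background term and truncation cutoff."""

    model: AtomicModel
    background: float = 0.0
    cutoff_sigma: float = 4.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.background) and self.background >= 0):
            raise ValueError("background must be finite and >= 0")
        if self.cutoff_sigma < 3.0:
            log.warning(
                "cutoff_sigma %.2f < 3 truncates significant density", self.cutoff_sigma
            )

    def simulate(self, grid: DensityMap) -> DensityMap:
        return simulate_map(self, grid)

    def responsibilities(self, grid: DensityMap) -> "ResponsibilityField":
        return responsibilities(self, grid)


def _atom_block(
    grid: DensityMap, center: np.ndarray, radius: float
) -> tuple[tuple[slice, slice, slice], np.ndarray] | None:
    """Index slices of the voxel box around ``center`` and squared
    distances (Å²) of the box's voxel centres from it.  None if the box
    does not intersect the grid."""
    lo = np.ceil((center - radius - grid.origin) / grid.voxel_size).astype(int)
    hi = np.floor((center + radius - grid.origin) / grid.voxel_size).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.shape)
    if np.any(lo >= hi):
        return None
    slices = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    dx = grid.axis_coords(0)[slices[0]] - center[0]
    dy = grid.axis_coords(1)[slices[1]] - center[1]
    dz = grid.axis_coords(2)[slices[2]] - center[2]
    r2 = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    return slices, r2  # type: ignore[return-value]


def _iter_contributions(state: GMMState, grid: DensityMap):
    """Yield (atom index, slices, P_block) for atoms intersecting the grid.

    P_block is the truncated Gaussian contribution of the atom on its box
    (exactly zero beyond ``cutoff_sigma · B``).
    """
    m = state.model
    for i in range(len(m)):
        radius = state.cutoff_sigma * m.bwidth[i]
        blk = _atom_block(grid, m.positions[i], radius)
        if blk is None:
            continue
        slices, r2 = blk
        p = m.atomic_number[i] * np.exp(-r2 / m.bwidth[i] ** 2)
        p[r2 > radius**2] = 0.0
        yield i, slices, p


def simulate_map(state: GMMState, grid: DensityMap) -> DensityMap:
    """Simulated map on ``grid``: sum of truncated atom Gaussians plus E."""
    values = np.full(grid.shape, float(state.background), dtype=np.float64)
    for _, slices, p in _iter_contributions(state, grid):
        values[slices] += p
    return grid.like(values)


def support_mask(state: GMMState, grid: DensityMap) -> np.ndarray:
    """Boolean mask of voxels within ``cutoff_sigma · B_i`` of any atom."""
    mask = np.zeros(grid.shape, dtype=bool)
    m = state.model
    for i in range(len(m)):
        radius = state.cutoff_sigma * m.bwidth[i]
        blk = _atom_block(grid, m.positions[i], radius)
        if blk is None:
            continue
        slices, r2 = blk
        mask[slices] |= r2 <= radius**2
    return mask


@dataclasses.dataclass
class ResponsibilityField:
    """Per-atom and background voxel responsibilities γ on a grid.

    ``atom_entries[i]`` is ``(slices, γ_i block)`` for atom i (possibly
    ``None`` if the atom is entirely off-grid); ``gamma_err`` is the
    background responsibility on the full grid (zero outside the support);
    ``support`` flags voxels within cutoff of at least one atom for which
    the simulated map is positive.
    """

    atom_entries: list[tuple[tuple[slice, slice, slice], np.ndarray] | None]
    gamma_err: np.ndarray
    support: np.ndarray
    simulated: DensityMap

    def check_normalisation(self, tol: float = 1e-9) -> float:
        """Max |Σ_i γ_i + γ_err − 1| over the support (raises above tol)."""
        total = np.zeros(self.gamma_err.shape)
        for entry in self.atom_entries:
            if entry is None:
                continue
            slices, g = entry
            total[slices] += g
        total += self.gamma_err
        dev = float(np.max(np.abs(total[self.support] - 1.0))) if self.support.any() else 0.0
        if dev > tol:
            raise AssertionError(f"responsibility normalisation off by {dev:.3e}")
        return dev


def responsibilities(state: GMMState, grid: DensityMap) -> ResponsibilityField:
    """Mixture responsibilities γ_i(v) = P_i(v)/M_s(v), γ_err = E/M_s(v).

    Voxels inside the geometric support where ``M_s`` is zero (possible
    only when ``E = 0``) are excluded from the support and logged.
    """
    contribs = list(_iter_contributions(state, grid))
    ms = np.full(grid.shape, float(state.background), dtype=np.float64)
    for _, slices, p in contribs:
        ms[slices] += p
    geo = support_mask(state, grid)
    positive = ms > 0
    support = geo & positive
    n_dead = int(np.count_nonzero(geo & ~positive))
    if n_dead:
        log.info("excluded %d supported voxels with zero simulated intensity", n_dead)
    safe_ms = np.where(positive, ms, 1.0)
    entries: list[tuple[tuple[slice, slice, slice], np.ndarray] | None] = [
        None
    ] * len(state.model)
    for i, slices, p in contribs:
        entries[i] = (slices, np.where(positive[slices], p / safe_ms[slices], 0.0))
    gamma_err = np.where(support, state.background / safe_ms, 0.0)
    return ResponsibilityField(
        atom_entries=entries,
        gamma_err=gamma_err,
        support=support,
        simulated=grid.like(ms),
    )
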
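"""Synthetic fixtures: toy polymer models and ground-truth maps.

Every generator is deterministic per seed and returns its ground truth
(positions, widths, background) so that recovery experiments can compare
refined parameters against the values that generated the data.  The toy
chains are self-avoiding random walks with fixed bond lengths — they
exercise the refinement machinery without requiring any downloaded
structure or map.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .composite import ComponentSet
from .forward import GMMState, simulate_map
from .grid import DensityMap
from .models import AtomicModel

log = logging.getLogger(__name__)

__all__ = [
    "ToySpec",
    "make_toy_model",
    "make_ground_truth_map",
    "make_two_conformer_map",
    "make_component_set",
    "displace_segment",
]

_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]
_Z_CYCLE = [7, 6, 6, 8]  # N, C, C, O


@dataclasses.dataclass
class ToySpec:
    """Parameters of the toy fixtures.

    A chain of ``n_residues`` residues with ``atoms_per_residue`` bonded
    atoms each (bond length 1.5 Å), per-atom widths drawn uniformly from
    ``b_range`` (Å), simulated on a grid with ``grid_voxel`` Å voxels;
    ``noise_level`` sets the uniform background as a fraction of the peak
    simulated intensity.  ``directional_bias`` > 0 biases the walk along +x,
    producing an extended chain (used by fixtures that need spatially
    separated regions).
    """

    n_residues: int = 10
    atoms_per_residue: int = 4
    bond_length: float = 1.5
    b_range: tuple[float, float] = (0.5, 1.5)
    grid_voxel: float = 1.0
    noise_level: float = 0.05
    seed: int = 0
    cutoff_sigma: float = 4.0
    directional_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.atoms_per_residue < 1:
            raise ValueError("n_residues and atoms_per_residue must be >= 1")
        lo, hi = self.b_range
        if not (0 < lo <= hi <= 5.0):
            raise ValueError("b_range must lie within (0, 5]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def make_toy_model(spec: ToySpec) -> AtomicModel:
    """Self-avoiding random-walk chain with bonds, deterministic per seed.

    Atoms are placed sequentially at ``bond_length`` from the previous
    atom in a random direction, rejecting placements within 2.0 Å of any
    earlier non-bonded atom; Z cycles through N/C/C/O.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues * spec.atoms_per_residue
    positions = np.zeros((n, 3))
    min_dist = 2.0  # non-bonded contacts below ~2 Å do not occur in real structures
    for i in range(1, n):
        for attempt in range(200):
            direction = rng.standard_normal(3)
            direction[0] += spec.directional_bias
            direction /= np.linalg.norm(direction)
            cand = positions[i - 1] + spec.bond_length * direction
            d = np.linalg.norm(positions[: i - 1] - cand, axis=1) if i > 1 else np.array([np.inf])
            if not len(d) or d.min() >= min_dist:
                positions[i] = cand
                break
        else:
            raise RuntimeError(
                "self-avoiding walk failed to place an atom; reduce chain length "
                "or density"
            )
    names = _ATOM_NAMES[: spec.atoms_per_residue]
    if spec.atoms_per_residue == 1:
        names = ["CA"]
    if spec.atoms_per_residue > len(_ATOM_NAMES):
        raise ValueError(f"atoms_per_residue must be <= {len(_ATOM_NAMES)}")
    bwidth = rng.uniform(*spec.b_range, size=n)
    return AtomicModel(
        serial=np.arange(1, n + 1),
        element=["N" if z == 7 else "O" if z == 8 else "C" for z in
                 (np.array(_Z_CYCLE)[np.arange(n) % len(_Z_CYCLE)])],
        atomic_number=np.array(_Z_CYCLE)[np.arange(n) % len(_Z_CYCLE)],
        chain_id=["A"] * n,
        residue_index=np.arange(n) // spec.atoms_per_residue + 1,
        residue_name=["GLY"] * n,
        atom_name=[names[i % spec.atoms_per_residue] for i in range(n)],
        positions=positions,
        bwidth=bwidth,
        bonds=[(i, i + 1) for i in range(n - 1)],
    )


def _grid_for(model: AtomicModel, spec: ToySpec, margin: float | None = None) -> DensityMap:
    """Empty grid enclosing the model with a cutoff-width margin; cubic."""
    if margin is None:
        margin = spec.cutoff_sigma * max(model.bwidth.max(), 1.0) + spec.grid_voxel
    lo = model.positions.min(axis=0) - margin
    hi = model.positions.max(axis=0) + margin
    n = int(np.ceil((hi - lo).max() / spec.grid_voxel)) + 1
    n = max(n, 8)
    center = 0.5 * (lo + hi)
    origin = center - 0.5 * (n - 1) * spec.grid_voxel
    return DensityMap(
        values=np.zeros((n, n, n)),
        voxel_size=np.full(3, spec.grid_voxel),
        origin=origin,
    )


def make_ground_truth_map(
    model: AtomicModel,
    spec: ToySpec,
    gaussian_sd: float = 0.0,
) -> tuple[DensityMap, GMMState]:
    """Ground-truth map plus the generating mixture state.

    The map is the simulated mixture of the model plus a uniform
    background ``E = noise_level × peak intensity``; ``gaussian_sd`` adds
    seeded voxelwise Gaussian noise (absolute map units).
    """
    grid = _grid_for(model, spec)
    clean = simulate_map(GMMState(model, 0.0, spec.cutoff_sigma), grid)
    peak = float(clean.values.max()) if len(model) else 1.0
    background = spec.noise_level * peak
    truth = GMMState(model.copy(), background, spec.cutoff_sigma)
    values = clean.values + background
    if gaussian_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        values = values + rng.normal(0.0, gaussian_sd, size=values.shape)
    return grid.like(values), truth


def displace_segment(
    model: AtomicModel,
    displacement: np.ndarray | float,
    lo_residue: int,
    hi_residue: int,
) -> AtomicModel:
    """Copy of the model with residues ``lo..hi`` (inclusive) translated."""
    disp = np.asarray(displacement, dtype=np.float64)
    if disp.ndim == 0:
        disp = np.array([float(disp), 0.0, 0.0])
    out = model.copy()
    sel = (model.residue_index >= lo_residue) & (model.residue_index <= hi_residue)
    out.positions[sel] += disp
    return out


def make_two_conformer_map(
    model: AtomicModel,
    displacement: np.ndarray | float,
    fraction: float,
    spec: ToySpec,
) -> tuple[DensityMap, AtomicModel]:
    """Heterogeneous map: voxel average of two conformers.

    The middle third of the chain is displaced by ``displacement`` to form
    the second conformer; the map is ``(1−fraction)·M_A + fraction·M_B``
    plus the uniform background.  Returns the map and the displaced
    conformer.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_res = int(model.residue_index.max())
    lo = n_res // 3 + 1
    hi = 2 * n_res // 3
    conf_b = displace_segment(model, displacement, lo, hi)
    grid = _grid_for(model, spec)
    map_a = simulate_map(GMMState(model, 0.0, spec.cutoff_sigma), grid)
    map_b = simulate_map(GMMState(conf_b, 0.0, spec.cutoff_sigma), grid)
    mixed = (1.0 - fraction) * map_a.values + fraction * map_b.values
    background = spec.noise_level * float(mixed.max())
    return grid.like(mixed + background), conf_b


def make_component_set(
    model: AtomicModel,
    n_components: int,
    overlap_fraction: float,
    spec: ToySpec,
) -> tuple[ComponentSet, DensityMap]:
    """Overlapping focused-reconstruction fixture.

    The chain is split into ``n_components`` residue windows overlapping
    by ``overlap_fraction`` of the window length; each component holds
    its window's atoms (duplicated in overlaps) with widths sharpest at
    the window centre, and a map simulated from them plus background.
    Returns the set and the full-model ground-truth map on the same grid.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    n_res = int(model.residue_index.max())
    grid = _grid_for(model, spec)
    stride = n_res / (n_components - (n_components - 1) * overlap_fraction)
    window = stride / (1.0 - overlap_fraction) if overlap_fraction else stride
    b_center, b_edge = spec.b_range
    components = []
    backgrounds = []
    for c in range(n_components):
        start = 1 + int(round(c * stride * (1.0 - overlap_fraction) if overlap_fraction else c * stride))
        stop = min(n_res, int(round(start + window - 1)))
        if c == n_components - 1:
            stop = n_res
        sel = (model.residue_index >= start) & (model.residue_index <= stop)
        comp = model.subset(np.flatnonzero(sel))
        # sharper widths near the window centre
        mid = 0.5 * (start + stop)
        half = max(0.5 * (stop - start), 1.0)
        t = np.abs(comp.residue_index - mid) / half
        comp.bwidth[:] = b_center + (b_edge - b_center) * np.clip(t, 0.0, 1.0)
        cmap = simulate_map(GMMState(comp, 0.0, spec.cutoff_sigma), grid)
        background = spec.noise_level * float(cmap.values.max())
        components.append((comp, grid.like(cmap.values + background)))
        backgrounds.append(background)
    truth = simulate_map(GMMState(model, 0.0, spec.cutoff_sigma), grid)
    cset = ComponentSet(
        components=components,
        consensus_grid=grid,
        backgrounds=backgrounds,
        cutoff_sigma=spec.cutoff_sigma,
    )
    return cset, truth
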
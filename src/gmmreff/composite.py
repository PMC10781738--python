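"""Responsibility-weighted composition of overlapping component maps.

Focused or multibody reconstructions of one complex are combined into a
single seam-free map: each component's fitted model simulates a component
map on a consensus grid; per-voxel component responsibilities (component
simulated intensity over the sum across components) then weight the
pre-aligned experimental maps, which are summed.  In overlap regions an
atom contributes only to the component where it is best resolved (lowest
width); its atomic number is zeroed in the others.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .forward import GMMState, simulate_map
from .grid import DensityMap, resample_to
from .models import AtomicModel

log = logging.getLogger(__name__)

__all__ = [
    "ComponentSet",
    "component_simulated_map",
    "component_responsibilities",
    "compose",
]


@dataclasses.dataclass
class ComponentSet:
    """Pre-aligned component maps with their fitted models.

    ``components`` is a list of ``(model, experimental map)`` pairs;
    ``consensus_grid`` defines the target geometry; ``backgrounds`` holds
    one background term per component (defaults to 0 — use each
    component's refined background when available).
    """

    components: list[tuple[AtomicModel, DensityMap]]
    consensus_grid: DensityMap
    backgrounds: list[float] | None = None
    cutoff_sigma: float = 4.0
    dedup: bool = True

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one component is required")
        for model, _ in self.components:
            if len(model) == 0:
                raise ValueError("component models must be non-empty")
        if self.backgrounds is None:
            self.backgrounds = [0.0] * len(self.components)
        if len(self.backgrounds) != len(self.components):
            raise ValueError("one background per component required")


def _retention_masks(cset: ComponentSet) -> list[np.ndarray]:
    """Per-component boolean masks of atoms whose Z is retained.

    Correspondence across components is by exact
    (chain_id, residue_index, atom_name).  An atom shared between
    components keeps its Z only in the component where its width is
    lowest; ties keep the earliest component (logged).  Atoms present in
    a single component are always retained.
    """
    best: dict[tuple, tuple[float, int]] = {}
    multiplicity: dict[tuple, int] = {}
    for c, (model, _) in enumerate(cset.components):
        for i in range(len(model)):
            key = (str(model.chain_id[i]), int(model.residue_index[i]), str(model.atom_name[i]))
            multiplicity[key] = multiplicity.get(key, 0) + 1
            cand = (float(model.bwidth[i]), c)
            if key not in best or cand < best[key]:
                best[key] = cand
    n_ties = 0
    masks = []
    for c, (model, _) in enumerate(cset.components):
        keep = np.ones(len(model), dtype=bool)
        for i in range(len(model)):
            key = (str(model.chain_id[i]), int(model.residue_index[i]), str(model.atom_name[i]))
            if multiplicity[key] > 1 and best[key][1] != c:
                keep[i] = False
                if best[key][0] == float(model.bwidth[i]):
                    n_ties += 1
        masks.append(keep)
    if n_ties:
        log.info(
            "%d shared atoms with tied widths kept in the earliest component", n_ties
        )
    return masks


def component_simulated_map(cset: ComponentSet, c: int) -> DensityMap:
    """Simulate component ``c`` on the consensus grid.

    Atoms losing the width competition against a corresponding atom in
    another component get Z = 0 (``dedup=False`` disables the rule); the
    component's background term is added.
    """
    model, _ = cset.components[c]
    model = model.copy()
    if cset.dedup and len(cset.components) > 1:
        keep = _retention_masks(cset)[c]
        model.atomic_number[~keep] = 0
    state = GMMState(model, cset.backgrounds[c], cset.cutoff_sigma)
    return simulate_map(state, cset.consensus_grid)


def component_responsibilities(cset: ComponentSet) -> list[DensityMap]:
    """Per-component weight maps γ_c(v) = M_c(v) / Σ_c M_c(v).

    Voxels where the denominator is zero get γ_c = 0 for every component
    (excluded from the composite).
    """
    sims = [component_simulated_map(cset, c) for c in range(len(cset.components))]
    total = np.sum([s.values for s in sims], axis=0)
    safe = np.where(total > 0, total, 1.0)
    return [
        cset.consensus_grid.like(np.where(total > 0, s.values / safe, 0.0))
        for s in sims
    ]


def compose(cset: ComponentSet) -> DensityMap:
    """Composite map: Σ_c γ_c(v) · M_e,c(v) on the consensus grid.

    Experimental maps are resampled to the consensus grid by trilinear
    interpolation (zero outside their bounding box).
    """
    gammas = component_responsibilities(cset)
    out = np.zeros(cset.consensus_grid.shape)
    for gamma, (_, emap) in zip(gammas, cset.components):
        resampled = resample_to(emap, cset.consensus_grid)
        out += gamma.values * resampled.values
    return cset.consensus_grid.like(out)
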
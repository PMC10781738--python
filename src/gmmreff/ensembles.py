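"""Width-driven model ensembles, ensemble-average maps and RMSF.

The refined per-atom widths encode local positional uncertainty.  An
ensemble member is drawn by sampling every atom from an isotropic Gaussian
centred on the anchor model, with per-coordinate variance equal to the
*shifted* width (widths rigidly shifted so their minimum is 0.25 Å), then
relaxed under an anchoring potential, a density-guided force and bond
restraints.  The ensemble-average map is the voxelwise mean of the maps
simulated from each member; RMSF is computed per residue anchor atom
about the ensemble mean structure.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize

from .forward import GMMState, simulate_map, support_mask
from .grid import DensityMap, trilinear_value_and_gradient
from .models import AtomicModel
from . import scoring

log = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "Ensemble",
    "shifted_bfactors",
    "perturb_model",
    "ensemble_energy",
    "refine_member",
    "sample_ensemble",
    "ensemble_map",
    "select_ensemble_size",
    "rmsf",
]

TWO_PI_CUBED = (2.0 * np.pi) ** 3


@dataclasses.dataclass
class EnsembleConfig:
    """Ensemble generation parameters.

    ``k_ens`` scales the anchoring potential (1000 by default); ``k_dens``
    scales the density-guided force (map-dependent, typically 5–200, 50 by
    default); widths are shifted so the minimum is ``b_shift_floor``
    (0.25 Å); the per-member minimisation uses at most ``relax_steps``
    energy evaluations.  ``step_time`` (fs) is metadata for external
    dynamics engines and is unused by the built-in minimiser.
    """

    k_ens: float = 1000.0
    k_dens: float = 50.0
    b_shift_floor: float = 0.25
    relax_steps: int = 2000
    step_time: float = 0.1
    max_models: int = 50
    plateau_tol: float = 1e-4
    seed: int = 0
    k_bond: float = 100.0
    cutoff_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.k_ens <= 0 or self.b_shift_floor <= 0:
            raise ValueError("k_ens and b_shift_floor must be positive")
        if self.max_models < 1:
            raise ValueError("max_models must be >= 1")


@dataclasses.dataclass
class Ensemble:
    """An anchor model plus perturbed members (identical atom ordering)."""

    anchor: AtomicModel
    members: list[AtomicModel]
    seeds: list[int]

    def __post_init__(self) -> None:
        for mem in self.members:
            if len(mem) != len(self.anchor):
                raise ValueError("ensemble members must match the anchor atom count")

    def __len__(self) -> int:
        return len(self.members)

    def map(self, grid: DensityMap, background: float = 0.0) -> DensityMap:
        return ensemble_map(self, grid, background)

    def rmsf(self) -> pd.DataFrame:
        return rmsf(self)


def shifted_bfactors(model: AtomicModel, floor: float = 0.25) -> np.ndarray:
    """Widths rigidly shifted so the minimum equals ``floor`` (Å)."""
    return model.bwidth - model.bwidth.min() + floor


def member_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-member seeds (< 2^31) derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def perturb_model(
    anchor: AtomicModel, config: EnsembleConfig, member_seed: int
) -> AtomicModel:
    """Draw one member: each atom sampled from an isotropic Gaussian at the
    anchor position with per-coordinate variance equal to its shifted
    width (Å²).  Deterministic given ``member_seed``."""
    rng = np.random.default_rng(member_seed)
    sd = np.sqrt(shifted_bfactors(anchor, config.b_shift_floor))
    out = anchor.copy()
    out.positions += rng.standard_normal(out.positions.shape) * sd[:, None]
    return out


def ensemble_energy(
    position: np.ndarray,
    anchor_position: np.ndarray,
    bwidth: np.ndarray | float,
    k_ens: float = 1000.0,
) -> tuple[float, np.ndarray]:
    """Anchoring potential of the ensemble relaxation.

    ``E = k/sqrt((2π)³·B³) · (1 − exp(−d²/B³))`` per atom with
    ``d = |x − x'|``; returns total energy and analytic gradient.
    Accepts one atom ((3,)) or N atoms ((N, 3)).
    """
    x = np.atleast_2d(np.asarray(position, dtype=np.float64))
    t = np.atleast_2d(np.asarray(anchor_position, dtype=np.float64))
    b = np.broadcast_to(np.asarray(bwidth, dtype=np.float64), (x.shape[0],))
    amp = k_ens / np.sqrt(TWO_PI_CUBED * b**3)
    diff = x - t
    d2 = np.sum(diff**2, axis=1)
    expterm = np.exp(-d2 / b**3)
    energy = float(np.sum(amp * (1.0 - expterm)))
    grad = (amp * expterm * 2.0 / b**3)[:, None] * diff
    if np.asarray(position).ndim == 1:
        return energy, grad[0]
    return energy, grad


def _member_energy(
    flat: np.ndarray,
    anchor: AtomicModel,
    bwidth: np.ndarray,
    exp_map: DensityMap | None,
    bonds: np.ndarray,
    bond_eq: np.ndarray,
    config: EnsembleConfig,
) -> tuple[float, np.ndarray]:
    pos = flat.reshape(-1, 3)
    energy, grad = ensemble_energy(pos, anchor.positions, bwidth, config.k_ens)
    if exp_map is not None and config.k_dens != 0.0:
        vals, g = trilinear_value_and_gradient(exp_map, pos)
        energy += float(np.sum(-config.k_dens * vals))
        grad += -config.k_dens * g
    if bonds.size:
        d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        r_safe = np.where(r > 1e-12, r, 1.0)
        energy += float(np.sum(config.k_bond * (r - bond_eq) ** 2))
        g = (2.0 * config.k_bond * (r - bond_eq) / r_safe)[:, None] * d
        np.add.at(grad, bonds[:, 0], g)
        np.add.at(grad, bonds[:, 1], -g)
    return energy, grad.ravel()


def refine_member(
    member: AtomicModel,
    anchor: AtomicModel,
    exp_map: DensityMap | None,
    config: EnsembleConfig,
) -> AtomicModel:
    """Relax a perturbed member by limited-memory quasi-Newton minimisation
    of the anchoring potential, the density-guided energy
    ``−k_dens · M_e(x_i)`` (trilinear) and harmonic bond restraints."""
    bwidth = shifted_bfactors(anchor, config.b_shift_floor)
    bonds = np.array(anchor.bonds, dtype=int).reshape(-1, 2)
    if bonds.size:
        bond_eq = np.linalg.norm(
            anchor.positions[bonds[:, 0]] - anchor.positions[bonds[:, 1]], axis=1
        )
    else:
        bond_eq = np.zeros(0)
    res = optimize.minimize(
        _member_energy,
        member.positions.ravel(),
        args=(anchor, bwidth, exp_map, bonds, bond_eq, config),
        jac=True,
        method="L-BFGS-B",
        options={"maxfun": config.relax_steps, "maxiter": config.relax_steps},
    )
    out = member.copy()
    out.positions[:] = res.x.reshape(-1, 3)
    return out


def sample_ensemble(
    anchor: AtomicModel,
    config: EnsembleConfig,
    n_members: int,
    exp_map: DensityMap | None = None,
    relax: bool = True,
) -> Ensemble:
    """Draw ``n_members`` perturbed (and optionally relaxed) members."""
    seeds = member_seeds(config.seed, n_members)
    members = []
    for s in seeds:
        mem = perturb_model(anchor, config, s)
        if relax:
            mem = refine_member(mem, anchor, exp_map, config)
        members.append(mem)
    return Ensemble(anchor=anchor.copy(), members=members, seeds=seeds)


def ensemble_map(
    ensemble: Ensemble, grid: DensityMap, background: float = 0.0
) -> DensityMap:
    """Voxelwise mean of the maps simulated from each member.

    Each member keeps its own widths; the background is shared.
    """
    if len(ensemble) < 1:
        raise ValueError("ensemble must have at least one member")
    acc = np.zeros(grid.shape)
    for mem in ensemble.members:
        acc += simulate_map(GMMState(mem, background), grid).values
    return grid.like(acc / len(ensemble))


def select_ensemble_size(
    anchor: AtomicModel,
    exp_map: DensityMap,
    config: EnsembleConfig,
    relax: bool = True,
) -> tuple[int, Ensemble]:
    """Grow the ensemble until the CCC of the ensemble-average map against
    the experimental map stops increasing (ΔCCC ≤ ``plateau_tol``) or
    ``max_models`` is reached.  The CCC is evaluated on the anchor model's
    support."""
    seeds = member_seeds(config.seed, config.max_models)
    mask = support_mask(GMMState(anchor, 0.0, config.cutoff_sigma), exp_map)
    members: list[AtomicModel] = []
    acc = np.zeros(exp_map.shape)
    last_ccc = -np.inf
    for j, s in enumerate(seeds, start=1):
        mem = perturb_model(anchor, config, s)
        if relax:
            mem = refine_member(mem, anchor, exp_map, config)
        members.append(mem)
        acc += simulate_map(GMMState(mem, 0.0), exp_map).values
        c = scoring.ccc(acc / j, exp_map.values, mask)
        if j > 1 and c - last_ccc <= config.plateau_tol:
            if c < last_ccc:  # reject the member that lowered the fit
                members.pop()
            else:
                last_ccc = c
            break
        last_ccc = c
    ens = Ensemble(anchor=anchor.copy(), members=members, seeds=seeds[: len(members)])
    log.info("ensemble size %d selected (CCC %.4f)", len(ens), last_ccc)
    return len(ens), ens


def rmsf(ensemble: Ensemble) -> pd.DataFrame:
    """Per-residue RMSF (Å) of the anchor atoms about the ensemble mean.

    ``RMSF_i = sqrt(mean_j |x_i(j) − ⟨x_i⟩|²)`` over members j, evaluated
    at each residue's Cα (C1′ for nucleotides); residues without an
    anchor atom are skipped (logged).
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least two members")
    anchors = ensemble.anchor.anchor_indices()
    n_skipped = len(ensemble.anchor.residue_groups()) - len(anchors)
    if n_skipped:
        log.info("rmsf: %d residues without an anchor atom skipped", n_skipped)
    idx = np.array(sorted(anchors.values()))
    stack = np.stack([mem.positions[idx] for mem in ensemble.members])
    mean = stack.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    keys = sorted(anchors.items(), key=lambda kv: kv[1])
    return pd.DataFrame(
        {
            "chain_id": [k[0][0] for k in keys],
            "residue_index": [k[0][1] for k in keys],
            "rmsf": vals,
        }
    )
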
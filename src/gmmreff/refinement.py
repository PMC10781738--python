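"""Expectation–maximisation refinement of positions and B-factors.

The refinement alternates an expectation step (simulate the map from the
current per-atom Gaussians plus background, compute voxel responsibilities)
with a maximisation step (responsibility-weighted position, width and
background updates).  Instead of assigning the maximised positions
directly, a biasing potential pulls atoms towards them, either exactly
(``mode="direct"``) or through the built-in restrained minimiser
(``mode="relaxer"``); external relaxation engines can be plugged in as a
callable ``(model, targets, config) -> model``.

The public surface follows the Model/Results idiom: build a
:class:`MapRefinement` from an atomic model and a density map, call
:meth:`~MapRefinement.fit`, and inspect the returned
:class:`RefinementResults`.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forward import GMMState, ResponsibilityField, responsibilities, simulate_map, support_mask
from .grid import DensityMap
from .models import AtomicModel
from . import scoring

log = logging.getLogger(__name__)

__all__ = [
    "RefinementConfig",
    "RefinementResults",
    "MapRefinement",
    "refine",
    "maximise_positions",
    "maximise_bfactors",
    "update_background",
    "restrain_bfactors",
    "gmm_energy",
    "relax",
    "polish_positions",
    "invert_second_moment",
]

#: "no improvement" guard against float noise in the convergence CCC
CCC_IMPROVEMENT_TOL = 1e-6


@dataclasses.dataclass
class RefinementConfig:
    """Tunable parameters of the refinement loop.

    Defaults: biasing-potential constant ``k_gmm = 1e5``; widths are kept in
    ``[b_floor, b_cap]`` Å with ``b_cap = 2.5`` (use 1.5 for membrane
    proteins); 25 width-only iterations precede positional refinement; the
    relaxer takes at most 2000 steps per iteration; the loop stops when the
    convergence CCC has not improved for 5 consecutive iterations, or after
    300 iterations.
    """

    k_gmm: float = 1e5
    b_cap: float = 2.5
    b_floor: float = 0.25
    b_only_iterations: int = 25
    relax_steps: int = 2000
    patience: int = 5
    max_iterations: int = 300
    residue_blend: float = 0.5
    mode: str = "direct"
    seed: int = 0
    cutoff_sigma: float = 4.0
    # descent steps completing the positional maximisation each iteration
    position_polish_steps: int = 50
    # built-in relaxer constants
    k_bond: float = 100.0
    k_repulsion: float = 10.0
    repulsion_radius: float = 2.0

    @classmethod
    def membrane(cls, **overrides) -> "RefinementConfig":
        """Membrane-protein preset: width cap 1.5 Å."""
        overrides.setdefault("b_cap", 1.5)
        return cls(**overrides)

    def __post_init__(self) -> None:
        if not (0 < self.b_floor < self.b_cap):
            raise ValueError("need 0 < b_floor < b_cap")
        if self.patience < 1 or self.max_iterations < 1:
            raise ValueError("patience and max_iterations must be >= 1")
        if not 0.0 <= self.residue_blend <= 1.0:
            raise ValueError("residue_blend must be in [0, 1]")
        if self.mode not in ("direct", "relaxer"):
            raise ValueError("mode must be 'direct' or 'relaxer'")


# -- maximisation step ----------------------------------------------------


def _weighted_sums(
    state: GMMState,
    exp_map: DensityMap,
    resp: ResponsibilityField,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-atom Σ W_i, Σ W_i·r(v) and Σ W_i·|r(v) − x_i|² over each atom's
    supported voxels, with W_i(v) = M_e(v)·γ_i(v)."""
    m = state.model
    n = len(m)
    wsum = np.zeros(n)
    wpos = np.zeros((n, 3))
    wvar = np.zeros(n)
    for i, entry in enumerate(resp.atom_entries):
        if entry is None:
            continue
        slices, gamma = entry
        w = exp_map.values[slices] * gamma
        wsum[i] = w.sum()
        cx = exp_map.axis_coords(0)[slices[0]]
        cy = exp_map.axis_coords(1)[slices[1]]
        cz = exp_map.axis_coords(2)[slices[2]]
        wpos[i, 0] = (w.sum(axis=(1, 2)) * cx).sum()
        wpos[i, 1] = (w.sum(axis=(0, 2)) * cy).sum()
        wpos[i, 2] = (w.sum(axis=(0, 1)) * cz).sum()
        dx = cx - m.positions[i, 0]
        dy = cy - m.positions[i, 1]
        dz = cz - m.positions[i, 2]
        r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        wvar[i] = (w * r2).sum()
    return wsum, wpos, wvar


def maximise_positions(
    state: GMMState,
    exp_map: DensityMap,
    resp: ResponsibilityField | None = None,
) -> np.ndarray:
    """Responsibility-weighted real-space mean position per atom.

    ``x'_i = Σ_v W_i(v)·r(v) / Σ_v W_i(v)`` with ``W_i = M_e·γ_i`` over the
    atom's supported voxels.  Atoms whose total weight is non-positive
    (empty or negative density) keep their current position (logged).
    """
    if resp is None:
        resp = responsibilities(state, exp_map)
    wsum, wpos, _ = _weighted_sums(state, exp_map, resp)
    targets = state.model.positions.copy()
    ok = wsum > 0
    targets[ok] = wpos[ok] / wsum[ok, None]
    n_bad = int(np.count_nonzero(~ok))
    if n_bad:
        log.warning("%d atoms had non-positive total weight; positions kept", n_bad)
    return targets


def variance_to_width(variance: np.ndarray | float) -> np.ndarray | float:
    """Continuum width for a 3-D radial second moment (Å²).

    For density ``exp(-r²/B²)`` the expected squared radial deviation is
    ``3B²/2``, so ``B = sqrt(2·variance/3)``.  This is the untruncated
    continuum limit of :func:`invert_second_moment`.
    """
    return np.sqrt(np.maximum(2.0 * np.asarray(variance, dtype=np.float64) / 3.0, 0.0))


#: bisection bracket and step count of the width-update moment inversion
WIDTH_BRACKET = (0.05, 12.0)
WIDTH_BISECTIONS = 60


def invert_second_moment(r2: np.ndarray, moment: float) -> float:
    """Width whose truncated, voxelised Gaussian has the given second moment.

    Solves ``Σ r²·e^(−r²/B²) / Σ e^(−r²/B²) = moment`` over the supplied
    squared voxel distances ``r2`` by bisection.  Because the sum runs over
    exactly the voxels used to measure the moment, truncation and
    discretisation cancel: a map simulated from the model reproduces the
    model's widths exactly.  Monotone in B; clamps at the bracket when the
    moment saturates.
    """
    r2 = np.asarray(r2, dtype=np.float64).ravel()

    def moment_of(width: float) -> float:
        w = np.exp(-r2 / (width * width))
        return float((r2 * w).sum() / w.sum())

    lo, hi = WIDTH_BRACKET
    if moment_of(hi) <= moment:
        return hi
    if moment_of(lo) >= moment:
        return lo
    for _ in range(WIDTH_BISECTIONS):
        mid = 0.5 * (lo + hi)
        if moment_of(mid) < moment:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def maximise_bfactors(
    state: GMMState,
    exp_map: DensityMap,
    resp: ResponsibilityField | None = None,
    b_floor: float = 0.25,
    b_cap: float = 2.5,
    dominance: float = 4.0,
) -> np.ndarray:
    """Width update: responsibility-weighted second moment per atom,
    inverted to the stored width convention.

    The moment ``Σ_v W_i(v)·|r(v) − x_i|² / Σ_v W_i(v)`` (``W_i = M_e·γ_i``)
    is measured over the atom's *signal-dominant* window — voxels within
    the radius where the atom's Gaussian still exceeds ``dominance × E``
    (never beyond the ``cutoff_sigma·B`` support, never below 1.5 voxels).
    Restricting to this window keeps the far field, where the uniform
    background dominates and would inflate the moment as r⁴, out of the
    estimate.  The measured moment is then mapped to a width with
    :func:`invert_second_moment` and clamped to ``[b_floor, b_cap]``.
    Atoms with zero total window weight keep their current width (logged).
    """
    if resp is None:
        resp = responsibilities(state, exp_map)
    m = state.model
    widths = m.bwidth.copy()
    background = state.background
    min_radius = 1.5 * float(np.max(exp_map.voxel_size))
    n_kept = 0
    for i, entry in enumerate(resp.atom_entries):
        if entry is None:
            continue
        z = m.atomic_number[i]
        if z <= 0:
            continue
        slices, gamma = entry
        b_i = m.bwidth[i]
        radius = state.cutoff_sigma * b_i
        if background > 0 and z > dominance * background:
            radius = min(radius, b_i * np.sqrt(np.log(z / (dominance * background))))
        radius = max(radius, min_radius)
        cx = exp_map.axis_coords(0)[slices[0]] - m.positions[i, 0]
        cy = exp_map.axis_coords(1)[slices[1]] - m.positions[i, 1]
        cz = exp_map.axis_coords(2)[slices[2]] - m.positions[i, 2]
        r2 = (
            cx[:, None, None] ** 2
            + cy[None, :, None] ** 2
            + cz[None, None, :] ** 2
        )
        window = r2 <= radius * radius
        w = (exp_map.values[slices] * gamma)[window]
        wsum = float(w.sum())
        if wsum <= 0:
            n_kept += 1
            continue
        moment = float((w * r2[window]).sum()) / wsum
        widths[i] = invert_second_moment(r2[window], moment)
    if n_kept:
        log.warning("%d atoms had non-positive window weight; widths kept", n_kept)
    return np.clip(widths, b_floor, b_cap)


def background_floor(exp_map: DensityMap) -> float:
    """Positive floor for the background term: 1e-6 × max map value.

    The update multiplies by the current E, so E = 0 would be absorbing.
    """
    peak = float(np.max(exp_map.values))
    return 1e-6 * peak if peak > 0 else 1e-12


def update_background(
    state: GMMState,
    exp_map: DensityMap,
    resp: ResponsibilityField | None = None,
) -> float:
    """Background update: mean of ``M_e·E/M_s`` over the supported voxels,
    floored at a small positive epsilon."""
    if resp is None:
        resp = responsibilities(state, exp_map)
    v = resp.support
    if not v.any():
        return background_floor(exp_map)
    w_err = exp_map.values[v] * resp.gamma_err[v]
    return max(float(w_err.mean()), background_floor(exp_map))


def restrain_bfactors(model: AtomicModel, blend: float = 0.5) -> AtomicModel:
    """Blend each atom's width toward its residue mean.

    ``B ← (1 − blend)·B + blend·mean(B over the residue)``; ``blend = 0``
    is the identity, ``blend = 1`` full per-residue smoothing.
    """
    out = model.copy()
    if blend == 0.0 or len(model) == 0:
        return out
    keys = model.residue_keys()
    s = pd.Series(model.bwidth)
    means = s.groupby(keys).transform("mean").to_numpy()
    out.bwidth[:] = (1.0 - blend) * model.bwidth + blend * means
    return out


def initial_background(
    model: AtomicModel, exp_map: DensityMap, cutoff_sigma: float = 4.0
) -> float:
    """Mean experimental intensity outside the model's support; if the
    support covers the grid, 10% of the map mean.  Floored at epsilon."""
    mask = support_mask(GMMState(model, 0.0, cutoff_sigma), exp_map)
    outside = exp_map.values[~mask]
    if outside.size:
        e0 = float(outside.mean())
    else:
        e0 = 0.1 * float(exp_map.values.mean())
    return max(e0, background_floor(exp_map))


def _map_residual_loss_grad(
    state: GMMState,
    exp_map: DensityMap,
    bonds: np.ndarray | None = None,
    bond_eq: np.ndarray | None = None,
    k_bond: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Σ_v (M_s − M_e)² (+ harmonic bond penalty) and its position gradient."""
    from .forward import _atom_block  # local import to keep module API clean

    m = state.model
    ms = np.full(exp_map.shape, float(state.background))
    blocks: list = []
    for i in range(len(m)):
        radius = state.cutoff_sigma * m.bwidth[i]
        blk = _atom_block(exp_map, m.positions[i], radius)
        if blk is None:
            blocks.append(None)
            continue
        slices, r2 = blk
        p = m.atomic_number[i] * np.exp(-r2 / m.bwidth[i] ** 2)
        p[r2 > radius**2] = 0.0
        ms[slices] += p
        blocks.append((slices, p))
    resid = ms - exp_map.values
    loss = float(np.sum(resid**2))
    grad = np.zeros_like(m.positions)
    for i, blk in enumerate(blocks):
        if blk is None:
            continue
        slices, p = blk
        rp = resid[slices] * p
        scale = 2.0 * 2.0 / m.bwidth[i] ** 2  # d/dx of exp(-r²/B²) brings 2d/B²
        cx = exp_map.axis_coords(0)[slices[0]] - m.positions[i, 0]
        cy = exp_map.axis_coords(1)[slices[1]] - m.positions[i, 1]
        cz = exp_map.axis_coords(2)[slices[2]] - m.positions[i, 2]
        grad[i, 0] = scale * (rp.sum(axis=(1, 2)) * cx).sum()
        grad[i, 1] = scale * (rp.sum(axis=(0, 2)) * cy).sum()
        grad[i, 2] = scale * (rp.sum(axis=(0, 1)) * cz).sum()
    if bonds is not None and len(bonds) and k_bond > 0:
        pos = m.positions
        d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        r_safe = np.where(r > 1e-12, r, 1.0)
        loss += float(np.sum(k_bond * (r - bond_eq) ** 2))
        gb = (2.0 * k_bond * (r - bond_eq) / r_safe)[:, None] * d
        np.add.at(grad, bonds[:, 0], gb)
        np.add.at(grad, bonds[:, 1], -gb)
    return loss, grad


def polish_positions(
    state: GMMState,
    exp_map: DensityMap,
    steps: int = 50,
    bond_eq: np.ndarray | None = None,
    bond_weight: float = 0.01,
) -> None:
    """Complete the positional maximisation by backtracking gradient
    descent on the squared map residual ``Σ_v (M_s − M_e)²``.

    The responsibility-weighted mean of :func:`maximise_positions` is
    biased wherever atoms overlap (each atom claims part of its
    neighbours' density); descending the residual removes that coupling.
    If the model carries bonds, a weak harmonic bond penalty (equilibrium
    ``bond_eq``, defaulting to the current lengths; strength
    ``bond_weight × max(M_e)²`` per Å²) keeps tightly overlapping
    neighbours from swapping into permuted local minima without
    competing with the density term.  Mutates
    ``state.model.positions`` in place; never increases the objective.
    The first trial step moves at most 0.25 Å.
    """
    if steps <= 0 or len(state.model) == 0:
        return
    bonds = np.array(state.model.bonds, dtype=int).reshape(-1, 2)
    k_bond = bond_weight * float(np.max(exp_map.values)) ** 2 if len(bonds) else 0.0
    if len(bonds) and bond_eq is None:
        bond_eq = np.linalg.norm(
            state.model.positions[bonds[:, 0]] - state.model.positions[bonds[:, 1]],
            axis=1,
        )
    loss, grad = _map_residual_loss_grad(state, exp_map, bonds, bond_eq, k_bond)
    gmax = float(np.abs(grad).max())
    step = 0.25 / max(gmax, 1e-12)
    for _ in range(steps):
        old = state.model.positions.copy()
        state.model.positions -= step * grad
        new_loss, new_grad = _map_residual_loss_grad(
            state, exp_map, bonds, bond_eq, k_bond
        )
        if new_loss < loss:
            loss, grad = new_loss, new_grad
            step *= 1.4
        else:
            state.model.positions[:] = old
            step *= 0.5
            if step < 1e-12:
                break


# -- biasing potential and relaxation -------------------------------------


def gmm_energy(
    position: np.ndarray,
    target: np.ndarray,
    bwidth: np.ndarray | float,
    k_gmm: float = 1e5,
) -> tuple[float, np.ndarray]:
    """Fitting potential pulling an atom to its maximised position.

    ``E = k·(1 − exp(−d²/(2B³)))`` with ``d = |x − x'|``; saturates at
    ``k`` for large displacements.  Returns the total energy and its
    analytic gradient with respect to the positions.  Accepts a single
    atom ((3,) arrays) or N atoms ((N, 3)).
    """
    x = np.atleast_2d(np.asarray(position, dtype=np.float64))
    t = np.atleast_2d(np.asarray(target, dtype=np.float64))
    b = np.broadcast_to(np.asarray(bwidth, dtype=np.float64), (x.shape[0],))
    diff = x - t
    d2 = np.sum(diff**2, axis=1)
    scale = 2.0 * b**3
    expterm = np.exp(-d2 / scale)
    energy = float(np.sum(k_gmm * (1.0 - expterm)))
    grad = k_gmm * expterm[:, None] * diff / b[:, None] ** 3
    if np.asarray(position).ndim == 1:
        return energy, grad[0]
    return energy, grad


def _pair_terms(
    model: AtomicModel,
) -> tuple[np.ndarray, np.ndarray]:
    bonds = np.array(model.bonds, dtype=int).reshape(-1, 2)
    if bonds.size:
        eq = np.linalg.norm(
            model.positions[bonds[:, 0]] - model.positions[bonds[:, 1]], axis=1
        )
    else:
        eq = np.zeros(0)
    return bonds, eq


def _relax_energy(
    pos: np.ndarray,
    targets: np.ndarray,
    bwidth: np.ndarray,
    bonds: np.ndarray,
    bond_eq: np.ndarray,
    bonded: set[tuple[int, int]],
    config: RefinementConfig,
) -> tuple[float, np.ndarray]:
    energy, grad = gmm_energy(pos, targets, bwidth, config.k_gmm)
    if bonds.size:
        d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        r_safe = np.where(r > 1e-12, r, 1.0)
        energy += float(np.sum(config.k_bond * (r - bond_eq) ** 2))
        g = (2.0 * config.k_bond * (r - bond_eq) / r_safe)[:, None] * d
        np.add.at(grad, bonds[:, 0], g)
        np.add.at(grad, bonds[:, 1], -g)
    if len(pos) > 1 and config.k_repulsion > 0:
        pairs = cKDTree(pos).query_pairs(config.repulsion_radius, output_type="ndarray")
        if len(pairs):
            keep = np.array(
                [tuple(sorted(p)) not in bonded for p in pairs], dtype=bool
            )
            pairs = pairs[keep]
        if len(pairs):
            d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            r_safe = np.where(r > 1e-12, r, 1.0)
            gap = config.repulsion_radius - r
            energy += float(np.sum(config.k_repulsion * gap**2))
            g = (-2.0 * config.k_repulsion * gap / r_safe)[:, None] * d
            np.add.at(grad, pairs[:, 0], g)
            np.add.at(grad, pairs[:, 1], -g)
    return energy, grad


def relax(
    model: AtomicModel,
    targets: np.ndarray,
    config: RefinementConfig,
) -> AtomicModel:
    """Move atoms towards their maximised positions.

    ``mode="direct"`` assigns the targets exactly.  ``mode="relaxer"`` runs
    up to ``relax_steps`` backtracking gradient-descent steps on the
    biasing potential plus harmonic bond restraints (equilibrium = input
    lengths) and a soft-sphere repulsion between non-bonded close pairs.
    """
    out = model.copy()
    targets = np.asarray(targets, dtype=np.float64).reshape(len(model), 3)
    if config.mode == "direct":
        out.positions[:] = targets
        return out
    bonds, bond_eq = _pair_terms(model)
    bonded = {tuple(sorted(map(int, b))) for b in bonds}
    pos = out.positions.copy()
    energy, grad = _relax_energy(pos, targets, out.bwidth, bonds, bond_eq, bonded, config)
    gmax = float(np.max(np.abs(grad))) if grad.size else 0.0
    step = 0.1 / max(gmax, 1e-12)  # first trial step moves at most 0.1 Å
    min_step = 1e-12
    for _ in range(config.relax_steps):
        if gmax < 1e-8:
            break
        trial = pos - step * grad
        e_new, g_new = _relax_energy(
            trial, targets, out.bwidth, bonds, bond_eq, bonded, config
        )
        if e_new <= energy + 1e-12 * max(abs(energy), 1.0):
            pos, energy, grad = trial, e_new, g_new
            gmax = float(np.max(np.abs(grad))) if grad.size else 0.0
            step *= 1.2
        else:
            step *= 0.5
            if step < min_step:
                log.warning("relaxer step size underflow; stopping early")
                break
    out.positions[:] = pos
    return out


#: Signature of a pluggable relaxation engine.
Relaxer = Callable[[AtomicModel, np.ndarray, RefinementConfig], AtomicModel]


# -- results --------------------------------------------------------------


@dataclasses.dataclass
class RefinementResults:
    """Outcome of :func:`refine` / :meth:`MapRefinement.fit`.

    ``ccc_history`` holds the convergence CCC of each positional
    iteration (length ``iterations_run``); ``history`` is a DataFrame of
    per-iteration diagnostics over both phases (phase, iteration, ccc,
    model-width ccc, background, width statistics).
    """

    final_model: AtomicModel
    final_background: float
    ccc_history: np.ndarray
    history: pd.DataFrame
    iterations_run: int
    stop_reason: str
    config: RefinementConfig
    resolution: float
    initial_ccc: float
    final_ccc: float
    exp_map: DensityMap | None = None

    @property
    def b_history(self) -> pd.DataFrame:
        return self.history[["phase", "iteration", "b_min", "b_median", "b_max"]]

    def final_state(self) -> GMMState:
        return GMMState(self.final_model, self.final_background, self.config.cutoff_sigma)

    def simulate(self, grid: DensityMap | None = None) -> DensityMap:
        """Simulated map from the refined model (per-atom widths plus E)."""
        if grid is None:
            if self.exp_map is None:
                raise ValueError("no grid available; pass one explicitly")
            grid = self.exp_map
        return simulate_map(self.final_state(), grid)

    def sample_ensemble(self, config=None, n_members: int | None = None):
        """Draw a width-driven ensemble around the refined model; see
        :mod:`gmmreff.ensembles`."""
        from . import ensembles

        cfg = config or ensembles.EnsembleConfig(seed=self.config.seed)
        if self.exp_map is None:
            raise ValueError("ensemble sampling needs the experimental map")
        if n_members is not None:
            return ensembles.sample_ensemble(
                self.final_model, cfg, n_members, exp_map=self.exp_map
            )
        _, ens = ensembles.select_ensemble_size(self.final_model, self.exp_map, cfg)
        return ens

    def summary(self) -> str:
        b = self.final_model.bwidth
        lines = [
            "Gaussian-mixture map refinement results",
            "=" * 47,
            f"atoms                 {len(self.final_model):>10d}",
            f"mode                  {self.config.mode:>10s}",
            f"resolution (A)        {self.resolution:>10.2f}",
            f"iterations run        {self.iterations_run:>10d}",
            f"stop reason           {self.stop_reason:>10s}",
            f"CCC initial           {self.initial_ccc:>10.4f}",
            f"CCC final (best)      {self.final_ccc:>10.4f}",
            f"background E          {self.final_background:>10.4g}",
            f"width B min/med/max   {b.min():>6.3f} {np.median(b):>6.3f} {b.max():>6.3f}",
        ]
        return "\n".join(lines)

    def to_log_dict(self) -> dict:
        return {
            "iterations_run": self.iterations_run,
            "stop_reason": self.stop_reason,
            "initial_ccc": self.initial_ccc,
            "final_ccc": self.final_ccc,
            "final_background": self.final_background,
            "resolution": self.resolution,
            "ccc_history": [float(c) for c in self.ccc_history],
            "history": self.history.to_dict(orient="list"),
        }


def _convergence_scorer(
    model_positions_source: GMMState, exp_map: DensityMap, resolution: float
) -> float:
    """Convergence CCC: zero-mean Pearson between the experimental map and
    a map simulated with a single global width equal to the map's global
    resolution, over that scoring model's support."""
    scoring_model = model_positions_source.model.copy()
    scoring_model.bwidth[:] = resolution
    s = GMMState(scoring_model, 0.0, model_positions_source.cutoff_sigma)
    sim = simulate_map(s, exp_map)
    mask = support_mask(s, exp_map)
    return scoring.ccc(sim, exp_map, mask)


def refine(
    model: AtomicModel,
    exp_map: DensityMap,
    config: RefinementConfig | None = None,
    scorer: Callable[[GMMState], float] | None = None,
    relaxer: Relaxer | None = None,
) -> RefinementResults:
    """Full refinement: width-only warm-up, then positional EM iterations.

    Phase 1 runs ``b_only_iterations`` of width + background updates with
    positions fixed.  Phase 2 iterates expectation → maximisation
    (positions, widths, background) → relaxation, scoring each iteration
    with the convergence CCC; it stops when the CCC has not improved for
    ``patience`` consecutive iterations (converged) or after
    ``max_iterations``.  The best-scoring model is returned, not the last.

    ``scorer`` may replace the convergence CCC (it receives the current
    :class:`GMMState`); ``relaxer`` may replace the built-in relaxation.
    """
    config = config or RefinementConfig()
    if exp_map.global_resolution is None:
        raise ValueError(
            "exp_map.global_resolution is required (set it on the map or pass "
            "resolution= to MapRefinement)"
        )
    resolution = float(exp_map.global_resolution)
    state = GMMState(
        model.copy(),
        initial_background(model, exp_map, config.cutoff_sigma),
        config.cutoff_sigma,
    )
    state.model.bwidth[:] = np.clip(state.model.bwidth, config.b_floor, config.b_cap)

    if scorer is None:
        scorer = lambda s: _convergence_scorer(s, exp_map, resolution)  # noqa: E731

    bonds = np.array(model.bonds, dtype=int).reshape(-1, 2)
    bond_eq = (
        np.linalg.norm(
            model.positions[bonds[:, 0]] - model.positions[bonds[:, 1]], axis=1
        )
        if len(bonds)
        else None
    )

    records: list[dict] = []

    def record(phase: str, iteration: int, conv_ccc: float) -> None:
        sim = simulate_map(state, exp_map)
        mask = support_mask(state, exp_map)
        try:
            model_ccc = scoring.ccc(sim, exp_map, mask)
        except ValueError:
            model_ccc = float("nan")
        b = state.model.bwidth
        records.append(
            {
                "phase": phase,
                "iteration": iteration,
                "ccc": conv_ccc,
                "ccc_model_width": model_ccc,
                "background": state.background,
                "b_min": float(b.min()) if len(b) else float("nan"),
                "b_median": float(np.median(b)) if len(b) else float("nan"),
                "b_max": float(b.max()) if len(b) else float("nan"),
            }
        )

    initial_ccc = scorer(state)
    record("initial", 0, initial_ccc)

    # phase 1: widths and background only, positions fixed
    for it in range(1, config.b_only_iterations + 1):
        resp = responsibilities(state, exp_map)
        widths = maximise_bfactors(
            state, exp_map, resp, b_floor=config.b_floor, b_cap=config.b_cap
        )
        tmp = state.model.copy()
        tmp.bwidth[:] = widths
        tmp = restrain_bfactors(tmp, config.residue_blend)
        state.model.bwidth[:] = np.clip(tmp.bwidth, config.b_floor, config.b_cap)
        state.background = update_background(state, exp_map, resp)
        record("bfactor", it, scorer(state))

    # phase 2: full EM with relaxation
    best_ccc = -np.inf
    best_model = state.model.copy()
    best_background = state.background
    stall = 0
    ccc_history: list[float] = []
    iterations = 0
    stop_reason = "max_iterations"
    do_relax = relaxer if relaxer is not None else relax
    for it in range(1, config.max_iterations + 1):
        iterations = it
        resp = responsibilities(state, exp_map)
        widths = maximise_bfactors(
            state, exp_map, resp, b_floor=config.b_floor, b_cap=config.b_cap
        )
        new_e = update_background(state, exp_map, resp)
        tmp = state.model.copy()
        tmp.bwidth[:] = widths
        tmp = restrain_bfactors(tmp, config.residue_blend)
        state.model.bwidth[:] = np.clip(tmp.bwidth, config.b_floor, config.b_cap)
        state.background = new_e
        # positional maximisation: start from the responsibility-weighted
        # means, then descend the map residual to remove overlap bias
        target_state = GMMState(
            state.model.copy(), state.background, state.cutoff_sigma
        )
        if config.position_polish_steps > 0:
            polish_positions(
                target_state, exp_map, config.position_polish_steps, bond_eq=bond_eq
            )
            targets = target_state.model.positions
        else:
            targets = maximise_positions(state, exp_map, resp)
        state.model = do_relax(state.model, targets, config)
        c = scorer(state)
        ccc_history.append(c)
        record("full", it, c)
        if c > best_ccc + CCC_IMPROVEMENT_TOL:
            best_ccc = c
            best_model = state.model.copy()
            best_background = state.background
            stall = 0
        else:
            stall += 1
        if stall >= config.patience:
            stop_reason = "converged"
            break

    return RefinementResults(
        final_model=best_model,
        final_background=best_background,
        ccc_history=np.array(ccc_history),
        history=pd.DataFrame.from_records(records),
        iterations_run=iterations,
        stop_reason=stop_reason,
        config=config,
        resolution=resolution,
        initial_ccc=initial_ccc,
        final_ccc=float(best_ccc),
        exp_map=exp_map,
    )


class MapRefinement:
    """Gaussian-mixture refinement of an atomic model against a map.

    Parameters
    ----------
    model : AtomicModel
        Starting model (positions in Å, widths in the sigma convention).
    exp_map : DensityMap
        Experimental map; must carry a global resolution (or pass
        ``resolution=``).
    resolution : float, optional
        Global map resolution in Å; overrides ``exp_map.global_resolution``.
    config : RefinementConfig, optional

    Examples
    --------
    >>> res = MapRefinement(model, emap, resolution=3.3).fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        model: AtomicModel,
        exp_map: DensityMap,
        resolution: float | None = None,
        config: RefinementConfig | None = None,
    ) -> None:
        self.model = model
        if resolution is not None:
            exp_map = exp_map.like(exp_map.values)
            exp_map.global_resolution = float(resolution)
        self.exp_map = exp_map
        self.config = config or RefinementConfig()

    @classmethod
    def from_files(
        cls,
        map_path,
        model_path,
        resolution: float,
        bfactor_convention: str = "sigma",
        config: RefinementConfig | None = None,
    ) -> "MapRefinement":
        from .grid import read_density_map
        from .models import read_model

        dmap = read_density_map(map_path, global_resolution=resolution)
        mdl = read_model(model_path, bfactor_convention=bfactor_convention)
        return cls(mdl, dmap, config=config)

    def fit(
        self,
        mode: str | None = None,
        scorer: Callable[[GMMState], float] | None = None,
        relaxer: Relaxer | None = None,
        **overrides,
    ) -> RefinementResults:
        cfg = self.config
        if mode is not None or overrides:
            params = dataclasses.asdict(cfg)
            if mode is not None:
                params["mode"] = mode
            params.update(overrides)
            cfg = RefinementConfig(**params)
        return refine(self.model, self.exp_map, cfg, scorer=scorer, relaxer=relaxer)
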
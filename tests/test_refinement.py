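"""Maximisation-step operations against independent brute-force oracles,
the biasing potential, the relaxer and the refinement loop bookkeeping."""

import numpy as np
import pytest

from gmmreff import (
    AtomicModel,
    GMMState,
    MapRefinement,
    RefinementConfig,
    gmm_energy,
    maximise_bfactors,
    maximise_positions,
    refine,
    relax,
    restrain_bfactors,
    simulate_map,
    update_background,
)
from gmmreff.refinement import (
    WIDTH_BISECTIONS,
    WIDTH_BRACKET,
    background_floor,
    polish_positions,
)

from conftest import centered_grid, single_atom_model


def small_state(seed=0, n_atoms=3, background=0.4):
    rng = np.random.default_rng(seed)
    model = AtomicModel(
        serial=np.arange(1, n_atoms + 1),
        element=["C"] * n_atoms,
        atomic_number=rng.integers(1, 9, n_atoms),
        chain_id=["A"] * n_atoms,
        residue_index=np.arange(1, n_atoms + 1),
        residue_name=["GLY"] * n_atoms,
        atom_name=["CA"] * n_atoms,
        positions=rng.uniform(-3, 3, (n_atoms, 3)),
        bwidth=rng.uniform(0.4, 1.6, n_atoms),
    )
    return GMMState(model, background=background)


# -- independent scalar-loop oracle of the maximisation step --------------


def _oracle_fields(state, grid):
    """Per-voxel P_i, M_s via plain python loops with the spherical cutoff."""
    shape = grid.shape
    n = len(state.model)
    p = np.zeros((n,) + shape)
    for idx, atom in enumerate(state.model.atoms()):
        cutoff = state.cutoff_sigma * atom.bwidth
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    r = grid.index_to_point(np.array([i, j, k])) - atom.position
                    r2 = float(r @ r)
                    if r2 <= cutoff**2:
                        p[idx, i, j, k] = atom.atomic_number * np.exp(
                            -r2 / atom.bwidth**2
                        )
    ms = p.sum(axis=0) + state.background
    return p, ms


def oracle_m_step(state, exp_map, dominance=4.0, b_floor=0.25, b_cap=2.5):
    """Brute-force positions/widths/background updates."""
    p, ms = _oracle_fields(state, exp_map)
    n = len(state.model)
    positions = state.model.positions.copy()
    widths = state.model.bwidth.copy()
    min_radius = 1.5 * float(np.max(exp_map.voxel_size))
    for idx, atom in enumerate(state.model.atoms()):
        wsum = 0.0
        wpos = np.zeros(3)
        window_r2 = []
        window_w = []
        radius = state.cutoff_sigma * atom.bwidth
        win = radius
        e = state.background
        if e > 0 and atom.atomic_number > dominance * e:
            win = min(win, atom.bwidth * np.sqrt(np.log(atom.atomic_number / (dominance * e))))
        win = max(win, min_radius)
        for i in range(exp_map.shape[0]):
            for j in range(exp_map.shape[1]):
                for k in range(exp_map.shape[2]):
                    if p[idx, i, j, k] <= 0 or ms[i, j, k] <= 0:
                        continue
                    gamma = p[idx, i, j, k] / ms[i, j, k]
                    w = exp_map.values[i, j, k] * gamma
                    r = exp_map.index_to_point(np.array([i, j, k]))
                    wsum += w
                    wpos += w * r
                    r2 = float((r - atom.position) @ (r - atom.position))
                    if r2 <= win**2:
                        window_r2.append(r2)
                        window_w.append(w)
        if wsum > 0:
            positions[idx] = wpos / wsum
        window_r2 = np.array(window_r2)
        window_w = np.array(window_w)
        if atom.atomic_number > 0 and window_w.sum() > 0:
            moment = float((window_w * window_r2).sum() / window_w.sum())
            lo, hi = WIDTH_BRACKET

            def g(width):
                wts = np.exp(-window_r2 / width**2)
                return (window_r2 * wts).sum() / wts.sum()

            if g(hi) <= moment:
                widths[idx] = hi
            elif g(lo) >= moment:
                widths[idx] = lo
            else:
                for _ in range(WIDTH_BISECTIONS):
                    mid = 0.5 * (lo + hi)
                    if g(mid) < moment:
                        lo = mid
                    else:
                        hi = mid
                widths[idx] = 0.5 * (lo + hi)
    widths = np.clip(widths, b_floor, b_cap)
    # background
    w_sum = 0.0
    count = 0
    for i in range(exp_map.shape[0]):
        for j in range(exp_map.shape[1]):
            for k in range(exp_map.shape[2]):
                supported = any(p[idx2, i, j, k] > 0 for idx2 in range(n)) or False
                # geometric support: within cutoff of any atom
                r = exp_map.index_to_point(np.array([i, j, k]))
                geo = any(
                    float((r - a.position) @ (r - a.position))
                    <= (state.cutoff_sigma * a.bwidth) ** 2
                    for a in state.model.atoms()
                )
                if geo and ms[i, j, k] > 0:
                    w_sum += exp_map.values[i, j, k] * state.background / ms[i, j, k]
                    count += 1
    e_new = w_sum / count if count else background_floor(exp_map)
    e_new = max(e_new, background_floor(exp_map))
    return positions, widths, e_new


class TestMStepOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        """Vectorised M-step equals an independent voxel-loop oracle."""
        state = small_state(seed=seed)
        grid = centered_grid(12, 1.0)
        rng = np.random.default_rng(seed + 100)
        exp_map = grid.like(
            simulate_map(state, grid).values * rng.uniform(0.8, 1.2, grid.shape)
        )
        o_pos, o_b, o_e = oracle_m_step(state, exp_map)
        pos = maximise_positions(state, exp_map)
        widths = maximise_bfactors(state, exp_map)
        e = update_background(state, exp_map)
        np.testing.assert_allclose(pos, o_pos, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(widths, o_b, rtol=1e-10, atol=1e-12)
        assert e == pytest.approx(o_e, rel=1e-10)


class TestMaximisePositions:
    def test_self_consistent_fixed_point(self):
        grid = centered_grid(16, 0.5)
        state = GMMState(single_atom_model(bwidth=1.0, z=6), 0.0)
        exp_map = simulate_map(state, grid)
        targets = maximise_positions(state, exp_map)
        np.testing.assert_allclose(targets[0], state.model.positions[0], atol=0.05)

    def test_mirror_symmetric_map_keeps_plane(self):
        """A map symmetric about x = 0 leaves the target on that plane."""
        grid = centered_grid(15, 1.0)
        state = GMMState(single_atom_model(bwidth=1.0, z=6), 0.0)
        x = grid.axis_coords(0)
        sym = np.exp(-np.abs(x))[:, None, None] * np.ones(grid.shape)
        targets = maximise_positions(state, grid.like(sym))
        assert targets[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_offset_gaussian_pulls_towards_it(self):
        grid = centered_grid(16, 0.5)
        state = GMMState(single_atom_model(bwidth=1.0, z=6), 0.0)
        shifted = GMMState(single_atom_model(bwidth=1.0, z=6, position=(0.8, 0, 0)), 0.0)
        exp_map = simulate_map(shifted, grid)
        targets = maximise_positions(state, exp_map)
        assert 0.1 < targets[0, 0] <= 0.85

    def test_empty_density_keeps_position(self):
        grid = centered_grid(12, 1.0)
        state = GMMState(single_atom_model(bwidth=1.0, z=6), 0.0)
        targets = maximise_positions(state, grid.like(np.zeros(grid.shape)))
        np.testing.assert_allclose(targets, state.model.positions)


class TestMaximiseBfactors:
    @pytest.mark.parametrize("bwidth", [0.6, 1.0, 1.7])
    def test_fixed_point_on_fine_grid(self, bwidth):
        """Simulating an atom and re-estimating reproduces its width."""
        grid = centered_grid(48, 0.3)
        state = GMMState(single_atom_model(bwidth=bwidth, z=6), 0.0)
        exp_map = simulate_map(state, grid)
        widths = maximise_bfactors(state, exp_map, b_floor=0.1, b_cap=5.0)
        assert widths[0] == pytest.approx(bwidth, rel=1e-3)

    def test_broadened_map_increases_width(self):
        grid = centered_grid(32, 0.5)
        state = GMMState(single_atom_model(bwidth=1.0, z=6), 0.0)
        wide = GMMState(single_atom_model(bwidth=2.0, z=6), 0.0)
        exp_map = simulate_map(wide, grid)
        widths = maximise_bfactors(state, exp_map, b_floor=0.1, b_cap=5.0)
        assert widths[0] > 1.0

    def test_point_density_clamps_to_floor(self):
        grid = centered_grid(9, 1.0)
        state = GMMState(single_atom_model(bwidth=1.0, z=6), 0.0)
        values = np.zeros(grid.shape)
        values[tuple(int(round(v)) for v in grid.point_to_index(np.zeros(3)))] = 5.0
        widths = maximise_bfactors(state, grid.like(values), b_floor=0.25, b_cap=2.5)
        assert widths[0] == pytest.approx(0.25)


class TestUpdateBackground:
    def test_pure_background_limit(self):
        """All-Z=0 model over a constant map recovers that constant."""
        grid = centered_grid(12, 1.0)
        model = single_atom_model(bwidth=2.0, z=0)
        state = GMMState(model, background=0.5)
        exp_map = grid.like(np.full(grid.shape, 1.7))
        assert update_background(state, exp_map) == pytest.approx(1.7, rel=1e-12)

    def test_zero_background_is_not_absorbing(self):
        grid = centered_grid(12, 1.0)
        state = GMMState(single_atom_model(), background=0.0)
        exp_map = simulate_map(state, grid)
        e = update_background(state, exp_map)
        assert e == pytest.approx(background_floor(exp_map))
        assert e > 0


class TestRestrainBfactors:
    def test_blend_zero_is_identity(self, toy_model):
        out = restrain_bfactors(toy_model, 0.0)
        np.testing.assert_allclose(out.bwidth, toy_model.bwidth)

    def test_full_blend_gives_residue_means(self):
        m = AtomicModel(
            serial=[1, 2, 3],
            element=["C"] * 3,
            atomic_number=[6] * 3,
            chain_id=["A"] * 3,
            residue_index=[1, 1, 1],
            residue_name=["GLY"] * 3,
            atom_name=["N", "CA", "C"],
            positions=np.zeros((3, 3)),
            bwidth=[1.0, 2.0, 3.0],
        )
        np.testing.assert_allclose(restrain_bfactors(m, 1.0).bwidth, 2.0)

    def test_half_blend_hand_value(self):
        m = AtomicModel(
            serial=[1, 2],
            element=["C"] * 2,
            atomic_number=[6] * 2,
            chain_id=["A"] * 2,
            residue_index=[1, 1],
            residue_name=["GLY"] * 2,
            atom_name=["N", "CA"],
            positions=np.zeros((2, 3)),
            bwidth=[1.0, 3.0],
        )
        np.testing.assert_allclose(restrain_bfactors(m, 0.5).bwidth, [1.5, 2.5])


class TestGmmEnergy:
    def test_zero_displacement(self):
        e, g = gmm_energy(np.zeros(3), np.zeros(3), 1.0, k_gmm=1e5)
        assert e == 0.0
        np.testing.assert_allclose(g, 0.0)

    def test_saturates_at_k(self):
        e, _ = gmm_energy(np.array([100.0, 0, 0]), np.zeros(3), 1.0, k_gmm=1e5)
        assert e == pytest.approx(1e5, rel=1e-9)

    def test_hand_value_and_finite_difference_gradient(self):
        """k=1, B=1, d=1 gives 1 − e^(−1/2) ≈ 0.3935."""
        x = np.array([1.0, 0.0, 0.0])
        e, g = gmm_energy(x, np.zeros(3), 1.0, k_gmm=1.0)
        assert e == pytest.approx(1.0 - np.exp(-0.5), rel=1e-12)
        assert e == pytest.approx(0.3935, abs=1e-4)
        eps = 1e-6
        for a in range(3):
            dx = np.zeros(3)
            dx[a] = eps
            ep, _ = gmm_energy(x + dx, np.zeros(3), 1.0, k_gmm=1.0)
            em, _ = gmm_energy(x - dx, np.zeros(3), 1.0, k_gmm=1.0)
            assert g[a] == pytest.approx((ep - em) / (2 * eps), abs=1e-6)


class TestRelax:
    def bonded_pair(self):
        return AtomicModel(
            serial=[1, 2],
            element=["C", "C"],
            atomic_number=[6, 6],
            chain_id=["A", "A"],
            residue_index=[1, 2],
            residue_name=["GLY", "GLY"],
            atom_name=["CA", "CA"],
            positions=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
            bwidth=[1.0, 1.0],
            bonds=[(0, 1)],
        )

    def test_fixed_point_both_modes(self):
        m = self.bonded_pair()
        for mode in ("direct", "relaxer"):
            cfg = RefinementConfig(mode=mode, relax_steps=100)
            out = relax(m, m.positions.copy(), cfg)
            np.testing.assert_allclose(out.positions, m.positions, atol=1e-6)

    def test_direct_mode_assigns_targets(self):
        m = self.bonded_pair()
        targets = m.positions + np.array([1.0, 0.0, 0.0])
        out = relax(m, targets, RefinementConfig(mode="direct"))
        np.testing.assert_allclose(out.positions, targets)

    def test_relaxer_decreases_energy_and_keeps_bond(self):
        from gmmreff.refinement import _pair_terms, _relax_energy

        m = self.bonded_pair()
        targets = m.positions.copy()
        targets[1] += np.array([0.8, 0.4, 0.0])
        cfg = RefinementConfig(mode="relaxer", relax_steps=500, k_gmm=5.0)
        bonds, eq = _pair_terms(m)
        bonded = {(0, 1)}
        e0, _ = _relax_energy(m.positions, targets, m.bwidth, bonds, eq, bonded, cfg)
        out = relax(m, targets, cfg)
        e1, _ = _relax_energy(out.positions, targets, out.bwidth, bonds, eq, bonded, cfg)
        assert e1 < e0
        length = np.linalg.norm(out.positions[0] - out.positions[1])
        assert length == pytest.approx(1.5, rel=0.05)


class TestRefineLoop:
    def test_patience_arithmetic_with_stubbed_scorer(self, toy_model, toy_map):
        """A never-improving scorer stops after exactly 1 + patience scored
        iterations."""
        exp_map, truth = toy_map
        exp_map.global_resolution = 3.0
        calls = []

        def flat_scorer(state):
            calls.append(1)
            return 0.5

        cfg = RefinementConfig(
            patience=5, b_only_iterations=0, position_polish_steps=0, max_iterations=300
        )
        res = refine(toy_model, exp_map, cfg, scorer=flat_scorer)
        assert res.iterations_run == 6
        assert res.stop_reason == "converged"
        assert len(res.ccc_history) == 6

    def test_hard_stop_at_max_iterations(self, toy_model, toy_map):
        exp_map, _ = toy_map
        exp_map.global_resolution = 3.0
        it = [0]

        def rising_scorer(state):
            it[0] += 1
            return it[0] * 1e-3  # always improves

        cfg = RefinementConfig(
            patience=5, b_only_iterations=0, position_polish_steps=0, max_iterations=12
        )
        res = refine(toy_model, exp_map, cfg, scorer=rising_scorer)
        assert res.iterations_run == 12
        assert res.stop_reason == "max_iterations"

    def test_missing_resolution_raises(self, toy_model, toy_map):
        exp_map, _ = toy_map
        exp_map.global_resolution = None
        with pytest.raises(ValueError, match="resolution"):
            refine(toy_model, exp_map, RefinementConfig())

    def test_self_consistent_input_converges_in_place(self, toy_model, toy_spec):
        """Refining against the model's own noise-free map keeps positions."""
        from gmmreff import ToySpec, make_ground_truth_map

        spec = ToySpec(**{**toy_spec.__dict__, "noise_level": 0.0})
        exp_map, _ = make_ground_truth_map(toy_model, spec)
        exp_map.global_resolution = 3.0
        res = MapRefinement(
            toy_model,
            exp_map,
            config=RefinementConfig(residue_blend=0.0, b_only_iterations=3),
        ).fit()
        assert res.stop_reason == "converged"
        assert res.final_ccc >= res.initial_ccc - 1e-9
        d = np.linalg.norm(res.final_model.positions - toy_model.positions, axis=1)
        assert d.max() < 0.1

    def test_bounds_respected_and_histories_consistent(self, toy_model, toy_map):
        exp_map, _ = toy_map
        exp_map.global_resolution = 3.0
        cfg = RefinementConfig(b_only_iterations=3, max_iterations=4, patience=2)
        res = MapRefinement(toy_model, exp_map, config=cfg).fit()
        assert np.all(res.final_model.bwidth >= cfg.b_floor - 1e-12)
        assert np.all(res.final_model.bwidth <= cfg.b_cap + 1e-12)
        assert res.final_background > 0
        assert len(res.ccc_history) == res.iterations_run
        assert set(res.history.phase) <= {"initial", "bfactor", "full"}
        summary = res.summary()
        assert "CCC" in summary and "iterations" in summary

    def test_bonly_phase_improves_model_width_ccc(self, toy_model, toy_spec):
        """Starting from inflated widths, the width-only phase improves the
        per-atom-width CCC between simulated and experimental maps."""
        from gmmreff import ToySpec, make_ground_truth_map

        spec = ToySpec(**{**toy_spec.__dict__, "noise_level": 0.0})
        exp_map, truth = make_ground_truth_map(toy_model, spec)
        exp_map.global_resolution = 3.0
        start = toy_model.copy()
        start.bwidth[:] = np.clip(start.bwidth * 3, 0.25, 2.5)
        cfg = RefinementConfig(
            residue_blend=0.0, b_only_iterations=10, max_iterations=1, patience=1
        )
        res = refine(start, exp_map, cfg)
        b_phase = res.history[res.history.phase.isin(["initial", "bfactor"])]
        assert b_phase.ccc_model_width.iloc[-1] > b_phase.ccc_model_width.iloc[0]

    def test_convergence_ccc_constant_during_width_phase(self, toy_model, toy_map):
        """The convergence CCC uses a global width, so the width-only phase
        cannot decrease it (positions are fixed)."""
        exp_map, _ = toy_map
        exp_map.global_resolution = 3.0
        cfg = RefinementConfig(b_only_iterations=6, max_iterations=1, patience=1)
        res = refine(toy_model, exp_map, cfg)
        ccc = res.history[res.history.phase.isin(["initial", "bfactor"])].ccc.to_numpy()
        assert np.all(np.diff(ccc) >= -1e-9)


def test_polish_positions_never_increases_residual(toy_model, toy_map):
    exp_map, truth = toy_map
    state = GMMState(toy_model.copy(), truth.background)
    state.model.positions += 0.3
    from gmmreff.refinement import _map_residual_loss_grad

    before, _ = _map_residual_loss_grad(state, exp_map)
    polish_positions(state, exp_map, steps=10)
    after, _ = _map_residual_loss_grad(state, exp_map)
    assert after <= before
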
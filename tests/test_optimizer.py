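"""Optimizer stages: initialization, branch lengths, shapes, mutation
rates, optimal-sequence sweeps, and the monotone four-stage cycle."""

import numpy as np
import pytest

from selon.core import (
    PopulationConfig,
    SelectionProfile,
    build_mutation_matrix,
)
from selon.engine import SelonEngine, SelonParams
from selon.io import UCEDataset
from selon.optimize import (
    FitResult,
    OptimizerConfig,
    _FitState,
    _SelonBranchEvaluator,
    _branch_sweeps,
    fit_selon,
    initialize_fit,
    majority_rule_optima,
    optimize_mutation_rates,
    optimize_optimal_sequence,
    optimize_shape_params,
)
from selon.simulate import (
    SCENARIO_MUTATION_RATES,
    SimulationScenario,
    UCESpec,
    scenario_tree,
    simulate_scenario_dataset,
)
from selon.tree import RootedTree


def _simulate(tree, specs, mutation=None, seed=0):
    mutation = mutation or build_mutation_matrix("UNREST", np.ones(11))
    scen = SimulationScenario(0, tree, specs, mutation, PopulationConfig(), seed)
    return scen, simulate_scenario_dataset(scen, np.random.default_rng(seed))


class TestInitialization:
    def test_majority_rule(self):
        codes = np.array([[0, 1], [0, 1], [0, 2], [1, 2], [2, 3]])
        # col 0: A=3,C=1,G=1 -> A; col 1: C=2,G=2,T=1 -> C (tie -> first)
        assert list(majority_rule_optima(codes)) == [0, 1]

    def test_tie_breaks_alphabetically(self):
        codes = np.array([[0], [0], [1], [1]])
        assert majority_rule_optima(codes)[0] == 0

    def test_missing_ignored(self):
        codes = np.array([[4], [4], [3], [2], [3]])
        assert majority_rule_optima(codes)[0] == 3

    def test_same_seed_identical_start(self):
        tree = scenario_tree(1)
        specs = [
            UCESpec("u0", 30, SelectionProfile(2.0, 15.0, 5.0),
                    np.random.default_rng(0).integers(0, 4, 30))
        ]
        _, ds = _simulate(tree, specs)
        cfg = OptimizerConfig(seed=5)
        p1, l1 = initialize_fit(ds, tree, cfg)
        p2, l2 = initialize_fit(ds, tree, cfg)
        assert all(
            a.nes_max == b.nes_max and a.center == b.center and a.width == b.width
            for a, b in zip(p1.profiles, p2.profiles)
        )
        assert np.allclose(l1, l2, equal_nan=True, rtol=0, atol=0)
        assert all(np.array_equal(a, b) for a, b in zip(p1.optima, p2.optima))


class TestBranchLengths:
    def _neutral_setup(self, nwk, n_sites=5000, seed=7):
        tree = RootedTree.from_newick(nwk)
        rng = np.random.default_rng(seed)
        specs = [
            UCESpec("u0", n_sites, SelectionProfile(0.0, n_sites / 2, n_sites / 4),
                    rng.integers(0, 4, n_sites))
        ]
        scen, ds = _simulate(tree, specs, seed=seed)
        engine = SelonEngine(ds, tree)
        params = SelonParams(scen.mutation, [s.profile for s in specs],
                             [s.optimal for s in specs], scen.pop)
        return tree, engine, params

    def test_simulation_recovery_within_15_percent(self):
        tree, engine, params = self._neutral_setup(
            "((a:0.12,b:0.06):0.09,(c:0.2,d:0.07):0.05);"
        )
        start = np.where(np.isnan(tree.lengths), np.nan, 0.05)
        ev = _SelonBranchEvaluator(engine, params, None, start)
        _branch_sweeps(ev, tree, OptimizerConfig())
        # terminal branches are well identified; the two root-adjacent
        # branches trade off (only their sum is constrained), so compare
        # terminal lengths and the root-pair sum
        for leaf in range(4):
            assert ev.lengths[leaf] == pytest.approx(tree.lengths[leaf], rel=0.15)
        root_pair = [n for n in tree.branch_nodes if not tree.is_leaf(n)]
        assert sum(ev.lengths[n] for n in root_pair) == pytest.approx(
            sum(tree.lengths[n] for n in root_pair), rel=0.25, abs=0.02
        )

    def test_lnl_never_decreases_within_sweeps(self):
        tree, engine, params = self._neutral_setup(
            "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);", n_sites=400
        )
        start = np.where(np.isnan(tree.lengths), np.nan, 0.02)
        ev = _SelonBranchEvaluator(engine, params, None, start)
        lnl0 = ev.total()
        lnl1 = _branch_sweeps(ev, tree, OptimizerConfig())
        assert lnl1 >= lnl0

    def test_branch_at_optimum_barely_moves(self):
        tree, engine, params = self._neutral_setup(
            "((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);", n_sites=2000
        )
        ev = _SelonBranchEvaluator(engine, params, None, tree.lengths.copy())
        _branch_sweeps(ev, tree, OptimizerConfig(rel_tol=1e-9))  # to convergence
        ev2 = _SelonBranchEvaluator(engine, params, None, ev.lengths.copy())
        _branch_sweeps(ev2, tree, OptimizerConfig(branch_cycle_max=1))
        assert np.nanmax(np.abs(ev2.lengths - ev.lengths)) < 1e-3


class TestShapeStage:
    def test_recovers_profile_on_simulated_uce(self):
        l = 400
        tree = scenario_tree(1)
        rng = np.random.default_rng(13)
        true = SelectionProfile(nes_max=5.0, center=l / 2, width=l / 8)
        specs = [UCESpec("u0", l, true, rng.integers(0, 4, l))]
        scen, ds = _simulate(tree, specs, seed=13)
        engine = SelonEngine(ds, tree)
        params = SelonParams(scen.mutation, [SelectionProfile(2.0, l / 3, l / 3)],
                             [s.optimal for s in specs], scen.pop)
        state = _FitState(engine=engine, params=params, lengths=tree.lengths.copy())
        state.refresh()
        lnl0 = state.lnl
        optimize_shape_params(state, OptimizerConfig(), np.random.default_rng(0),
                              restarts=3)
        state.refresh()
        fitted = state.params.profiles[0]
        assert state.lnl >= lnl0
        assert abs(fitted.center - true.center) <= 0.1 * l
        assert 0.75 * true.width <= fitted.width <= 1.5 * true.width

    def test_neutral_uce_gets_small_nes(self):
        l = 300
        tree = scenario_tree(1)
        rng = np.random.default_rng(14)
        specs = [UCESpec("u0", l, SelectionProfile(0.0, l / 2, l / 8),
                         rng.integers(0, 4, l))]
        scen, ds = _simulate(tree, specs, seed=14)
        engine = SelonEngine(ds, tree)
        params = SelonParams(scen.mutation, [SelectionProfile(3.0, l / 2, l / 6)],
                             [s.optimal for s in specs], scen.pop)
        state = _FitState(engine=engine, params=params, lengths=tree.lengths.copy())
        state.refresh()
        neutral = SelonParams(scen.mutation, [SelectionProfile(1e-9, l / 2, l / 6)],
                              [s.optimal for s in specs], scen.pop)
        lnl_neutral = engine.loglik(neutral, tree.lengths)
        optimize_shape_params(state, OptimizerConfig(), np.random.default_rng(1),
                              restarts=3)
        state.refresh()
        # the ML solution on neutral data may be a degenerate near-zero-width
        # spike covering a single coincidentally matching site; what matters
        # is that the fitted profile carries no real spatial selection signal
        fitted = state.params.profiles[0]
        pos = np.arange(1.0, l + 1.0)
        assert fitted.sensitivity(pos).mean() < 0.2
        assert state.lnl - lnl_neutral < 2.0


class TestMutationStage:
    def test_recovers_transition_bias_on_neutral_data(self):
        rates = np.ones(11)
        rates[1] = 4.0  # A->G
        mutation = build_mutation_matrix("UNREST", rates)
        tree = scenario_tree(1)
        rng = np.random.default_rng(15)
        n = 10_000
        specs = [UCESpec("u0", n, SelectionProfile(0.0, n / 2, n / 4),
                         rng.integers(0, 4, n))]
        scen, ds = _simulate(tree, specs, mutation=mutation, seed=15)
        engine = SelonEngine(ds, tree)
        params = SelonParams(build_mutation_matrix("UNREST", np.ones(11)),
                             [s.profile for s in specs], [s.optimal for s in specs],
                             scen.pop)
        state = _FitState(engine=engine, params=params, lengths=tree.lengths.copy())
        state.refresh()
        optimize_mutation_rates(state, OptimizerConfig(mutation_maxeval=2000))
        state.refresh()
        fitted = np.asarray(state.params.mutation.free_rates)
        # rates are relative to the pinned G->T entry
        assert fitted[1] == pytest.approx(4.0, rel=0.25)
        assert state.params.mutation.matrix[2, 3] == 1.0

    def test_stage_noop_when_started_at_truth(self):
        tree = scenario_tree(2)
        rng = np.random.default_rng(16)
        n = 3000
        specs = [UCESpec("u0", n, SelectionProfile(0.0, n / 2, n / 4),
                         rng.integers(0, 4, n))]
        scen, ds = _simulate(tree, specs, seed=16)
        engine = SelonEngine(ds, tree)
        params = SelonParams(scen.mutation, [s.profile for s in specs],
                             [s.optimal for s in specs], scen.pop)
        state = _FitState(engine=engine, params=params, lengths=tree.lengths.copy())
        state.refresh()
        lnl0 = state.lnl
        optimize_mutation_rates(state, OptimizerConfig())
        state.refresh()
        assert state.lnl >= lnl0
        assert (state.lnl - lnl0) / abs(lnl0) < 1e-3


class TestOptimalSequenceStage:
    def _state(self, specs, seed, start_optima=None, mutation=None):
        tree = scenario_tree(1)
        scen, ds = _simulate(tree, specs, mutation=mutation, seed=seed)
        engine = SelonEngine(ds, tree)
        optima = start_optima or [s.optimal.copy() for s in specs]
        params = SelonParams(scen.mutation, [s.profile for s in specs], optima,
                             scen.pop)
        state = _FitState(engine=engine, params=params, lengths=tree.lengths.copy())
        state.refresh()
        return state, scen, ds

    def test_invariant_column_selects_observed_base(self):
        l = 50
        rng = np.random.default_rng(17)
        specs = [UCESpec("u0", l, SelectionProfile(6.0, l / 2, l / 4),
                         rng.integers(0, 4, l))]
        state, scen, ds = self._state(specs, 17)
        codes = ds.alignments[0].codes
        invariant = (codes == codes[0]).all(axis=0)
        # start from deliberately wrong optima
        state.params.optima = [(specs[0].optimal + 1) % 4]
        state.refresh()
        optimize_optimal_sequence(state, OptimizerConfig())
        chosen = state.params.optima[0]
        strong = specs[0].profile.sensitivity(np.arange(1.0, l + 1)) > 2.0
        sel = invariant & strong
        assert sel.any()
        assert np.array_equal(chosen[sel], codes[0][sel])

    def test_sweep_idempotent(self):
        l = 60
        rng = np.random.default_rng(18)
        specs = [UCESpec("u0", l, SelectionProfile(4.0, l / 2, l / 5),
                         rng.integers(0, 4, l))]
        state, _, _ = self._state(specs, 18)
        optimize_optimal_sequence(state, OptimizerConfig())
        first = [o.copy() for o in state.params.optima]
        state.refresh()
        optimize_optimal_sequence(state, OptimizerConfig())
        assert all(np.array_equal(a, b) for a, b in zip(first, state.params.optima))

    def test_lnl_non_decreasing(self):
        l = 80
        rng = np.random.default_rng(19)
        specs = [UCESpec("u0", l, SelectionProfile(5.0, l / 2, l / 6),
                         rng.integers(0, 4, l))]
        state, _, _ = self._state(specs, 19)
        state.params.optima = [(specs[0].optimal + 2) % 4]
        state.refresh()
        lnl0 = state.lnl
        optimize_optimal_sequence(state, OptimizerConfig())
        state.refresh()
        assert state.lnl >= lnl0 - 1e-9


class TestFullFit:
    def _tiny_fixture(self, seed=21):
        tree = RootedTree.from_newick(
            "((a:0.1,b:0.025):0.05,(c:0.1,d:0.025):0.05);"
        )
        rng = np.random.default_rng(seed)
        specs = [
            UCESpec("u0", 60, SelectionProfile(4.0, 30.0, 8.0), rng.integers(0, 4, 60)),
            UCESpec("u1", 50, SelectionProfile(1.5, 20.0, 6.0), rng.integers(0, 4, 50)),
        ]
        mutation = build_mutation_matrix("UNREST", SCENARIO_MUTATION_RATES)
        scen, ds = _simulate(tree, specs, mutation=mutation, seed=seed)
        return tree, scen, ds

    def test_trace_monotone_and_caps_respected(self):
        tree, scen, ds = self._tiny_fixture()
        cfg = OptimizerConfig(seed=2, shape_maxeval=120, mutation_maxeval=200)
        fit = fit_selon(ds, tree, cfg)
        trace = np.array(fit.lnl_trace)
        assert np.all(np.diff(trace) >= -1e-6)
        assert fit.n_cycles <= cfg.outer_cycle_max
        assert fit.model == "selon"

    def test_seeded_fit_deterministic(self):
        tree, scen, ds = self._tiny_fixture()
        cfg = OptimizerConfig(seed=3, shape_maxeval=100, mutation_maxeval=150)
        f1 = fit_selon(ds, tree, cfg)
        f2 = fit_selon(ds, tree, cfg)
        assert f1.log_likelihood == f2.log_likelihood
        assert f1.tree_newick == f2.tree_newick
        assert f1.params == f2.params

    def test_refit_from_truth_not_below_truth(self):
        tree, scen, ds = self._tiny_fixture()
        truth = SelonParams(scen.mutation, [s.profile for s in scen.uce_specs],
                            [s.optimal.copy() for s in scen.uce_specs], scen.pop)
        engine = SelonEngine(ds, tree)
        lnl_truth = engine.loglik(truth, tree.lengths)
        cfg = OptimizerConfig(seed=4, shape_maxeval=100, mutation_maxeval=150)
        fit = fit_selon(ds, tree, cfg, initial=(truth, tree.lengths.copy()))
        assert fit.log_likelihood >= lnl_truth - 0.5

    def test_parameter_count_and_aicc(self):
        tree, scen, ds = self._tiny_fixture()
        cfg = OptimizerConfig(seed=5, outer_cycle_max=1, shape_maxeval=60,
                              mutation_maxeval=80)
        fit = fit_selon(ds, tree, cfg)
        expected_k = 11 + 3 * 2 + tree.n_branches + 110
        assert fit.n_parameters == expected_k
        from selon.likelihood import aicc

        assert fit.aicc == pytest.approx(
            aicc(fit.log_likelihood, expected_k, 4, 110)
        )

    def test_result_json_round_trip(self, tmp_path):
        tree, scen, ds = self._tiny_fixture()
        cfg = OptimizerConfig(seed=6, outer_cycle_max=1, shape_maxeval=60,
                              mutation_maxeval=80)
        fit = fit_selon(ds, tree, cfg)
        path = tmp_path / "fit.json"
        fit.save(path)
        loaded = FitResult.load(path)
        assert loaded.log_likelihood == fit.log_likelihood
        engine = SelonEngine(ds, loaded.tree)
        relnl = engine.loglik(loaded.selon_params, loaded.tree.lengths)
        assert relnl == pytest.approx(fit.log_likelihood, abs=1e-6)
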
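"""Evolutionary search: mutation, hill climbing, oracle, regime labelling."""

import numpy as np
import pytest

import antreg as A
from antreg.evolve import apply_values


@pytest.fixture
def small_bounds():
    return A.ParameterBounds({"b1": (0.0, 10.0), "b2": (0.0, 10.0)})


@pytest.fixture
def quick_cfg():
    return A.SearchConfig(restarts=2, iterations=60, seed=3)


class TestMutation:
    def test_small_step_small_change(self, small_bounds):
        rng = np.random.default_rng(0)
        values = {"b1": 1.0, "b2": 2.0}
        out = A.mutate_parameters(values, small_bounds, 1e-9, rng)
        for k in values:
            assert out[k] == pytest.approx(values[k], rel=1e-6)

    def test_single_parameter_changes(self, small_bounds):
        rng = np.random.default_rng(1)
        values = {"b1": 1.0, "b2": 2.0}
        out = A.mutate_parameters(values, small_bounds, 0.5, rng)
        assert sum(out[k] != values[k] for k in values) <= 1

    def test_clipping_at_upper_bound(self, small_bounds):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            out = A.mutate_parameters({"b1": 10.0, "b2": 10.0}, small_bounds, 1.0, rng)
            assert out["b1"] <= 10.0 and out["b2"] <= 10.0
            hits += out["b1"] == 10.0 or out["b2"] == 10.0
        assert hits > 0

    def test_deterministic_under_seed(self, small_bounds):
        a = A.mutate_parameters({"b1": 1.0, "b2": 2.0}, small_bounds, 0.5, np.random.default_rng(7))
        b = A.mutate_parameters({"b1": 1.0, "b2": 2.0}, small_bounds, 0.5, np.random.default_rng(7))
        assert a == b

    def test_zero_is_reachable_and_escapable(self, small_bounds):
        rng = np.random.default_rng(3)
        reached_zero = escaped = False
        v = {"b1": 1e-5, "b2": 1.0}
        for _ in range(500):
            out = A.mutate_parameters(v, small_bounds, 2.0, rng)
            if out["b1"] == 0.0:
                reached_zero = True
            if v["b1"] == 0.0 and out["b1"] > 0.0:
                escaped = True
            v = out
        assert reached_zero and escaped

    def test_empty_bounds_rejected(self):
        with pytest.raises(A.ConfigurationError):
            A.ParameterBounds({})


class TestHillClimb:
    def test_collapsed_bounds_return_point(self, schedule, base_params, fitness_params):
        bounds = A.ParameterBounds({"b1": (0.0, 0.0), "b2": (2.0, 2.0)})
        cfg = A.SearchConfig(restarts=1, iterations=1, seed=0)
        opt = A.hill_climb(schedule, base_params, bounds, fitness_params, cfg)
        assert opt.values == {"b1": 0.0, "b2": 2.0}

    def test_seed_determinism(self, schedule, base_params, fitness_params, quick_cfg):
        bounds = A.default_bounds()
        o1 = A.hill_climb(schedule, base_params.with_(kd2=0.5), bounds, fitness_params, quick_cfg)
        o2 = A.hill_climb(schedule, base_params.with_(kd2=0.5), bounds, fitness_params, quick_cfg)
        assert o1.values == o2.values
        assert o1.fitness.net == o2.fitness.net

    def test_stored_fitness_reproducible(self, schedule, base_params, fitness_params, quick_cfg):
        bounds = A.default_bounds()
        opt = A.hill_climb(schedule, base_params.with_(kd2=0.3), bounds, fitness_params, quick_cfg)
        params = apply_values(base_params.with_(kd2=0.3), opt.values, quick_cfg.mode)
        traj = A.simulate(params, schedule, n_points=quick_cfg.n_points)
        re_net = A.evaluate_fitness(traj, fitness_params, kd2=0.3).net
        assert re_net == pytest.approx(opt.fitness.net, rel=1e-9)

    def test_beats_grid_oracle(self, schedule, base_params, fitness_params):
        cfg = A.SearchConfig(restarts=2, iterations=100, seed=5)
        bounds = A.default_bounds()
        p = base_params.with_(kd2=0.5)
        climb = A.hill_climb(schedule, p, bounds, fitness_params, cfg)
        oracle = A.grid_search_oracle(schedule, p, bounds, fitness_params, 3, cfg)
        assert climb.fitness.net >= oracle.fitness.net - 1e-9

    def test_warm_start_never_hurts(self, schedule, base_params, fitness_params, quick_cfg):
        bounds = A.default_bounds()
        p = base_params.with_(kd2=1.0)
        warm = {"b1": 0.0, "b2": 5.0, "Km1": 1.0, "Km2": 1.0}
        start_net = A.evaluate_fitness(
            A.simulate(apply_values(p, warm, quick_cfg.mode), schedule, n_points=quick_cfg.n_points),
            fitness_params,
            kd2=1.0,
        ).net
        opt = A.hill_climb(schedule, p, bounds, fitness_params, quick_cfg, extra_starts=[warm])
        assert opt.fitness.net >= start_net - 1e-12


class TestGridOracle:
    def test_enumeration_count(self, schedule, base_params, fitness_params):
        bounds = A.ParameterBounds({"b1": (0.0, 0.0), "b2": (1.0, 4.0)})
        opt = A.grid_search_oracle(schedule, base_params, bounds, fitness_params, 2)
        assert opt.n_evaluations == 2  # exactly the two grid candidates

    def test_constant_surface_tie_break(self, schedule, base_params):
        fp = A.FitnessParams(E_max=0.0, c0=0.0)
        bounds = A.ParameterBounds({"b1": (1.0, 4.0), "b2": (1.0, 4.0)})
        opt = A.grid_search_oracle(schedule, base_params, bounds, fp, 3)
        assert opt.values == {"b1": 1.0, "b2": 1.0}
        assert opt.fitness.net == pytest.approx(0.0, abs=1e-12)

    def test_dimension_guard(self, schedule, base_params, fitness_params):
        bounds = A.ParameterBounds({f"Km{i}": (0.1, 1.0) for i in (1, 2)} | {f"b{i}": (0, 1) for i in (1, 2)} | {"k_on1": (0.1, 1)})
        with pytest.raises(A.ContractError):
            A.grid_search_oracle(schedule, base_params, bounds, fitness_params, 2)


class TestClassification:
    def _opt(self, b1, b2):
        return A.Optimum(values={"b1": b1, "b2": b2}, params=A.default_parameters(), fitness=A.FitnessResult(0, 0, 0))

    def test_three_labels(self, small_bounds):
        assert A.classify_regime(self._opt(5.0, 0.0), small_bounds) == A.Regime.R1_ONLY
        assert A.classify_regime(self._opt(0.0, 5.0), small_bounds) == A.Regime.R2_ONLY
        assert A.classify_regime(self._opt(2.0, 7.0), small_bounds) == A.Regime.ANTICIPATORY

    def test_degenerate_warns_and_follows_larger(self, small_bounds):
        with pytest.warns(RuntimeWarning):
            lab = A.classify_regime(self._opt(1e-6, 2e-6), small_bounds)
        assert lab == A.Regime.R2_ONLY
        with pytest.warns(RuntimeWarning):
            lab = A.classify_regime(self._opt(2e-6, 1e-6), small_bounds)
        assert lab == A.Regime.R1_ONLY


class TestSmoothingAndWidth:
    def test_majority_smoothing_removes_isolated_flip(self):
        R1, ANT = A.Regime.R1_ONLY, A.Regime.ANTICIPATORY
        labels = [R1, R1, ANT, R1, R1]
        assert A.majority_smooth(labels) == [R1] * 5

    def test_band_structure_collapse(self):
        R1, ANT, R2 = A.Regime.R1_ONLY, A.Regime.ANTICIPATORY, A.Regime.R2_ONLY
        assert A.band_structure([R1, R1, ANT, ANT, R2]) == [R1, ANT, R2]

    def test_width_no_anticipatory(self):
        kd = np.geomspace(1e-3, 10, 5)
        labels = [A.Regime.R1_ONLY] * 5
        assert A.anticipatory_window_width(labels, kd) == 0.0

    def test_width_single_cell_is_one_spacing(self):
        kd = np.geomspace(1e-3, 10, 5)
        labels = [A.Regime.R1_ONLY, A.Regime.ANTICIPATORY] + [A.Regime.R2_ONLY] * 3
        spacing = np.mean(np.diff(np.log10(kd)))
        assert A.anticipatory_window_width(labels, kd) == pytest.approx(spacing)

    def test_width_longest_run_wins(self):
        kd = np.geomspace(1e-3, 10, 7)
        R1, ANT = A.Regime.R1_ONLY, A.Regime.ANTICIPATORY
        labels = [ANT, R1, ANT, ANT, ANT, R1, ANT]
        spacing = np.mean(np.diff(np.log10(kd)))
        assert A.anticipatory_window_width(labels, kd) == pytest.approx(3 * spacing)


class TestSweeps:
    def test_single_point_sweep(self, schedule, base_params, fitness_params):
        cfg = A.SearchConfig(restarts=1, iterations=40, seed=2)
        m = A.sweep_kd([0.5], schedule=schedule, base_params=base_params, fp=fitness_params, cfg=cfg)
        assert len(m.table) == 1
        assert m.table["regime"].iloc[0] in {r.value for r in A.Regime}

    def test_sweep_seeded_per_point_and_deterministic(self, schedule, base_params, fitness_params):
        cfg = A.SearchConfig(restarts=1, iterations=40, seed=2)
        kd = [0.1, 1.0]
        m1 = A.sweep_kd(kd, schedule=schedule, base_params=base_params, fp=fitness_params, cfg=cfg)
        m2 = A.sweep_kd(kd, schedule=schedule, base_params=base_params, fp=fitness_params, cfg=cfg)
        assert m1.table.equals(m2.table)

    def test_bad_grid_rejected(self, fitness_params):
        with pytest.raises(A.ContractError):
            A.sweep_kd([1.0, 0.5], fp=fitness_params)
        with pytest.raises(A.ContractError):
            A.sweep_kd([-1.0, 0.5], fp=fitness_params)

    def test_emax_zero_row_has_no_anticipatory_cells(self, schedule, base_params):
        cfg = A.SearchConfig(restarts=1, iterations=40, seed=4)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = A.sweep_kd(
                np.geomspace(1e-2, 1.0, 3),
                schedule=schedule,
                base_params=base_params,
                cfg=cfg,
                emax=0.0,
            )
        assert A.Regime.ANTICIPATORY.value not in set(m.table["regime"])
        assert m.window_width() == 0.0
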
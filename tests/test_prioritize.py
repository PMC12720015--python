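import numpy as np
import pandas as pd
import pytest

from consplan import prioritize, synth
from consplan.grids import GridSpec
from consplan.prioritize import (
    AVAILABLE,
    LOCKED_IN,
    LOCKED_OUT,
    PlanningProblem,
    SAParams,
    anneal,
    blm_sweep,
    build_problem,
    local_morans_i,
    objective,
    overlap_cpas,
    read_marxan_inputs,
    run_portfolio,
    tier_target,
    write_marxan_inputs,
)
from tests._oracles import brute_force_optimum, objective_by_hand, random_instance


class TestTierTargets:
    @pytest.mark.parametrize(
        "area,fraction",
        [(500, 1.0), (1000, 1.0), (1000.1, 0.30), (5000, 0.30),
         (10_000, 0.30), (10_000.1, 0.10), (50_000, 0.10)],
    )
    def test_tier_boundaries(self, area, fraction):
        assert tier_target(area) == fraction

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            tier_target(0)


def simple_problem(grid, cost=None, status=None, features=(), targets=()):
    n = grid.n_cells
    return PlanningProblem(
        grid,
        np.ones(n) if cost is None else cost,
        np.zeros(n, dtype=int) if status is None else status,
        [f"f{i}" for i in range(len(features))],
        [np.asarray(f) for f in features],
        [np.ones(len(f)) for f in features],
        np.asarray(targets, dtype=float),
    )


class TestBuildProblem:
    def test_amounts_match_hand_built_matrix(self, range_factory):
        grid = GridSpec(10, 10)
        r1 = range_factory(grid, [0, 11, 22], "sp1")
        r2 = range_factory(grid, [22, 23], "sp2")
        problem = build_problem(
            [r1, r2], np.zeros(grid.shape, bool), np.ones(grid.shape),
            None, grid,
        )
        assert problem.feature_ids == ["sp1", "sp2"]
        assert set(problem.feature_pus[0]) == {0, 11, 22}
        assert set(problem.feature_pus[1]) == {22, 23}
        np.testing.assert_allclose(problem.feature_amounts[0], 1.0)
        # both ranges are tiny (<= 1000 km^2): 100% targets
        np.testing.assert_allclose(problem.targets, [3.0, 2.0])

    def test_pa_overlap_wins_over_town_proximity(self, range_factory):
        grid = GridSpec(10, 10)
        pa = np.zeros(grid.shape, bool)
        pa[0, 0] = True  # centre (0.5, 9.5)
        setts = synth.SettlementSet(
            pd.DataFrame({"x": [0.5], "y": [9.5], "kind": ["city"]})
        )
        with pytest.warns(UserWarning, match="infeasible"):
            # the single range cell sits in the lock-out buffer
            problem = build_problem(
                [range_factory(grid, [50], "s")], pa, np.ones(grid.shape),
                setts, grid, buffer_km=5.0,
            )
        assert problem.status[0] == LOCKED_IN
        # neighbours inside the 5 km buffer and outside the PA are locked out
        assert problem.status[1] == LOCKED_OUT

    def test_no_pa_gives_zero_locked_in(self, range_factory):
        grid = GridSpec(5, 5)
        problem = build_problem(
            [range_factory(grid, [0], "s")], np.zeros(grid.shape, bool),
            np.ones(grid.shape), None, grid,
        )
        assert len(problem.locked_in) == 0
        assert (problem.status == AVAILABLE).all()

    def test_unreachable_target_flagged_infeasible(self, range_factory):
        grid = GridSpec(5, 5)
        setts = synth.SettlementSet(
            pd.DataFrame({"x": [2.5], "y": [2.5], "kind": ["city"]})
        )
        with pytest.warns(UserWarning, match="infeasible"):
            problem = build_problem(
                [range_factory(grid, [12], "s")],  # centre cell, locked out
                np.zeros(grid.shape, bool), np.ones(grid.shape),
                setts, grid, buffer_km=1.0,
            )
        assert problem.infeasible[0]


class TestObjective:
    def test_locked_in_only_all_targets_met(self):
        grid = GridSpec(2, 2)
        cost = np.array([2.0, 3.0, 1.0, 1.0])
        status = np.array([LOCKED_IN, LOCKED_IN, AVAILABLE, AVAILABLE])
        problem = simple_problem(grid, cost, status,
                                 features=[[0]], targets=[1.0])
        sol = objective(np.array([1, 1, 0, 0], bool), problem,
                        SAParams(blm=0.0))
        assert sol.total == pytest.approx(5.0)
        assert sol.penalty == 0.0
        assert sol.feasible.all()

    def test_single_cell_perimeter_is_four(self):
        grid = GridSpec(3, 3)
        problem = simple_problem(grid, cost=np.zeros(9))
        sel = np.zeros(9, bool)
        sel[4] = True
        sol = objective(sel, problem, SAParams(blm=1.0))
        assert sol.total == pytest.approx(4.0)
        assert sol.boundary == pytest.approx(4.0)

    def test_matches_explicit_loop_recomputation(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            problem, params = random_instance(seed)
            sel = np.zeros(problem.n_pu, bool)
            sel[problem.locked_in] = True
            avail = problem.available
            sel[avail[rng.random(len(avail)) < 0.5]] = True
            sol = objective(sel, problem, params)
            assert sol.total == pytest.approx(
                objective_by_hand(sel, problem, params), abs=1e-9
            )
            assert sol.cost + sol.boundary + sol.penalty == pytest.approx(sol.total)
            assert min(sol.cost, sol.boundary, sol.penalty) >= 0

    def test_lock_violations_rejected(self):
        grid = GridSpec(2, 2)
        status = np.array([LOCKED_IN, AVAILABLE, LOCKED_OUT, AVAILABLE])
        problem = simple_problem(grid, status=status)
        with pytest.raises(ValueError):
            objective(np.array([0, 1, 0, 0], bool), problem, SAParams())
        with pytest.raises(ValueError):
            objective(np.array([1, 0, 1, 0], bool), problem, SAParams())


class TestAnneal:
    def test_zero_targets_converge_to_locked_in_only(self):
        grid = GridSpec(3, 3)
        status = np.zeros(9, dtype=int)
        status[0] = LOCKED_IN
        problem = simple_problem(grid, status=status)
        sol = anneal(problem, SAParams(blm=0.0, n_iterations=3000), seed=1)
        assert sol.n_selected == 1
        assert sol.selected[0]

    def test_must_have_species_pu_always_selected(self):
        grid = GridSpec(3, 3)
        problem = simple_problem(
            grid, cost=np.full(9, 2.0), features=[[4]], targets=[1.0]
        )
        for seed in range(10):
            sol = anneal(problem, SAParams(blm=0.0, n_iterations=2000),
                         seed=seed)
            assert sol.selected[4]
            assert sol.feasible.all()

    def test_lock_constraints_hold_in_every_run(self):
        problem, params = random_instance(3)
        params = SAParams(blm=params.blm, n_iterations=500, n_runs=10)
        res = run_portfolio(problem, params, seed=2)
        for sol in res.solutions:
            assert sol.selected[problem.locked_in].all()
            assert not sol.selected[problem.locked_out].any()

    def test_best_of_runs_matches_brute_force_on_one_instance(self):
        problem, params = random_instance(7)
        opt = brute_force_optimum(problem, params)
        params = SAParams(blm=params.blm, n_iterations=1500, n_runs=10)
        res = run_portfolio(problem, params, seed=3)
        assert res.best.total == pytest.approx(opt, abs=1e-6)

    def test_high_spf_meets_all_targets_when_feasible(self, range_factory):
        grid = GridSpec(8, 8)
        rng = np.random.default_rng(4)
        ranges = [
            range_factory(grid, rng.choice(64, size=6, replace=False), f"s{i}")
            for i in range(4)
        ]
        problem = build_problem(
            ranges, np.zeros(grid.shape, bool),
            rng.uniform(1, 3, grid.shape), None, grid,
        )
        res = run_portfolio(
            problem, SAParams(n_iterations=4000, n_runs=5), seed=5
        )
        assert res.best.feasible.all()


class TestPortfolio:
    def test_single_run_frequency_is_indicator(self):
        problem, params = random_instance(11)
        params = SAParams(blm=params.blm, n_iterations=300, n_runs=1)
        res = run_portfolio(problem, params, seed=6)
        np.testing.assert_array_equal(
            res.selection_frequency, res.best.selected.astype(float)
        )

    def test_locked_units_have_extreme_frequencies(self):
        grid = GridSpec(3, 3)
        status = np.zeros(9, dtype=int)
        status[0], status[8] = LOCKED_IN, LOCKED_OUT
        problem = simple_problem(grid, status=status)
        res = run_portfolio(
            problem, SAParams(n_iterations=200, n_runs=8), seed=7
        )
        assert res.selection_frequency[0] == 1.0
        assert res.selection_frequency[8] == 0.0

    def test_bitwise_reproducible_for_fixed_master_seed(self):
        problem, params = random_instance(13)
        params = SAParams(blm=params.blm, n_iterations=400, n_runs=5)
        a = run_portfolio(problem, params, seed=8)
        b = run_portfolio(problem, params, seed=8)
        np.testing.assert_array_equal(a.selection_frequency,
                                      b.selection_frequency)
        assert a.best.total == b.best.total

    def test_blm_sweep_boundary_non_increasing(self, range_factory):
        grid = GridSpec(6, 6)
        rng = np.random.default_rng(9)
        ranges = [range_factory(grid, rng.choice(36, 8, replace=False), f"s{i}")
                  for i in range(3)]
        problem = build_problem(
            ranges, np.zeros(grid.shape, bool),
            rng.uniform(1, 2, grid.shape), None, grid,
        )
        sweep = blm_sweep(
            problem, [0.0, 0.5, 5.0],
            SAParams(n_iterations=3000, n_runs=20), seed=10,
        )
        b = sweep["boundary_length"].to_numpy()
        assert (np.diff(b) <= 1e-9).all()


class TestLocalMoran:
    def test_constant_map_all_ns_and_warned(self):
        with pytest.warns(UserWarning, match="constant"):
            res = local_morans_i(np.ones((5, 5)), 99, seed=0)
        assert (res.labels == "ns").all()

    def test_high_block_core_is_hh(self):
        field = np.zeros((20, 20))
        field[8:11, 8:11] = 1.0
        res = local_morans_i(field, 999, seed=1)
        assert res.labels[9, 9] == "HH"

    def test_isolated_spike_is_hl_outlier(self):
        rng = np.random.default_rng(2)
        field = rng.normal(0, 0.01, (15, 15))
        field[7, 7] = 10.0
        res = local_morans_i(field, 999, seed=3)
        assert res.labels[7, 7] == "HL"

    def test_global_i_equals_weighted_mean_relation(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(10, 10))
        res = local_morans_i(v, 9, seed=5)
        # with row-standardized weights, global I = sum(z*lag)/sum(z^2)
        z = (v - v.mean()).ravel()
        num = (res.I.ravel() * np.mean(z**2)).sum()  # = sum z*lag
        assert res.global_I == pytest.approx(num / (z**2).sum() * len(z) / len(z))
        assert res.global_I == pytest.approx(res.I.mean())

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            local_morans_i(np.zeros((2, 2)), 9, seed=0)


class TestOverlap:
    def test_identical_solutions_fully_overlapped(self):
        sel = np.zeros((4, 4), bool)
        sel[:2] = True
        labels, summary = overlap_cpas(sel, sel)
        assert (labels[sel] == "overlapped").all()
        assert summary.set_index("class").loc["current_only", "n_cells"] == 0

    def test_disjoint_solutions_no_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[3] = True, True
        _, summary = overlap_cpas(a, b)
        assert summary.set_index("class").loc["overlapped", "n_cells"] == 0

    def test_known_intersection_area(self):
        grid = GridSpec(5, 5)
        a = np.zeros(25, bool)
        b = np.zeros(25, bool)
        a[:10] = True
        b[3:15] = True  # intersection = cells 3..9 -> 7 cells
        labels, summary = overlap_cpas(
            a.reshape(5, 5), b.reshape(5, 5), grid
        )
        row = summary.set_index("class").loc["overlapped"]
        assert row["n_cells"] == 7
        assert row["area_km2"] == pytest.approx(7.0)


class TestMarxanIO:
    def test_round_trip_tables(self, tmp_path, range_factory):
        grid = GridSpec(4, 4)
        ranges = [range_factory(grid, [0, 1, 5], "spA"),
                  range_factory(grid, [10], "spB")]
        pa = np.zeros(grid.shape, bool)
        pa[0, 0] = True
        problem = build_problem(ranges, pa, np.ones(grid.shape), None, grid)
        write_marxan_inputs(problem, tmp_path)
        tables = read_marxan_inputs(tmp_path)
        assert len(tables["pu"]) == 16
        assert list(tables["spec"]["name"]) == ["spA", "spB"]
        # amounts conserved through the puvspr table
        assert tables["puvspr"]["amount"].sum() == pytest.approx(4.0)
        assert (tables["puvspr"]["pu"].diff().dropna() >= 0).all()
        # every rook edge appears once; self-pairs carry the exterior
        bound = tables["bound"]
        inner = bound[bound["id1"] != bound["id2"]]
        assert len(inner) == 2 * 4 * 3
        # 24 interior edges once each + 16 exterior sides as self-pairs
        assert bound["boundary"].sum() == pytest.approx(24.0 + 16.0)
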
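"""Population dynamics: ligand PK, hazards, simulation vs the Markov twin."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tandemgpc as tg
from tandemgpc.compiler import DELETED
from tandemgpc.dynamics import Population, transition_hazard
from tandemgpc.presets import SELF_DELETION_HAZARD


def ga3am_pk():
    return tg.PKParams(GIB=tg.PKLigand("first_order", clearance_halflife=4.0,
                                       trapped=True),
                       ABA=tg.PKLigand("instant"))


class TestLigandActivity:
    def test_instant_clearance_drops_to_zero(self, fluor):
        sched = tg.LigandSchedule((("GIB", 0, 48),), horizon=96)
        assert tg.ligand_activity(sched, fluor.pk, "GIB", 24) == 1.0
        assert tg.ligand_activity(sched, fluor.pk, "GIB", 49) == 0.0

    def test_first_order_half_life(self):
        sched = tg.LigandSchedule((("GIB", 0, 48),), horizon=96)
        a = tg.ligand_activity(sched, ga3am_pk(), "GIB", 52.0)
        assert a == pytest.approx(0.5)

    def test_zero_before_any_window(self, fluor):
        sched = tg.LigandSchedule((("ABA", 10, 20),), horizon=30)
        assert tg.ligand_activity(sched, fluor.pk, "ABA", 5.0) == 0.0

    def test_unknown_ligand_rejected(self, fluor):
        sched = tg.LigandSchedule((), horizon=10)
        with pytest.raises(ValueError):
            tg.ligand_activity(sched, fluor.pk, "RAPA", 1.0)

    def test_ga3am_needs_more_than_12h_to_clear(self):
        sched = tg.LigandSchedule((("GIB", 0, 48),), horizon=96)
        assert tg.ligand_activity(sched, ga3am_pk(), "GIB", 60.0) > 0.1
        # fully cleared only past the activity floor (~26.6 h post washout)
        assert tg.ligand_activity(sched, ga3am_pk(), "GIB", 48 + 27) == 0.0


class TestTransitionHazard:
    def test_cognate_ligand_gives_excision_hazard(self, fluor):
        h, tgt = transition_hazard(1, fluor.design, {"GIB": 1.0, "ABA": 0.0},
                                   fluor.kinetics)
        assert h == fluor.kinetics.excision_hazard
        assert tgt == 2

    def test_orthogonal_ligand_gives_leak_only(self, fluor):
        h, _ = transition_hazard(1, fluor.design, {"GIB": 0.0, "ABA": 1.0},
                                 fluor.kinetics)
        assert h == fluor.kinetics.leak_hazard

    def test_terminal_stage_inert(self, fluor):
        h, tgt = transition_hazard(4, fluor.design, {"GIB": 1.0, "ABA": 1.0},
                                   fluor.kinetics)
        assert h == 0.0 and tgt is None

    def test_phic31_stage_of_wrapped_design_self_deletes(self, attp):
        h, tgt = transition_hazard(3, attp.design, {"GIB": 1.0, "ABA": 0.0},
                                   attp.kinetics)
        assert h == attp.kinetics.self_deletion_hazard
        assert tgt == DELETED


class TestSimulate:
    def test_frozen_without_leak_or_ligand(self, fluor):
        params = tg.KineticParams(excision_hazard=0.2, leak_hazard=0.0)
        traj = tg.simulate_population(
            fluor.design, params, fluor.pk, fluor.copy_model,
            tg.LigandSchedule.empty(100), n=200, seed=0,
            sample_times=[0, 50, 100])
        assert (traj.occupancy["stage_1"] == 1.0).all()

    def test_aba_first_window_is_inert_then_cascade_completes(self, fluor):
        """The wrong ligand first produces no transitions; the proper
        GA4/ABA/GA4 sequence afterwards still completes the cascade."""
        params = tg.KineticParams(excision_hazard=0.2, leak_hazard=0.0)
        sched = tg.LigandSchedule.alternating(
            ["ABA"] + fluor.design.ligand_order(), 48, 12)
        traj = tg.simulate_population(
            fluor.design, params, fluor.pk, fluor.copy_model, sched,
            n=500, seed=2, sample_times=[48, sched.horizon])
        assert traj.occupancy["stage_1"].iloc[0] == 1.0
        assert traj.occupancy["stage_4"].iloc[-1] > 0.99

    def test_deterministic_cascade_in_strong_excision_limit(self, fluor,
                                                            fluor_schedule):
        params = tg.KineticParams(excision_hazard=1e3, leak_hazard=0.0)
        traj = tg.simulate_population(
            fluor.design, params, fluor.pk, fluor.copy_model,
            fluor_schedule, n=300, seed=4, sample_times=[48, 108, 168])
        for i, stage in enumerate([2, 3, 4]):
            assert traj.occupancy[f"stage_{stage}"].iloc[i] == 1.0

    def test_stage_indices_never_reverse(self, cascade_run):
        et = cascade_run.population.entry_times
        capped = np.where(np.isfinite(et), et, 1e18)  # avoid inf - inf
        assert (np.diff(capped, axis=1) >= 0).all()

    def test_occupancy_rows_sum_to_one(self, cascade_run):
        total = cascade_run.occupancy.sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_reproducible_for_fixed_seed(self, fluor, fluor_schedule,
                                         calib_params):
        runs = [tg.simulate_population(
            fluor.design, calib_params, fluor.pk, fluor.copy_model,
            fluor_schedule, n=300, seed=11, sample_times=[48, 168])
            for _ in range(2)]
        assert np.array_equal(runs[0].population.entry_times,
                              runs[1].population.entry_times)

    def test_ligand_orthogonality(self, fluor):
        """ABA exposure leaves GIB-gated stage-1 statistics indistinguishable
        from a ligand-free run (two-proportion test, alpha=0.01)."""
        from statsmodels.stats.proportion import proportions_ztest

        params = tg.KineticParams(excision_hazard=0.2, leak_hazard=5e-4)
        aba = tg.LigandSchedule((("ABA", 0, 48),), horizon=48)
        none = tg.LigandSchedule.empty(48)
        n = 4000
        counts = []
        for sched, seed in [(aba, 21), (none, 22)]:
            traj = tg.simulate_population(
                fluor.design, params, fluor.pk, fluor.copy_model, sched,
                n=n, seed=seed, sample_times=[48])
            counts.append(round(traj.occupancy["stage_1"].iloc[0] * n))
        _, p = proportions_ztest(counts, [n, n])
        assert p > 0.01


class TestExpectedOccupancy:
    def test_all_hazards_zero_is_identity(self, fluor, fluor_schedule):
        params = tg.KineticParams(excision_hazard=0.0, leak_hazard=0.0)
        occ = tg.expected_occupancy(fluor.design, params, fluor.pk,
                                    fluor_schedule, [0, 48, 168])
        assert np.allclose(occ[:, 0], 1.0)

    def test_single_gpc_closed_form(self):
        d = tg.random_design(1, n_stages=1)
        params = tg.KineticParams(excision_hazard=0.15, leak_hazard=0.0)
        sched = tg.LigandSchedule((("GIB", 0, 30),), horizon=30)
        occ = tg.expected_occupancy(d, params, tg.PKParams(), sched, [30.0])
        assert occ[0, 1] == pytest.approx(1 - np.exp(-0.15 * 30), abs=1e-8)

    def test_hazard_point2_for_24h_is_nearly_complete(self):
        """0.2/h over a 24 h window leaves ~0.8% unexcised: near-complete
        single-window excision."""
        d = tg.random_design(2, n_stages=1)
        params = tg.KineticParams(excision_hazard=0.2, leak_hazard=0.0)
        sched = tg.LigandSchedule((("GIB", 0, 24),), horizon=24)
        occ = tg.expected_occupancy(d, params, tg.PKParams(), sched, [24.0])
        assert occ[0, 1] == pytest.approx(0.992, abs=5e-4)

    def test_matches_independent_ode_oracle(self, fluor, fluor_schedule,
                                            calib_params):
        """Full-cascade occupancies agree with a direct ODE integration of
        the same piecewise master equation, including a GA3-AM washout
        tail (the matrix-exponential path never runs in that regime)."""
        design, params = fluor.design, calib_params
        pk = ga3am_pk()
        times = [24.0, 48.0, 55.0, 108.0, 168.0]

        def rhs(t, y):
            acts = {lig: tg.ligand_activity(fluor_schedule, pk, lig, t)
                    for lig in ("GIB", "ABA")}
            dy = np.zeros_like(y)
            for k in range(1, design.n_gpcs + 1):
                lam, tgt = transition_hazard(k, design, acts, params)
                dy[k - 1] -= lam * y[k - 1]
                dy[tgt - 1] += lam * y[k - 1]
            return dy

        y = np.zeros(design.n_stages + 1)
        y[0] = 1.0
        # integrate window-by-window so the solver never steps across a
        # ligand on/off discontinuity
        knots = [0.0, 48.0, 60.0, 108.0, 120.0, 168.0]
        oracle = {}
        for t0, t1 in zip(knots, knots[1:]):
            grid = sorted({t for t in times if t0 < t <= t1} | {t1})
            sol = solve_ivp(rhs, (t0, t1), y, t_eval=grid, rtol=1e-10,
                            atol=1e-12, max_step=0.5)
            for j, t in enumerate(grid):
                oracle[t] = sol.y[:, j]
            y = sol.y[:, -1]
        occ = tg.expected_occupancy(design, params, pk, fluor_schedule, times)
        expected = np.stack([oracle[t] for t in times])
        assert np.allclose(occ, expected, atol=1e-6)

    def test_monte_carlo_within_three_binomial_se(self, fluor, fluor_schedule,
                                                  calib_params, cascade_run):
        times = [48.0, 108.0, 168.0]
        occ = tg.expected_occupancy(fluor.design, calib_params, fluor.pk,
                                    fluor_schedule, times)
        n = cascade_run.n_cells
        for i, t in enumerate(times):
            mc = cascade_run.population.occupancy_at(t)
            for k in range(occ.shape[1]):
                p = occ[i, k]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(mc[k] - p) <= 3 * se + 1e-9, (t, k, mc[k], p)


class TestSelection:
    @staticmethod
    def toy_population(design, params, copy_stages):
        """Population at a frozen time with given per-cell copy stages."""
        cell_of_copy = np.concatenate(
            [[i] * len(cs) for i, cs in enumerate(copy_stages)]).astype(int)
        n_copies = len(cell_of_copy)
        n_stages = design.n_stages
        entry = np.full((n_copies, n_stages), np.inf)
        flat = [s for cs in copy_stages for s in cs]
        for c, s in enumerate(flat):
            entry[c, :s] = 0.0
        return Population(design=design, params=params,
                          cell_of_copy=cell_of_copy, entry_times=entry,
                          deleted_time=np.full(n_copies, np.inf),
                          alive=np.ones(len(copy_stages), dtype=bool))

    def test_no_op_when_everything_survives(self, fluor, cascade_run):
        pop = tg.apply_selection(cascade_run.population, 3, 1.0, 1.0,
                                 t=108, seed=0)
        assert pop.alive.all()

    def test_single_copy_hard_selection_keeps_exactly_marker_cells(
            self, fluor):
        stages = [[1], [2], [3], [3], [4], [2], [3]]
        pop = self.toy_population(fluor.design, fluor.kinetics, stages)
        out = tg.apply_selection(pop, 3, 1.0, 0.0, t=0.0, seed=1)
        assert out.alive.tolist() == [s == [3] for s in stages]

    def test_multicopy_survivors_match_enumeration_oracle(self, fluor):
        """One marker-stage copy suffices: brute-force enumeration over a
        20-cell mixed 1-/2-copy toy population."""
        rng = np.random.default_rng(42)
        stages = [list(rng.integers(1, 5, size=rng.integers(1, 3)))
                  for _ in range(20)]
        pop = self.toy_population(fluor.design, fluor.kinetics, stages)
        out = tg.apply_selection(pop, 3, 1.0, 0.0, t=0.0, seed=3)
        oracle = [any(s == 3 for s in cs) for cs in stages]
        assert out.alive.tolist() == oracle


class TestSelfDelete:
    def test_zero_hazard_deletes_nothing(self, attp):
        sched = tg.LigandSchedule((("GIB", 0, 48),), horizon=48)
        params = dataclasses.replace(attp.kinetics, self_deletion_hazard=0.0)
        traj = tg.simulate_population(attp.design, params, attp.pk,
                                      attp.copy_model, sched, n=100, seed=0,
                                      sample_times=[48], init_stage=3)
        pop = tg.self_delete(traj.population, params, attp.pk, sched, seed=1)
        assert not np.isfinite(pop.deleted_time).any()

    def test_window_probability_matches_closed_form(self, attp):
        h = 0.02
        sched = tg.LigandSchedule((("GIB", 0, 48),), horizon=48)
        params = dataclasses.replace(
            attp.kinetics, self_deletion_hazard=h, leak_hazard=0.0)
        n = 10_000
        traj = tg.simulate_population(attp.design, params, attp.pk,
                                      attp.copy_model, sched, n=n, seed=5,
                                      sample_times=[0, 48], init_stage=3)
        p = 1 - np.exp(-h * 48)
        frac = traj.occupancy["deleted"].iloc[-1]
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_preset_hazard_gives_78pct_per_window(self):
        assert 1 - np.exp(-SELF_DELETION_HAZARD * 48) == pytest.approx(0.78)

    def test_requires_att_wrapper(self, fluor, cascade_run):
        sched = tg.LigandSchedule((("GIB", 0, 48),), horizon=48)
        with pytest.raises(ValueError):
            tg.self_delete(cascade_run.population, fluor.kinetics, fluor.pk,
                           sched, seed=0)


class TestFitHazard:
    def test_no_decay_gives_zero(self):
        q, _ = tg.fit_hazard_from_timecourse([0, 96, 192], [1.0, 1.0, 1.0])
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        q, _ = tg.fit_hazard_from_timecourse([0.0, 192.0], [1.0, 0.9])
        assert q == pytest.approx(-np.log(0.9) / 192, rel=1e-6)

    def test_recovers_leak_rate_within_20pct(self, fluor):
        """Parameter recovery from a simulated ligand-free memory decay at
        the calibrated leak rate, n=10,000 cells, 5 time points."""
        q_true = 5e-4
        params = tg.KineticParams(excision_hazard=0.2, leak_hazard=q_true)
        times = [0.0, 48.0, 96.0, 144.0, 192.0]
        traj = tg.simulate_population(
            fluor.design, params, fluor.pk, fluor.copy_model,
            tg.LigandSchedule.empty(192), n=10_000, seed=9,
            sample_times=times, init_stage=2)
        fractions = traj.occupancy["stage_2"].to_numpy()
        q_hat, (lo, hi) = tg.fit_hazard_from_timecourse(times, fractions,
                                                        model="leak", seed=1)
        assert abs(q_hat - q_true) / q_true < 0.20
        assert lo <= q_hat <= hi

    def test_non_monotone_data_warns_but_fits(self):
        with pytest.warns(UserWarning, match="not monotone"):
            q, _ = tg.fit_hazard_from_timecourse(
                [0, 50, 100], [0.9, 1.0, 0.85], model="leak", n_boot=50)
        assert q >= 0
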
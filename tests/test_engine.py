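"""Cohort-engine tests: life table, calibration, birth/aging rules, the
migration rebalancer, and equivalence with a naive cell-by-cell oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcast.engine import (
    OPEN_INTERVAL_CAP,
    CalibrationError,
    age_and_educate,
    calibrate_fertility,
    calibrate_mortality,
    compute_births,
    life_expectancy,
    project,
    rebalance_migration,
)
from popcast.scenarios import assemble_ssp
from popcast.state import (
    N_AGE,
    N_EDU,
    N_SEX,
    TRANSITIONS,
    PopulationState,
    RateSet,
    implied_tfr,
)


def geometric_le(q: float) -> float:
    """Closed-form life expectancy for a constant annual death probability.

    With l_x = (1-q)^x, a_x = 0.5 and the open interval credited 1/m years
    at m = q: e0 = sum_x 0.5 (l_x + l_{x+1}) + l_100 / q.
    """
    lx = (1.0 - q) ** np.arange(101)
    return float((0.5 * (lx[:100] + lx[1:])).sum() + lx[100] / q)


def make_rates(p, fer=None, mor=None, g=None, netpim=0.0, netgim=0.0,
               srb=1.07):
    srb_arr = np.full(p, srb)
    return RateSet(
        fer=np.zeros((p, N_AGE, N_EDU)) if fer is None else fer,
        mor=np.zeros((p, N_SEX, N_AGE)) if mor is None else mor,
        g=np.zeros((p, N_SEX, len(TRANSITIONS))) if g is None else g,
        netpim=np.asarray(netpim, dtype=float).reshape(-1, 1, 1, 1)
        if np.ndim(netpim) == 1 else np.asarray(netpim, dtype=float),
        netgim=netgim,
        bm=srb_arr / (1 + srb_arr),
        bf=1 / (1 + srb_arr),
    )


def random_state(rng, p=3, year=2010):
    counts = rng.uniform(0, 1000, size=(p, N_SEX, N_AGE, N_EDU))
    return PopulationState(counts, year, tuple(f"P{i}" for i in range(p)))


# --------------------------------------------------------------------------
# life table
# --------------------------------------------------------------------------

class TestLifeExpectancy:
    @pytest.mark.parametrize("q", [0.005, 0.01, 0.05])
    def test_constant_hazard_matches_geometric_closed_form(self, q):
        sched = np.full(N_AGE, q)
        assert life_expectancy(sched) == pytest.approx(geometric_le(q), abs=1e-10)

    def test_zero_mortality_hits_open_interval_cap(self):
        assert life_expectancy(np.zeros(N_AGE)) == 100.0 + OPEN_INTERVAL_CAP

    def test_uniformly_higher_mortality_lowers_le(self, rng):
        base = rng.uniform(0.001, 0.1, size=N_AGE)
        assert life_expectancy(2 * np.clip(base, 0, 0.5)) < life_expectancy(base)

    def test_rejects_out_of_range_schedule(self):
        bad = np.zeros(N_AGE)
        bad[3] = 1.5
        with pytest.raises(ValueError):
            life_expectancy(bad)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

class TestCalibration:
    def test_fertility_identity_scale(self, rng):
        fer = np.zeros((2, N_AGE, N_EDU))
        fer[:, 15:50, :] = rng.uniform(0.01, 0.1, size=(2, 35, N_EDU))
        fem = rng.uniform(10, 100, size=(2, N_AGE, N_EDU))
        target = implied_tfr(fer, fem)
        out, s = calibrate_fertility(fer, target, fem)
        assert s == pytest.approx(1.0)
        np.testing.assert_allclose(out, fer)

    def test_fertility_scaling_is_proportional_and_exact(self, rng):
        fer = np.zeros((2, N_AGE, N_EDU))
        fer[:, 15:50, :] = rng.uniform(0.01, 0.1, size=(2, 35, N_EDU))
        fem = rng.uniform(10, 100, size=(2, N_AGE, N_EDU))
        out, s = calibrate_fertility(fer, 1.8, fem)
        assert implied_tfr(out, fem) == pytest.approx(1.8, abs=1e-9)
        out2, s2 = calibrate_fertility(fer, 3.6, fem)
        np.testing.assert_allclose(out2, 2 * out, rtol=1e-12)

    def test_fertility_all_zero_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_fertility(np.zeros((1, N_AGE, N_EDU)), 1.6,
                                np.ones((1, N_AGE, N_EDU)))

    def test_mortality_round_trip_hits_target(self, rng):
        base = np.clip(rng.uniform(0.001, 0.05, size=N_AGE), 0, 1)
        le0 = life_expectancy(base)
        out, k = calibrate_mortality(base, le0)
        assert k == pytest.approx(1.0)
        out, k = calibrate_mortality(base, le0 + 5.0)
        assert k < 1.0
        assert life_expectancy(out) == pytest.approx(le0 + 5.0, abs=1e-6)

    def test_mortality_unreachable_target_names_bracket(self):
        base = np.full(N_AGE, 0.01)
        with pytest.raises(CalibrationError, match="achievable range"):
            calibrate_mortality(base, 200.0)


# --------------------------------------------------------------------------
# births and cohort iteration
# --------------------------------------------------------------------------

class TestBirthsAndAging:
    def test_zero_fertility_zero_newborns(self, rng):
        st_ = random_state(rng)
        boys, girls = compute_births(
            st_.females(), np.zeros((3, N_AGE, N_EDU)),
            np.full(3, 0.517), np.full(3, 0.483))
        assert np.all(boys == 0) and np.all(girls == 0)

    def test_single_fertile_cell_hand_arithmetic(self):
        fem = np.zeros((1, N_AGE, N_EDU))
        fem[0, 25, 2] = 1000.0
        fer = np.zeros((1, N_AGE, N_EDU))
        fer[0, 25, 2] = 0.1
        boys, girls = compute_births(fem, fer, np.array([0.517]),
                                     np.array([0.483]))
        assert boys[0] == pytest.approx(51.7)
        assert girls[0] == pytest.approx(48.3)

    def test_births_invariant_to_province_permutation(self, rng):
        st_ = random_state(rng)
        fer = np.zeros((3, N_AGE, N_EDU))
        fer[:, 15:50, :] = rng.uniform(0, 0.2, size=(3, 35, N_EDU))
        bm, bf = np.full(3, 0.51), np.full(3, 0.49)
        boys, girls = compute_births(st_.females(), fer, bm, bf)
        perm = [2, 0, 1]
        boys_p, girls_p = compute_births(st_.females()[perm], fer[perm], bm, bf)
        assert boys_p.sum() == pytest.approx(boys.sum())
        np.testing.assert_allclose(boys_p, boys[perm])

    def test_pure_aging_shifts_and_conserves(self, rng):
        st_ = random_state(rng)
        nxt = age_and_educate(st_, make_rates(3))
        # each cohort advances exactly one year
        np.testing.assert_allclose(nxt.counts[:, :, 1:100, :],
                                   st_.counts[:, :, 0:99, :])
        assert nxt.counts[:, :, 0, :].sum() == 0
        assert nxt.total() == pytest.approx(st_.total())

    def test_open_interval_pools_99_and_100plus(self):
        counts = np.zeros((1, N_SEX, N_AGE, N_EDU))
        counts[0, 0, 99, 0] = 100.0
        counts[0, 0, 100, 0] = 50.0
        st_ = PopulationState(counts, 2010, ("A",))
        nxt = age_and_educate(st_, make_rates(1))
        assert nxt.counts[0, 0, 100, 0] == pytest.approx(150.0)

    def test_survival_and_migration_hand_arithmetic(self):
        counts = np.zeros((1, N_SEX, N_AGE, N_EDU))
        counts[0, 0, 40, 3] = 1000.0
        st_ = PopulationState(counts, 2010, ("A",))
        nxt = age_and_educate(st_, make_rates(
            1, mor=np.full((1, N_SEX, N_AGE), 0.1), netpim=0.05))
        assert nxt.counts[0, 0, 41, 3] == pytest.approx(1000 * 0.9 * 1.05)

    def test_education_transition_fires_only_at_entry_age(self):
        counts = np.zeros((1, N_SEX, N_AGE, N_EDU))
        counts[0, 0, 5, 0] = 100.0   # will reach primary entry age 6
        counts[0, 0, 8, 0] = 100.0   # will reach 9: no transition
        st_ = PopulationState(counts, 2010, ("A",))
        g = np.zeros((1, N_SEX, len(TRANSITIONS)))
        g[:, :, 0] = 0.9  # enrolment
        nxt = age_and_educate(st_, make_rates(1, g=g))
        assert nxt.counts[0, 0, 6, 1] == pytest.approx(90.0)
        assert nxt.counts[0, 0, 6, 0] == pytest.approx(10.0)
        assert nxt.counts[0, 0, 9, 0] == pytest.approx(100.0)
        assert nxt.counts[0, 0, 9, 1] == 0.0

    def test_senior_high_branches_to_college_and_bachelor(self):
        counts = np.zeros((1, N_SEX, N_AGE, N_EDU))
        counts[0, 1, 18, 3] = 1000.0  # senior high, reaching age 19
        st_ = PopulationState(counts, 2010, ("A",))
        g = np.zeros((1, N_SEX, len(TRANSITIONS)))
        g[:, :, 3] = 0.2   # senior -> college
        g[:, :, 4] = 0.5   # senior -> bachelor
        nxt = age_and_educate(st_, make_rates(1, g=g))
        assert nxt.counts[0, 1, 19, 4] == pytest.approx(200.0)
        assert nxt.counts[0, 1, 19, 5] == pytest.approx(500.0)
        assert nxt.counts[0, 1, 19, 3] == pytest.approx(300.0)


# --------------------------------------------------------------------------
# naive oracle equivalence
# --------------------------------------------------------------------------

def naive_iterate(state: PopulationState, rates: RateSet) -> np.ndarray:
    """Deliberately slow per-cell reference of the cohort-iteration rule."""
    p = state.n_provinces
    counts = state.counts
    netpim = rates.netpim_full()
    out = np.zeros_like(counts)
    entry_of = {}  # (src, dst) -> entry age
    for t, (src, dst, entry) in enumerate(TRANSITIONS):
        entry_of[(src, dst)] = (t, entry)
    for i in range(p):
        for s in range(N_SEX):
            for a in range(N_AGE):
                a_next = min(a + 1, 100)
                for e in range(N_EDU):
                    base = (counts[i, s, a, e]
                            * (1 - rates.mor[i, s, a])
                            * (1 + netpim[i, s, a, e]))
                    g_out = 0.0
                    for (src, dst), (t, entry) in entry_of.items():
                        if src == e and a == entry - 1:
                            g_out += rates.g[i, s, t]
                            out[i, s, a_next, dst] += (
                                base * rates.g[i, s, t] * (1 + rates.netgim))
                    out[i, s, a_next, e] += base * (1 - g_out) * (1 + rates.netgim)
    return out


class TestOracleEquivalence:
    def test_vectorized_engine_matches_naive_loop(self, rng):
        for trial in range(3):
            st_ = random_state(rng)
            g = rng.uniform(0, 0.4, size=(3, N_SEX, len(TRANSITIONS)))
            g[:, :, 3] = rng.uniform(0, 0.3, size=(3, N_SEX))
            g[:, :, 4] = rng.uniform(0, 0.6, size=(3, N_SEX))
            rates = make_rates(
                3,
                mor=rng.uniform(0, 0.2, size=(3, N_SEX, N_AGE)),
                g=g,
                netpim=rng.uniform(-0.05, 0.05, size=(3, 1, N_AGE, 1)),
                netgim=-0.0003,
            )
            expected = naive_iterate(st_, rates)
            got = age_and_educate(st_, rates).counts
            np.testing.assert_allclose(
                got[:, :, 1:, :], expected[:, :, 1:, :], rtol=1e-9)


# --------------------------------------------------------------------------
# migration rebalancing
# --------------------------------------------------------------------------

class TestRebalance:
    def _flows(self, netpim, state):
        full = np.broadcast_to(
            netpim, (state.n_provinces, N_SEX, N_AGE, N_EDU))
        return (full * state.counts).sum(axis=(1, 2, 3))

    def test_balanced_flows_unchanged(self):
        counts = np.ones((2, N_SEX, N_AGE, N_EDU))
        st_ = PopulationState(counts, 2010, ("A", "B"))
        netpim = np.array([0.01, -0.01]).reshape(2, 1, 1, 1)
        out, factor = rebalance_migration(netpim, st_)
        assert factor == 1.0
        np.testing.assert_allclose(out, netpim)

    def test_proportional_cutback_of_heavier_side(self):
        # at-risk populations equal; inflow 150+50, outflow 100
        counts = np.full((3, N_SEX, N_AGE, N_EDU), 1.0)
        st_ = PopulationState(counts, 2010, ("A", "B", "C"))
        n_cells = N_SEX * N_AGE * N_EDU
        netpim = (np.array([150.0, 50.0, -100.0]) / n_cells).reshape(3, 1, 1, 1)
        out, factor = rebalance_migration(netpim, st_)
        assert factor == pytest.approx(0.5)
        flows = self._flows(out, st_)
        assert flows[0] == pytest.approx(75.0)
        assert flows[1] == pytest.approx(25.0)
        assert flows[2] == pytest.approx(-100.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_flow_sum_zero_property(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 6))
        counts = rng.uniform(0, 1e5, size=(p, N_SEX, N_AGE, N_EDU))
        st_ = PopulationState(counts, 2010, tuple(f"P{i}" for i in range(p)))
        netpim = rng.uniform(-0.05, 0.05, size=(p, 1, N_AGE, 1))
        out, _ = rebalance_migration(netpim, st_)
        assert abs(self._flows(out, st_).sum()) < 1e-9 * counts.sum() + 1e-9


# --------------------------------------------------------------------------
# full projection
# --------------------------------------------------------------------------

class TestProject:
    def test_zero_everything_conserves_total(self, rng, small_world):
        st_ = random_state(rng, p=3)

        class ZeroScenario:
            tfr_path = {y: 1e-12 for y in range(2010, 2101)}
            le_path = {y: np.full((3, 2), 110.0) for y in range(2010, 2101)}
            netpim_path = {y: np.zeros(3) for y in range(2010, 2101)}
            netgim_path = {y: 0.0 for y in range(2010, 2101)}
            srb_path = {y: np.full(3, 1.07) for y in range(2010, 2101)}
            pr_path = {y: np.zeros((3, N_SEX, len(TRANSITIONS)))
                       for y in range(2010, 2101)}

        rates = make_rates(3)
        rates.fer[:, 15:50, :] = 1.0  # shape only; scaled to ~0 TFR
        states, _ = project(st_, ZeroScenario(), rates, end_year=2030)
        for out in states:
            assert out.total() == pytest.approx(st_.total(), rel=1e-9)
        # everyone born before 2010 eventually pools in the open interval
        assert states[-1].counts[:, :, 80:, :].sum() > 0

    def test_no_negative_counts_and_determinism(self, small_world):
        spec = assemble_ssp("SSP2", small_world)
        states, _ = project(small_world.base_state, spec,
                            small_world.base_rates, end_year=2040)
        for st_ in states:
            assert np.all(st_.counts >= 0)
        states2, _ = project(small_world.base_state, spec,
                             small_world.base_rates, end_year=2040)
        np.testing.assert_array_equal(states[-1].counts, states2[-1].counts)

    def test_calibration_round_trips_every_year(self, small_world):
        spec = assemble_ssp("SSP2", small_world)
        states, logs = project(small_world.base_state, spec,
                               small_world.base_rates, end_year=2025)
        for prev, lg in zip(states, logs):
            fer = small_world.base_rates.fer * lg.fertility_scale
            assert implied_tfr(fer, prev.females()) == pytest.approx(
                spec.tfr_path[lg.year], abs=1e-9)

    def test_high_fertility_ssp3_exceeds_ssp1_by_2100(self, small_world):
        s1 = assemble_ssp("SSP1", small_world)
        s3 = assemble_ssp("SSP3", small_world)
        st1, _ = project(small_world.base_state, s1, small_world.base_rates)
        st3, _ = project(small_world.base_state, s3, small_world.base_rates)
        assert st3[-1].total() >= st1[-1].total()
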
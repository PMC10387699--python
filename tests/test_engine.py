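import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from msseqsim.economics import compute_nhb
from msseqsim.engine import (
    EDSS_MILESTONE,
    OFF_TREATMENT,
    PatientState,
    UnknownEfficacyError,
    _baseline_edss,
    _poisson_icdf,
    _simulate_patient_from_uniforms,
    apply_switch_rules,
    check_discontinuation,
    draw_cycle_outcome,
    effective_progression_prob,
    effective_relapse_rate,
    initialize_cohort,
    run_cohort_detail,
    simulate_cohort,
    simulate_patient,
)
from msseqsim.grammar import SequenceSpec
from msseqsim.parameters import MAX_AGE, EfficacyEstimate, Measure, UNKNOWN

from conftest import make_toy_params


def _irr(x):
    return EfficacyEstimate.certain(x, Measure.IRR_ARR)


def _rr(x):
    return EfficacyEstimate.certain(x, Measure.RR_CDP)


class TestEfficacyScaling:
    @pytest.mark.parametrize(
        "base, ratio, expected",
        [(0.5, 1.0, 0.5), (0.5, 0.40, 0.20), (0.5, 0.30, 0.15)],
    )
    def test_relapse_rate_scaling(self, base, ratio, expected):
        assert effective_relapse_rate(base, _irr(ratio)) == pytest.approx(expected)

    def test_relapse_rate_rejects_negative_base(self):
        with pytest.raises(ValueError):
            effective_relapse_rate(-0.1, _irr(0.5))

    @pytest.mark.parametrize(
        "p, rr, expected",
        [
            (0.10, 1.0, 0.10),
            # 1 - exp(0.45 * ln 0.90), frozen from the closed form
            (0.10, 0.45, 0.0463058268),
            (0.0, 0.45, 0.0),
        ],
    )
    def test_progression_prob_rate_scaling(self, p, rr, expected):
        assert effective_progression_prob(p, _rr(rr)) == pytest.approx(expected, abs=1e-9)

    def test_progression_prob_unknown_sentinel(self):
        with pytest.raises(UnknownEfficacyError, match="threshold"):
            effective_progression_prob(0.1, UNKNOWN)


class TestPoissonInverseCdf:
    def test_matches_scipy_ppf(self):
        rng = np.random.default_rng(0)
        u = rng.random(5000)
        lam = rng.uniform(0.01, 2.5, 5000)
        ours = _poisson_icdf(u, lam)
        theirs = stats.poisson.ppf(u, lam)
        np.testing.assert_array_equal(ours, theirs.astype(int))

    def test_monotone_in_rate_for_fixed_uniform(self):
        u = np.full(200, 0.9)
        lam = np.linspace(0.01, 2.0, 200)
        k = _poisson_icdf(u, lam)
        assert (np.diff(k) >= 0).all()


class TestCohortInitialization:
    def test_even_split_over_baseline_states(self, default_params):
        patients = initialize_cohort(default_params, 10_000)
        counts = np.bincount([p.edss for p in patients], minlength=4)
        assert counts.tolist() == [2500, 2500, 2500, 2500]
        assert all(p.age == 29 and p.alive and p.current_line_index == 0 for p in patients)

    def test_n4_one_per_state(self, default_params):
        patients = initialize_cohort(default_params, 4)
        assert sorted(p.edss for p in patients) == [0, 1, 2, 3]

    def test_n7_max_difference_one_and_deterministic(self, default_params):
        c1 = [p.edss for p in initialize_cohort(default_params, 7, seed=1)]
        c2 = [p.edss for p in initialize_cohort(default_params, 7, seed=1)]
        assert c1 == c2
        counts = np.bincount(c1, minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_rejects_tiny_cohort(self, default_params):
        with pytest.raises(ValueError):
            initialize_cohort(default_params, 3)


class TestCycleOutcome:
    def test_huge_mortality_multiplier_kills(self):
        params = make_toy_params(hazard=1e9)
        state = PatientState(age=29, edss=0)
        rng = np.random.default_rng(0)
        outcomes = [draw_cycle_outcome(state, None, params, rng) for _ in range(200)]
        assert all(o.died for o in outcomes)

    def test_zero_relapse_rate_yields_zero_counts(self):
        params = make_toy_params(relapse_rates=(0.0, 0.0, 0.0), hazard=1e-9)
        state = PatientState(age=29, edss=0)
        rng = np.random.default_rng(0)
        assert all(
            draw_cycle_outcome(state, None, params, rng).n_relapses == 0 for _ in range(200)
        )

    def test_poisson_mean_under_treatment(self, default_params):
        """Base rate 0.4 under IRR 0.40 averages 0.16 relapses/cycle."""
        params = make_toy_params(relapse_rates=(0.4, 0.4, 0.4), hazard=1e-9)
        dmt = dataclasses.replace(
            default_params.dmt("OCR"), efficacy_arr=_irr(0.40), efficacy_cdp=_rr(1.0),
            ae_discontinuation_prob=0.0,
        )
        state = PatientState(age=29, edss=0)
        rng = np.random.default_rng(42)
        k = [draw_cycle_outcome(state, dmt, params, rng).n_relapses for _ in range(10_000)]
        se = math.sqrt(0.16 / 10_000)
        assert np.mean(k) == pytest.approx(0.16, abs=3 * se)


class TestSwitchRules:
    def _seq(self, with_1b):
        if with_1b:
            return SequenceSpec(lines=("E1", "E2", "H1", "H2", "L"), has_line1b=True)
        return SequenceSpec(lines=("H1", "H2", "H3", "L"))

    def _state(self, pos, seq):
        return PatientState(
            age=30.0, edss=2, current_line_index=pos, current_line_label=seq.line_label(pos)
        )

    def _outcome(self, relapses=0, progressed=False, ae=False):
        from msseqsim.engine import CycleOutcome

        return CycleOutcome(relapses, progressed, 2 + progressed, ae, died=False)

    def test_adverse_event_on_1a_enters_1b(self):
        seq = self._seq(with_1b=True)
        s = apply_switch_rules(self._state(0, seq), self._outcome(ae=True), seq)
        assert s.current_line_index == 1 and s.current_line_label == "1b"

    def test_efficacy_event_on_1a_skips_1b(self):
        seq = self._seq(with_1b=True)
        s = apply_switch_rules(self._state(0, seq), self._outcome(relapses=1), seq)
        assert s.current_line_index == 2 and s.current_line_label == "2"

    def test_event_on_final_line_goes_off_treatment(self):
        seq = self._seq(with_1b=False)
        s = apply_switch_rules(self._state(3, seq), self._outcome(relapses=1), seq)
        assert s.current_line_index == OFF_TREATMENT

    def test_quiet_cycle_stays_put(self):
        seq = self._seq(with_1b=False)
        state = self._state(1, seq)
        state.years_since_last_event = 3
        s = apply_switch_rules(state, self._outcome(), seq)
        assert s.current_line_index == 1
        assert s.years_since_last_event == 4
        assert s.years_on_current_dmt == 1

    def test_relapse_resets_event_clock_but_ae_does_not(self):
        seq = self._seq(with_1b=False)
        state = self._state(1, seq)
        state.years_since_last_event = 3
        s = apply_switch_rules(state, self._outcome(ae=True), seq)
        assert s.years_since_last_event == 4  # AE is not a disease event
        state2 = self._state(1, seq)
        state2.years_since_last_event = 3
        s2 = apply_switch_rules(state2, self._outcome(relapses=2), seq)
        assert s2.years_since_last_event == 0


class TestDiscontinuation:
    @pytest.mark.parametrize(
        "age, quiet_years, label, expected",
        [
            (50, 5, "2", True),
            (50, 5, "1a", True),
            (49, 10, "1a", False),
            (50, 4, "1b", False),
            (70, 10, "3", True),
            (69, 12, "3", False),
            (70, 9, "3", False),
            (80, 20, "4", False),  # final line carries no stopping rule
        ],
    )
    def test_stopping_rule_truth_table(self, age, quiet_years, label, expected):
        state = PatientState(
            age=age, edss=3, current_line_index=1, current_line_label=label,
            years_since_last_event=quiet_years,
        )
        assert check_discontinuation(state) is expected

    def test_off_treatment_never_discontinues(self):
        state = PatientState(age=80, edss=3, current_line_index=OFF_TREATMENT,
                             years_since_last_event=30)
        assert check_discontinuation(state) is False


class TestSimulatePatient:
    def test_instant_mortality_gives_empty_accrual(self):
        params = make_toy_params(hazard=1e9)
        traj = simulate_patient(None, params, np.random.default_rng(0))
        assert len(traj.records) == 0
        assert traj.summary.life_years == 0
        assert traj.summary.lifetime_relapses == 0

    def test_same_seed_identical_trajectory(self, default_params, ocr_first_line):
        t1 = simulate_patient(ocr_first_line, default_params, np.random.default_rng(5))
        t2 = simulate_patient(ocr_first_line, default_params, np.random.default_rng(5))
        assert t1.summary == t2.summary
        assert t1.records == t2.records


class TestSimulateCohort:
    def test_single_patient_cohort_equals_patient_path(self, default_params, ocr_first_line):
        det = run_cohort_detail(ocr_first_line, default_params, n=1, seed=3)
        rng = np.random.default_rng(np.random.SeedSequence([3]))
        summary = simulate_patient(ocr_first_line, default_params, rng).summary
        assert det.result.qalys == pytest.approx(summary.qalys, abs=1e-12)
        assert det.result.costs.total == pytest.approx(summary.costs.total, abs=1e-6)
        assert det.result.lifetime_relapses == summary.lifetime_relapses
        assert det.result.life_years == summary.life_years

    def test_scalar_and_vectorized_paths_agree(self, default_params, ocr_first_line):
        """The per-patient reference loop and the vectorized cohort loop
        consume the same streams and must agree patient by patient."""
        n = 25
        C = MAX_AGE - default_params.cohort.start_age
        U = np.random.default_rng(np.random.SeedSequence([11])).random((n, C, 4))
        det = run_cohort_detail(ocr_first_line, default_params, n=n, seed=11)
        e0 = _baseline_edss(default_params, n)
        for i in range(n):
            s = _simulate_patient_from_uniforms(
                ocr_first_line, default_params, U[i], edss0=int(e0[i])
            ).summary
            assert s.qalys == pytest.approx(det.qalys[i], abs=1e-12)
            assert s.costs.total == pytest.approx(det.total_costs[i], abs=1e-6)
            assert s.lifetime_relapses == det.relapses[i]
            assert s.life_years == det.life_years[i]
            assert s.time_in_line1 == det.time_in_line1[i]

    def test_bit_identical_given_seed(self, default_params, ocr_first_line):
        r1 = simulate_cohort(ocr_first_line, default_params, n=400, seed=13)
        r2 = simulate_cohort(ocr_first_line, default_params, n=400, seed=13)
        assert r1 == r2

    def test_unknown_progression_efficacy_refused(self, default_params):
        seq = SequenceSpec(lines=("RIT", "CLA", "NAT", "ALE"))
        with pytest.raises(UnknownEfficacyError, match="RIT"):
            simulate_cohort(seq, default_params, n=10, seed=0)

    def test_qalys_bounded_by_life_years(self, default_params, ocr_first_line):
        r = simulate_cohort(ocr_first_line, default_params, n=400, seed=13)
        assert r.qalys <= r.life_years
        assert r.nhb == pytest.approx(
            compute_nhb(r.qalys, r.costs.total, default_params.economics.wtp), abs=1e-9
        )

    def test_flat_utility_no_discounting_accrues_product(self):
        """Ten event-free years at a 0.782 utility accrue 7.82 QALYs."""
        params = make_toy_params(hazard=1e-12, relapse_rates=(0.0, 0.0, 0.0), worsen=(0.0, 0.0))
        params.economics.utility_by_edss = np.array([0.782, 0.782, 0.782])
        params.economics.discount_rate_effects = 0.0
        lt = params.natural_history.life_table.copy()
        lt[39:] = 1e9  # force death at age 39, ten cycles in
        params.natural_history.life_table = lt
        r = simulate_cohort(None, params, n=50, seed=0)
        assert r.life_years == 10.0
        assert r.qalys == pytest.approx(7.82, abs=1e-9)


class TestEffectMonotonicityUnderCommonRandomNumbers:
    def test_lower_irr_never_more_relapses(self, default_params, ocr_first_line):
        strong = default_params.replace_dmt(
            dataclasses.replace(default_params.dmt("OCR"), efficacy_arr=_irr(0.30))
        )
        weak = default_params.replace_dmt(
            dataclasses.replace(default_params.dmt("OCR"), efficacy_arr=_irr(0.90))
        )
        rs = simulate_cohort(ocr_first_line, strong, n=2000, seed=21)
        rw = simulate_cohort(ocr_first_line, weak, n=2000, seed=21)
        assert rs.lifetime_relapses <= rw.lifetime_relapses

    def test_lower_rr_slows_disability(self, default_params, ocr_first_line):
        strong = default_params.replace_dmt(default_params.dmt("OCR").with_cdp(0.30))
        weak = default_params.replace_dmt(default_params.dmt("OCR").with_cdp(1.0))
        rs = simulate_cohort(ocr_first_line, strong, n=2000, seed=21)
        rw = simulate_cohort(ocr_first_line, weak, n=2000, seed=21)
        assert rs.time_to_edss6 >= rw.time_to_edss6
        assert rs.fraction_reaching_edss6 <= rw.fraction_reaching_edss6


class TestEffectRecovery:
    def test_progression_and_relapse_ratios_recovered(self, default_params):
        """Simulating a known IRR/RR and re-estimating both from pooled
        on-treatment patient-cycles recovers the inputs within Monte-Carlo
        CIs (cross-checked against a cloglog GLM for the hazard ratio)."""
        from msseqsim.engine import estimate_irr_from_cycles, estimate_rr_cdp_from_cycles

        test_dmt = dataclasses.replace(
            default_params.dmt("OCR"),
            name="TST",
            efficacy_arr=_irr(0.40),
            efficacy_cdp=_rr(0.45),
            ae_discontinuation_prob=0.0,
        )
        params = default_params.replace_dmt(test_dmt)
        seq = SequenceSpec(lines=("TST", "ALE"))
        det = run_cohort_detail(seq, params, n=10_000, seed=101, collect_cycles=True)
        irr_hat, irr_ci = estimate_irr_from_cycles(det.cycles, params, position=0)
        rr_hat, rr_ci = estimate_rr_cdp_from_cycles(det.cycles, params, position=0)
        assert irr_ci[0] <= 0.40 <= irr_ci[1]
        assert rr_ci[0] <= 0.45 <= rr_ci[1]
        # independent oracle: statsmodels binomial GLM with cloglog link and
        # the natural-history worsening rate as offset -> exp(intercept) = RR
        import statsmodels.api as sm

        T = params.natural_history.transition_matrix
        w = np.array([T[s, s + 1:].sum() for s in range(T.shape[0])])
        m = det.cycles["position"] == 0
        r = -np.log1p(-w[det.cycles["edss"][m]])
        keep = r > 0
        y = det.cycles["progressed"][m][keep].astype(float)
        glm = sm.GLM(
            y,
            np.ones((y.size, 1)),
            family=sm.families.Binomial(link=sm.families.links.CLogLog()),
            offset=np.log(r[keep]),
        ).fit()
        rr_glm = float(np.exp(glm.params[0]))
        assert rr_hat == pytest.approx(rr_glm, rel=1e-3)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_cohort_means_are_finite_and_ordered(seed):
    """Basic sanity over arbitrary seeds on the toy model: finite outputs,
    QALYs bounded by life years, non-negative accruals."""
    params = make_toy_params()
    r = simulate_cohort(None, params, n=50, seed=seed)
    assert np.isfinite(r.qalys) and np.isfinite(r.costs.total)
    assert 0 <= r.qalys <= r.life_years <= MAX_AGE - 29
    assert r.costs.drug == 0.0
    assert r.lifetime_relapses >= 0
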
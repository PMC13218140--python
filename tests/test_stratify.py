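import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from improve_cea.params import ImproveCoefficients
from improve_cea.stratify import (
    StrategyError,
    assign,
    conditional_risk,
    confusion_stats,
    improve_risk,
    km_stroke_free,
    needs_mri,
    risk_3y,
)

from oracles import greenwood_se, product_limit


def make_patient(**kw):
    base = dict(
        age=70.0,
        sex="female",
        index_event="amaurosis_fugax",
        stenosis="lt50",
        iph=False,
        days_since_event=5.0,
    )
    base.update(kw)
    return base


def null_coefficients(**kw):
    base = dict(
        baseline_survival_36m=0.90,
        age_center=70.0,
        beta_age=0.0,
        beta_male=0.0,
        beta_sten_50_69=0.0,
        beta_sten_70_99=0.0,
        beta_cerebral=0.0,
        beta_iph=0.0,
    )
    base.update(kw)
    return ImproveCoefficients(**base)


class TestRiskModel:
    def test_reference_patient_risk_is_one_minus_baseline_survival(self):
        coef = null_coefficients()
        assert improve_risk(make_patient(), coef) == pytest.approx(0.10)

    def test_doubled_hazard_squares_survival(self):
        # exp(LP) = 2 -> risk = 1 - 0.9^2 = 0.19
        coef = null_coefficients(beta_iph=np.log(2.0))
        assert improve_risk(make_patient(iph=True), coef) == pytest.approx(0.19)

    def test_positive_coefficient_raises_risk(self, params):
        lo = improve_risk(make_patient(), params.improve)
        hi = improve_risk(make_patient(iph=True), params.improve)
        assert hi > lo

    @given(
        beta=st.floats(0.01, 2.0),
        age_delta=st.floats(0.5, 20.0),
    )
    def test_risk_monotone_in_age(self, beta, age_delta):
        coef = null_coefficients(beta_age=beta)
        young = improve_risk(make_patient(age=70.0), coef)
        old = improve_risk(make_patient(age=70.0 + age_delta), coef)
        assert old > young

    def test_conditional_equals_unconditional_within_9_days(self):
        coef = null_coefficients()
        assert improve_risk(make_patient(days_since_event=9.0), coef) == pytest.approx(
            improve_risk(make_patient(days_since_event=1.0), coef)
        )

    def test_next36_window_with_constant_hazard_is_memoryless(self):
        coef = null_coefficients()
        assert improve_risk(
            make_patient(days_since_event=120.0), coef
        ) == pytest.approx(0.10)

    def test_post_index_window_shrinks_with_elapsed_time(self):
        coef = null_coefficients(conditional_window="post_index")
        risks = [
            improve_risk(make_patient(days_since_event=d), coef)
            for d in (9.0, 60.0, 300.0, 36.5 * 30.4375)
        ]
        assert risks[0] > risks[1] > risks[2] > risks[3]
        assert risks[3] == pytest.approx(0.0)
        assert risks[0] == pytest.approx(0.10)


class TestConditionalRisk:
    def test_no_conditioning(self):
        assert conditional_risk(0.90, 1.0) == pytest.approx(0.10)

    def test_partial_conditioning(self):
        assert conditional_risk(0.90, 0.95) == pytest.approx(1 - 0.90 / 0.95)

    def test_zero_residual_at_window_end(self):
        assert conditional_risk(0.9, 0.9) == 0.0

    def test_undefined_on_zero_survival(self):
        with pytest.raises(ZeroDivisionError):
            conditional_risk(0.0, 0.0)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            conditional_risk(0.95, 0.90)


class TestAssign:
    def test_cau_depends_only_on_stenosis(self, cohort):
        a = assign(cohort, "cau")
        merged = cohort.merge(a, left_on="id", right_on="patient_id")
        assert (
            (merged.assigned == "cea_plus_omt")
            == merged.stenosis.isin(["s50_69", "s70_99"])
        ).all()
        assert not a.needs_mri.any()

    def test_cau_70_99_variant(self, cohort):
        a = assign(cohort, "cau_70_99")
        merged = cohort.merge(a, left_on="id", right_on="patient_id")
        assert ((merged.assigned == "cea_plus_omt") == (merged.stenosis == "s70_99")).all()

    def test_risk_at_threshold_assigns_surgery(self, params):
        df = pd.DataFrame([make_patient(iph=True, stenosis="s70_99", sex="male")])
        df["id"] = [0]
        tau = float(risk_3y(df, params.improve).iloc[0])
        a = assign(df, "improve", params.improve, tau)
        assert a.assigned.iloc[0] == "cea_plus_omt"

    def test_unreachable_threshold_assigns_nobody(self, cohort, params):
        a = assign(cohort, "improve", params.improve, 1.0)
        assert (a.assigned == "omt_only").all()

    def test_unknown_strategy(self, cohort):
        with pytest.raises(StrategyError, match="unknown strategy"):
            assign(cohort, "guidelines_2003")

    def test_threshold_monotonicity(self, cohort, params):
        taus = [0.05, 0.08, 0.12, 0.20]
        sets = [
            set(
                assign(cohort, "improve", params.improve, t)
                .query("assigned == 'cea_plus_omt'")["patient_id"]
            )
            for t in taus
        ]
        for lower, higher in zip(sets, sets[1:]):
            assert higher <= lower


class TestNeedsMri:
    def test_straddling_patients_flagged(self, cohort, params):
        tau = 0.10
        flagged = needs_mri(cohort, params.improve, tau)
        r0 = risk_3y(cohort.assign(iph=False), params.improve)
        r1 = risk_3y(cohort.assign(iph=True), params.improve)
        assert (flagged == ((r0 >= tau) != (r1 >= tau))).all()
        # a patient already above threshold without IPH needs no scan
        assert not flagged[(r0 >= tau)].any()

    def test_zero_threshold_needs_no_scans(self, cohort, params):
        assert not needs_mri(cohort, params.improve, 0.0).any()


class TestKaplanMeier:
    def test_no_censoring_matches_binomial(self):
        times = np.array([5, 8, 40, 40, 40, 40, 40, 40, 40, 40], dtype=float)
        events = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=bool)
        est = km_stroke_free(times, events, 36.0)
        assert est.survival == pytest.approx(0.8)
        assert est.risk == pytest.approx(0.2)

    @pytest.mark.filterwarnings("ignore:no follow-up")
    def test_event_after_censoring_drives_survival_to_zero(self):
        est = km_stroke_free([5.0, 10.0, 20.0], [True, False, True], 36.0)
        assert est.survival == pytest.approx(0.0)

    def test_all_censored(self):
        est = km_stroke_free([10.0, 20.0, 40.0], [False] * 3, 36.0)
        assert est.risk == 0.0 and est.se == 0.0

    def test_short_followup_warns(self):
        with pytest.warns(UserWarning, match="carrying"):
            km_stroke_free([5.0, 10.0], [True, False], 36.0)

    def test_empty_subcohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            km_stroke_free([], [], 36.0)

    @pytest.mark.filterwarnings("ignore:no follow-up")
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_product_limit_oracle_on_small_instances(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 21))
        times = np.round(r.exponential(20.0, n), 1) + 0.1
        events = r.random(n) < 0.6
        est = km_stroke_free(times, events, 36.0)
        assert est.survival == pytest.approx(
            product_limit(times, events, 36.0), abs=1e-12
        )
        assert est.se == pytest.approx(greenwood_se(times, events, 36.0), abs=1e-12)

    def test_beta_spec_moment_matches_km(self):
        r = np.random.default_rng(1)
        times = r.exponential(30.0, 200)
        events = r.random(200) < 0.5
        est = km_stroke_free(times, events, 36.0)
        spec = est.beta_spec()
        a, b = spec.params
        assert a / (a + b) == pytest.approx(est.risk)


class TestConfusionStats:
    @staticmethod
    def build(case_flags, cea_flags, followup=40.0):
        n = len(case_flags)
        cohort = pd.DataFrame(
            {
                "id": range(n),
                "followup_months": [20.0 if c else followup for c in case_flags],
                "ipsilateral_stroke": case_flags,
            }
        )
        assignments = pd.DataFrame(
            {
                "patient_id": range(n),
                "assigned": [
                    "cea_plus_omt" if c else "omt_only" for c in cea_flags
                ],
            }
        )
        return assignments, cohort

    def test_perfect_classification(self):
        a, c = self.build([True, True, False, False], [True, True, False, False])
        stats = confusion_stats(a, c)
        assert stats.sensitivity == 1.0 and stats.specificity == 1.0

    def test_plain_counting(self):
        cases = [True] * 4 + [False] * 10
        cea = [True, True, True, False] + [True] * 4 + [False] * 6
        stats = confusion_stats(*self.build(cases, cea))
        assert stats.sensitivity == pytest.approx(0.75)
        assert stats.specificity == pytest.approx(0.60)
        lo, hi = stats.sensitivity_ci
        assert lo < 0.75 < hi

    def test_everyone_operated(self):
        stats = confusion_stats(*self.build([True, False, False], [True] * 3))
        assert stats.sensitivity == 1.0 and stats.specificity == 0.0

    def test_no_cases_flagged_undefined(self):
        stats = confusion_stats(*self.build([False, False], [True, False]))
        assert stats.sensitivity is None and stats.n_cases == 0

    def test_early_censoring_excluded(self):
        a, c = self.build([False, False, False], [False, False, False], followup=40.0)
        c.loc[2, "followup_months"] = 5.0  # unknown 3-year status
        stats = confusion_stats(a, c)
        assert stats.n_excluded == 1 and stats.n_noncases == 2
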
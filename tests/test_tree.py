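import dataclasses

import numpy as np
import pandas as pd
import pytest

from improve_cea.params import SeveritySplit
from improve_cea.tree import (
    TreeStateError,
    accrue_cost,
    accrue_qaly,
    compare,
    evaluate_tree,
)

from oracles import enumerate_tree


def tiny_cohort(rows):
    """Build a minimal cohort frame from (index_event, baseline_mrs) pairs."""
    return pd.DataFrame(
        {
            "id": range(len(rows)),
            "index_event": [r[0] for r in rows],
            "baseline_mrs": [r[1] for r in rows],
        }
    )


def assignments_for(cohort, assigned, needs_mri=None, strategy="improve"):
    return pd.DataFrame(
        {
            "patient_id": cohort["id"],
            "strategy": strategy,
            "assigned": assigned,
            "needs_mri": needs_mri if needs_mri is not None else [False] * len(cohort),
        }
    )


class TestAccrueQaly:
    def test_full_horizon_at_no_symptom_utility(self):
        assert accrue_qaly(0.960, 0.960, 36.0) == pytest.approx(2.88)

    def test_fatal_perioperative_event(self):
        assert accrue_qaly(0.960, 0.864, 0.0, fatal=True) == 0.0

    def test_disabling_recurrence_at_24_months(self):
        assert accrue_qaly(0.960, 0.356, 24.0) == pytest.approx(
            0.960 * 2 + 0.356 * 1
        )

    def test_negative_time_rejected(self):
        with pytest.raises(TreeStateError):
            accrue_qaly(0.9, 0.5, -1.0)


class TestAccrueCost:
    def test_surgery_plus_scan_no_events(self, params):
        p = params.base()
        assert accrue_cost("none", 36.0, p, is_cea=True, needs_mri=True) == (
            8733 + 254
        )

    def test_nondisabling_recurrence_at_24_months(self, params):
        p = params.base()
        # 3 peak months then 9 tail months to the horizon
        assert accrue_cost("nondisabling", 24.0, p) == pytest.approx(
            14511 + 9 * 999
        )

    def test_peak_cost_prorated_at_horizon(self, params):
        p = params.base()
        assert accrue_cost("nondisabling", 34.5, p) == pytest.approx(14511 * 1.5 / 3)

    def test_fatal_event_stops_baseline_stream(self, params):
        p = params.base().replace(cost_baseline_per_month=100.0)
        assert accrue_cost("fatal", 12.0, p) == pytest.approx(13111 + 100.0 * 12)

    def test_index_stream_truncated_by_early_death(self, params):
        p = params.base()
        cost = accrue_cost("fatal", 1.0, p, index_peak_monthly=14511 / 3)
        assert cost == pytest.approx(13111 + 14511 / 3)

    def test_unknown_severity(self, params):
        with pytest.raises(TreeStateError, match="severity"):
            accrue_cost("catastrophic", 0.0, params.base())


class TestEvaluateTree:
    def test_null_risks_leave_cohort_untouched(self, params):
        p = params.base().replace(p_periop=0.0, p_residual=0.0)
        cohort = tiny_cohort([("tia", 0), ("stroke", 1), ("stroke", 2)])
        a = assignments_for(cohort, ["cea_plus_omt", "omt_only", "omt_only"])
        out = evaluate_tree(cohort, a, p, omt_risk=0.0)
        assert out.primary_endpoint == 0.0
        np.testing.assert_allclose(out.mrs_distribution, [1, 1, 1, 0, 0, 0, 0])

    def test_forced_fatal_perioperative_path(self, params):
        p = params.base().replace(
            p_periop=1.0,
            periop_sev=SeveritySplit(p_nondisabling=0, p_disabling=0, p_fatal=1),
        )
        cohort = tiny_cohort([("tia", 0)])
        out = evaluate_tree(cohort, assignments_for(cohort, ["cea_plus_omt"]), p, 0.0)
        assert out.mrs_distribution[6] == pytest.approx(1.0)
        assert out.qaly_per_patient == 0.0

    def test_expected_stroke_count_on_medical_therapy(self, params):
        cohort = tiny_cohort([("tia", 0), ("tia", 0)])
        a = assignments_for(cohort, ["omt_only", "omt_only"])
        out = evaluate_tree(cohort, a, params.base(), omt_risk=0.5)
        assert out.n_omt.sum() == pytest.approx(1.0)
        assert out.ipsilateral_strokes == pytest.approx(1.0)

    def test_unassigned_patient_rejected(self, params):
        cohort = tiny_cohort([("tia", 0), ("stroke", 1)])
        a = assignments_for(cohort.head(1), ["cea_plus_omt"])
        with pytest.raises(TreeStateError, match="assignment"):
            evaluate_tree(cohort, a, params.base(), 0.1)

    def test_mrs_distribution_sums_to_n(self, cohort, params):
        from improve_cea import assign

        a = assign(cohort, "improve", params.improve, 0.10)
        out = evaluate_tree(cohort, a, params.base(), 0.05)
        assert out.mrs_distribution.sum() == pytest.approx(len(cohort))

    def test_higher_surgical_risk_hurts(self, params):
        cohort = tiny_cohort([("tia", 0)] * 4)
        a = assignments_for(cohort, ["cea_plus_omt"] * 4)
        lo = evaluate_tree(cohort, a, params.base().replace(p_periop=0.01), 0.0)
        hi = evaluate_tree(cohort, a, params.base().replace(p_periop=0.10), 0.0)
        assert hi.qaly_per_patient < lo.qaly_per_patient
        assert hi.primary_endpoint > lo.primary_endpoint

    def test_equal_utilities_zero_costs_no_qaly_difference(self, params):
        p = params.base().replace(
            u_mrs0=0.8, u_nondis_first=0.8, u_nondis_recurrent=0.8,
            u_disabling=0.8, u_fatal=0.8,
            cost_mri=0.0, cost_cea=0.0, cost_nd_first3m=0.0, cost_nd_per_month=0.0,
            cost_dis_first3m=0.0, cost_dis_per_month=0.0, cost_fatal=0.0,
            cost_baseline_per_month=0.0,
        )
        cohort = tiny_cohort([("tia", 0), ("stroke", 2), ("stroke", 1)])
        a1 = assignments_for(cohort, ["cea_plus_omt", "omt_only", "cea_plus_omt"])
        a2 = assignments_for(cohort, ["omt_only"] * 3, strategy="cau")
        o1 = evaluate_tree(cohort, a1, p, 0.2)
        o2 = evaluate_tree(cohort, a2, p, 0.2)
        comp = compare(o2, o1, wtp=50_000)
        assert comp.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert comp.delta_cost == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, params, seed):
        """Expectation arithmetic equals brute-force path enumeration on
        cohorts of up to 5 patients with arbitrary probabilities."""
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 6))
        events = r.choice(["tia", "stroke", "amaurosis_fugax"], n)
        rows = [
            (e, int(r.choice([1, 2])) if e == "stroke" else 0) for e in events
        ]
        cohort = tiny_cohort(rows)
        assigned = r.choice(["cea_plus_omt", "omt_only"], n)
        mri = (r.random(n) < 0.5).tolist()
        a = assignments_for(cohort, assigned.tolist(), needs_mri=mri)

        def random_split():
            x = r.dirichlet([1, 1, 1])
            return SeveritySplit.from_probs(x)

        p = params.base().replace(
            p_periop=float(r.random()),
            p_residual=float(r.random()),
            periop_sev=random_split(),
            residual_sev=random_split(),
            omt_sev=random_split(),
            t_recurrence=float(r.uniform(1, 40)),
            cost_baseline_per_month=float(r.uniform(0, 300)),
        )
        q = float(r.random())
        out = evaluate_tree(cohort, a, p, q)
        oracle = enumerate_tree(
            [
                {"assigned": s, "needs_mri": m, "baseline_mrs": row[1]}
                for s, m, row in zip(assigned, mri, rows)
            ],
            p,
            q,
        )
        assert out.qaly_per_patient == pytest.approx(oracle["qaly_per_patient"])
        assert out.cost_per_patient == pytest.approx(oracle["cost_per_patient"])
        assert out.primary_endpoint == pytest.approx(oracle["primary_endpoint"])
        np.testing.assert_allclose(
            out.mrs_distribution, oracle["mrs_distribution"], atol=1e-10
        )


class TestCompare:
    @staticmethod
    def outcome(qaly, cost, primary=10.0, strategy="x", n=678):
        from improve_cea.tree import TreeOutcome

        return TreeOutcome(
            strategy=strategy,
            n=n,
            n_cea=0.0,
            n_mri=0.0,
            n_periop=np.zeros(3),
            n_postcea=np.zeros(3),
            n_omt=np.zeros(3),
            ipsilateral_strokes=primary,
            primary_endpoint=primary,
            mrs_distribution=np.zeros(7),
            qaly_per_patient=qaly,
            cost_per_patient=cost,
            index_cost_per_patient=0.0,
        )

    def test_printed_delta_arithmetic(self):
        # dQALY 0.014 and a 1386 EUR saving at 50k/QALY give NMB 2086
        ref = self.outcome(2.677, 6509.0)
        alt = self.outcome(2.691, 5123.0)
        comp = compare(ref, alt, wtp=50_000)
        assert comp.nmb == pytest.approx(50_000 * 0.014 + 1386, abs=0.5)
        assert comp.dominant

    def test_identical_outcomes(self):
        o = self.outcome(2.7, 6000.0)
        comp = compare(o, dataclasses.replace(o), 50_000)
        assert comp.delta_qaly == 0 and comp.delta_cost == 0
        assert comp.icer is None and comp.nmb == 0

    def test_reduction_of_primary_endpoint(self):
        comp = compare(
            self.outcome(2.6, 7000.0, primary=29.0),
            self.outcome(2.7, 6000.0, primary=19.0),
            50_000,
        )
        assert comp.reduction_primary_endpoint == pytest.approx(10 / 29)

    def test_mismatched_cohorts_rejected(self):
        with pytest.raises(TreeStateError):
            compare(self.outcome(2.7, 1.0, n=10), self.outcome(2.7, 1.0, n=11), 1.0)
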
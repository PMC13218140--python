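import numpy as np
import pandas as pd
import pytest

from improve_cea.pipeline import base_case
from improve_cea.psa import (
    ce_plane_quadrants,
    ceac,
    run_psa,
    tornado,
    tornado_table,
)

from test_params import _all_fixed_parameters


@pytest.fixture(scope="module")
def psa_result(small_cohort, params):
    return run_psa(small_cohort, params, 0.10, n_draws=300, rng=42)


class TestRunPsa:
    def test_reproducible_with_same_seed(self, small_cohort, params):
        a = run_psa(small_cohort, params, 0.10, n_draws=25, rng=5)
        b = run_psa(small_cohort, params, 0.10, n_draws=25, rng=5)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_degenerate_psa_equals_deterministic(self, small_cohort):
        fixed = _all_fixed_parameters()
        det = base_case(small_cohort, fixed, 0.10)
        res = run_psa(
            small_cohort, fixed, 0.10, n_draws=1, rng=0, sample_stratum_risk=False
        )
        row = res.draws.iloc[0]
        assert row.qaly_ref == pytest.approx(det.reference.outcome.qaly_per_patient)
        assert row.cost_alt == pytest.approx(det.alternative.outcome.cost_per_patient)
        assert row.delta_qaly == pytest.approx(det.comparison.delta_qaly)

    def test_nmb_identity(self, psa_result):
        np.testing.assert_allclose(
            psa_result.draws["nmb"],
            psa_result.wtp * psa_result.draws["delta_qaly"]
            - psa_result.draws["delta_cost"],
            atol=1e-9,
        )

    def test_prob_cost_effective_is_positive_nmb_fraction(self, psa_result):
        assert psa_result.summary["prob_cost_effective"] == pytest.approx(
            (psa_result.draws["nmb"] > 0).mean()
        )

    def test_deterministic_result_inside_psa_interval(self, small_cohort, params):
        det = base_case(small_cohort, params, 0.10)
        res = run_psa(small_cohort, params, 0.10, n_draws=300, rng=42)
        for key, value in (
            ("delta_qaly", det.comparison.delta_qaly),
            ("delta_cost", det.comparison.delta_cost),
        ):
            s = res.summary[key]
            assert s["ci_low"] <= value <= s["ci_high"]

    def test_quadrant_counts_sum_to_draws(self, psa_result):
        assert sum(ce_plane_quadrants(psa_result.draws).values()) == psa_result.n_draws

    def test_sampled_parameter_mean_converges(self, params, rng):
        # PSA draws of the perioperative risk centre on the Beta mean
        draws = np.array([params.sample(rng).p_periop for _ in range(10_000)])
        mean = 235 / (235 + 6224)
        se = np.sqrt(mean * (1 - mean) / (235 + 6224 + 1))
        assert abs(draws.mean() - mean) < 3 * se / np.sqrt(draws.size)

    def test_rejects_no_draws(self, small_cohort, params):
        with pytest.raises(ValueError):
            run_psa(small_cohort, params, 0.10, n_draws=0, rng=0)


class TestCeac:
    @staticmethod
    def fake_draws(dq, dc):
        return pd.DataFrame({"delta_qaly": dq, "delta_cost": dc})

    def test_dominant_draws_give_flat_curve_at_one(self):
        draws = self.fake_draws([0.01, 0.02], [-100.0, -50.0])
        curve = ceac(draws, [0, 25_000, 50_000])
        assert (curve["prob_cost_effective"] == 1.0).all()

    def test_lambda_zero_counts_cost_savings(self):
        draws = self.fake_draws([0.01, 0.01, 0.01], [-1.0, 2.0, -5.0])
        curve = ceac(draws, [0.0])
        assert curve["prob_cost_effective"].iloc[0] == pytest.approx(2 / 3)

    def test_single_draw_is_step_function(self):
        draws = self.fake_draws([0.01], [100.0])  # breaks even at 10,000
        curve = ceac(draws, [5_000, 20_000])
        assert list(curve["prob_cost_effective"]) == [0.0, 1.0]

    def test_monotone_when_all_draws_gain_qalys(self, psa_result):
        curve = ceac(psa_result.draws, np.linspace(0, 100_000, 11))
        assert (np.diff(curve["prob_cost_effective"]) >= 0).all()

    def test_empty_grid_rejected(self, psa_result):
        with pytest.raises(ValueError):
            ceac(psa_result.draws, [])


@pytest.fixture(scope="module")
def entries(small_cohort, params):
    return tornado(small_cohort, params, 0.10, outcome="nmb", top_k=30)


class TestTornado:
    def test_sorted_by_decreasing_range(self, entries):
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_top_k_truncation(self, small_cohort, params):
        top = tornado(small_cohort, params, 0.10, top_k=5)
        assert len(top) == 5

    def test_inputs_bracket_the_distribution(self, entries):
        for e in entries:
            assert e.low_input < e.high_input

    def test_unit_cost_linearity(self, small_cohort, params):
        """Varying the surgery price moves incremental cost by exactly
        (surgery-count difference) x (price change) / n."""
        det = base_case(small_cohort, params, 0.10)
        d_count = det.alternative.outcome.n_cea - det.reference.outcome.n_cea
        entries = tornado(small_cohort, params, 0.10, outcome="delta_cost", top_k=30)
        e = next(x for x in entries if x.parameter == "cost_cea")
        expected = d_count * (e.high_input - e.low_input) / len(small_cohort)
        assert e.outcome_high - e.outcome_low == pytest.approx(expected)

    def test_unused_parameter_has_zero_range(self, small_cohort, params):
        # disable the IPH coefficient: no patient's triage can change with
        # MRI, so the scan price cannot matter
        no_iph = params.model_copy(
            update={"improve": params.improve.model_copy(update={"beta_iph": 0.0})}
        )
        entries = tornado(small_cohort, no_iph, 0.10, outcome="delta_cost", top_k=50)
        e = next(x for x in entries if x.parameter == "cost_mri")
        assert e.range == 0.0

    def test_fixed_parameters_skipped(self, small_cohort):
        fixed = _all_fixed_parameters()
        names = [e.parameter for e in tornado(small_cohort, fixed, 0.10, top_k=50)]
        assert "periop_stroke_death_risk" not in names
        assert "cost_cea" not in names

    def test_table_layout(self, entries):
        table = tornado_table(entries)
        assert list(table.columns) == [
            "parameter", "low_input", "high_input",
            "outcome_low", "outcome_high", "range",
        ]
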
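"""Probabilistic sensitivity analysis, acceptability curves and tornado
diagrams.

Each Monte Carlo draw samples every uncertain input from its distribution
(Beta for probabilities and utilities, Dirichlet for categorical splits,
gamma for costs and recurrence timing) and re-evaluates both strategies on
the same realisation (common random numbers), so each draw's deltas isolate
the strategy effect.  The two strategies' Kaplan-Meier-derived stroke risks
on medical therapy are sampled comonotonically -- one shared uniform pushed
through each stratum's Beta quantile function -- because they estimate risk
in overlapping patient strata.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, distribution_mean, quantile
from .params import NumericParams, ParameterSet, SeveritySplit
from .pipeline import evaluate_strategy
from .tree import compare, evaluate_tree

SEVERITY_LABELS = ("nondisabling", "disabling", "fatal")


@dataclasses.dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws and their summary."""

    draws: pd.DataFrame  # one row per draw
    summary: dict
    reference: str
    alternative: str
    wtp: float
    seed: int | None
    n_draws: int


def _percentile_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = 100 * (1 - level) / 2
    return tuple(np.percentile(x, [lo, 100 - lo]))


def run_psa(
    cohort: pd.DataFrame,
    params: ParameterSet,
    threshold: float,
    n_draws: int | None = None,
    rng: np.random.Generator | int | None = None,
    reference_strategy: str = "cau",
    sample_stratum_risk: bool = True,
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty through both strategies.

    Triage assignments and the per-stratum Beta risk specifications are fixed
    (they derive from the cohort); each draw samples a parameter realisation
    plus comonotone stratum risks and re-evaluates the decision tree.
    """
    if n_draws is None:
        n_draws = params.mc_draws
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    ref = evaluate_strategy(cohort, reference_strategy, params)
    alt = evaluate_strategy(cohort, "improve", params, threshold=threshold)
    q_specs = {"ref": ref.km.beta_spec(), "alt": alt.km.beta_spec()}

    records = []
    for i in range(n_draws):
        numeric = params.sample(rng)
        if sample_stratum_risk:
            u = rng.random()  # shared uniform: comonotone stratum risks
            q_ref = float(np.clip(quantile(q_specs["ref"], u), 0.0, 1.0))
            q_alt = float(np.clip(quantile(q_specs["alt"], u), 0.0, 1.0))
        else:
            q_ref, q_alt = ref.km.risk, alt.km.risk
        out_ref = evaluate_tree(cohort, ref.assignments, numeric, q_ref)
        out_alt = evaluate_tree(cohort, alt.assignments, numeric, q_alt)
        comp = compare(out_ref, out_alt, params.wtp)
        records.append(
            {
                "draw": i,
                "qaly_ref": out_ref.qaly_per_patient,
                "cost_ref": out_ref.cost_per_patient,
                "primary_ref": out_ref.primary_endpoint,
                "qaly_alt": out_alt.qaly_per_patient,
                "cost_alt": out_alt.cost_per_patient,
                "primary_alt": out_alt.primary_endpoint,
                "delta_qaly": comp.delta_qaly,
                "delta_cost": comp.delta_cost,
                "nmb": comp.nmb,
            }
        )
    draws = pd.DataFrame.from_records(records)

    summary = {}
    for col in ("delta_qaly", "delta_cost", "nmb", "qaly_ref", "qaly_alt",
                "cost_ref", "cost_alt", "primary_ref", "primary_alt"):
        x = draws[col].to_numpy()
        ci = _percentile_ci(x)
        summary[col] = {"mean": float(x.mean()), "ci_low": ci[0], "ci_high": ci[1]}
    summary["prob_cost_effective"] = float((draws["nmb"] > 0).mean())
    summary["prob_dominant"] = float(
        ((draws["delta_qaly"] > 0) & (draws["delta_cost"] < 0)).mean()
    )
    summary["reduction_primary_pct"] = float(
        100.0
        * (draws["primary_ref"].mean() - draws["primary_alt"].mean())
        / draws["primary_ref"].mean()
    )
    return PSAResult(
        draws=draws,
        summary=summary,
        reference=reference_strategy,
        alternative="improve",
        wtp=params.wtp,
        seed=seed,
        n_draws=n_draws,
    )


def ceac(draws: pd.DataFrame, lambda_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay lambda, the fraction of draws with positive
    net monetary benefit lambda * dQALY - dCost.
    """
    lambdas = np.asarray(list(lambda_grid), dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be non-empty")
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    p = [(lam * dq - dc > 0).mean() for lam in lambdas]
    return pd.DataFrame({"wtp": lambdas, "prob_cost_effective": p})


def ce_plane_quadrants(draws: pd.DataFrame) -> dict[str, int]:
    """Draw counts per cost-effectiveness-plane quadrant (NE/SE/SW/NW)."""
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    return {
        "ne": int(((dq > 0) & (dc >= 0)).sum()),
        "se": int(((dq > 0) & (dc < 0)).sum()),
        "sw": int(((dq <= 0) & (dc < 0)).sum()),
        "nw": int(((dq <= 0) & (dc >= 0)).sum()),
    }


# ---------------------------------------------------------------------------
# One-way deterministic (tornado) analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float

    @property
    def range(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _severity_variants(split: SeveritySplit, i: int, value: float) -> SeveritySplit:
    """Set category ``i`` of a 3-way split to ``value``, renormalising the rest."""
    p = split.as_array().copy()
    rest = 1.0 - p[i]
    p[i] = value
    others = [j for j in range(3) if j != i]
    if rest > 0:
        for j in others:
            p[j] = p[j] / rest * (1.0 - value)
    else:
        for j in others:
            p[j] = (1.0 - value) / 2.0
    return SeveritySplit.from_probs(p / p.sum())


def _uncertain_parameters(params: ParameterSet, km_ref, km_alt):
    """(name, spec, apply) triples; ``apply(numeric, q_ref, q_alt, value)``
    returns modified (numeric, q_ref, q_alt)."""
    u, c = params.utilities, params.costs
    ess = u.uncertainty_ess

    def beta_spec(mean: float) -> DistributionSpec:
        if ess is None or mean <= 0.0 or mean >= 1.0:
            return DistributionSpec(family="fixed", params=(max(mean, 0.0),))
        return DistributionSpec(family="beta", params=(mean * ess, (1 - mean) * ess))

    def gamma_spec(mean: float) -> DistributionSpec:
        if c.gamma_cv is None or mean <= 0.0:
            return DistributionSpec(family="fixed", params=(max(mean, 0.0),))
        return DistributionSpec(family="gamma", params=(mean, c.gamma_cv))

    entries: list[tuple[str, DistributionSpec, object]] = []

    def scalar(name: str, spec: DistributionSpec, field: str):
        entries.append(
            (name, spec, lambda n, qr, qa, v, f=field: (n.replace(**{f: v}), qr, qa))
        )

    scalar("periop_stroke_death_risk", params.p_periop_stroke_death, "p_periop")
    scalar("residual_stroke_risk_post_cea", params.p_residual_3y_post_cea, "p_residual")

    for attr, label in (
        ("periop_sev", "periop"),
        ("residual_sev", "post_cea"),
        ("omt_sev", "omt"),
    ):
        spec_attr = {"periop": "periop_severity", "post_cea": "residual_severity",
                     "omt": "omt_severity"}[label]
        dir_spec: DistributionSpec = getattr(params, spec_attr)
        counts = np.asarray(dir_spec.params, dtype=float)
        for i, sev in enumerate(SEVERITY_LABELS):
            marg = DistributionSpec(
                family="beta", params=(counts[i], counts.sum() - counts[i])
            )

            def apply_sev(n, qr, qa, v, a=attr, j=i):
                return (
                    n.replace(**{a: _severity_variants(getattr(n, a), j, v)}),
                    qr,
                    qa,
                )

            entries.append((f"{label}_severity_{sev}", marg, apply_sev))

    def apply_u_nd(n, qr, qa, v):
        return (
            n.replace(
                u_nondis_first=v,
                u_nondis_recurrent=max(0.0, v - u.recurrent_decrement),
            ),
            qr,
            qa,
        )

    entries.append(("utility_nondisabling", beta_spec(u.nondisabling_first), apply_u_nd))
    scalar("utility_no_symptoms", beta_spec(u.mrs0), "u_mrs0")
    scalar("utility_disabling", beta_spec(u.disabling), "u_disabling")

    for field, mean, label in (
        ("cost_mri", c.mri, "cost_mri"),
        ("cost_cea", c.cea, "cost_cea"),
        ("cost_nd_first3m", c.nondisabling_first3m, "cost_nondisabling_first3m"),
        ("cost_nd_per_month", c.nondisabling_per_month, "cost_nondisabling_per_month"),
        ("cost_dis_first3m", c.disabling_first3m, "cost_disabling_first3m"),
        ("cost_dis_per_month", c.disabling_per_month, "cost_disabling_per_month"),
        ("cost_fatal", c.fatal_onetime, "cost_fatal_stroke"),
    ):
        scalar(label, gamma_spec(mean), field)

    if params.timing.sd_months > 0:
        timing_spec = DistributionSpec(
            family="gamma",
            params=(params.timing.mean_months,
                    params.timing.sd_months / params.timing.mean_months),
        )
    else:
        timing_spec = DistributionSpec(
            family="fixed", params=(params.timing.mean_months,)
        )
    scalar("time_to_recurrence", timing_spec, "t_recurrence")

    entries.append(
        ("omt_stroke_risk_reference", km_ref.beta_spec(),
         lambda n, qr, qa, v: (n, v, qa))
    )
    entries.append(
        ("omt_stroke_risk_risk_based", km_alt.beta_spec(),
         lambda n, qr, qa, v: (n, qr, v))
    )
    return entries


def tornado(
    cohort: pd.DataFrame,
    params: ParameterSet,
    threshold: float,
    outcome: str = "nmb",
    top_k: int = 10,
    q_low: float = 0.025,
    q_high: float = 0.975,
    reference_strategy: str = "cau",
) -> list[TornadoEntry]:
    """One-at-a-time sensitivity: each uncertain parameter set to its 2.5th
    and 97.5th percentile with the rest at base, ranked by outcome range.

    ``outcome`` is one of nmb / delta_cost / delta_qaly.  Parameters with
    degenerate (fixed) distributions are skipped.
    """
    if outcome not in ("nmb", "delta_cost", "delta_qaly"):
        raise ValueError(f"unknown tornado outcome {outcome!r}")
    ref = evaluate_strategy(cohort, reference_strategy, params)
    alt = evaluate_strategy(cohort, "improve", params, threshold=threshold)
    base_numeric = params.base()

    def evaluate(numeric: NumericParams, q_ref: float, q_alt: float) -> float:
        o_ref = evaluate_tree(cohort, ref.assignments, numeric, q_ref)
        o_alt = evaluate_tree(cohort, alt.assignments, numeric, q_alt)
        return getattr(compare(o_ref, o_alt, params.wtp), outcome)

    results = []
    for name, spec, apply in _uncertain_parameters(params, ref.km, alt.km):
        if spec.family == "fixed":
            continue
        lo = float(np.clip(quantile(spec, q_low), 0.0, np.inf))
        hi = float(np.clip(quantile(spec, q_high), 0.0, np.inf))
        if distribution_mean(spec) is not None and np.isclose(lo, hi):
            continue
        out_lo = evaluate(*apply(base_numeric, ref.km.risk, alt.km.risk, lo))
        out_hi = evaluate(*apply(base_numeric, ref.km.risk, alt.km.risk, hi))
        results.append(TornadoEntry(name, lo, hi, out_lo, out_hi))
    results.sort(key=lambda e: e.range, reverse=True)
    return results[:top_k]


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "range": e.range,
            }
            for e in entries
        ]
    )
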
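"""Shared orchestration: evaluate named strategies on a cohort.

A strategy evaluation couples three steps that the analyses reuse: triage
assignment, Kaplan-Meier estimation of the medical-therapy stratum's 3-year
stroke risk (with its Beta specification for the probabilistic analysis), and
expected-value evaluation of the decision tree.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .params import NumericParams, ParameterSet
from .stratify import KMEstimate, assign, omt_stratum_risk
from .tree import Comparison, TreeOutcome, compare, evaluate_tree


@dataclasses.dataclass(frozen=True)
class StrategyEvaluation:
    strategy: str
    assignments: pd.DataFrame
    km: KMEstimate
    outcome: TreeOutcome


def evaluate_strategy(
    cohort: pd.DataFrame,
    strategy: str,
    params: ParameterSet,
    threshold: float | None = None,
    numeric: NumericParams | None = None,
    omt_risk: float | None = None,
) -> StrategyEvaluation:
    """Assign, estimate the stratum risk and evaluate the tree for one strategy.

    ``numeric`` (a parameter realisation) and ``omt_risk`` default to the
    base case and the KM point estimate; the probabilistic analysis passes
    sampled values instead.
    """
    assignments = assign(cohort, strategy, coef=params.improve, threshold=threshold)
    if (assignments["assigned"] == "omt_only").any():
        km = omt_stratum_risk(cohort, assignments, params.horizon_months)
    else:
        # every patient triaged to surgery: the medical-therapy stroke risk
        # is vacuous, represented as a degenerate estimate
        km = KMEstimate(
            survival=1.0,
            se=0.0,
            risk=0.0,
            horizon_months=params.horizon_months,
            n=0,
            n_events=0,
        )
    if numeric is None:
        numeric = params.base()
    if omt_risk is None:
        omt_risk = km.risk
    outcome = evaluate_tree(cohort, assignments, numeric, omt_risk)
    return StrategyEvaluation(strategy, assignments, km, outcome)


@dataclasses.dataclass(frozen=True)
class BaseCaseResult:
    reference: StrategyEvaluation
    alternative: StrategyEvaluation
    comparison: Comparison


def base_case(
    cohort: pd.DataFrame,
    params: ParameterSet,
    threshold: float,
    reference_strategy: str = "cau",
) -> BaseCaseResult:
    """Deterministic comparison of risk-based triage vs the reference strategy."""
    ref = evaluate_strategy(cohort, reference_strategy, params)
    alt = evaluate_strategy(cohort, "improve", params, threshold=threshold)
    return BaseCaseResult(ref, alt, compare(ref.outcome, alt.outcome, params.wtp))


def seed_streams(seed: int | None, names: tuple[str, ...] = ("cohort", "psa", "scenarios")) -> dict[str, np.random.Generator]:
    """Expand one global seed into named independent substreams.

    Substreams are spawned in a fixed order so, e.g., adding Monte Carlo
    draws never perturbs cohort generation.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}
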
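"""Pre-packaged scenario and subgroup analyses.

Scenarios vary the perioperative stroke/death risk (optimistic 2%, guideline
ceiling 6%) or restrict the reference strategy to 70-99% stenosis; subgroup
analyses re-run the comparison within each stenosis category with
subgroup-specific recurrence timing and subgroup-re-estimated stroke risks
on medical therapy, at both the 3-year and the lifetime horizon.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .lifetime import LifetimePerMRS, configured_lifetime_table, lifetime_comparison
from .params import ParameterSet
from .pipeline import BaseCaseResult, base_case
from .psa import PSAResult, run_psa
from .tree import Comparison

SCENARIOS = ("base", "surgical_risk_2", "surgical_risk_6", "cau_70_99_only")


class ScenarioError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    name: str
    params: ParameterSet
    reference_strategy: str
    deterministic: BaseCaseResult
    lifetime: Comparison
    psa: PSAResult | None


def scenario_overrides(name: str, params: ParameterSet) -> tuple[ParameterSet, str]:
    """Apply a named scenario: (possibly modified) parameters and the
    reference strategy to compare against."""
    if name not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    reference = "cau"
    if name == "surgical_risk_2":
        params = params.model_copy(
            update={
                "p_periop_stroke_death": DistributionSpec(
                    family="fixed", params=(0.02,)
                )
            }
        )
    elif name == "surgical_risk_6":
        params = params.model_copy(
            update={
                "p_periop_stroke_death": DistributionSpec(
                    family="fixed", params=(0.06,)
                )
            }
        )
    elif name == "cau_70_99_only":
        reference = "cau_70_99"
    return params, reference


def run_scenario(
    name: str,
    cohort: pd.DataFrame,
    params: ParameterSet,
    threshold: float,
    n_draws: int = 0,
    rng: np.random.Generator | int | None = None,
    lifetime_table: LifetimePerMRS | None = None,
) -> ScenarioResult:
    """Full deterministic (and optionally probabilistic) comparison under a
    named scenario.  ``name="base"`` reproduces the base-case pipeline."""
    sc_params, reference = scenario_overrides(name, params)
    det = base_case(cohort, sc_params, threshold, reference_strategy=reference)
    if lifetime_table is None:
        lifetime_table = configured_lifetime_table(
            sc_params.lifetime_qaly_per_mrs, sc_params.lifetime_cost_per_mrs
        )
    life = lifetime_comparison(
        det.reference.outcome, det.alternative.outcome, lifetime_table, sc_params.wtp
    )
    psa = (
        run_psa(cohort, sc_params, threshold, n_draws=n_draws, rng=rng,
                reference_strategy=reference)
        if n_draws
        else None
    )
    return ScenarioResult(
        name=name,
        params=sc_params,
        reference_strategy=reference,
        deterministic=det,
        lifetime=life,
        psa=psa,
    )


@dataclasses.dataclass(frozen=True)
class SubgroupResult:
    stenosis: str
    n: int
    timing_mean_months: float
    deterministic: BaseCaseResult
    lifetime: Comparison
    psa: PSAResult | None


def run_subgroups(
    cohort: pd.DataFrame,
    params: ParameterSet,
    threshold: float,
    n_draws: int = 0,
    rng: np.random.Generator | int | None = None,
    lifetime_table: LifetimePerMRS | None = None,
) -> dict[str, SubgroupResult]:
    """Per-stenosis-category comparison with subgroup-specific recurrence
    timing and subgroup-re-estimated medical-therapy stroke risks.

    Empty subgroups are skipped with a warning.
    """
    if lifetime_table is None:
        lifetime_table = configured_lifetime_table(
            params.lifetime_qaly_per_mrs, params.lifetime_cost_per_mrs
        )
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    out: dict[str, SubgroupResult] = {}
    for stenosis in ("lt50", "s50_69", "s70_99"):
        sub = cohort[cohort["stenosis"] == stenosis].reset_index(drop=True)
        if sub.empty:
            warnings.warn(f"subgroup {stenosis} is empty; skipped", stacklevel=2)
            continue
        timing = params.timing_by_stenosis.get(stenosis, params.timing)
        sub_params = params.model_copy(update={"timing": timing})
        try:
            det = base_case(sub, sub_params, threshold)
        except ValueError as exc:  # e.g. no medical-therapy patients in stratum
            warnings.warn(f"subgroup {stenosis}: {exc}; skipped", stacklevel=2)
            continue
        life = lifetime_comparison(
            det.reference.outcome, det.alternative.outcome, lifetime_table,
            sub_params.wtp,
        )
        psa = (
            run_psa(sub, sub_params, threshold, n_draws=n_draws, rng=rng)
            if n_draws
            else None
        )
        out[stenosis] = SubgroupResult(
            stenosis=stenosis,
            n=len(sub),
            timing_mean_months=timing.mean_months,
            deterministic=det,
            lifetime=life,
            psa=psa,
        )
    return out
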
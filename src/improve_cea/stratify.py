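"""Risk-score computation, triage rules, Kaplan-Meier stroke risk and
classification accuracy.

Two triage strategies are compared.  Care-as-usual ("cau") sends every
patient with >=50% carotid stenosis to endarterectomy; the risk-based
strategy ("improve") sends patients whose predicted 3-year ipsilateral
ischaemic stroke risk reaches a threshold tau (scanned over 5-20%).  A
scenario variant ("cau_70_99") restricts surgery to 70-99% stenosis.

The risk model is a proportional-hazards score S(t|x) = S0(t)^exp(LP) over
age, sex, stenosis category, index-event type (cerebral vs ocular) and
intraplaque haemorrhage.  For patients assessed more than 9 days after the
index event the risk is conditioned on being stroke-free at assessment.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.stats.proportion import proportion_confint

from .distributions import DistributionSpec, beta_from_mean_se
from .params import ImproveCoefficients

DAYS_PER_MONTH = 30.4375  # mean Gregorian month

STRATEGIES = ("cau", "improve", "cau_70_99")


class StrategyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Risk model
# ---------------------------------------------------------------------------


def linear_predictor(patients: pd.DataFrame, coef: ImproveCoefficients) -> np.ndarray:
    """Linear predictor LP for each row (centred age)."""
    lp = (
        coef.beta_age * (patients["age"].to_numpy(dtype=float) - coef.age_center)
        + coef.beta_male * (patients["sex"].to_numpy() == "male")
        + coef.beta_sten_50_69 * (patients["stenosis"].to_numpy() == "s50_69")
        + coef.beta_sten_70_99 * (patients["stenosis"].to_numpy() == "s70_99")
        + coef.beta_cerebral * np.isin(patients["index_event"].to_numpy(), ("tia", "stroke"))
        + coef.beta_iph * patients["iph"].to_numpy(dtype=bool)
    )
    return np.asarray(lp, dtype=float)


def baseline_survival(coef: ImproveCoefficients, t_months) -> np.ndarray:
    """Baseline stroke-free survival S0(t), Weibull-interpolated from S0(36).

    S0(t) = S0(36) ** (t/36)^shape; shape 1 gives a constant hazard.
    """
    t = np.asarray(t_months, dtype=float)
    return np.power(coef.baseline_survival_36m, (t / 36.0) ** coef.s0_shape)


def conditional_risk(s_future: float, s_current: float) -> float:
    """Risk over a window given survival to its start: 1 - S_future/S_current.

    ``s_future`` is survival to the window end, ``s_current`` survival at
    conditioning time; with ``s_current`` = 1 this is the unconditional risk.
    """
    if s_current <= 0.0:
        raise ZeroDivisionError("cannot condition on survival probability 0")
    if not 0.0 <= s_future <= s_current <= 1.0:
        raise ValueError(
            f"need 0 <= S_future ({s_future}) <= S_current ({s_current}) <= 1"
        )
    return 1.0 - s_future / s_current


def risk_3y(
    patients: pd.DataFrame,
    coef: ImproveCoefficients,
    days_since_event: np.ndarray | None = None,
) -> pd.Series:
    """Predicted 3-year ipsilateral ischaemic stroke risk per patient.

    Within 9 days of the index event the unconditional risk 1 - S(36|x) is
    returned.  Beyond 9 days the risk is conditioned on being stroke-free at
    assessment, using the configured window convention:

    - ``next36`` (default): risk over the 36 months following assessment,
      1 - S(t+36|x)/S(t|x);
    - ``post_index``: risk up to 36 months after the index event,
      1 - S(36|x)/S(t|x) (zero once t >= 36).
    """
    if days_since_event is None:
        days_since_event = patients["days_since_event"].to_numpy(dtype=float)
    t = np.asarray(days_since_event, dtype=float) / DAYS_PER_MONTH
    hr = np.exp(linear_predictor(patients, coef))

    s36 = baseline_survival(coef, 36.0) ** hr
    s_t = baseline_survival(coef, t) ** hr
    recent = np.asarray(days_since_event) <= 9.0
    if coef.conditional_window == "next36":
        s_end = baseline_survival(coef, t + 36.0) ** hr
        risk = np.where(recent, 1.0 - s36, 1.0 - s_end / s_t)
    elif coef.conditional_window == "post_index":
        with np.errstate(invalid="ignore"):
            cond = np.clip(1.0 - s36 / s_t, 0.0, 1.0)
        risk = np.where(recent, 1.0 - s36, np.where(t >= 36.0, 0.0, cond))
    else:
        raise StrategyError(
            f"unknown conditional window {coef.conditional_window!r}"
        )
    return pd.Series(risk, index=patients.index, name="risk_3y")


def improve_risk(patient, coef: ImproveCoefficients) -> float:
    """Scalar 3-year risk for a single patient (record, dict or Series)."""
    if isinstance(patient, pd.Series):
        row = patient.to_dict()
    elif isinstance(patient, Mapping):
        row = dict(patient)
    else:  # NamedTuple-like
        row = patient._asdict()
    df = pd.DataFrame([row])
    return float(risk_3y(df, coef).iloc[0])


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------


def needs_mri(
    patients: pd.DataFrame, coef: ImproveCoefficients, threshold: float
) -> pd.Series:
    """Whether knowing IPH status can change the triage decision.

    IPH is unknown before MRI; a scan is only charged to patients whose risk
    with IPH absent and with IPH present falls on opposite sides of the
    threshold.
    """
    with_iph = patients.assign(iph=True)
    without_iph = patients.assign(iph=False)
    above_with = risk_3y(with_iph, coef) >= threshold
    above_without = risk_3y(without_iph, coef) >= threshold
    out = above_with != above_without
    out.name = "needs_mri"
    return out


def assign(
    cohort: pd.DataFrame,
    strategy: str,
    coef: ImproveCoefficients | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-patient triage under a named strategy.

    Returns columns: patient_id, strategy, assigned (cea_plus_omt/omt_only),
    risk_3y (risk-based strategy only), needs_mri, threshold.  Risk at or
    above the threshold assigns surgery (ties inclusive).
    """
    if strategy not in STRATEGIES:
        raise StrategyError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    out = pd.DataFrame({"patient_id": cohort["id"].to_numpy()})
    out["strategy"] = strategy
    if strategy == "cau":
        cea = cohort["stenosis"].isin(["s50_69", "s70_99"]).to_numpy()
        out["risk_3y"] = np.nan
        out["needs_mri"] = False
        out["threshold"] = np.nan
    elif strategy == "cau_70_99":
        cea = (cohort["stenosis"] == "s70_99").to_numpy()
        out["risk_3y"] = np.nan
        out["needs_mri"] = False
        out["threshold"] = np.nan
    else:
        if coef is None or threshold is None:
            raise StrategyError("risk-based strategy needs coefficients and threshold")
        risk = risk_3y(cohort, coef)
        cea = (risk >= threshold).to_numpy()
        out["risk_3y"] = risk.to_numpy()
        out["needs_mri"] = needs_mri(cohort, coef, threshold).to_numpy()
        out["threshold"] = threshold
    out["assigned"] = np.where(cea, "cea_plus_omt", "omt_only")
    return out[["patient_id", "strategy", "assigned", "risk_3y", "needs_mri", "threshold"]]


# ---------------------------------------------------------------------------
# Kaplan-Meier stroke risk
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class KMEstimate:
    """Product-limit stroke-free survival at a horizon with Greenwood SE."""

    survival: float
    se: float
    risk: float  # 1 - survival
    horizon_months: float
    n: int
    n_events: int

    def beta_spec(self) -> DistributionSpec:
        """Moment-matched Beta for the 3-year risk (PSA input)."""
        return beta_from_mean_se(self.risk, self.se)


def km_stroke_free(
    times: np.ndarray, events: np.ndarray, horizon_months: float
) -> KMEstimate:
    """Kaplan-Meier stroke-free survival at ``horizon_months``.

    ``times`` are follow-up times in months; ``events`` marks an observed
    ipsilateral stroke at that time (False = censored).  The standard error
    is Greenwood's.  If follow-up ends before the horizon the estimate at the
    last observed time is carried forward with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_stroke_free needs a non-empty subcohort")
    if times.max() < horizon_months:
        warnings.warn(
            f"no follow-up reaches {horizon_months} months; carrying the "
            f"estimate at {times.max():.1f} months forward",
            stacklevel=2,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    s = float(kmf.survival_function_at_times(horizon_months).iloc[0])

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    tbl = kmf.event_table
    mask = (tbl.index <= horizon_months) & (tbl["observed"] > 0)
    d = tbl.loc[mask, "observed"].to_numpy(dtype=float)
    n_at_risk = tbl.loc[mask, "at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (n_at_risk * (n_at_risk - d))
    terms = terms[np.isfinite(terms)]
    se = float(s * np.sqrt(terms.sum())) if terms.size else 0.0
    return KMEstimate(
        survival=s,
        se=se,
        risk=1.0 - s,
        horizon_months=horizon_months,
        n=int(times.size),
        n_events=int(events.sum()),
    )


def omt_stratum_risk(
    cohort: pd.DataFrame, assignments: pd.DataFrame, horizon_months: float = 36.0
) -> KMEstimate:
    """KM-derived 3-year stroke risk of the stratum kept on medical therapy."""
    omt_ids = assignments.loc[assignments["assigned"] == "omt_only", "patient_id"]
    sub = cohort[cohort["id"].isin(omt_ids)]
    if sub.empty:
        raise ValueError("no patients assigned to medical therapy in this stratum")
    return km_stroke_free(
        sub["followup_months"].to_numpy(),
        sub["ipsilateral_stroke"].to_numpy(),
        horizon_months,
    )


# ---------------------------------------------------------------------------
# Classification accuracy
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConfusionStats:
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    n_cases: int
    n_noncases: int
    n_excluded: int


def confusion_stats(
    assignments: pd.DataFrame,
    cohort: pd.DataFrame,
    horizon_months: float = 36.0,
    min_censor_months: float = 12.0,
    alpha: float = 0.05,
) -> ConfusionStats:
    """Sensitivity/specificity of a triage rule for 3-year stroke status.

    A case is a patient with an observed ipsilateral stroke within the
    horizon; a non-case is stroke-free with follow-up of at least
    ``min_censor_months``; patients censored earlier without an event are
    excluded (their 3-year status is unknown).  Wilson score intervals.
    """
    df = cohort.merge(
        assignments[["patient_id", "assigned"]], left_on="id", right_on="patient_id"
    )
    event_in_horizon = df["ipsilateral_stroke"] & (
        df["followup_months"] <= horizon_months
    )
    noncase = ~event_in_horizon & (
        (df["followup_months"] >= min_censor_months) | df["ipsilateral_stroke"]
    )
    excluded = ~event_in_horizon & ~noncase
    cea = df["assigned"] == "cea_plus_omt"

    n_cases = int(event_in_horizon.sum())
    n_noncases = int(noncase.sum())
    if n_cases:
        tp = int((event_in_horizon & cea).sum())
        sens = tp / n_cases
        sens_ci = tuple(proportion_confint(tp, n_cases, alpha=alpha, method="wilson"))
    else:
        sens, sens_ci = None, None
    if n_noncases:
        tn = int((noncase & ~cea).sum())
        spec = tn / n_noncases
        spec_ci = tuple(proportion_confint(tn, n_noncases, alpha=alpha, method="wilson"))
    else:
        spec, spec_ci = None, None
    return ConfusionStats(
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        n_cases=n_cases,
        n_noncases=n_noncases,
        n_excluded=int(excluded.sum()),
    )
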
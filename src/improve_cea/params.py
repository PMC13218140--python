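"""Model parameter set: stroke risks, severity splits, utilities, societal
costs and fixed analysis settings, each uncertain input paired with its
uncertainty distribution.

The deterministic analysis uses :meth:`ParameterSet.base`; the probabilistic
sensitivity analysis draws realisations with :meth:`ParameterSet.sample`.
Both return a flat :class:`NumericParams` consumed by the decision tree.

All currency fields are EUR-2022 (societal perspective); inputs priced in
EUR-2012 can be brought forward with :func:`cpi_2012_to_2022`.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .distributions import (
    DistributionSpec,
    distribution_mean,
    ppf,
    sample_distribution,
)

#: CPI 2022 / CPI 2012 conversion factor for Dutch societal costs.
CPI_2012_TO_2022 = 1.265


def cpi_2012_to_2022(amount_eur_2012: float, factor: float = CPI_2012_TO_2022) -> float:
    """Convert a EUR-2012 amount to EUR-2022 via the consumer price index."""
    return amount_eur_2012 * factor


class SeveritySplit(BaseModel):
    """Share of stroke events that are non-disabling / disabling / fatal."""

    p_nondisabling: float = Field(ge=0.0, le=1.0)
    p_disabling: float = Field(ge=0.0, le=1.0)
    p_fatal: float = Field(ge=0.0, le=1.0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _sums_to_one(self) -> "SeveritySplit":
        total = self.p_nondisabling + self.p_disabling + self.p_fatal
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"severity split sums to {total!r}, not 1")
        return self

    @classmethod
    def from_probs(cls, p: np.ndarray) -> "SeveritySplit":
        p = np.asarray(p, dtype=float)
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"severity probabilities sum to {p.sum()!r}, not 1")
        p = p / p.sum()  # absorb float rounding in sampled simplex points
        return cls(p_nondisabling=p[0], p_disabling=p[1], p_fatal=p[2])

    def as_array(self) -> np.ndarray:
        return np.array([self.p_nondisabling, self.p_disabling, self.p_fatal])


class Utilities(BaseModel):
    """Annual utilities indexed by health state (QALY weights per year)."""

    mrs0: float = Field(0.960, ge=0.0, le=1.0)
    nondisabling_first: float = Field(0.864, ge=0.0, le=1.0)
    nondisabling_recurrent: float = Field(0.812, ge=0.0, le=1.0)
    disabling: float = Field(0.356, ge=0.0, le=1.0)
    fatal: float = Field(0.0, ge=0.0, le=1.0)
    base: float = Field(0.918, ge=0.0, le=1.0)
    recurrent_decrement: float = Field(0.0524, ge=0.0, le=1.0)
    #: effective sample size of the moment-matched Beta used in the PSA;
    #: ``None`` holds utilities fixed across draws
    uncertainty_ess: Optional[float] = Field(1000.0, gt=0.0)


class Costs(BaseModel):
    """Societal unit costs, EUR-2022."""

    mri: float = Field(254.0, ge=0.0)
    cea: float = Field(8733.0, ge=0.0)
    nondisabling_first3m: float = Field(14511.0, ge=0.0)
    nondisabling_per_month: float = Field(999.0, ge=0.0)
    disabling_first3m: float = Field(45265.0, ge=0.0)
    disabling_per_month: float = Field(5865.0, ge=0.0)
    fatal_onetime: float = Field(13111.0, ge=0.0)
    baseline_per_month: float = Field(0.0, ge=0.0)
    #: coefficient of variation of the gamma distributions in the PSA;
    #: ``None`` holds costs fixed across draws
    gamma_cv: Optional[float] = Field(0.2, gt=0.0)


class RecurrenceTiming(BaseModel):
    """Gamma-distributed time from index event to stroke recurrence, months."""

    mean_months: float = Field(24.1, gt=0.0)
    #: 0 holds the recurrence time fixed at the mean across draws
    sd_months: float = Field(2.7, ge=0.0)

    model_config = {"frozen": True}


class ImproveCoefficients(BaseModel):
    """Proportional-hazards risk-score coefficients.

    S(t | x) = S0(t) ** exp(LP), with linear predictor
    LP = beta_age * (age - age_center) + beta_male * male + stenosis terms
         + beta_cerebral * (index event cerebral, i.e. TIA or stroke)
         + beta_iph * IPH.

    The published coefficients are not reproduced here; the defaults are a
    documented synthetic set chosen so that the default cohort's 3-year risks
    span roughly 1-40%.  Replace them from the published model before any use
    on real patients.
    """

    baseline_survival_36m: float = Field(0.985, gt=0.0, lt=1.0)
    age_center: float = 70.0
    beta_age: float = 0.03
    beta_male: float = 0.2
    beta_sten_50_69: float = 0.6
    beta_sten_70_99: float = 1.0
    beta_cerebral: float = 0.5
    beta_iph: float = 1.5
    #: Weibull shape of the baseline survival curve (1.0 = constant hazard)
    s0_shape: float = Field(1.0, gt=0.0)
    #: conditional-risk window: "next36" (risk over the next 36 months from
    #: assessment) or "post_index" (risk up to 36 months after the index event)
    conditional_window: str = "next36"


class ParameterSet(BaseModel):
    """All model inputs with their uncertainty specifications."""

    # --- stroke risks -----------------------------------------------------
    p_periop_stroke_death: DistributionSpec = DistributionSpec(
        family="beta", params=(235, 6224)
    )
    periop_severity: DistributionSpec = DistributionSpec(
        family="dirichlet", params=(43, 34, 12)
    )
    p_residual_3y_post_cea: DistributionSpec = DistributionSpec(
        family="beta", params=(166, 7423)
    )
    residual_severity: DistributionSpec = DistributionSpec(
        family="dirichlet", params=(115, 80, 35)
    )
    omt_severity: DistributionSpec = DistributionSpec(
        family="dirichlet", params=(81, 46, 25)
    )
    evt_fraction: DistributionSpec = DistributionSpec(family="beta", params=(58, 942))

    # --- mRS mapping of severity categories ------------------------------
    mrs12_split: DistributionSpec = DistributionSpec(family="dirichlet", params=(55, 45))
    mrs345_split: DistributionSpec = DistributionSpec(
        family="dirichlet", params=(50, 30, 20)
    )

    utilities: Utilities = Utilities()
    costs: Costs = Costs()
    timing: RecurrenceTiming = RecurrenceTiming()
    #: subgroup-specific recurrence timing by stenosis category
    timing_by_stenosis: dict[str, RecurrenceTiming] = {
        "lt50": RecurrenceTiming(mean_months=34.2, sd_months=0.9),
        "s50_69": RecurrenceTiming(mean_months=24.2, sd_months=1.4),
        "s70_99": RecurrenceTiming(mean_months=10.7, sd_months=1.2),
    }

    improve: ImproveCoefficients = ImproveCoefficients()

    #: lifetime QALY / societal cost per end-of-horizon mRS state; ``None``
    #: selects the package's configured defaults (see the lifetime module)
    lifetime_qaly_per_mrs: Optional[dict[int, float]] = None
    lifetime_cost_per_mrs: Optional[dict[int, float]] = None

    # --- fixed analysis settings -----------------------------------------
    wtp: float = Field(50_000.0, gt=0.0)
    horizon_months: float = Field(36.0, gt=0.0)
    discount_cost: float = Field(0.04, ge=0.0)
    discount_qaly: float = Field(0.015, ge=0.0)
    cpi_factor: float = Field(CPI_2012_TO_2022, gt=0.0)
    mc_draws: int = Field(10_000, ge=1)

    @field_validator("periop_severity", "residual_severity", "omt_severity")
    @classmethod
    def _three_categories(cls, v: DistributionSpec) -> DistributionSpec:
        if v.family == "dirichlet" and len(v.params) != 3:
            raise ValueError("severity splits need 3 Dirichlet categories")
        return v

    # --- derived base values ---------------------------------------------
    def base(self) -> "NumericParams":
        """Deterministic (base-case) realisation: every input at its mean."""
        u = self.utilities
        c = self.costs
        return NumericParams(
            p_periop=float(distribution_mean(self.p_periop_stroke_death)),
            periop_sev=SeveritySplit.from_probs(distribution_mean(self.periop_severity)),
            p_residual=float(distribution_mean(self.p_residual_3y_post_cea)),
            residual_sev=SeveritySplit.from_probs(
                distribution_mean(self.residual_severity)
            ),
            omt_sev=SeveritySplit.from_probs(distribution_mean(self.omt_severity)),
            u_mrs0=u.mrs0,
            u_nondis_first=u.nondisabling_first,
            u_nondis_recurrent=u.nondisabling_recurrent,
            u_disabling=u.disabling,
            u_fatal=u.fatal,
            cost_mri=c.mri,
            cost_cea=c.cea,
            cost_nd_first3m=c.nondisabling_first3m,
            cost_nd_per_month=c.nondisabling_per_month,
            cost_dis_first3m=c.disabling_first3m,
            cost_dis_per_month=c.disabling_per_month,
            cost_fatal=c.fatal_onetime,
            cost_baseline_per_month=c.baseline_per_month,
            mrs12=np.asarray(distribution_mean(self.mrs12_split)),
            mrs345=np.asarray(distribution_mean(self.mrs345_split)),
            t_recurrence=self.timing.mean_months,
            horizon=self.horizon_months,
            wtp=self.wtp,
        )

    def sample(self, rng: np.random.Generator) -> "NumericParams":
        """One probabilistic-sensitivity-analysis realisation.

        Binary probabilities draw from their Beta, severity and mRS splits
        jointly from their Dirichlet, costs from mean/CV gammas, utilities
        from moment-matched Betas (recurrent utility = first-event utility
        minus the fixed decrement, floored at 0), and recurrence timing from
        its gamma.
        """
        u, c = self.utilities, self.costs
        ess = u.uncertainty_ess

        def beta_u(mean: float) -> float:
            if ess is None or mean <= 0.0 or mean >= 1.0:
                return mean
            return float(rng.beta(mean * ess, (1.0 - mean) * ess))

        def gamma_c(mean: float) -> float:
            if c.gamma_cv is None or mean <= 0.0:
                return mean
            shape = 1.0 / c.gamma_cv**2
            return float(rng.gamma(shape, mean / shape))

        u_nd_first = beta_u(u.nondisabling_first)
        u_nd_recurrent = (
            u.nondisabling_recurrent  # configured value when utilities are fixed
            if ess is None
            else max(0.0, u_nd_first - u.recurrent_decrement)
        )
        tim = self.timing
        if tim.sd_months > 0:
            t_rec = float(
                rng.gamma((tim.mean_months / tim.sd_months) ** 2,
                          tim.sd_months**2 / tim.mean_months)
            )
        else:
            t_rec = tim.mean_months
        return NumericParams(
            p_periop=float(sample_distribution(self.p_periop_stroke_death, rng)),
            periop_sev=SeveritySplit.from_probs(
                sample_distribution(self.periop_severity, rng)
            ),
            p_residual=float(sample_distribution(self.p_residual_3y_post_cea, rng)),
            residual_sev=SeveritySplit.from_probs(
                sample_distribution(self.residual_severity, rng)
            ),
            omt_sev=SeveritySplit.from_probs(sample_distribution(self.omt_severity, rng)),
            u_mrs0=beta_u(u.mrs0),
            u_nondis_first=u_nd_first,
            u_nondis_recurrent=u_nd_recurrent,
            u_disabling=beta_u(u.disabling),
            u_fatal=u.fatal,
            cost_mri=gamma_c(c.mri),
            cost_cea=gamma_c(c.cea),
            cost_nd_first3m=gamma_c(c.nondisabling_first3m),
            cost_nd_per_month=gamma_c(c.nondisabling_per_month),
            cost_dis_first3m=gamma_c(c.disabling_first3m),
            cost_dis_per_month=gamma_c(c.disabling_per_month),
            cost_fatal=gamma_c(c.fatal_onetime),
            cost_baseline_per_month=gamma_c(c.baseline_per_month),
            mrs12=np.asarray(sample_distribution(self.mrs12_split, rng)),
            mrs345=np.asarray(sample_distribution(self.mrs345_split, rng)),
            t_recurrence=t_rec,
            horizon=self.horizon_months,
            wtp=self.wtp,
        )


@dataclasses.dataclass(frozen=True)
class NumericParams:
    """A fully numeric realisation of the parameter set (one tree evaluation)."""

    p_periop: float
    periop_sev: SeveritySplit
    p_residual: float
    residual_sev: SeveritySplit
    omt_sev: SeveritySplit
    u_mrs0: float
    u_nondis_first: float
    u_nondis_recurrent: float
    u_disabling: float
    u_fatal: float
    cost_mri: float
    cost_cea: float
    cost_nd_first3m: float
    cost_nd_per_month: float
    cost_dis_first3m: float
    cost_dis_per_month: float
    cost_fatal: float
    cost_baseline_per_month: float
    mrs12: np.ndarray
    mrs345: np.ndarray
    t_recurrence: float
    horizon: float
    wtp: float

    def replace(self, **kw) -> "NumericParams":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


class ConfigError(ValueError):
    """Raised for missing, out-of-range or inconsistent config entries."""


def load_parameters(path: str | Path | io.TextIOBase) -> ParameterSet:
    """Read and validate a YAML parameter file.

    Raises :class:`ConfigError` naming the offending key on any validation
    failure (missing key, probability outside [0, 1], severity split not
    summing to one, ...).
    """
    if isinstance(path, io.TextIOBase):
        raw = yaml.safe_load(path)
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"parameter file not found: {p}")
        raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("parameter file must contain a mapping at top level")
    try:
        return ParameterSet.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigError(str(exc)) from exc


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialise a parameter set to YAML (round-trips with load_parameters)."""
    Path(path).write_text(
        yaml.safe_dump(params.model_dump(mode="json"), sort_keys=False)
    )


def default_parameters() -> ParameterSet:
    """The base-case parameter set."""
    return ParameterSet()


def parameter_table(params: ParameterSet) -> pd.DataFrame:
    """Resolved parameter table (name, base value, family, params, units)."""
    rows: list[dict] = []

    def add(name: str, spec: DistributionSpec, units: str) -> None:
        mean = distribution_mean(spec)
        if isinstance(mean, np.ndarray):
            mean = ", ".join(f"{m:.4g}" for m in mean)
        rows.append(
            {
                "name": name,
                "base_value": mean,
                "family": spec.family,
                "params": ", ".join(f"{p:g}" for p in spec.params),
                "units": units,
            }
        )

    add("p_periop_stroke_death", params.p_periop_stroke_death, "probability")
    add("periop_severity", params.periop_severity, "share of surgical events")
    add("p_residual_3y_post_cea", params.p_residual_3y_post_cea, "probability")
    add("residual_severity", params.residual_severity, "share of post-surgical events")
    add("omt_severity", params.omt_severity, "share of OMT strokes")
    add("evt_fraction", params.evt_fraction, "probability")
    add("mrs12_split", params.mrs12_split, "share of non-disabling strokes")
    add("mrs345_split", params.mrs345_split, "share of disabling strokes")
    for name, val in params.utilities.model_dump().items():
        if name == "uncertainty_ess":
            continue
        rows.append(
            {"name": f"utility.{name}", "base_value": val, "family": "beta",
             "params": f"ess={params.utilities.uncertainty_ess:g}",
             "units": "utility/year"}
        )
    for name, val in params.costs.model_dump().items():
        if name == "gamma_cv":
            continue
        rows.append(
            {"name": f"cost.{name}", "base_value": val, "family": "gamma",
             "params": f"cv={params.costs.gamma_cv:g}", "units": "EUR-2022"}
        )
    rows.append({"name": "timing.mean_months", "base_value": params.timing.mean_months,
                 "family": "gamma", "params": f"sd={params.timing.sd_months:g}",
                 "units": "months"})
    for name, val in (("wtp", params.wtp), ("horizon_months", params.horizon_months),
                      ("discount_cost", params.discount_cost),
                      ("discount_qaly", params.discount_qaly),
                      ("cpi_factor", params.cpi_factor)):
        rows.append({"name": name, "base_value": val, "family": "fixed",
                     "params": "", "units": ""})
    return pd.DataFrame(rows)
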
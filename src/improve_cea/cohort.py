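"""Synthetic patient-level cohorts of recently symptomatic carotid-disease
patients.

The generator emulates the marginal structure of a pooled observational
cohort (n=678: half <50% stenosis, 30% 50-69%, 20% 70-99%; index events 42%
TIA / 44% stroke / 14% amaurosis fugax; 43% IPH-positive plaques; age 71 +/- 10;
66% male; median 37 days since the index event) and attaches event times whose
3-year ipsilateral-stroke probability equals the risk model's prediction for
each patient, with independent exponential censoring calibrated to the
cohort's median follow-up.

The canonical in-memory container is a pandas DataFrame with the columns in
:data:`COHORT_COLUMNS`; :class:`PatientRecord` is the row-level view.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .params import ImproveCoefficients
from .stratify import risk_3y

SEX_CODES = ("male", "female")
INDEX_EVENTS = ("tia", "stroke", "amaurosis_fugax")
STENOSIS_CODES = ("lt50", "s50_69", "s70_99")

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "index_event",
    "stenosis",
    "iph",
    "days_since_event",
    "followup_months",
    "ipsilateral_stroke",
    "event_time_months",
    "baseline_mrs",
]


class PatientRecord(NamedTuple):
    id: int
    age: float
    sex: str
    index_event: str
    stenosis: str
    iph: bool
    days_since_event: float
    followup_months: float
    ipsilateral_stroke: bool
    event_time_months: Optional[float]
    baseline_mrs: int


class CohortSpecError(ValueError):
    pass


class CohortSpec(BaseModel):
    """Sampling specification for a synthetic cohort.

    Marginals default to the pooled cohort's overall column; predictors are
    drawn independently unless ``iph_by_stenosis`` supplies a per-stenosis
    IPH probability (dependence hook).
    """

    n: int = Field(678, ge=1)
    age_mean: float = 71.0
    age_sd: float = Field(10.0, gt=0.0)
    age_min: float = 30.0
    p_male: float = Field(0.66, ge=0.0, le=1.0)
    index_event: dict[str, float] = {"tia": 0.42, "stroke": 0.44, "amaurosis_fugax": 0.14}
    stenosis: dict[str, float] = {"lt50": 0.50, "s50_69": 0.30, "s70_99": 0.20}
    p_iph: float = Field(0.43, ge=0.0, le=1.0)
    iph_by_stenosis: Optional[dict[str, float]] = None
    days_since_event_median: float = Field(37.0, gt=0.0)
    days_since_event_log_sd: float = Field(0.80, gt=0.0)
    followup_median_months: float = Field(17.0, gt=0.0)
    max_followup_months: float = Field(72.0, gt=0.0)
    #: Weibull shape of the event-time distribution (1.0 = exponential)
    event_time_shape: float = Field(1.0, gt=0.0)
    #: baseline mRS split (mRS1, mRS2) for index-stroke patients
    mrs12_split: tuple[float, float] = (0.55, 0.45)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check_marginals(self) -> "CohortSpec":
        for name, marg, keys in (
            ("index_event", self.index_event, INDEX_EVENTS),
            ("stenosis", self.stenosis, STENOSIS_CODES),
        ):
            if set(marg) != set(keys):
                raise CohortSpecError(f"{name} marginal must have keys {keys}")
            total = sum(marg.values())
            if total <= 0 or any(v < 0 for v in marg.values()):
                raise CohortSpecError(f"{name} marginal has no probability mass")
        if sum(self.mrs12_split) <= 0 or any(v < 0 for v in self.mrs12_split):
            raise CohortSpecError("mrs12_split has no probability mass")
        return self


def _draw_categorical(
    rng: np.random.Generator, keys: tuple[str, ...], marg: dict[str, float], n: int
) -> np.ndarray:
    p = np.array([marg[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p)]


def generate_cohort(
    spec: CohortSpec,
    coef: ImproveCoefficients,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw a cohort of ``spec.n`` patients.

    Event times are Weibull with shape ``spec.event_time_shape`` and a
    per-patient scale solved so that P(event <= 36 months | x) equals the
    risk model's 3-year prediction for x; censoring is exponential with the
    configured median follow-up, truncated administratively at
    ``max_followup_months``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = spec.n

    age = np.maximum(spec.age_min, rng.normal(spec.age_mean, spec.age_sd, size=n))
    sex = np.where(rng.random(n) < spec.p_male, "male", "female").astype(object)
    index_event = _draw_categorical(rng, INDEX_EVENTS, spec.index_event, n)
    stenosis = _draw_categorical(rng, STENOSIS_CODES, spec.stenosis, n)
    if spec.iph_by_stenosis is not None:
        p_iph = np.array([spec.iph_by_stenosis[s] for s in stenosis])
    else:
        p_iph = np.full(n, spec.p_iph)
    iph = rng.random(n) < p_iph
    days = rng.lognormal(np.log(spec.days_since_event_median),
                         spec.days_since_event_log_sd, size=n)
    mrs12 = np.asarray(spec.mrs12_split, dtype=float)
    mrs12 = mrs12 / mrs12.sum()
    baseline_mrs = np.where(
        index_event == "stroke", rng.choice([1, 2], size=n, p=mrs12), 0
    )

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "index_event": index_event,
            "stenosis": stenosis,
            "iph": iph,
            "days_since_event": days,
            "baseline_mrs": baseline_mrs,
        }
    )

    # Ground-truth 3-year risk drives the event-time scale.
    risk = risk_3y(df, coef).to_numpy()
    risk = np.clip(risk, 1e-9, 1.0 - 1e-9)
    k = spec.event_time_shape
    scale = 36.0 / (-np.log1p(-risk)) ** (1.0 / k)
    event_time = scale * rng.weibull(k, size=n)
    censor = np.minimum(
        rng.exponential(spec.followup_median_months / np.log(2.0), size=n),
        spec.max_followup_months,
    )
    observed_event = event_time <= censor
    followup = np.where(observed_event, event_time, censor)

    df["followup_months"] = followup
    df["ipsilateral_stroke"] = observed_event
    df["event_time_months"] = np.where(observed_event, event_time, np.nan)
    return df[COHORT_COLUMNS]


def iter_records(cohort: pd.DataFrame):
    """Iterate a cohort DataFrame as :class:`PatientRecord` rows."""
    for row in cohort.itertuples(index=False):
        yield PatientRecord(
            id=int(row.id),
            age=float(row.age),
            sex=str(row.sex),
            index_event=str(row.index_event),
            stenosis=str(row.stenosis),
            iph=bool(row.iph),
            days_since_event=float(row.days_since_event),
            followup_months=float(row.followup_months),
            ipsilateral_stroke=bool(row.ipsilateral_stroke),
            event_time_months=None
            if pd.isna(row.event_time_months)
            else float(row.event_time_months),
            baseline_mrs=int(row.baseline_mrs),
        )


class CohortParseError(ValueError):
    pass


_HEADER_COMMENT = (
    "# Synthetic carotid-disease cohort (one row per patient).\n"
    "# sex: male/female; index_event: tia/stroke/amaurosis_fugax;\n"
    "# stenosis: lt50 (<50%), s50_69 (50-69%), s70_99 (70-99%); iph: True/False;\n"
    "# times in months except days_since_event (days); event_time_months empty\n"
    "# when no ipsilateral stroke was observed within follow-up.\n"
)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV with a documented header comment."""
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortParseError(f"cohort is missing columns: {missing}")
    with path.open("w") as fh:
        fh.write(_HEADER_COMMENT)
        cohort[COHORT_COLUMNS].to_csv(fh, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (lossless round-trip)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise CohortParseError(f"{path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.sex not in SEX_CODES:
            raise CohortParseError(f"{path}: row {i}: bad sex code {row.sex!r}")
        if row.index_event not in INDEX_EVENTS:
            raise CohortParseError(
                f"{path}: row {i}: bad index_event {row.index_event!r}"
            )
        if row.stenosis not in STENOSIS_CODES:
            raise CohortParseError(f"{path}: row {i}: bad stenosis {row.stenosis!r}")
    df["iph"] = df["iph"].astype(bool)
    df["ipsilateral_stroke"] = df["ipsilateral_stroke"].astype(bool)
    df["baseline_mrs"] = df["baseline_mrs"].astype(int)
    df["event_time_months"] = df["event_time_months"].astype(float)
    return df[COHORT_COLUMNS]
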
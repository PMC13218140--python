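"""Lifetime extrapolation of the 3-year end-state mRS distribution.

After 3 years the two strategies are assumed to face the same stroke
recurrence hazard, so patients simply remain in their end-of-horizon mRS
state.  Each mRS state carries a lifetime QALY and societal cost computed by
an annual-cycle cohort model: survivors at each cycle start accrue a full
year of state utility and cost, discounted at separate annual rates (1.5%
for QALYs, 4% for costs), with survival driven by a general-population life
table from a starting age of 74 years.

A configured table (supplementary anchors: 7.771 QALY / EUR 55,317 for mRS 0
down to 0.795 QALY / EUR 1,041,095 for mRS 5) ships as the default; the
generator rebuilds the table from per-state annual inputs when those are
available.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import Comparison, TreeOutcome, TreeStateError

MRS_STATES = (0, 1, 2, 3, 4, 5)

#: Default lifetime values per mRS state.  mRS 0 and mRS 5 reproduce the
#: published anchors; mRS 1-4 are synthetic monotone placeholders for the
#: supplementary table and should be replaced from it when available.
DEFAULT_LIFETIME_QALY = {0: 7.771, 1: 6.9, 2: 5.6, 3: 3.2, 4: 1.7, 5: 0.795, 6: 0.0}
DEFAULT_LIFETIME_COST = {
    0: 55_317.0,
    1: 160_000.0,
    2: 320_000.0,
    3: 560_000.0,
    4: 820_000.0,
    5: 1_041_095.0,
    6: 0.0,
}


@dataclasses.dataclass(frozen=True)
class LifetimePerMRS:
    """Lifetime QALY and societal cost per end-of-horizon mRS state."""

    qaly: dict[int, float]
    cost: dict[int, float]
    provenance: str  # "configured" or "generated"

    def __post_init__(self):
        for table, label in ((self.qaly, "qaly"), (self.cost, "cost")):
            missing = [s for s in (*MRS_STATES, 6) if s not in table]
            if missing:
                raise ValueError(f"lifetime {label} table missing mRS states {missing}")
        q = [self.qaly[s] for s in MRS_STATES]
        if any(a < b - 1e-9 for a, b in zip(q, q[1:])):
            raise ValueError("lifetime QALY must be non-increasing in mRS")
        if abs(self.qaly[6]) > 1e-12 or abs(self.cost[6]) > 1e-12:
            raise ValueError("mRS 6 (death) carries no further QALY or cost")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mrs": list(self.qaly),
                "lifetime_qaly": list(self.qaly.values()),
                "lifetime_cost": list(self.cost.values()),
                "provenance": self.provenance,
            }
        )


def configured_lifetime_table(
    qaly: dict[int, float] | None = None, cost: dict[int, float] | None = None
) -> LifetimePerMRS:
    return LifetimePerMRS(
        qaly=dict(qaly or DEFAULT_LIFETIME_QALY),
        cost=dict(cost or DEFAULT_LIFETIME_COST),
        provenance="configured",
    )


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------


def synthetic_life_table(
    min_age: int = 50,
    max_age: int = 110,
    makeham: float = 2e-4,
    gompertz_b: float = 3.3e-5,
    gompertz_g: float = 0.0866,
) -> pd.DataFrame:
    """Synthetic general-population life table (age, qx).

    Gompertz-Makeham annual death probabilities calibrated to a roughly
    Western-European shape (about 2% at age 74, doubling every 8 years).
    Replace with a national statistics life table (columns ``age``, ``qx``)
    for country-specific results.
    """
    ages = np.arange(min_age, max_age + 1)
    qx = np.clip(makeham + gompertz_b * np.exp(gompertz_g * ages), 0.0, 1.0)
    qx[-1] = 1.0  # close the table
    return pd.DataFrame({"age": ages, "qx": qx})


def read_life_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not {"age", "qx"}.issubset(df.columns):
        raise ValueError(f"{path}: life table needs columns age, qx")
    if ((df["qx"] < 0) | (df["qx"] > 1)).any():
        raise ValueError(f"{path}: qx outside [0, 1]")
    ages = df["age"].to_numpy()
    if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)):
        raise ValueError(f"{path}: ages must be contiguous")
    return df[["age", "qx"]]


def generate_lifetime_table(
    annual_utility: dict[int, float],
    annual_cost: dict[int, float],
    mortality: pd.DataFrame,
    start_age: float = 74.0,
    discount_cost: float = 0.04,
    discount_qaly: float = 0.015,
    max_age: float = 110.0,
    hazard_ratio: dict[int, float] | float = 1.0,
) -> LifetimePerMRS:
    """Build the lifetime table from per-state annual utility and cost.

    Yearly cycles from ``start_age``: those alive at cycle start accrue a
    full year of utility/cost (no half-cycle correction), discounted at the
    QALY/cost rates; survival follows the life table, optionally accelerated
    by a per-state excess-mortality hazard ratio.
    """
    ages = np.arange(int(start_age), int(max_age))
    lt = mortality.set_index("age")["qx"]
    missing = [a for a in ages if a not in lt.index]
    if missing:
        raise ValueError(f"life table does not cover ages {missing[:5]}...")
    qx = lt.loc[ages].to_numpy(dtype=float)

    qaly_table: dict[int, float] = {}
    cost_table: dict[int, float] = {}
    for state in MRS_STATES:
        hr = hazard_ratio.get(state, 1.0) if isinstance(hazard_ratio, dict) else hazard_ratio
        q_state = 1.0 - (1.0 - qx) ** hr
        alive = np.concatenate([[1.0], np.cumprod(1.0 - q_state)])[:-1]
        years = np.arange(alive.size)
        qaly_table[state] = float(
            np.sum(alive * annual_utility[state] / (1.0 + discount_qaly) ** years)
        )
        cost_table[state] = float(
            np.sum(alive * annual_cost[state] / (1.0 + discount_cost) ** years)
        )
    qaly_table[6] = 0.0
    cost_table[6] = 0.0
    return LifetimePerMRS(qaly=qaly_table, cost=cost_table, provenance="generated")


# ---------------------------------------------------------------------------
# Application to strategy outcomes
# ---------------------------------------------------------------------------


def apply_lifetime(
    mrs_distribution: np.ndarray, table: LifetimePerMRS
) -> tuple[float, float]:
    """Lifetime QALY and cost per person beyond the 3-year horizon.

    ``mrs_distribution`` holds expected patient counts in mRS 0..6 at the
    end of the horizon; the result is the count-weighted average of the
    per-state lifetime values (linear in the distribution).
    """
    dist = np.asarray(mrs_distribution, dtype=float)
    if dist.size != 7:
        raise TreeStateError("mrs distribution must cover states 0..6")
    n = dist.sum()
    if n <= 0:
        raise TreeStateError("empty mRS distribution")
    q = np.array([table.qaly[s] for s in range(7)])
    c = np.array([table.cost[s] for s in range(7)])
    return float(dist @ q / n), float(dist @ c / n)


def lifetime_comparison(
    reference: TreeOutcome,
    alternative: TreeOutcome,
    table: LifetimePerMRS,
    wtp: float,
) -> Comparison:
    """Lifetime-horizon incremental results: 3-year accruals plus the
    mRS-indexed lifetime tail."""
    q_ref, c_ref = apply_lifetime(reference.mrs_distribution, table)
    q_alt, c_alt = apply_lifetime(alternative.mrs_distribution, table)
    dq = (alternative.qaly_per_patient + q_alt) - (reference.qaly_per_patient + q_ref)
    dc = (alternative.cost_per_patient + c_alt) - (reference.cost_per_patient + c_ref)
    nmb = wtp * dq - dc
    ref_primary = reference.primary_endpoint
    return Comparison(
        reference=reference.strategy,
        alternative=alternative.strategy,
        delta_qaly=dq,
        delta_cost=dc,
        nmb=nmb,
        icer=None if dq == 0 else dc / dq,
        dominant=dq > 0 and dc < 0,
        reduction_primary_endpoint=(
            (ref_primary - alternative.primary_endpoint) / ref_primary
            if ref_primary > 0
            else 0.0
        ),
        reference_primary=ref_primary,
        alternative_primary=alternative.primary_endpoint,
    )
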
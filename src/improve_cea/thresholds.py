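"""Risk-threshold scan for the risk-based triage strategy.

The triage threshold tau is scanned over 3-year-risk values (5-20% by
default) and the operating point minimising the expected primary endpoint --
ipsilateral ischaemic strokes plus perioperative strokes and deaths -- is
selected, ties broken toward the lower (more stroke-averse) threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ParameterSet
from .pipeline import evaluate_strategy
from .tree import compare

DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.05, 0.2001, 0.01), 4))


def select_threshold(taus, values, prefer: str = "min") -> float:
    """The threshold optimising ``values`` (ties -> lowest threshold).

    ``prefer="min"`` for endpoint counts, ``"max"`` for reduction
    percentages.  The result does not depend on grid ordering.
    """
    taus = np.asarray(taus, dtype=float)
    values = np.asarray(values, dtype=float)
    if taus.size == 0 or taus.size != values.size:
        raise ValueError("need equally sized, non-empty threshold and value arrays")
    order = np.argsort(taus, kind="stable")
    taus, values = taus[order], values[order]
    best = values.min() if prefer == "min" else values.max()
    return float(taus[np.flatnonzero(values == best)[0]])


def scan(
    cohort: pd.DataFrame,
    params: ParameterSet,
    tau_grid=DEFAULT_TAU_GRID,
    reference_strategy: str = "cau",
) -> tuple[pd.DataFrame, float]:
    """Evaluate the risk-based strategy on each threshold of ``tau_grid``.

    Returns the scan table (threshold, surgery and MRI counts, expected
    endpoint counts, QALY and cost per patient, reduction vs the reference)
    and the selected optimal threshold tau*.
    """
    taus = sorted(float(t) for t in tau_grid)
    if not taus or not all(0.0 < t < 1.0 for t in taus):
        raise ValueError("tau grid must be non-empty with thresholds in (0, 1)")
    ref = evaluate_strategy(cohort, reference_strategy, params)
    rows = []
    for tau in taus:
        ev = evaluate_strategy(cohort, "improve", params, threshold=tau)
        comp = compare(ref.outcome, ev.outcome, params.wtp)
        rows.append(
            {
                "threshold": tau,
                "n_cea": ev.outcome.n_cea,
                "n_mri": ev.outcome.n_mri,
                "omt_risk_3y": ev.km.risk,
                "primary_endpoint": ev.outcome.primary_endpoint,
                "ipsilateral_strokes": ev.outcome.ipsilateral_strokes,
                "qaly_per_patient": ev.outcome.qaly_per_patient,
                "cost_per_patient": ev.outcome.cost_per_patient,
                "reduction_primary_pct": 100.0 * comp.reduction_primary_endpoint,
                "delta_qaly": comp.delta_qaly,
                "delta_cost": comp.delta_cost,
            }
        )
    table = pd.DataFrame(rows)
    tau_star = select_threshold(
        table["threshold"].to_numpy(), table["primary_endpoint"].to_numpy(), "min"
    )
    return table, tau_star
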
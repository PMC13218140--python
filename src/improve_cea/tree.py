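"""Expected-value evaluation of the 3-year decision tree.

Each patient follows one branch of a chance tree.  Surgical patients face a
perioperative stroke/death risk (severity split non-disabling / disabling /
fatal); perioperative-event-free survivors face a residual 3-year stroke
risk.  Medical-therapy patients face the Kaplan-Meier-derived 3-year stroke
risk of their stratum.  Perioperative transitions happen at month 0;
recurrences at the modelled recurrence time.  mRS can only worsen (worst-state
rule); severity maps to mRS 1-2 / 3-5 / 6.  QALYs integrate annual utilities
over the horizon; societal costs combine procedure, imaging, baseline-state
and event cost streams, with the strategy-average index-event cost subtracted
so only preventable recurrence costs remain.

Everything is cohort-level expectation arithmetic (no patient-level
randomness): path probabilities multiply per-path QALY/cost, which keeps a
10,000-draw probabilistic analysis cheap.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .params import NumericParams

# severity codes used by the vectorised path arithmetic
SEV_NONE, SEV_NONDIS, SEV_DIS, SEV_FATAL = 0, 1, 2, 3
_SEVERITY_NAMES = {
    "none": SEV_NONE,
    "nondisabling": SEV_NONDIS,
    "disabling": SEV_DIS,
    "fatal": SEV_FATAL,
}


class TreeStateError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TreeOutcome:
    """Strategy-level expected outcomes over the 3-year horizon."""

    strategy: str
    n: int
    n_cea: float
    n_mri: float
    #: expected perioperative events (non-disabling, disabling, fatal)
    n_periop: np.ndarray
    #: expected post-surgical strokes within 3 years, by severity
    n_postcea: np.ndarray
    #: expected strokes on medical therapy, by severity
    n_omt: np.ndarray
    #: ipsilateral strokes (post-surgical + medical-therapy)
    ipsilateral_strokes: float
    #: ipsilateral strokes + perioperative strokes/deaths
    primary_endpoint: float
    #: expected patient counts in mRS 0..6 at 36 months
    mrs_distribution: np.ndarray
    qaly_per_patient: float
    #: societal cost per patient, index-event cost subtracted, EUR-2022
    cost_per_patient: float
    #: strategy-average accrued index-event cost that was subtracted
    index_cost_per_patient: float


def accrue_qaly(
    u_before,
    u_after,
    event_time_months,
    horizon_months: float = 36.0,
    fatal=False,
    u_fatal: float = 0.0,
):
    """QALYs over the horizon for a single health-state switch at
    ``event_time_months`` (utilities are per year; times in months).

    No event: pass ``event_time_months = horizon_months``.  Fatal events
    accrue ``u_fatal`` (normally 0) after the event.
    """
    t = np.asarray(event_time_months, dtype=float)
    if np.any(t < 0):
        raise TreeStateError("event times must be non-negative")
    t = np.minimum(t, horizon_months)
    after = np.where(np.asarray(fatal, dtype=bool), u_fatal, u_after)
    out = (np.asarray(u_before) * t + after * (horizon_months - t)) / 12.0
    return float(out) if out.ndim == 0 else out


def _path_cost(
    sev_code,
    event_time_months,
    p: NumericParams,
    is_cea,
    needs_mri,
    index_peak_monthly,
):
    """Vectorised societal cost and accrued index-event cost of one path."""
    sev = np.asarray(sev_code)
    t = np.asarray(event_time_months, dtype=float)
    if np.any(t < 0):
        raise TreeStateError("event times must be non-negative")
    if np.any(~np.isin(sev, (SEV_NONE, SEV_NONDIS, SEV_DIS, SEV_FATAL))):
        raise TreeStateError(f"unknown severity code in {np.unique(sev)}")
    horizon = p.horizon
    t = np.minimum(t, horizon)
    alive_months = np.where(sev == SEV_FATAL, t, horizon)

    cost = p.cost_cea * np.asarray(is_cea, dtype=float)
    cost = cost + p.cost_mri * np.asarray(needs_mri, dtype=float)
    cost = cost + p.cost_baseline_per_month * alive_months
    index_accrued = np.asarray(index_peak_monthly) * np.minimum(3.0, alive_months)
    cost = cost + index_accrued

    remaining = horizon - t
    peak_frac = np.minimum(3.0, remaining) / 3.0
    tail = np.maximum(0.0, remaining - 3.0)
    cost = cost + np.where(
        sev == SEV_NONDIS,
        p.cost_nd_first3m * peak_frac + p.cost_nd_per_month * tail,
        0.0,
    )
    cost = cost + np.where(
        sev == SEV_DIS,
        p.cost_dis_first3m * peak_frac + p.cost_dis_per_month * tail,
        0.0,
    )
    cost = cost + np.where(sev == SEV_FATAL, p.cost_fatal, 0.0)
    return cost, index_accrued


def accrue_cost(
    severity: str,
    event_time_months: float,
    p: NumericParams,
    is_cea: bool = False,
    needs_mri: bool = False,
    index_peak_monthly: float = 0.0,
) -> float:
    """Societal cost of one fully specified patient path (EUR-2022).

    ``severity`` is one of none / nondisabling / disabling / fatal; the event
    (if any) happens at ``event_time_months``.  Peak event costs cover the
    three months after the event pro-rated at the horizon; fatal events add
    the one-time fatal cost and stop all cost streams.
    """
    if severity not in _SEVERITY_NAMES:
        raise TreeStateError(f"unknown severity {severity!r}")
    cost, _ = _path_cost(
        _SEVERITY_NAMES[severity],
        event_time_months,
        p,
        is_cea,
        needs_mri,
        index_peak_monthly,
    )
    return float(cost)


def _mrs_path_distribution(
    baseline_mrs: np.ndarray, sev_code: int, p: NumericParams
) -> np.ndarray:
    """(n, 7) end-of-horizon mRS distribution for one path, worst-state rule."""
    n = baseline_mrs.size
    out = np.zeros((n, 7))
    if sev_code == SEV_NONE:
        out[np.arange(n), baseline_mrs] = 1.0
    elif sev_code == SEV_NONDIS:
        # new mRS ~ mrs12 over {1, 2}; final state = max(baseline, new)
        low = baseline_mrs <= 1
        out[low, 1] = p.mrs12[0]
        out[low, 2] = p.mrs12[1]
        out[~low, 2] = 1.0  # baseline already mRS 2
    elif sev_code == SEV_DIS:
        out[:, 3:6] = p.mrs345[np.newaxis, :]
    else:  # fatal
        out[:, 6] = 1.0
    return out


def evaluate_tree(
    cohort: pd.DataFrame,
    assignments: pd.DataFrame,
    p: NumericParams,
    omt_risk: float,
) -> TreeOutcome:
    """Expected 3-year outcomes of one strategy on one cohort.

    ``omt_risk`` is the 3-year ipsilateral stroke risk of the stratum kept on
    medical therapy (KM-derived).  Every patient must appear in
    ``assignments``.
    """
    df = cohort.merge(
        assignments[["patient_id", "strategy", "assigned", "needs_mri"]],
        left_on="id",
        right_on="patient_id",
        how="left",
    )
    if df["assigned"].isna().any():
        missing = df.loc[df["assigned"].isna(), "id"].tolist()[:5]
        raise TreeStateError(f"patients without an assignment, e.g. {missing}")
    if not 0.0 <= omt_risk <= 1.0:
        raise TreeStateError(f"omt_risk must be a probability, got {omt_risk}")

    n = len(df)
    is_cea = (df["assigned"] == "cea_plus_omt").to_numpy()
    mri = df["needs_mri"].to_numpy(dtype=bool)
    baseline_mrs = df["baseline_mrs"].to_numpy(dtype=int)
    index_stroke = baseline_mrs > 0

    u_base = np.where(index_stroke, p.u_nondis_first, p.u_mrs0)
    u_nd_post = np.where(index_stroke, p.u_nondis_recurrent, p.u_nondis_first)
    index_peak_monthly = np.where(index_stroke, p.cost_nd_first3m / 3.0, 0.0)

    t_rec = min(p.t_recurrence, p.horizon)

    # Path layout: 0-2 perioperative (nd, dis, fatal) at month 0;
    # 3-5 recurrence (nd, dis, fatal) at t_rec -- residual post-surgical risk
    # for surgical patients, stratum risk for medical patients; 6 no event.
    probs = np.zeros((n, 7))
    periop = p.periop_sev.as_array()
    resid = p.residual_sev.as_array()
    omt = p.omt_sev.as_array()
    probs[is_cea, 0:3] = p.p_periop * periop
    probs[is_cea, 3:6] = (1.0 - p.p_periop) * p.p_residual * resid
    probs[is_cea, 6] = (1.0 - p.p_periop) * (1.0 - p.p_residual)
    probs[~is_cea, 3:6] = omt_risk * omt
    probs[~is_cea, 6] = 1.0 - omt_risk

    path_sev = np.array([SEV_NONDIS, SEV_DIS, SEV_FATAL] * 2 + [SEV_NONE])
    path_time = np.array([0.0, 0.0, 0.0, t_rec, t_rec, t_rec, p.horizon])
    path_u_after = [u_nd_post, p.u_disabling, p.u_fatal,
                    u_nd_post, p.u_disabling, p.u_fatal, u_base]

    qaly = np.zeros((n, 7))
    cost = np.zeros((n, 7))
    index_acc = np.zeros((n, 7))
    mrs = np.zeros((n, 7, 7))
    for j in range(7):
        qaly[:, j] = accrue_qaly(
            u_base,
            path_u_after[j],
            path_time[j],
            p.horizon,
            fatal=path_sev[j] == SEV_FATAL,
            u_fatal=p.u_fatal,
        )
        cost[:, j], index_acc[:, j] = _path_cost(
            path_sev[j], path_time[j], p, is_cea, mri, index_peak_monthly
        )
        mrs[:, j, :] = _mrs_path_distribution(baseline_mrs, path_sev[j], p)

    exp_qaly = float((probs * qaly).sum() / n)
    exp_cost_raw = float((probs * cost).sum() / n)
    exp_index = float((probs * index_acc).sum() / n)
    mrs_dist = (probs[:, :, np.newaxis] * mrs).sum(axis=(0, 1))

    n_periop = p.p_periop * periop * is_cea.sum()
    n_postcea = (1.0 - p.p_periop) * p.p_residual * resid * is_cea.sum()
    n_omt = omt_risk * omt * (~is_cea).sum()
    ipsi = float(n_postcea.sum() + n_omt.sum())
    strategy = str(assignments["strategy"].iloc[0]) if len(assignments) else ""
    return TreeOutcome(
        strategy=strategy,
        n=n,
        n_cea=float(is_cea.sum()),
        n_mri=float(mri.sum()),
        n_periop=n_periop,
        n_postcea=n_postcea,
        n_omt=n_omt,
        ipsilateral_strokes=ipsi,
        primary_endpoint=ipsi + float(n_periop.sum()),
        mrs_distribution=mrs_dist,
        qaly_per_patient=exp_qaly,
        cost_per_patient=exp_cost_raw - exp_index,
        index_cost_per_patient=exp_index,
    )


@dataclasses.dataclass(frozen=True)
class Comparison:
    """Incremental results, alternative minus reference strategy."""

    reference: str
    alternative: str
    delta_qaly: float
    delta_cost: float
    nmb: float
    icer: float | None
    dominant: bool
    reduction_primary_endpoint: float
    reference_primary: float
    alternative_primary: float


def compare(reference: TreeOutcome, alternative: TreeOutcome, wtp: float) -> Comparison:
    """Incremental cost-effectiveness of ``alternative`` vs ``reference``.

    NMB = wtp * dQALY - dCost.  The ICER is undefined at dQALY = 0 and the
    strategy is flagged dominant when it gains QALYs while saving costs.
    """
    if reference.n != alternative.n:
        raise TreeStateError("strategies must be evaluated on the same cohort")
    dq = alternative.qaly_per_patient - reference.qaly_per_patient
    dc = alternative.cost_per_patient - reference.cost_per_patient
    nmb = wtp * dq - dc
    icer = None if dq == 0.0 else dc / dq
    red = (
        (reference.primary_endpoint - alternative.primary_endpoint)
        / reference.primary_endpoint
        if reference.primary_endpoint > 0
        else 0.0
    )
    return Comparison(
        reference=reference.strategy,
        alternative=alternative.strategy,
        delta_qaly=dq,
        delta_cost=dc,
        nmb=nmb,
        icer=icer,
        dominant=dq > 0 and dc < 0,
        reduction_primary_endpoint=red,
        reference_primary=reference.primary_endpoint,
        alternative_primary=alternative.primary_endpoint,
    )
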
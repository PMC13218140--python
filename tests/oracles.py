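"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the product-limit oracle
is a direct textbook product over event times, and the tree oracle is an
exhaustive enumeration of every outcome path of every patient with plain
scalar arithmetic.
"""

from __future__ import annotations

import math


def product_limit(times, events, horizon):
    """Textbook Kaplan-Meier estimate of S(horizon) by explicit products."""
    pairs = sorted(zip(times, events))
    distinct_event_times = sorted({t for t, e in pairs if e and t <= horizon})
    s = 1.0
    for t in distinct_event_times:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ei and ti == t)
        s *= 1.0 - d / at_risk
    return s


def greenwood_se(times, events, horizon):
    pairs = sorted(zip(times, events))
    s = product_limit(times, events, horizon)
    total = 0.0
    for t in sorted({t for t, e in pairs if e and t <= horizon}):
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ei and ti == t)
        if at_risk > d:
            total += d / (at_risk * (at_risk - d))
    return s * math.sqrt(total)


def enumerate_tree(patients, params, omt_risk):
    """Exhaustive path enumeration of the 3-year decision tree.

    ``patients`` is a list of dicts with keys: assigned ('cea_plus_omt' or
    'omt_only'), needs_mri (bool), baseline_mrs (0/1/2).  ``params`` is a
    NumericParams.  Returns totals: expected QALY/person, net cost/person
    (index cost subtracted), primary endpoint count and the expected mRS
    count vector.
    """
    p = params
    horizon = p.horizon
    t_rec = min(p.t_recurrence, horizon)

    total_qaly = 0.0
    total_cost = 0.0
    total_index = 0.0
    primary = 0.0
    mrs_counts = [0.0] * 7

    for pat in patients:
        is_cea = pat["assigned"] == "cea_plus_omt"
        stroke_index = pat["baseline_mrs"] > 0
        u_base = p.u_nondis_first if stroke_index else p.u_mrs0
        u_nd = p.u_nondis_recurrent if stroke_index else p.u_nondis_first
        index_monthly = p.cost_nd_first3m / 3.0 if stroke_index else 0.0

        if is_cea:
            sev_periop = [p.periop_sev.p_nondisabling, p.periop_sev.p_disabling,
                          p.periop_sev.p_fatal]
            sev_rec = [p.residual_sev.p_nondisabling, p.residual_sev.p_disabling,
                       p.residual_sev.p_fatal]
            paths = (
                [(p.p_periop * sev_periop[i], sev, 0.0) for i, sev in
                 enumerate(["nd", "dis", "fatal"])]
                + [((1 - p.p_periop) * p.p_residual * sev_rec[i], sev, t_rec)
                   for i, sev in enumerate(["nd", "dis", "fatal"])]
                + [((1 - p.p_periop) * (1 - p.p_residual), "none", None)]
            )
        else:
            sev_omt = [p.omt_sev.p_nondisabling, p.omt_sev.p_disabling,
                       p.omt_sev.p_fatal]
            paths = [(omt_risk * sev_omt[i], sev, t_rec)
                     for i, sev in enumerate(["nd", "dis", "fatal"])]
            paths.append((1 - omt_risk, "none", None))

        for prob, sev, t in paths:
            # --- QALY ---
            if sev == "none":
                q = u_base * horizon / 12.0
            elif sev == "nd":
                q = (u_base * t + u_nd * (horizon - t)) / 12.0
            elif sev == "dis":
                q = (u_base * t + p.u_disabling * (horizon - t)) / 12.0
            else:
                q = (u_base * t + p.u_fatal * (horizon - t)) / 12.0
            # --- cost ---
            alive = t if sev == "fatal" else horizon
            cost = 0.0
            if is_cea:
                cost += p.cost_cea
            if pat["needs_mri"]:
                cost += p.cost_mri
            cost += p.cost_baseline_per_month * alive
            idx = index_monthly * min(3.0, alive)
            cost += idx
            if sev == "nd":
                cost += (p.cost_nd_first3m * min(3.0, horizon - t) / 3.0
                         + p.cost_nd_per_month * max(0.0, horizon - t - 3.0))
            elif sev == "dis":
                cost += (p.cost_dis_first3m * min(3.0, horizon - t) / 3.0
                         + p.cost_dis_per_month * max(0.0, horizon - t - 3.0))
            elif sev == "fatal":
                cost += p.cost_fatal
            # --- mRS ---
            if sev == "none":
                dist = {pat["baseline_mrs"]: 1.0}
            elif sev == "nd":
                if pat["baseline_mrs"] == 2:
                    dist = {2: 1.0}
                else:
                    dist = {1: float(p.mrs12[0]), 2: float(p.mrs12[1])}
            elif sev == "dis":
                dist = {3: float(p.mrs345[0]), 4: float(p.mrs345[1]),
                        5: float(p.mrs345[2])}
            else:
                dist = {6: 1.0}

            total_qaly += prob * q
            total_cost += prob * cost
            total_index += prob * idx
            if sev != "none":
                primary += prob
            for state, w in dist.items():
                mrs_counts[state] += prob * w

    n = len(patients)
    return {
        "qaly_per_patient": total_qaly / n,
        "cost_per_patient": (total_cost - total_index) / n,
        "primary_endpoint": primary,
        "mrs_distribution": mrs_counts,
    }
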
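"""Triage the cohort under both strategies and scan risk thresholds 5-20%.

Reports, per strategy, the surgical fraction, the Kaplan-Meier 3-year stroke
risk of the medical-therapy stratum, and sensitivity/specificity for 3-year
stroke status; then scans the risk-based strategy's threshold and selects
the operating point minimising ipsilateral strokes plus perioperative
strokes/deaths (ties toward the lower threshold).
"""

import argparse
from pathlib import Path

from improve_cea import default_parameters, read_cohort
from improve_cea.pipeline import evaluate_strategy
from improve_cea.stratify import confusion_stats
from improve_cea.thresholds import DEFAULT_TAU_GRID, scan


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    params = default_parameters()
    cohort = read_cohort(args.out_dir / "cohort.csv")

    for strategy, tau in (("cau", None), ("improve", 0.10)):
        ev = evaluate_strategy(cohort, strategy, params, threshold=tau)
        ev.assignments.to_csv(args.out_dir / f"assignments_{strategy}.csv", index=False)
        acc = confusion_stats(ev.assignments, cohort)
        label = strategy if tau is None else f"{strategy} (tau=10%)"
        sens = "n/a" if acc.sensitivity is None else f"{acc.sensitivity:.1%}"
        spec = "n/a" if acc.specificity is None else f"{acc.specificity:.1%}"
        print(
            f"{label:18s} surgery {ev.outcome.n_cea:.0f}/{len(cohort)}, "
            f"stratum risk {ev.km.risk:.3f} (SE {ev.km.se:.3f}), "
            f"sens {sens}, spec {spec}"
        )

    table, tau_star = scan(cohort, params, DEFAULT_TAU_GRID)
    table.to_csv(args.out_dir / "threshold_scan.csv", index=False)
    print("\nthreshold scan (primary endpoint = ipsilateral + perioperative events):")
    print(table[["threshold", "n_cea", "primary_endpoint",
                 "reduction_primary_pct"]].to_string(index=False))
    print(f"\nselected threshold tau* = {tau_star:.0%}")


if __name__ == "__main__":
    main()
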
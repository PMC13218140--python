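"""Deterministic base-case comparison at the selected threshold.

Evaluates the decision tree for care-as-usual and the risk-based strategy,
printing expected event counts, the end-of-horizon mRS mix, QALYs and
societal costs per patient, and the incremental results.
"""

import argparse
import json
from pathlib import Path

from improve_cea import base_case, default_parameters, read_cohort
from improve_cea.run import comparison_to_dict, outcome_to_dict


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=float, default=0.10)
    args = ap.parse_args()
    params = default_parameters()
    cohort = read_cohort(args.out_dir / "cohort.csv")

    det = base_case(cohort, params, args.threshold)
    for ev in (det.reference, det.alternative):
        o = ev.outcome
        print(f"{o.strategy}:")
        print(f"  surgeries                {o.n_cea:.0f}  (MRI scans {o.n_mri:.0f})")
        print(f"  perioperative events     {o.n_periop.sum():.1f}")
        print(f"  ipsilateral strokes      {o.ipsilateral_strokes:.1f}")
        print(f"  primary endpoint         {o.primary_endpoint:.1f}")
        print("  mRS at 36 months         "
              + " ".join(f"{x:.1f}" for x in o.mrs_distribution))
        print(f"  QALY/patient             {o.qaly_per_patient:.3f}")
        print(f"  cost/patient (EUR)       {o.cost_per_patient:.0f}")
    c = det.comparison
    print(f"\nincremental (risk-based - care-as-usual):")
    print(f"  dQALY {c.delta_qaly:+.4f}, dCost {c.delta_cost:+.0f} EUR, "
          f"NMB {c.nmb:.0f} EUR at WTP {params.wtp:.0f}")
    print(f"  primary endpoint reduction {c.reduction_primary_endpoint:.1%}"
          + ("  (dominant)" if c.dominant else ""))
    payload = {
        "cau": outcome_to_dict(det.reference.outcome),
        "improve": outcome_to_dict(det.alternative.outcome),
        "comparison": comparison_to_dict(c),
    }
    (args.out_dir / "base_case.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
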
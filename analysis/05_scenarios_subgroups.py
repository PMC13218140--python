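"""Scenario analyses (surgical risk 2% / 6%, surgery only for 70-99%
stenosis) and per-stenosis subgroup analyses with subgroup-specific
recurrence timing, each at the 3-year and lifetime horizon.
"""

import argparse
import json
from pathlib import Path

from improve_cea import default_parameters, read_cohort
from improve_cea.run import comparison_to_dict
from improve_cea.scenarios import SCENARIOS, run_scenario, run_subgroups


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--threshold", type=float, default=0.10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    params = default_parameters()
    cohort = read_cohort(args.out_dir / "cohort.csv")

    payload = {"scenarios": {}, "subgroups": {}}
    print("scenarios (3-year horizon):")
    for name in SCENARIOS:
        res = run_scenario(name, cohort, params, args.threshold)
        c, l = res.deterministic.comparison, res.lifetime
        icer = "dominant" if c.dominant else (
            "n/a" if c.icer is None else f"ICER {c.icer:.0f}")
        print(f"  {name:18s} dQALY {c.delta_qaly:+.4f}, dCost {c.delta_cost:+8.0f} EUR "
              f"({icer}); lifetime dQALY {l.delta_qaly:+.4f}, dCost {l.delta_cost:+8.0f}")
        payload["scenarios"][name] = {
            "deterministic": comparison_to_dict(c),
            "lifetime": comparison_to_dict(l),
        }

    print("\nstenosis subgroups (subgroup recurrence timing, re-estimated risks):")
    for name, res in run_subgroups(cohort, params, args.threshold).items():
        c, l = res.deterministic.comparison, res.lifetime
        print(f"  {name:8s} n={res.n:3d}, timing {res.timing_mean_months:.1f} m: "
              f"3y dQALY {c.delta_qaly:+.4f}, dCost {c.delta_cost:+8.0f}; "
              f"lifetime dQALY {l.delta_qaly:+.4f}, dCost {l.delta_cost:+8.0f}")
        payload["subgroups"][name] = {
            "n": res.n,
            "deterministic": comparison_to_dict(c),
            "lifetime": comparison_to_dict(l),
        }
    (args.out_dir / "scenarios_subgroups.json").write_text(
        json.dumps(payload, indent=2)
    )


if __name__ == "__main__":
    main()
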
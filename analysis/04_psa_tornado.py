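"""Probabilistic sensitivity analysis and one-way (tornado) analysis.

Propagates all parameter uncertainty (Beta/Dirichlet/gamma) through both
strategies with common random numbers, summarises the cost-effectiveness
plane and acceptability curve, and ranks the most influential single
parameters for net monetary benefit and incremental cost.
"""

import argparse
from pathlib import Path

import numpy as np

from improve_cea import default_parameters, read_cohort
from improve_cea.pipeline import seed_streams
from improve_cea.psa import ce_plane_quadrants, ceac, run_psa, tornado, tornado_table
from improve_cea.run import _plots


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--draws", type=int, default=10_000)
    ap.add_argument("--threshold", type=float, default=0.10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    params = default_parameters()
    cohort = read_cohort(args.out_dir / "cohort.csv")

    res = run_psa(cohort, params, args.threshold, n_draws=args.draws,
                  rng=seed_streams(args.seed)["psa"])
    res.draws.to_csv(args.out_dir / "psa_draws.csv", index=False)
    s = res.summary
    print(f"{res.n_draws} draws at tau={args.threshold:.0%}:")
    print(f"  dQALY  {s['delta_qaly']['mean']:+.4f} "
          f"[{s['delta_qaly']['ci_low']:+.4f}, {s['delta_qaly']['ci_high']:+.4f}]")
    print(f"  dCost  {s['delta_cost']['mean']:+.0f} EUR "
          f"[{s['delta_cost']['ci_low']:+.0f}, {s['delta_cost']['ci_high']:+.0f}]")
    print(f"  P(cost-effective at {params.wtp:.0f}/QALY) = {s['prob_cost_effective']:.4f}")
    print(f"  P(dominant) = {s['prob_dominant']:.4f}")
    print(f"  CE-plane quadrants: {ce_plane_quadrants(res.draws)}")

    ceac_table = ceac(res.draws, np.linspace(0, 100_000, 21))
    ceac_table.to_csv(args.out_dir / "ceac.csv", index=False)

    torn = tornado(cohort, params, args.threshold, outcome="nmb")
    tornado_table(torn).to_csv(args.out_dir / "tornado_nmb.csv", index=False)
    print("\ntop parameters by NMB range:")
    for e in torn:
        print(f"  {e.parameter:32s} {e.range:10.1f} EUR")
    torn_cost = tornado(cohort, params, args.threshold, outcome="delta_cost")
    tornado_table(torn_cost).to_csv(args.out_dir / "tornado_delta_cost.csv", index=False)

    _plots(args.out_dir, res.draws, ceac_table, torn)
    print(f"\nplots and tables written under {args.out_dir}/")


if __name__ == "__main__":
    main()
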
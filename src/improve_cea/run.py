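"""End-to-end pipeline: generate -> stratify -> scan -> base case -> PSA ->
tornado -> scenarios -> lifetime, with reproducible seeding and a run
manifest.

The main config file is a YAML document whose top level holds the parameter
set (see :mod:`improve_cea.params`) plus an optional ``cohort`` section (see
:class:`improve_cea.cohort.CohortSpec`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, generate_cohort, write_cohort
from .lifetime import configured_lifetime_table, lifetime_comparison
from .params import ConfigError, ParameterSet, parameter_table
from .pipeline import base_case, seed_streams
from .psa import ce_plane_quadrants, ceac, run_psa, tornado, tornado_table
from .scenarios import SCENARIOS, run_scenario, run_subgroups
from .stratify import confusion_stats
from .thresholds import DEFAULT_TAU_GRID, scan
from .tree import Comparison, TreeOutcome


def load_config(path: str | Path | None) -> tuple[ParameterSet, CohortSpec]:
    """Read the main config file; ``None`` gives the package defaults."""
    if path is None:
        return ParameterSet(), CohortSpec()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    cohort_raw = raw.pop("cohort", {})
    try:
        return ParameterSet.model_validate(raw), CohortSpec.model_validate(cohort_raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def outcome_to_dict(o: TreeOutcome) -> dict:
    d = dataclasses.asdict(o)
    for key in ("n_periop", "n_postcea", "n_omt", "mrs_distribution"):
        d[key] = [float(x) for x in d[key]]
    return d


def comparison_to_dict(c: Comparison) -> dict:
    return dataclasses.asdict(c)


def full_run(
    out_dir: str | Path,
    config: str | Path | None = None,
    seed: int | None = 0,
    n_draws: int | None = None,
    threshold: float | None = None,
    tau_grid=DEFAULT_TAU_GRID,
    make_plots: bool = True,
    scenario_draws: int = 0,
) -> dict:
    """Run the complete analysis into ``out_dir`` and return the manifest.

    ``threshold=None`` selects the optimum from the threshold scan.  The
    global seed is expanded into named substreams so, e.g., changing the
    number of Monte Carlo draws does not perturb the generated cohort.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params, cohort_spec = load_config(config)
    if n_draws is None:
        n_draws = params.mc_draws
    streams = seed_streams(seed)

    cohort = generate_cohort(cohort_spec, params.improve, streams["cohort"])
    write_cohort(cohort, out / "cohort.csv")
    parameter_table(params).to_csv(out / "parameters.csv", index=False)

    scan_table, tau_star = scan(cohort, params, tau_grid)
    scan_table.to_csv(out / "threshold_scan.csv", index=False)
    tau = float(threshold) if threshold is not None else tau_star

    det = base_case(cohort, params, tau)
    det.reference.assignments.to_csv(out / "assignments_cau.csv", index=False)
    det.alternative.assignments.to_csv(out / "assignments_improve.csv", index=False)

    acc = {
        name: dataclasses.asdict(confusion_stats(ev.assignments, cohort))
        for name, ev in (("cau", det.reference), ("improve", det.alternative))
    }

    psa_res = run_psa(cohort, params, tau, n_draws=n_draws, rng=streams["psa"])
    psa_res.draws.to_csv(out / "psa_draws.csv", index=False)
    lambda_grid = np.linspace(0, 100_000, 21)
    ceac_table = ceac(psa_res.draws, lambda_grid)
    ceac_table.to_csv(out / "ceac.csv", index=False)

    torn = tornado(cohort, params, tau, outcome="nmb")
    tornado_table(torn).to_csv(out / "tornado_nmb.csv", index=False)
    torn_cost = tornado(cohort, params, tau, outcome="delta_cost")
    tornado_table(torn_cost).to_csv(out / "tornado_delta_cost.csv", index=False)

    table = configured_lifetime_table(
        params.lifetime_qaly_per_mrs, params.lifetime_cost_per_mrs
    )
    table.as_frame().to_csv(out / "lifetime_table.csv", index=False)
    life = lifetime_comparison(
        det.reference.outcome, det.alternative.outcome, table, params.wtp
    )

    scenario_results = {}
    for name in SCENARIOS:
        res = run_scenario(name, cohort, params, tau, n_draws=scenario_draws,
                           rng=streams["scenarios"], lifetime_table=table)
        scenario_results[name] = {
            "reference_strategy": res.reference_strategy,
            "deterministic": comparison_to_dict(res.deterministic.comparison),
            "lifetime": comparison_to_dict(res.lifetime),
        }
    subgroup_results = {
        name: {
            "n": res.n,
            "timing_mean_months": res.timing_mean_months,
            "deterministic": comparison_to_dict(res.deterministic.comparison),
            "lifetime": comparison_to_dict(res.lifetime),
        }
        for name, res in run_subgroups(
            cohort, params, tau, lifetime_table=table
        ).items()
    }

    results = {
        "threshold": tau,
        "threshold_selected": tau_star,
        "base_case": {
            "cau": outcome_to_dict(det.reference.outcome),
            "improve": outcome_to_dict(det.alternative.outcome),
            "comparison": comparison_to_dict(det.comparison),
            "omt_risk_cau": det.reference.km.risk,
            "omt_risk_improve": det.alternative.km.risk,
        },
        "accuracy": acc,
        "psa_summary": psa_res.summary,
        "ce_plane_quadrants": ce_plane_quadrants(psa_res.draws),
        "lifetime": comparison_to_dict(life),
        "scenarios": scenario_results,
        "subgroups": subgroup_results,
    }
    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))

    if make_plots:
        _plots(out, psa_res.draws, ceac_table, torn)

    config_text = Path(config).read_text() if config else ""
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "n_draws": n_draws,
        "threshold": tau,
        "threshold_selected": tau_star,
        "config_path": str(config) if config else None,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "cohort_n": int(len(cohort)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _plots(out: Path, draws: pd.DataFrame, ceac_table: pd.DataFrame, torn) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(draws["delta_qaly"], draws["delta_cost"], s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALY / patient")
    ax.set_ylabel("Incremental societal cost (EUR) / patient")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(out / "ce_plane.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ceac_table["wtp"], ceac_table["prob_cost_effective"])
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Acceptability curve")
    fig.tight_layout()
    fig.savefig(out / "ceac.png", dpi=150)
    plt.close(fig)

    if torn:
        fig, ax = plt.subplots(figsize=(6, 4))
        names = [e.parameter for e in torn][::-1]
        lows = [e.outcome_low for e in torn][::-1]
        highs = [e.outcome_high for e in torn][::-1]
        base_val = np.median([*lows, *highs])
        for i, (lo, hi) in enumerate(zip(lows, highs)):
            ax.barh(i, hi - lo, left=lo, height=0.6)
        ax.set_yticks(range(len(names)), names, fontsize=7)
        ax.axvline(base_val, color="k", lw=0.5)
        ax.set_xlabel("NMB (EUR) / patient")
        ax.set_title("One-way sensitivity (top parameters)")
        fig.tight_layout()
        fig.savefig(out / "tornado.png", dpi=150)
        plt.close(fig)
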
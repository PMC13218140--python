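# improve-cea

Model-based cost-effectiveness of risk-score-guided versus stenosis-guided
triage for carotid endarterectomy (CEA) in recently symptomatic carotid
artery disease.

## The problem

Guidelines triage symptomatic patients to revascularisation on the degree of
carotid stenosis alone (surgery for ≥50% stenosis, "care-as-usual", CAU),
yet plaque vulnerability — in particular intraplaque haemorrhage (IPH) on
MRI — drives much of the recurrent-stroke risk. A clinical prediction model
(the IMPROVE score) estimates each patient's 3-year ipsilateral
ischaemic-stroke risk under optimal medical treatment (OMT) from age, sex,
stenosis category, index-event type (ocular vs cerebral) and IPH, as a
proportional-hazards score

S(t | x) = S₀(t)^exp(LP),  LP = Σᵢ βᵢ xᵢ,

with conditional survival applied when the patient is assessed more than
9 days after the index event. This package asks: if patients were sent to
surgery when their predicted 3-year risk reaches a threshold τ (scanned over
5–20%) instead of on stenosis alone, what happens to strokes, QALYs and
societal costs?

A decision-tree cohort model answers this over a 3-year horizon. Surgical
patients face a perioperative stroke/death risk (3.6%, Beta(235, 6224)) with
a non-disabling/disabling/fatal severity split, and survivors a residual
3-year stroke risk (2.2%); medical-therapy patients face their stratum's
Kaplan-Meier 3-year stroke risk. Events map to modified Rankin Scale (mRS)
states with mRS-indexed annual utilities and peak-then-monthly societal
costs (EUR-2022), the incremental results are summarised as ΔQALY, ΔCost and
net monetary benefit NMB = λ·ΔQALY − ΔCost at λ = €50,000/QALY, and
parameter uncertainty is propagated by Monte Carlo (Beta/Dirichlet/gamma,
10,000 draws). A lifetime horizon multiplies the 3-year end-state mRS mix by
per-state lifetime QALY/cost values from an annual-cycle survival model with
differential discounting (1.5% QALYs, 4% costs).

The pooled patient-level dataset behind the original analysis is not public,
so the package includes a synthetic-cohort generator that reproduces the
cohort's marginal structure (n = 678; 50/30/20% across stenosis categories;
42% TIA / 44% stroke / 14% amaurosis fugax; 43% IPH; age 71 ± 10; 66% male)
with event times calibrated to the risk model. The bundled score
coefficients are likewise a documented synthetic set — replace them with the
published ones before drawing clinical conclusions.

Intended users: health-economic modellers and stroke researchers who want a
tested, reproducible re-implementation of this triage comparison to probe
thresholds, scenarios and parameter sensitivity.

## Worked example

```python
import improve_cea as ic

params = ic.default_parameters()
cohort = ic.generate_cohort(ic.CohortSpec(), params.improve,
                            ic.seed_streams(1)["cohort"])
result = ic.base_case(cohort, params, threshold=0.10)

for ev in (result.reference, result.alternative):
    o = ev.outcome
    print(f"{o.strategy:8s} surgery {o.n_cea:.0f}/{o.n}  "
          f"strokes {o.ipsilateral_strokes:.1f}  periop {o.n_periop.sum():.1f}  "
          f"QALY {o.qaly_per_patient:.3f}  cost EUR {o.cost_per_patient:.0f}")
c = result.comparison
print(f"incremental: dQALY {c.delta_qaly:+.4f}, dCost {c.delta_cost:+.0f} EUR, "
      f"NMB {c.nmb:.0f} EUR" + ("  -> dominant" if c.dominant else ""))
```

prints

```
cau      surgery 327/678  strokes 41.9  periop 11.9  QALY 2.712  cost EUR 9007
improve  surgery 256/678  strokes 35.5  periop 9.3  QALY 2.720  cost EUR 7433
incremental: dQALY +0.0077, dCost -1574 EUR, NMB 1962 EUR  -> dominant
```

Read: on this synthetic cohort, triaging on a 10% 3-year-risk threshold
performs 71 fewer surgeries, which avoids perioperative events while
operating on the patients whose risk actually justifies surgery; it prevents
strokes, gains a small amount of quality-adjusted survival (+0.0077
QALY/patient) and saves €1,574/patient in societal costs — the risk-based
strategy *dominates* care-as-usual. A probabilistic sensitivity analysis
(`ic.run_psa`) propagates all parameter uncertainty and reports the
probability that this conclusion survives.

## The analysis, step by step

The numbered scripts under `analysis/` run the full study narrative and
write tables/figures under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | generate the synthetic cohort, check marginals |
| `02_stratify_scan.py` | triage under both strategies, sensitivity/specificity, threshold scan 5–20% |
| `03_base_case.py` | deterministic decision-tree comparison at the selected threshold |
| `04_psa_tornado.py` | 10,000-draw PSA, CE plane, acceptability curve, tornado diagrams |
| `05_scenarios_subgroups.py` | surgical risk 2%/6%, surgery-only-for-70–99% reference, stenosis subgroups |
| `06_lifetime.py` | lifetime extrapolation of the end-state mRS mix |

The same steps are available as a CLI (`improve-cea full-run --seed 0
--out-dir results`), driven by a single YAML config
(`src/improve_cea/data/default_config.yaml`) and one global seed that is
expanded into named substreams, so every output is regenerable from the run
manifest.

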
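# Methods

## Model structure

The comparison is a decision-tree cohort simulation over a 36-month horizon.
Each patient is triaged once, at study entry, by one of three rules:

- **cau** — surgery (CEA + OMT) for stenosis ≥50%, OMT alone otherwise;
- **improve** — surgery when the predicted 3-year ipsilateral-stroke risk is
  at or above a threshold τ (ties assign surgery, so the 5–20% grid scan is
  well defined);
- **cau_70_99** — scenario variant restricting surgery to 70–99% stenosis.

Surgical patients pass a perioperative chance node (stroke/death, base
probability 3.6%) whose events split non-disabling / disabling / fatal
(48.3/38.2/13.5%); event-free survivors face a residual 3-year stroke risk
(2.2%, split 50.0/34.8/15.2%). Medical-therapy patients face their stratum's
Kaplan-Meier 3-year stroke risk (split 53.3/30.3/16.4%). Perioperative
events happen at month 0; stroke recurrences at the modelled recurrence time
(gamma, mean 24.1 months, SD 2.7; subgroup means 34.2/24.2/10.7 months for
<50/50–69/70–99% stenosis). Perioperative-stroke survivors are *not*
additionally exposed to the residual risk (mutually exclusive branches — the
simplest tree consistent with the published structure); a config-free
convention, noted as an open modelling choice.

Everything is expectation arithmetic: path probabilities multiply per-path
QALYs and costs, so there is no patient-level Monte Carlo error and a full
tree evaluation costs a few milliseconds, which is what makes the
10,000-draw PSA cheap.

### Health states and QALYs

Baseline state follows the index event: TIA/amaurosis fugax → mRS 0
(utility 0.960/year), index stroke → mRS 1 or 2 (split 0.55/0.45; utility
0.864/year). New events can only worsen mRS (worst-state rule): a
non-disabling stroke maps to mRS 1–2, disabling to mRS 3–5 (split
0.50/0.30/0.20), fatal to mRS 6. A non-disabling event in a patient whose
index event was already a stroke uses the recurrent-stroke utility
(0.864 − 0.0524 = 0.812/year); disabling events use 0.356/year. Utility
switches exactly at the event time and stays constant to the horizon; QALYs
are the utility-time integral in years. No discounting is applied within the
3-year horizon (discounting enters only in the lifetime model).

The mRS 1/2 and 3/4/5 splits are placeholders for distributions published in
a supplementary source; both are configurable and sampled (Dirichlet) in the
PSA.

### Societal costs

EUR-2022 throughout; a CPI helper (factor 1.265) converts EUR-2012 inputs.
Cost components per path:

- CEA €8,733 at month 0 for surgical patients;
- MRI €254 only for patients whose triage *could* change with IPH status —
  i.e. whose risk with IPH absent and present straddles τ (IPH is unknown
  before imaging, so only these scans are causally attributable to the
  risk-based strategy);
- event costs: peak cost over the 3 months after the event (€14,511
  non-disabling; €45,265 disabling), pro-rated when the horizon cuts the
  peak window, then a monthly cost to the horizon (€999 / €5,865); fatal
  events cost €13,111 once and stop all streams;
- a baseline monthly cost for the index-event state. The mRS-0 monthly cost
  is not printed in the source and defaults to €0, so baseline costs cancel
  between arms except through differential survival — transparency was
  preferred over inventing a number.

The index event itself is unpreventable, so its cost (the first-3-month peak
of the index state, truncated at death) is accrued and then subtracted as a
strategy-level average. Because fatal-event frequencies differ between
strategies, the subtracted amount is strategy-dependent, which reproduces
the source's observation that average index-event costs differ between arms.

## The risk score

Box-style proportional-hazards score: S(t|x) = S₀(t)^exp(LP). The published
coefficients are not reproduced in the available text, so the package ships
a synthetic default set (S₀(36 m) = 0.985 at the reference pattern; per-year
age 0.03, male 0.2, stenosis 50–69% 0.6, 70–99% 1.0, cerebral index event
0.5, IPH 1.5), chosen once so the default cohort's 3-year risks span roughly
1–40% and documented as a stand-in: replace the `improve:` config block with
the published coefficients for real use.

Patients assessed within 9 days of the index event get the unconditional
risk 1 − S(36|x). Later assessments condition on being stroke-free at
assessment. Two window conventions are implemented:

- `next36` (default): 1 − S(t+36|x)/S(t|x) — a triage decision concerns the
  *future* 36 months. Note that with the default constant-hazard baseline
  (Weibull shape 1) this coincides with the unconditional risk; a shape
  parameter ≠ 1 makes the conditioning bite.
- `post_index`: 1 − S(36|x)/S(t|x) — risk up to 36 months after the index
  event, which shrinks to 0 as t → 36 months.

## Synthetic cohort

The generator emulates the pooled cohort's marginal structure (n = 678;
stenosis 50/30/20%; index events 42/44/14%; IPH 43%; age 71 ± 10 truncated
at 30; 66% male; days since event log-normal with median 37; baseline mRS of
index-stroke patients split 0.55/0.45). Predictors are drawn independently
by default; an `iph_by_stenosis` hook induces the IPH-stenosis dependence
seen in the source cohorts. Event times are Weibull (default shape 1,
exponential) with the per-patient scale solved so that
P(event ≤ 36 m | x) equals the risk model's prediction — the score is the
ground truth of the synthetic world. Censoring is exponential with median
17 months (the cohort's median follow-up), truncated administratively at 72
months.

What the generator does **not** emulate: the real joint predictor
distribution beyond the optional IPH hook, missing data (cohorts are
generated complete; the source imputed), non-proportional hazards,
competing mortality before stroke, and any misspecification of the score
itself (the synthetic truth *is* the score, so synthetic classification
metrics are optimistic). Passing tests therefore demonstrate the machinery
— calibration of the pipeline, internal consistency, dominance under the
stated inputs — not clinical performance on real patients.

## Estimation inputs

The per-strategy OMT-stratum 3-year stroke risk is a Kaplan-Meier estimate
(lifelines) at 36 months on the patients the strategy leaves on medical
therapy, with Greenwood standard error computed from the fitted event
table; if no follow-up reaches the horizon the last estimate is carried
forward with a warning. For the PSA the estimate is moment-matched to a
Beta distribution.

Sensitivity/specificity of a triage rule for 3-year stroke status use
observed-event cases within the horizon; stroke-free patients censored
before a configurable minimum follow-up (default 12 months) are excluded as
status-unknown — the source does not state its handling, and this choice is
conservative in both directions. Wilson score intervals (statsmodels).

## Probabilistic sensitivity analysis

Each draw samples: Beta for binary probabilities, joint Dirichlet for the
three-category severity and mRS splits (the printed two-parameter rows share
one denominator, so the underlying joint counts 43/34/12, 115/80/35 and
81/46/25 are sampled), gamma for costs and for the recurrence time, and
moment-matched Betas for utilities. Spreads not printed in the source are
configurable with conventional defaults: cost coefficient of variation 0.2,
utility effective sample size 1,000. The recurrent-stroke utility tracks the
sampled first-event utility minus the fixed decrement.

Both strategies are evaluated on the *same* parameter draw (common random
numbers), and the two strategies' stratum risks — estimates of risk in
overlapping patient strata — are drawn comonotonically (one shared uniform
through each Beta's quantile function). Without this coupling, independent
stratum-risk noise would swamp the paired strategy effect that the analysis
is about. Setting any spread to `None`/0 freezes that input, and a fully
frozen parameter set makes a 1-draw PSA reproduce the deterministic result
exactly (tested).

Tornado diagrams set one parameter at a time to the 2.5th/97.5th percentile
of its distribution (marginal Beta percentiles for Dirichlet categories,
with the remaining categories renormalised proportionally), recompute the
deterministic comparison and rank by outcome range (NMB by default; ΔCost
and ΔQALY variants). The source does not state its tornado ranges; the
percentile convention is configurable.

## Threshold selection

τ is scanned over 5–20% in 1% steps; the selected τ* minimises the expected
primary endpoint (ipsilateral strokes + perioperative strokes/deaths), ties
broken toward the lower τ (the more stroke-averse triage; the source does
not state a tie rule). On synthetic cohorts the scan is noisy because each
τ re-estimates the stratum risk from a few dozen observed events, so τ*
varies across seeds; the base-case analyses pin τ = 10% for comparability.

## Lifetime model

After 3 years both strategies are assumed to face the same recurrence
hazard, so patients remain in their end-of-horizon mRS state and lifetime
totals are linear in the mRS distribution. Per-state lifetime QALY/cost come
either from a configured table — anchors 7.771 QALY / €55,317 (mRS 0) and
0.795 QALY / €1,041,095 (mRS 5) with monotone synthetic placeholders for
mRS 1–4, which live in a supplementary table not available here and should
be replaced from it — or from a generator: yearly cycles from age 74,
full-year accrual for those alive at cycle start (no half-cycle
correction), discounting 1.5%/year for QALYs and 4%/year for costs,
survival from a life table with an optional per-state excess-mortality
hazard ratio (default 1, the source's per-state ratios being unavailable).
The bundled life table is synthetic Gompertz-Makeham (≈2% annual mortality
at 74, doubling every 8 years, closed at 110); substitute a national table
(`age`, `qx` CSV) for country-specific results.

## Numerical and testing choices

- All randomness flows from one seed expanded into named `SeedSequence`
  substreams (cohort / PSA / scenarios), so changing the draw count never
  perturbs the generated cohort.
- Degenerate inputs are errors, not silent defaults: empty subcohorts for
  KM, probabilities outside [0, 1], severity splits off the simplex
  (tolerance 1e-6 for sampled simplex points), negative event times,
  non-contiguous life tables. An all-surgery stratum gets a vacuous (zero)
  stratum risk rather than an error, which the 70–99%-only reference needs.
- The test suite checks the tree against exhaustive path enumeration on
  ≤5-patient cohorts and the survival estimate against a textbook
  product-limit oracle on ≤20-patient instances; both oracles are
  implemented independently in the tests. Monte-Carlo-based checks use 300–
  500 draws and cohorts of 150–678 patients, sizes chosen to keep the suite
  fast while leaving sampling-error margins of 3 standard errors.
- `scripts/acceptance.py` uses the full default conditions (n = 678,
  10,000 draws).

## Known limitations

- The score coefficients, mRS split proportions, mRS-0 monthly cost,
  utility/cost spreads and intermediate lifetime values are documented
  synthetic defaults standing in for supplementary or cited sources; all are
  config-replaceable, and headline synthetic numbers shift accordingly.
- Classification metrics computed on the synthetic cohort evaluate a score
  against a world generated by that same score.
- Healthcare and indirect societal costs are aggregated, as in the source.
- No external validation of the score, no comparison with other carotid risk
  tools, and no patient-level microsimulation (the tree is expectation
  arithmetic by design).
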
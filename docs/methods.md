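# Methods

This note documents the modelling choices, parameter defaults and
limitations of the pipeline, in the order data flows through it.

## Synthetic cohort: the stated world

Real PICU event streams are not shareable, so the package ships a
generator whose output has the statistical features the pipeline's claims
depend on. What it emulates:

* **Demographics.** Ages drawn from a paediatric mixture (bands <1 m,
  1–11 m, 1–2 y, 2–5 y, 5–12 y, ≥12 y with weights 0.08/0.24/0.16/0.20/
  0.22/0.10), giving a median near 2.3 years; weight/height follow smooth
  age curves with lognormal individual variation; length of stay is
  lognormal with median 48 h (σ = 0.6), clipped to [3 h, 21 d].
* **Vitals.** Ornstein–Uhlenbeck processes (τ = 120 min) around
  age-appropriate set-points, observed at exponential inter-observation
  gaps. The sparsest routine vital (non-invasive BP) is observed ~1.5/h;
  HR/SpO₂ ~2/h. Mean reversion gives realistic short-range
  autocorrelation, and the stationary SD makes "variability" a real,
  controllable signal.
* **Deteriorations.** A Poisson process at 0.105 events/admission-day
  (≥ 8 h apart, none before minute 420). Each event injects, over the
  preceding 12 h: a MAP decline of 2.5 stationary SDs, compensatory HR/RR
  rises, a lactate ramp of +2.5 mmol/l with extra blood-gas draws around
  the event, and a 2.5× observation-cadence boost (informative
  frequency). At the event a vasoactive infusion starts (or escalates
  across a dose band if one is already running); 30% of events are
  lactate-only, 4% end in death (truncating the admission), 2% start
  ECMO. MAP set-points sit 12 mmHg above the age-banded lower limit with
  OU SD 3.5 mmHg, so baseline noise crosses the hypotension threshold
  rarely (a small, realistic false-trigger floor) while the injected
  decline brings crossings near events.
* **Support and labs.** Ventilation episodes (invasive → non-invasive →
  none) for ~a third of patients with FiO₂ records; sparse daily labs
  (platelets, bilirubin, creatinine, sodium) that drift with events.

Defaults were calibrated **once** so that, with the default windowing,
~7% of windows are positive at horizon 12 h and ~22% of patients
deteriorate during their admission, then frozen; acceptance tests run on
different seeds than the calibration seed.

What it does **not** emulate: diagnosis-specific phenotypes, circadian
rhythm, treatment feedback beyond the single vasoactive response, device
artefacts, or documentation errors. A green test therefore establishes
that the pipeline recovers the signal structure it claims to use — not
clinical validity on real data.

Ground truth records injection times, but labels are always produced by
the labeller from the emitted observations; acceptance checks compare
against the labeller, not the injections, to avoid circularity in
boundary minutes.

## Reference ranges

Centile tables, LMS growth references and MAP lower limits are editable
CSVs with documented schemas. The shipped numbers are package defaults
chosen to be paediatrically plausible; they are deliberately **not**
reproductions of any published chart (tests use small synthetic tables).
Between-centile interpolation is linear in value↔probability — the
simplest monotone rule, matching common centile-chart practice — with
clipping at the outermost tabulated centiles. Age bands are half-open
[low, high). The LMS z-score uses the log-form limit for |L| < 1e-7.

## Gridding, imputation, scaling

* **Minute grid.** Same-minute observations are averaged after the device
  priority rule (arterial beats cuff); data outside the admission are
  dropped and logged.
* **Interpolation.** Whole gaps of ≤ 90 min are filled linearly; longer
  gaps stay wholly missing. The whole-gap reading (rather than filling the
  first 90 min of a long gap) avoids artificial level steps; 90 min allows
  routinely ~hourly observations to be entered slightly late.
* **Labs** carry forward up to 4 days as step functions (no
  interpolation); infusion rates carry until the next recorded change.
* **Imputation** is strategy-per-feature: age-stratified medians for
  age-dependent vitals (bands as above), global medians where missingness
  is uninformative (SpO₂, labs), and fixed values where absence is
  informative (no ventilation record ⇒ level 0; no FiO₂ ⇒ 0.21; no
  infusion ⇒ dose 0). Medians and the scaler are fitted on the training
  split only, to keep the holdout untouched.
* **Scaling** is a single rank-to-[0,1] transform (mid-rank empirical CDF
  position, clipping outside the training range). One monotone map robust
  to outliers, rather than min-max followed by ranking.

## Windows and summaries

Anchors start at admission + L and advance by a 60-min stride
(configurable; hourly matches observation cycles and yields realistic
per-encounter sample counts). Admissions shorter than L yield no samples.
Summaries are computed on the 1-minute imputed grid; **frequency of input
uses raw-observation provenance only**, so interpolation cannot inflate
it. Degenerate conventions: constant window ⇒ SD 0, slope 0, R² defined
as 0 ("no evidence of trend"); single point ⇒ slope 0, R² 0. The batched
implementation is checked against a two-pass per-window computation and a
normal-equations oracle to 1e-9.

Ablations (`latest_only`, `no_frequency`, `no_trend`, `topk`, 15/60-min
resampling) operate on the feature registry so experiment variants are
column-exact; the `topk` ranking comes from the tree model's internal
importance — one source of truth shared with the interpretability module.

## Outcomes

The cardiovascular sub-score's dose bands (dopamine ≤5 / >5 / >15
µg/kg/min; epinephrine/norepinephrine ≤0.1 / >0.1; any vasopressin ⇒ 4)
and age-banded MAP limits live in config CSVs; milrinone counts like
dobutamine. The **cv-rise baseline is the lookback-window maximum**,
symmetric with the explicitly windowed lactate rule; the alternative
(value at the anchor) is available behind `cv_rise_baseline="at_anchor"`.
The lookback interval for baselines is [t − L, t] inclusive; the horizon
(t, t + H] is inclusive of t + H and truncated at discharge. When several
conditions fire at the same minute the reported trigger follows death >
ECMO > cv-rise > lactate. Death windows are never generated after death
because discharge is set to the death time. Secondary flags (death within
48 h, discharge within 7 days) are computed but consumed by no model.

## Models and tuning

Families: scikit-learn gradient-boosted trees and L2-penalised logistic
regression. The positive-class weight enters as a sample weight and is
always among the searched parameters. Search: patient-grouped,
outcome-stratified 4-fold CV scored by mean out-of-fold AUPRC; the first
third of the budget is random exploration, later trials perturb a
configuration drawn from the best 30% (Gaussian moves in log/linear
space, occasional categorical resampling). Default budget 20 trials
(reduced in tests); searched ranges: trees 60–200, learning rate
0.05–0.3 (log), depth {2,3,4}, subsample 0.5–0.9, feature fraction
0.15–0.6, min leaf 5–60, positive weight 0.5–20 (log); logistic C
1e-3–100 (log). The winner is refit on the full training split.
Comparator models use the organ-dysfunction scores only: total score (1
predictor), six components (6), or components plus window mean and SD
(18).

## Evaluation

AUPRC uses the average-precision step convention (no linear PR
interpolation, which is optimistic); AUROC uses the rank rule with ties
at half credit. The recall-0.9 operating point is the **largest score
threshold achieving recall ≥ 0.9** (no between-threshold interpolation —
it corresponds to a deployable cut); tied samples enter the positive set
together; the adjusted F1 uses the **achieved** recall at that threshold.
Both are verified against brute-force all-thresholds enumeration.
Repeated retrains reuse one holdout so families are comparable;
mean and SD are reported across repeats.

## Interpretability

Attributions are decision-path contributions over the fitted ensemble:
walking each tree root→leaf, the node-value change at every split is
credited to the split feature, scaled by the learning rate. This makes
local accuracy (base + Σ contributions = log-odds margin) hold exactly by
construction, which is the contract the tests enforce, together with
symmetry and agreement of global mean-|contribution| ordering with the
internal gain importance on dominant features. Contributions are in
margin (log-odds) units; probabilities are for display only. This is an
authored explainer, not a Shapley-value computation: with strongly
correlated features the credit assignment follows split order, which is
the main caveat when reading per-feature magnitudes.

## Numerical and degenerate-input choices

* Empty feature matrices, zero-patient cohorts and zero-event worlds are
  valid inputs and produce empty outputs, not errors.
* Single-class label vectors raise `UndefinedMetricError` rather than
  returning a conventional value.
* Same-seed runs are byte-identical end to end; per-patient RNG streams
  are spawned from one seed sequence so patient i's data does not depend
  on how many patients precede it.
* The MAP↔DBP back-calculation is algebraically exact; on integer mmHg
  inputs the floating-point round trip is bit-exact.

## Known limitations

* The shipped reference tables are defaults, not clinical standards; any
  deployment must substitute validated charts.
* The comparator's organ-dysfunction bands are configurable defaults from
  the published paediatric adaptation of the SOFA score; respiratory
  scoring uses the SpO₂:FiO₂ ratio only (no PaO₂ route).
* Neural time-series families, probability calibration, decision-curve
  analysis and alarm-burden simulation are out of scope.
* Performance numbers on the synthetic cohort characterise the pipeline,
  not any real population.
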
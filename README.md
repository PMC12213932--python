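# pedews

An end-to-end paediatric intensive-care early-warning pipeline: it turns
asynchronous ICU event streams into age-normalised windowed features,
labels **cardiovascular deterioration** with a composite organ-dysfunction
rule, trains gradient-boosted and logistic risk models tuned for
imbalanced outcomes, evaluates them at a **fixed recall of 0.9**, and
explains every prediction with exact additive attributions. A synthetic
cohort generator with known ground truth makes the whole pipeline testable
without access to protected patient data.

## Who this is for

Researchers building deterioration-prediction models on ICU EHR extracts —
anyone who needs the unglamorous middle of that work done carefully:
device consolidation, minute-grid coercion, gap-limited interpolation,
informative-missingness imputation, leakage-safe scaling, patient-level
splits, and evaluation that respects a 7% positive rate.

## The problem and the model

Children's normal physiology varies enormously with age (a neonate's heart
rate would be alarming in a teenager), so raw vitals are mapped onto
age-centile positions before modelling. Observations arrive
asynchronously at device-specific rates; everything is coerced to a
one-minute grid, linearly interpolated across gaps of at most 90 minutes,
with laboratory values carried forward up to 4 days.

A prediction at anchor time *t* summarises the lookback window [*t* − L, *t*)
(L = 6 h by default) with, per feature: mean, SD, OLS trend slope
(units/hour), trend strength R², frequency of input (observed values/hour
— a proxy for clinical concern), and the latest value. The binary target
is deterioration within the horizon (*t*, *t* + H] (H = 12 h by default):

* a **rise in the cardiovascular sub-score** of the paediatric
  organ-dysfunction (pSOFA-style) score above its lookback maximum — the
  sub-score grades hypotension against age-banded MAP lower limits and
  vasoactive support intensity, with milrinone treated as equivalent to
  dobutamine;
* **lactate ≥ 2 mmol/l and increasing** relative to the lookback maximum;
* **new ECMO**; or
* **death**.

Models output P(deterioration within H). Because the clinical cost of a
missed deterioration dominates, the operating point is fixed at recall 0.9
(miss at most 1 in 10 events) and precision / F1 are reported there,
alongside AUPRC and AUROC.

## Worked example

```python
from pedews import default_config
from pedews.models import SearchConfig
from pedews.pipeline import run
from pedews.synthetic import CohortSpec

config = default_config(
    cohort=CohortSpec(n_patients=150, seed=42),
    search=SearchConfig(budget=4, seed=42),
    seed=42,
)
res = run("evaluate", config)
print(res.results_table.round(3))
```

prints (holdout metrics; `precision`/`f1` at the recall-0.9 threshold):

```
                      family  auprc  auroc  precision    f1  recall  threshold
                        gbdt  0.497  0.760      0.093 0.168   0.902      0.007
                 logistic_l2  0.451  0.775      0.101 0.182   0.902      0.018
            psofa_summary_lr  0.122  0.676      0.076 0.141   1.000      0.047
         psofa_components_lr  0.091  0.528      0.076 0.141   1.000      0.014
psofa_components_mean_var_lr  0.091  0.498      0.072 0.133   0.902      0.017
```

Window prevalence here is 0.068, the AUPRC of a no-skill model: the
gradient-boosted model's 0.497 means it concentrates real signal, while
the organ-score comparators — the clinical status quo — barely beat
chance. On the full default cohort (500 patients) the gap widens further
and adding per-component mean/variability lifts the comparator itself.

The `examples/` directory walks each capability: cohort simulation,
feature engineering, labelling, training/evaluation, and explanation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pinned acceptance targets — the four ordinal
ventilatory-support levels assigned by the feature-engineering rule — by
constructing each resolved ventilation state and applying the scoring
function, and also smoke-runs the synthetic pipeline end to end under the
given seed. Output is a JSON object keyed by target id.

## Layout

| module | responsibility |
| --- | --- |
| `pedews.synthetic` | synthetic PICU cohort with injected ground-truth deteriorations |
| `pedews.references` | centile tables, LMS growth z-scores, MAP thresholds (editable CSVs) |
| `pedews.features` | alias consolidation, ventilation ordinal, VIS, weight normalisation |
| `pedews.grid` | minute grid, interpolation, carry-forward, imputation, rank scaling |
| `pedews.windows` | anchors, window summary statistics, ablations, resampling |
| `pedews.outcomes` | cardiovascular sub-score, composite label, full organ-dysfunction vector |
| `pedews.models` | patient-level splits, adaptive tuning, comparators, prediction |
| `pedews.evaluation` | AUPRC/AUROC, fixed-recall operating point, repeat aggregation |
| `pedews.explain` | gain importance, additive attributions, patient timelines |
| `pedews.config` / `pedews.pipeline` | one declarative config; staged orchestration |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
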
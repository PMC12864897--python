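# slhs — Sepsis Learning Health System analytics

`slhs` implements the analytics core of a hospital *sepsis learning health
system*: it phenotypes hospital stays for sepsis from EHR time series and
turns the predictions into before/after quality-of-care indicators. It is
aimed at clinical data scientists who want a tested, desk-scale,
end-to-end implementation of this class of pipeline — registry in,
calibrated per-stay sepsis classification and impact report out — running
entirely on generated data (real sepsis registries are rarely shareable).

## What it computes

**Labels.** Expert-review events carry six fine labels grounded in the
Sepsis-3 consensus — no infection; infection without sepsis
(delta-SOFA < 2); sepsis-like (criterion unassessable); sepsis *sensu
lato* (delta-SOFA ≥ 2 with an alternative etiology); sepsis *sensu
stricto* (infection + organ failure + delta-SOFA ≥ 2); septic shock
(+ vasopressor and lactate > 2 mmol/L) — and collapse to the three-class
target NS/PS/CS (no / possible / confirmed sepsis). Here
delta-SOFA = max post-onset SOFA − pre-onset baseline SOFA.

**Classifier.** Each stay is cut into 6-hour windows. A random forest on
~240 rolling 7-day aggregate features and a (numpy) LSTM on 28-step
sequence tensors each emit per-window probability triples
(p_NS, p_PS, p_CS); a second-stage forest stacks the six probabilities
into the final triple. The stay-level score is the maximum windowed
confirmed-sepsis probability,

    p_stay = max_k p_CS(window k),

and the decision threshold τ is calibrated on the training set as the
largest value with CS recall ≥ 0.7. Retrained models deploy only when they
strictly beat the incumbent on the selection metric (champion–challenger).

**Impact.** Per cohort (stays *limited to* program wards, stays
*including* program wards, control wards) and year: sepsis ICD-coding
rates, flagged-stay rates, and mortality among flagged stays; adjusted
per-year odds ratios from logistic regressions on year, sex, age and
Charlson index; and a propensity-matched chi-squared comparison of
time-to-antibiotics (≤ 1 h / ≤ 3 h from onset) between pathway and
non-pathway stays.

The synthetic registry generator is first-class, tested code: it emits
multi-ward stays over a 2020–2024 calendar with realistic sampling density,
injects sepsis episodes whose physiology provably satisfies the injected
label's definition, under-codes sepsis in ICD (sensitivity 0.833), and
draws outcomes from a logistic model with a configurable per-year effect.

## Worked example

```sh
slhs generate --seed 8 --out registry/          # 2000-stay synthetic registry
slhs train    --registry registry --seed 8 --out model/
slhs evaluate --registry registry --model model/
slhs impact   --registry registry --model model/ --out report/
```

Or from Python:

```python
from slhs import GeneratorConfig, RunConfig, generate_registry, fit_heracles

registry = generate_registry(GeneratorConfig(seed=42, n_stays=2000))
bundle, stay_pred = fit_heracles(registry, RunConfig(seed=43))
print(round(bundle.threshold, 4), int(stay_pred["flag"].sum()))
```

prints

```
0.9733 78
```

i.e. the calibrated threshold landed at a CS probability of 0.9733 and 78
of the 2000 training stays are flagged. With that threshold the
training-set recall for confirmed sepsis is 0.83 (the calibration
guarantees ≥ 0.7; this registry holds 94 confirmed-sepsis stays) and the
flag's precision is 1.0 — the injected episodes are deliberately clean, so
do not read these as real-world performance. `slhs evaluate` prints the
full per-class
precision/recall/F1 table, the 3×3 confusion matrix and the two AUROC
contrasts (CS vs NS, CS∪PS vs NS); `slhs impact` writes `report.json` /
`report.txt` with the indicator table and odds-ratio list.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default 2000-stay registry, trains the full stack
(out-of-fold stacking over 5 patient-grouped folds), calibrates the
threshold at the 0.7 recall floor, and writes the realized training-set
confirmed-sepsis recall as target `t1`.

## Layout

- `slhs.registry_io` — registry tables, validation, CSV round trip, reports
- `slhs.synthetic_registry` — the generator
- `slhs.clinical_scores` — SOFA, delta-SOFA, NEWS2, Charlson
- `slhs.sepsis_labeling` — six-way label logic, window labeling
- `slhs.feature_engineering` — 6-h grid, rolling features, sequence tensors
- `slhs.heracles_model` — sub-models, stacking, calibration, governance
- `slhs.evaluation` — metrics, AUROC, Cohen's kappa
- `slhs.impact_analysis` — cohorts, indicators, ORs, time-to-antibiotics

See `docs/methods.md` for the modelling assumptions and design decisions.
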
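# Methods

`slhs` re-creates, on fully synthetic data, the analytics of a hospital
sepsis learning health system: a registry of ward stays with vital-sign and
laboratory time series, clinician-adjudicated suspected-sepsis events, a
window-level sepsis classifier with a recall-floor decision threshold, and
the before/after quality-of-care analyses built on its output. This note
records the model and the design choices made where the design was open.

## Label semantics

Every adjudicated event carries one of six fine labels aligned with the
Sepsis-3 consensus:

| fine label | condition |
|---|---|
| `0_no_infection` | no infection |
| `0_infection` | infection, no attributed organ failure, delta-SOFA < 2 |
| `1a_sepsis_like` | infection with organ-dysfunction signal but the SOFA criterion unmet or unassessable (delta < 2 with clinical organ failure, missing SOFA data, or an unattributed SOFA rise) |
| `1b_sepsis_sensu_lato` | infection, delta-SOFA ≥ 2, alternative etiology for the dysfunction |
| `2a_sepsis_sensu_stricto` | infection + attributed organ failure + delta-SOFA ≥ 2, no alternative etiology |
| `2b_septic_shock` | sensu stricto + vasopressor + lactate > 2.0 mmol/L |

Fine labels collapse to NS / PS / CS (no / possible / confirmed sepsis).
Two combinations required a decision:

* *delta-SOFA ≥ 2 without clinician-attributed organ failure and without an
  alternative etiology* is not covered verbatim by any row; it is classified
  `1a` (possible sepsis) because the attribution, not the score, is what
  separates confirmed from possible sepsis.
* *organ failure recorded with no infection* is rejected as inconsistent
  input rather than silently mapped.

`classify_event` is verified against an exhaustive, independently written
truth-table oracle over all 320 fact combinations.

## Clinical scores

SOFA uses the canonical Sepsis-3 organ tables (six organs, 0–4 each).
Numerical conventions: the respiratory 3/4 bands are assigned by
PaO2/FiO2 ratio alone (ventilatory support is not tracked at ward
granularity); vasopressor exposure is a dose *class* — the registry stores
drug class and administration time, not infusion rates — and any
vasopressor within the previous 24 h maps to the class scoring 2. A missing
organ scores 0 and is flagged imputed.

delta-SOFA = max post-onset SOFA (assessments every 6 h over 72 h, clipped
at discharge) minus the baseline SOFA from the 24 h before onset (zero
baseline when no prior data, the Sepsis-3 convention). The result is an
explicit *missing* marker — feeding the `1a` "missing SOFA information"
pathway — when there is no post-onset observation at all or when every
assessment has three or more absent organs.

NEWS2 uses the canonical seven-component bands (SpO2 scale 1; the
hypercapnic scale 2 is out of scope). Band edges are continuous so
fractional vitals score identically to the printed integer tables.

The Charlson index uses the original weights with the Quan (2005) ICD-10
coding algorithm, shipped as an editable in-package mapping, with the
standard hierarchical exclusions (metastatic > any malignancy, severe >
mild liver disease, complicated > uncomplicated diabetes).

## Windowing and features

Stays are cut into half-open 6-hour windows anchored at admission. A window
is labeled with the collapsed most-severe label among events whose onset
falls inside the trailing 7-day span ending at the window's close; windows
overlapping no onset are NS. Whether a window covering only the *aftermath*
of an onset (onset before the span) should be positive was an open point;
the implemented rule requires the onset inside the span.

The tree sub-model sees, per concept, six aggregators (last, min, max,
mean, count, slope of the least-squares fit on window index) over the
trailing 28 windows, for 40 physiology concepts plus 2 medication-count
channels (252 features), plus age and sex — 254 in total, emulating the
~240-feature scale of the original design; the exact upstream feature list
is unpublished, so the set is a declarative registry (concept × aggregator)
in the run configuration. The sequence sub-model sees 28-step right-aligned
tensors over 12 core concepts with per-channel observed masks (24
channels); values are forward-filled within the stay up to 48 h, then
filled with population medians, and imputed entries keep mask 0.
Pre-admission steps are zero-padded with mask 0.

## Classifier and calibration

Two sub-models — a random forest (150 trees, balanced class weights) and a
single-layer LSTM (hidden 16, ≤ 8 epochs, Adam, class-weighted
cross-entropy, best-epoch selection) — each emit NS/PS/CS probability
triples per window. A second-stage random forest consumes exactly the six
sub-model probabilities. The stacker is fitted on *out-of-fold* sub-model
probabilities from patient-grouped 5-fold splits; training it on in-fold
probabilities would let the meta-learner exploit sub-model overfit.
PyTorch is not available in the target environment, so the LSTM is a
compact numpy implementation (forward, BPTT, Adam) rather than a framework
model; hyperparameters are configuration-exposed. NS windows dominate
(~95%), so sub-models are fitted on all PS/CS windows plus a 3:1 random
subsample of NS windows; prediction always covers every window.

Stay-level aggregation takes the maximum CS probability across the stay's
windows; the stay's 3-class label is the argmax class of the peak window,
ties resolved toward higher severity. The decision threshold τ is the
largest cut-off whose training-set CS recall is at or above the configured
floor (0.7), i.e. the ⌈floor · n_CS⌉-th largest CS-stay probability;
calibration uses the final model's training-set predictions. Retrained
models deploy only on strict improvement of the selection metric (default:
CS F1 from patient-grouped cross-validation); ties keep the champion, so
the deployed metric sequence is non-decreasing by construction.

## Synthetic registry

The generator emulates the cohort the pipeline assumes: configurable stay
count (default 2000) over a 2020–2024 calendar, log-normal length of stay
(median 5 days, capped at 21), ward trajectories split between
program-ward-only (50%), mixed (30%) and control-only (20%) stays,
demographics centred on age 66 and 53% male. Physiology is simulated per
concept as noise around an individual set-point at ward sampling density
(vitals ~4 h, GCS ~8 h, labs one panel per day plus an admission panel) —
producing realistic missingness for the imputation path. Sepsis events hit
10% of stays (fine-label mix follows the documented event pool: 22%
invalidated, 32.7% possible, 45.2% confirmed; within-class splits are not
published and were fixed once at 50/50, 70/30, 70/30). Onset times are
truncated-exponential from admission (mean 48 h), matching the reported
concentration of flagged cases in the first days of a stay; episodes are
step perturbations with exponential recovery over 72 h.

Label consistency is guaranteed *constructively*: event-bearing stays have
their SOFA-input and lactate series clamped into score-zero bands at
baseline, and episode perturbations are clipped into the abnormal bands the
injected label requires (coagulation + renal dysfunction for delta-SOFA
≥ 2; vasopressor and lactate > 2 mmol/L for septic shock; a sepsis work-up
panel at onset + 4 h guarantees assessable post-onset data). The label
round trip — re-deriving the facts from the generated data and
re-classifying — therefore holds for every event, not just in expectation.
The cost of this guarantee is that the confirmed-sepsis signal is stronger
and cleaner than real EHR data: a green end-to-end test establishes that
the pipeline's mechanics (windowing, stacking, calibration, aggregation)
are correct, *not* that real-world discrimination would reach the same
level.

ICD coding is under-sensitive by design: confirmed-sepsis stays are coded
with probability 0.833, possible-sepsis stays 0.355, others 0. Mortality is
drawn from a logistic model on sepsis status, age, admission-year index and
antibiotic timeliness; the default per-year coefficient is ln(0.85), and
in-hospital death implies 90-day death. First antibiotic delays are
exponential with mean 0.5 h for pathway (order-set) events and 4 h for
consult-identified events.

## Impact analyses

Cohorts: *limited to* program wards (all segments), *including* program
wards (any segment; a superset of limited), control (control wards only);
stays matching none are reported as `other`. Indicator rates with empty
denominators are NaN, never 0. Adjusted odds ratios come from
maximum-likelihood logistic fits with year (continuous, so one OR per
panel), sex, age and Charlson; Wald 95% intervals; non-convergence and
separation are flagged in the result. A categorical-year variant can be
obtained by passing dummy columns as covariates. Time-to-antibiotics uses
1:1 nearest-neighbour propensity matching (age, sex, Charlson) on the logit
score with a 0.2 SD caliper, without replacement in seeded order, followed
by a chi-squared test of the 1 h (and 3 h) dichotomy; antibiotics at or
before onset count as timely. 90-day mortality is measured from admission.

## Known limitations

* The generator's episodes are univariately clean; it does not emulate
  inter-correlated organ failure, treatment feedback, or coding drift over
  calendar time.
* The LSTM is deliberately small; it is not a tuned re-creation of the
  original network, only an architecture-faithful stand-in.
* Real-data performance figures from the source setting are not
  reproducible on synthetic data and are not targets of the test suite.
* The ICD-10 sepsis code list is a documented stand-in (prefixes A40, A41,
  R65.2, R57.2) and should be overridden with the site list in practice.
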
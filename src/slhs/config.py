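"""Run-time and generator configuration.

Two dataclasses hold every tunable of the pipeline:

* :class:`RunConfig` — the analysis constants (6-hour window, 7-day lookback,
  recall floor 0.7, 5-fold cross-validation, the feature registry and the
  ICD-10 sepsis code prefixes).
* :class:`GeneratorConfig` — the statistical world the synthetic registry
  emulates (cohort size, calendar span, sepsis prevalence and label mix,
  physiology baselines, coding sensitivity, outcome model coefficients).

Both round-trip through YAML so a whole run is reproducible from a single
declarative file plus a seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

#: Aggregators applied per concept over the trailing lookback span.
DEFAULT_AGGREGATORS: tuple[str, ...] = ("last", "min", "max", "mean", "count", "slope")

#: Vital-sign concepts, sampled every few hours on the ward.
VITAL_CONCEPTS: tuple[str, ...] = (
    "heart_rate",
    "resp_rate",
    "sbp",
    "map",
    "temp",
    "spo2",
    "gcs",
    "on_oxygen",
)

#: Laboratory concepts, typically drawn once a day outside the ICU.
LAB_CONCEPTS: tuple[str, ...] = (
    "platelets",
    "bilirubin",
    "creatinine",
    "lactate",
    "pao2_fio2",
    "sodium",
    "potassium",
    "chloride",
    "bicarbonate",
    "urea",
    "glucose",
    "calcium",
    "magnesium",
    "phosphate",
    "albumin",
    "crp",
    "procalcitonin",
    "wbc",
    "hemoglobin",
    "hematocrit",
    "neutrophils",
    "lymphocytes",
    "monocytes",
    "inr",
    "aptt",
    "alt",
    "ast",
    "alp",
    "ggt",
    "ldh",
    "ck",
    "troponin",
)

#: Medication channels carried on the window grid (per-window counts).
MED_CONCEPTS: tuple[str, ...] = ("antibiotic", "vasopressor")

#: Concepts fed to the sequence (LSTM) sub-model: the clinical core set.
DEFAULT_SEQUENCE_CONCEPTS: tuple[str, ...] = (
    "heart_rate",
    "resp_rate",
    "sbp",
    "map",
    "temp",
    "spo2",
    "gcs",
    "platelets",
    "bilirubin",
    "creatinine",
    "lactate",
    "pao2_fio2",
)

#: Stand-in for the sepsis ICD-10 code list (sepsis, septicaemia, septic shock).
DEFAULT_ICD_SEPSIS_PREFIXES: tuple[str, ...] = ("A40", "A41", "R65.2", "R57.2")

#: Ward groups where the sepsis program runs.
SLHS_WARD_GROUPS: tuple[str, ...] = ("MED", "GIS", "EMD")
CONTROL_WARD_GROUPS: tuple[str, ...] = ("CONTROL",)


def default_feature_registry() -> list[tuple[str, tuple[str, ...]]]:
    """Concept × aggregator registry for the tree sub-model.

    40 physiology concepts plus 2 medication channels, each with 6
    aggregators: 252 windowed features, plus age and sex appended downstream.
    """
    concepts = VITAL_CONCEPTS + LAB_CONCEPTS + MED_CONCEPTS
    return [(c, DEFAULT_AGGREGATORS) for c in concepts]


@dataclass
class RunConfig:
    """Constants of the analysis pipeline."""

    seed: int = 0
    window_hours: int = 6
    lookback_days: int = 7
    recall_floor: float = 0.7
    cv_folds: int = 5
    feature_registry: list = field(default_factory=default_feature_registry)
    sequence_concepts: tuple[str, ...] = DEFAULT_SEQUENCE_CONCEPTS
    slhs_ward_groups: tuple[str, ...] = SLHS_WARD_GROUPS
    control_ward_groups: tuple[str, ...] = CONTROL_WARD_GROUPS
    icd_sepsis_codes: tuple[str, ...] = DEFAULT_ICD_SEPSIS_PREFIXES
    # sub-model hyperparameters (unpublished upstream; desk-scale defaults)
    rf_n_estimators: int = 150
    rf_max_depth: int | None = None
    lstm_hidden: int = 16
    lstm_epochs: int = 8
    lstm_batch: int = 256
    lstm_lr: float = 0.01
    # negative windows kept per positive window when fitting sub-models
    negative_subsample_ratio: float = 3.0
    # ward_group restriction for department-specific model variants (None = all)
    train_ward_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if 24 % self.window_hours != 0:
            raise ValueError(f"window_hours={self.window_hours} must divide 24")
        if self.lookback_days < 1:
            raise ValueError("lookback_days must be >= 1")
        if not (0.0 < self.recall_floor <= 1.0):
            raise ValueError("recall_floor must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def windows_per_day(self) -> int:
        return 24 // self.window_hours

    @property
    def lookback_windows(self) -> int:
        """Steps in the lookback span (28 for 7 days at 6 h)."""
        return self.lookback_days * self.windows_per_day


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class MortalityModel:
    """Logistic outcome model the generator draws deaths from.

    Linear predictor: intercept + cs*CS + ps*PS + age*(age-65)
    + year*(admission year - calendar start) + timely*(antibiotics <= 1 h).
    ``intercept_90d`` governs the extra post-discharge death process.
    """

    intercept: float = _logit(0.013)
    beta_sepsis_cs: float = 2.9
    beta_sepsis_ps: float = 1.2
    beta_age: float = 0.02
    beta_year: float = math.log(0.85)
    beta_timely: float = -0.3
    intercept_90d: float = _logit(0.05)


@dataclass
class GeneratorConfig:
    """The stated world the synthetic registry emulates."""

    seed: int = 0
    n_stays: int = 2000
    calendar_start_year: int = 2020
    calendar_years: int = 5
    # stay structure
    stays_per_patient_geom_p: float = 0.8
    los_log_mean_days: float = math.log(5.0)
    los_log_sd: float = 0.6
    los_min_days: float = 1.0
    los_max_days: float = 21.0
    # ward mix: fractions of stays limited-to-SLHS / mixed / control-only
    frac_limited_slhs: float = 0.5
    frac_mixed: float = 0.3
    emd_first_fraction: float = 0.5
    # demographics
    age_mean: float = 66.0
    age_sd: float = 16.0
    male_fraction: float = 0.53
    # sepsis events
    sepsis_prevalence: float = 0.10
    label_mix: dict = field(
        default_factory=lambda: {
            # coarse mix from the documented event pool: 22.0% invalidated,
            # 32.7% possible, 45.2% confirmed; within-class splits chosen once
            "0_no_infection": 0.110,
            "0_infection": 0.110,
            "1a_sepsis_like": 0.229,
            "1b_sepsis_sensu_lato": 0.098,
            "2a_sepsis_sensu_stricto": 0.316,
            "2b_septic_shock": 0.137,
        }
    )
    episode_recovery_hours: float = 72.0
    # ICD coding
    icd_sensitivity: float = 0.833
    ps_code_rate: float = 0.355
    ns_code_rate: float = 0.0
    comorbidity_rate: float = 1.2  # mean Charlson-relevant codes per stay
    # outcomes
    mortality: MortalityModel = field(default_factory=MortalityModel)
    # time-to-antibiotics delay (hours), exponential means
    tta_mean_pathway_h: float = 0.5
    tta_mean_control_h: float = 4.0

    def __post_init__(self) -> None:
        for name in ("sepsis_prevalence", "icd_sensitivity", "ps_code_rate",
                     "ns_code_rate", "frac_limited_slhs", "frac_mixed",
                     "emd_first_fraction", "male_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.calendar_years < 1:
            raise ValueError("calendar span must be >= 1 year")
        if self.n_stays < 1:
            raise ValueError("n_stays must be positive")
        if abs(sum(self.label_mix.values()) - 1.0) > 1e-6:
            raise ValueError("label_mix must sum to 1")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg, path) -> None:
    """Serialize a RunConfig or GeneratorConfig to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "feature_registry" in raw:
        raw["feature_registry"] = [
            (c, tuple(aggs)) for c, aggs in raw["feature_registry"]
        ]
    for key in ("sequence_concepts", "slhs_ward_groups", "control_ward_groups",
                "icd_sepsis_codes", "train_ward_groups"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def load_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "mortality" in raw and isinstance(raw["mortality"], dict):
        raw["mortality"] = MortalityModel(**raw["mortality"])
    return GeneratorConfig(**raw)
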
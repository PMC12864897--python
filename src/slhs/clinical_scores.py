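"""Clinical severity and comorbidity scores.

Implements the three scores the registry is enriched with and the label
logic depends on:

* SOFA (Sequential Organ Failure Assessment, Sepsis-3): six organ subscores
  0–4 (respiration, coagulation, liver, cardiovascular, CNS, renal),
  total 0–24.
* delta-SOFA: maximum SOFA in the post-onset assessment window minus the
  pre-onset baseline; an acute rise of >= 2 points is the Sepsis-3
  organ-dysfunction criterion.
* NEWS2 (National Early Warning Score 2): seven vital-sign bands, total 0–20.
* Charlson comorbidity index: original Charlson weights over ICD-10 code
  categories (Quan 2005 coding algorithm), with the standard hierarchical
  exclusions.

Missing data convention: an absent organ/vital scores 0 and is flagged as
imputed; delta-SOFA reports an explicit missing marker (never a silent 0)
when no post-onset assessment with enough organs can be made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreSnapshot",
    "SofaResult",
    "News2Result",
    "DeltaSofaResult",
    "sofa_total",
    "delta_sofa",
    "news2_score",
    "charlson_index",
    "CHARLSON_CATEGORIES",
    "snapshot_at",
]

VASOPRESSOR_CLASSES = ("none", "low", "mid", "high")


@dataclass
class ScoreSnapshot:
    """Latest per-concept values at a reference time; ``None`` = missing."""

    # SOFA inputs
    pao2_fio2: float | None = None      # mmHg
    platelets: float | None = None      # 10^9/L
    bilirubin: float | None = None      # umol/L
    map: float | None = None            # mmHg
    vasopressor_dose_class: str = "none"
    gcs: float | None = None            # 3..15
    creatinine: float | None = None     # umol/L
    urine_output_24h: float | None = None  # mL
    # NEWS2 vitals
    resp_rate: float | None = None      # /min
    spo2: float | None = None           # %
    on_oxygen: bool | None = None
    temp: float | None = None           # Celsius
    sbp: float | None = None            # mmHg
    heart_rate: float | None = None     # /min
    altered_consciousness: bool | None = None

    def __post_init__(self) -> None:
        if self.vasopressor_dose_class not in VASOPRESSOR_CLASSES:
            raise ValueError(
                f"vasopressor_dose_class must be one of {VASOPRESSOR_CLASSES}"
            )
        checks = [
            ("gcs", self.gcs, 3, 15),
            ("spo2", self.spo2, 1e-9, 100.0),
            ("pao2_fio2", self.pao2_fio2, 0.0, 1500.0),
            ("platelets", self.platelets, 0.0, 5000.0),
            ("bilirubin", self.bilirubin, 0.0, 2000.0),
            ("map", self.map, 0.0, 300.0),
            ("creatinine", self.creatinine, 0.0, 5000.0),
            ("resp_rate", self.resp_rate, 0.0, 120.0),
            ("temp", self.temp, 20.0, 45.0),
            ("sbp", self.sbp, 0.0, 400.0),
            ("heart_rate", self.heart_rate, 0.0, 400.0),
        ]
        for name, val, lo, hi in checks:
            if val is not None and not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside physiologic range [{lo}, {hi}]")


@dataclass
class SofaResult:
    total: int
    subscores: dict[str, int]
    imputed: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_imputed(self) -> int:
        return len(self.imputed)


@dataclass
class News2Result:
    total: int
    subscores: dict[str, int]
    imputed: frozenset[str] = field(default_factory=frozenset)


@dataclass
class DeltaSofaResult:
    """delta-SOFA with an explicit missing marker."""

    value: int | None
    missing: bool
    baseline: int | None = None
    post_max: int | None = None


def _sofa_respiration(pf: float) -> int:
    # ventilatory-support requirement for bands 3/4 is not tracked at ward
    # granularity; ratio alone decides (documented simplification)
    if pf < 100:
        return 4
    if pf < 200:
        return 3
    if pf < 300:
        return 2
    if pf < 400:
        return 1
    return 0


def _sofa_coagulation(plt: float) -> int:
    if plt < 20:
        return 4
    if plt < 50:
        return 3
    if plt < 100:
        return 2
    if plt < 150:
        return 1
    return 0


def _sofa_liver(bili: float) -> int:
    if bili > 204:
        return 4
    if bili >= 102:
        return 3
    if bili >= 33:
        return 2
    if bili >= 20:
        return 1
    return 0


def _sofa_cardio(map_: float | None, vaso: str) -> int:
    if vaso == "high":
        return 4
    if vaso == "mid":
        return 3
    if vaso == "low":
        return 2
    if map_ is not None and map_ < 70:
        return 1
    return 0


def _sofa_cns(gcs: float) -> int:
    if gcs < 6:
        return 4
    if gcs <= 9:
        return 3
    if gcs <= 12:
        return 2
    if gcs <= 14:
        return 1
    return 0


def _sofa_renal(creat: float | None, urine: float | None) -> int:
    by_creat = 0
    if creat is not None:
        if creat > 440:
            by_creat = 4
        elif creat >= 300:
            by_creat = 3
        elif creat >= 171:
            by_creat = 2
        elif creat >= 110:
            by_creat = 1
    by_urine = 0
    if urine is not None:
        if urine < 200:
            by_urine = 4
        elif urine < 500:
            by_urine = 3
    return max(by_creat, by_urine)


def sofa_total(snapshot: ScoreSnapshot) -> SofaResult:
    """Six organ subscores and their sum; missing organs score 0, flagged."""
    subs: dict[str, int] = {}
    imputed: set[str] = set()

    def organ(name, absent, score):
        if absent:
            subs[name] = 0
            imputed.add(name)
        else:
            subs[name] = score()

    organ("respiration", snapshot.pao2_fio2 is None,
          lambda: _sofa_respiration(snapshot.pao2_fio2))
    organ("coagulation", snapshot.platelets is None,
          lambda: _sofa_coagulation(snapshot.platelets))
    organ("liver", snapshot.bilirubin is None,
          lambda: _sofa_liver(snapshot.bilirubin))
    organ("cardiovascular",
          snapshot.map is None and snapshot.vasopressor_dose_class == "none",
          lambda: _sofa_cardio(snapshot.map, snapshot.vasopressor_dose_class))
    organ("cns", snapshot.gcs is None, lambda: _sofa_cns(snapshot.gcs))
    organ("renal",
          snapshot.creatinine is None and snapshot.urine_output_24h is None,
          lambda: _sofa_renal(snapshot.creatinine, snapshot.urine_output_24h))

    return SofaResult(total=sum(subs.values()), subscores=subs,
                      imputed=frozenset(imputed))


# NEWS2 banding (scale 1 SpO2 scoring; hypercapnic scale 2 out of scope).
# Bands are the canonical integer tables made continuous with upper-edge
# thresholds so fractional vitals (temp 38.05 degC) still score.
def news2_score(snapshot: ScoreSnapshot) -> News2Result:
    """Seven canonical NEWS2 sub-scores; missing vitals score 0, flagged."""
    subs: dict[str, int] = {}
    imputed: set[str] = set()

    def band(name, value, edges, default_pts):
        # edges: [(upper_bound_inclusive, points), ...] in ascending order
        if value is None:
            subs[name] = 0
            imputed.add(name)
            return
        for hi, pts in edges:
            if value <= hi:
                subs[name] = pts
                return
        subs[name] = default_pts

    band("resp_rate", snapshot.resp_rate,
         [(8, 3), (11, 1), (20, 0), (24, 2)], 3)
    band("spo2", snapshot.spo2, [(91, 3), (93, 2), (95, 1)], 0)
    if snapshot.on_oxygen is None:
        subs["oxygen"] = 0
        imputed.add("oxygen")
    else:
        subs["oxygen"] = 2 if snapshot.on_oxygen else 0
    band("temp", snapshot.temp, [(35.0, 3), (36.0, 1), (38.0, 0), (39.0, 1)], 2)
    band("sbp", snapshot.sbp, [(90, 3), (100, 2), (110, 1), (219, 0)], 3)
    band("heart_rate", snapshot.heart_rate,
         [(40, 3), (50, 1), (90, 0), (110, 1), (130, 2)], 3)
    if snapshot.altered_consciousness is None:
        subs["consciousness"] = 0
        imputed.add("consciousness")
    else:
        subs["consciousness"] = 3 if snapshot.altered_consciousness else 0

    return News2Result(total=sum(subs.values()), subscores=subs,
                       imputed=frozenset(imputed))


# ---------------------------------------------------------------------------
# snapshots from an observation series


_SOFA_CONCEPTS = ("pao2_fio2", "platelets", "bilirubin", "map", "gcs", "creatinine")


def snapshot_at(
    observations: pd.DataFrame,
    t: pd.Timestamp,
    *,
    medications: pd.DataFrame | None = None,
    staleness_hours: float = 48.0,
    vasopressor_window_hours: float = 24.0,
) -> ScoreSnapshot:
    """Latest value of each score concept at-or-before ``t``.

    A value older than ``staleness_hours`` is treated as missing. A
    vasopressor administration within ``vasopressor_window_hours`` before
    ``t`` maps to dose class ``low`` (the registry stores drug class, not
    dose rates).
    """
    lo = t - pd.Timedelta(hours=staleness_hours)
    recent = observations.loc[
        (observations["ts"] <= t) & (observations["ts"] > lo)
    ]
    latest = (
        recent.sort_values("ts").groupby("concept_id")["value"].last()
        if len(recent)
        else pd.Series(dtype=float)
    )

    def get(concept):
        v = latest.get(concept)
        return None if v is None or pd.isna(v) else float(v)

    vaso = "none"
    if medications is not None and len(medications):
        m = medications.loc[
            (medications["drug_class"] == "vasopressor")
            & (medications["admin_ts"] <= t)
            & (medications["admin_ts"] > t - pd.Timedelta(hours=vasopressor_window_hours))
        ]
        if len(m):
            vaso = "low"

    gcs = get("gcs")
    return ScoreSnapshot(
        pao2_fio2=get("pao2_fio2"),
        platelets=get("platelets"),
        bilirubin=get("bilirubin"),
        map=get("map"),
        vasopressor_dose_class=vaso,
        gcs=None if gcs is None else float(np.clip(round(gcs), 3, 15)),
        creatinine=get("creatinine"),
        resp_rate=get("resp_rate"),
        spo2=None if get("spo2") is None else min(get("spo2"), 100.0),
        on_oxygen=None if get("on_oxygen") is None else bool(get("on_oxygen") > 0.5),
        temp=get("temp"),
        sbp=get("sbp"),
        heart_rate=get("heart_rate"),
        altered_consciousness=None if gcs is None else gcs < 15,
    )


def delta_sofa(
    observations: pd.DataFrame,
    t0: pd.Timestamp,
    *,
    medications: pd.DataFrame | None = None,
    stay_interval: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    baseline_policy: str = "pre24h_or_zero",
    post_hours: float = 72.0,
    assessment_step_hours: float = 6.0,
    max_imputed_organs: int = 2,
) -> DeltaSofaResult:
    """Post-onset maximum SOFA minus baseline SOFA.

    Baseline: SOFA from the 24 h preceding ``t0`` (zero if no prior data,
    per ``baseline_policy='pre24h_or_zero'``). Post: max SOFA over
    assessments every ``assessment_step_hours`` in ``(t0, t0+post_hours]``
    (clipped at discharge). Assessments with more than ``max_imputed_organs``
    absent organs do not count; if none counts — or there is no post-onset
    observation at all — the result is an explicit missing marker.
    """
    if baseline_policy != "pre24h_or_zero":
        raise ValueError(f"unknown baseline_policy {baseline_policy!r}")
    if stay_interval is not None:
        admit, discharge = stay_interval
        if not (admit <= t0 < discharge):
            raise ValueError(f"t0={t0} outside stay interval [{admit}, {discharge})")
        end = min(t0 + pd.Timedelta(hours=post_hours), discharge)
    else:
        end = t0 + pd.Timedelta(hours=post_hours)

    pre = observations.loc[observations["ts"] < t0]
    if len(pre):
        base = sofa_total(snapshot_at(pre, t0, medications=medications,
                                      staleness_hours=24.0))
        baseline = base.total
    else:
        baseline = 0  # zero-baseline convention for unknown pre-onset state

    post_obs = observations.loc[(observations["ts"] > t0) & (observations["ts"] <= end)]
    if not len(post_obs):
        return DeltaSofaResult(value=None, missing=True, baseline=baseline)

    n_steps = int(np.floor((end - t0).total_seconds() / 3600.0 / assessment_step_hours))
    times = [t0 + pd.Timedelta(hours=assessment_step_hours * (i + 1))
             for i in range(max(n_steps, 1))]
    times = [min(t, end) for t in times]

    post_max: int | None = None
    for t in times:
        res = sofa_total(snapshot_at(observations, t, medications=medications))
        if res.n_imputed > max_imputed_organs:
            continue
        post_max = res.total if post_max is None else max(post_max, res.total)
    if post_max is None:
        return DeltaSofaResult(value=None, missing=True, baseline=baseline)

    return DeltaSofaResult(
        value=max(post_max - baseline, 0),
        missing=False,
        baseline=baseline,
        post_max=post_max,
    )


# ---------------------------------------------------------------------------
# Charlson comorbidity index

# original Charlson weights; ICD-10 prefixes follow the Quan 2005 coding
# algorithm (dots stripped). Editable: pass a custom mapping to
# charlson_index for site-specific coding practice.
CHARLSON_CATEGORIES: dict[str, tuple[int, tuple[str, ...]]] = {
    "myocardial_infarction": (1, ("I21", "I22", "I252")),
    "congestive_heart_failure": (
        1, ("I099", "I110", "I130", "I132", "I255", "I420", "I425", "I426",
            "I427", "I428", "I429", "I43", "I50", "P290")),
    "peripheral_vascular_disease": (
        1, ("I70", "I71", "I731", "I738", "I739", "I771", "I790", "I792",
            "K551", "K558", "K559", "Z958", "Z959")),
    "cerebrovascular_disease": (
        1, ("G45", "G46", "H340", "I60", "I61", "I62", "I63", "I64", "I65",
            "I66", "I67", "I68", "I69")),
    "dementia": (1, ("F00", "F01", "F02", "F03", "F051", "G30", "G311")),
    "chronic_pulmonary_disease": (
        1, ("I278", "I279", "J40", "J41", "J42", "J43", "J44", "J45", "J46",
            "J47", "J60", "J61", "J62", "J63", "J64", "J65", "J66", "J67",
            "J684", "J701", "J703")),
    "rheumatic_disease": (
        1, ("M05", "M06", "M315", "M32", "M33", "M34", "M351", "M353", "M360")),
    "peptic_ulcer_disease": (1, ("K25", "K26", "K27", "K28")),
    "mild_liver_disease": (
        1, ("B18", "K700", "K701", "K702", "K703", "K709", "K713", "K714",
            "K715", "K717", "K73", "K74", "K760", "K762", "K763", "K764",
            "K768", "K769", "Z944")),
    "diabetes_without_complications": (
        1, ("E100", "E101", "E106", "E108", "E109", "E110", "E111", "E116",
            "E118", "E119", "E130", "E131", "E136", "E138", "E139", "E140",
            "E141", "E146", "E148", "E149")),
    "diabetes_with_complications": (
        2, ("E102", "E103", "E104", "E105", "E107", "E112", "E113", "E114",
            "E115", "E117", "E132", "E133", "E134", "E135", "E137", "E142",
            "E143", "E144", "E145", "E147")),
    "hemiplegia_paraplegia": (
        2, ("G041", "G114", "G801", "G802", "G81", "G82", "G830", "G831",
            "G832", "G833", "G834", "G839")),
    "renal_disease": (
        2, ("I120", "I131", "N032", "N033", "N034", "N035", "N036", "N037",
            "N052", "N053", "N054", "N055", "N056", "N057", "N18", "N19",
            "N250", "Z490", "Z491", "Z492", "Z940", "Z992")),
    "any_malignancy": (
        2, tuple(f"C{i:02d}" for i in list(range(0, 27)) + list(range(30, 35))
                 + list(range(37, 42)) + [43] + list(range(45, 59))
                 + list(range(60, 77)) + list(range(81, 86)) + [88]
                 + list(range(90, 98)))),
    "moderate_severe_liver_disease": (
        3, ("I850", "I859", "I864", "I982", "K704", "K711", "K721", "K729",
            "K765", "K766", "K767")),
    "metastatic_solid_tumor": (6, ("C77", "C78", "C79", "C80")),
    "aids_hiv": (6, ("B20", "B21", "B22", "B24")),
}

# severer category silences the milder one
_CHARLSON_HIERARCHY = {
    "diabetes_with_complications": "diabetes_without_complications",
    "moderate_severe_liver_disease": "mild_liver_disease",
    "metastatic_solid_tumor": "any_malignancy",
}


def _normalize_code(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def charlson_index(
    icd_codes,
    mapping: dict[str, tuple[int, tuple[str, ...]]] | None = None,
) -> int:
    """Sum of Charlson weights over distinct present categories.

    Unknown codes are ignored. Duplicated codes and code order do not
    matter. Hierarchical exclusions apply (metastatic disease supersedes
    any malignancy, severe liver disease supersedes mild, complicated
    diabetes supersedes uncomplicated).
    """
    mapping = CHARLSON_CATEGORIES if mapping is None else mapping
    codes = {_normalize_code(c) for c in icd_codes}
    present = set()
    for category, (_, prefixes) in mapping.items():
        if any(code.startswith(p) for p in prefixes for code in codes):
            present.add(category)
    for severe, mild in _CHARLSON_HIERARCHY.items():
        if severe in present:
            present.discard(mild)
    return sum(mapping[cat][0] for cat in present)
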
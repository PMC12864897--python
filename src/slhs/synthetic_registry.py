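"""Synthetic sepsis-registry generator.

The study registry is not publicly available, so this module generates
registries with the statistical structure the pipeline assumes: multi-ward
stays over a multi-year calendar, vital-sign and laboratory series at
realistic ward sampling densities, clinician-adjudicated sepsis events whose
supporting facts are consistent with the six-way label logic, under-sensitive
ICD coding, and mortality / time-to-antibiotics outcome processes with
configurable period effects.

Label self-consistency is guaranteed constructively, not statistically:
event-bearing stays have their SOFA-input and lactate series clamped into
score-zero bands at baseline, and episode perturbations are clipped into
the abnormal bands the injected label requires (e.g. a septic-shock episode
forces a vasopressor administration, post-onset lactate > 2 mmol/L, and a
delta-SOFA of at least 2). ``sepsis_labeling.classify_event`` applied to the
facts recomputed from the generated data therefore recovers the injected
label for every event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    GeneratorConfig,
    LAB_CONCEPTS,
    VITAL_CONCEPTS,
)
from .registry_io import Registry
from .sepsis_labeling import CoarseLabel, FineLabel, collapse_label

__all__ = [
    "generate_registry",
    "inject_sepsis_episode",
    "assign_icd_codes",
    "simulate_outcomes",
    "CONCEPT_BASELINES",
]

# concept -> (mean, sd, unit); sampling cadence is per kind (vitals ~4 h,
# GCS ~8 h, labs ~24 h). Individual set-points add within-stay correlation.
CONCEPT_BASELINES: dict[str, tuple[float, float, str]] = {
    "heart_rate": (75.0, 9.0, "/min"),
    "resp_rate": (16.0, 2.0, "/min"),
    "sbp": (122.0, 11.0, "mmHg"),
    "map": (86.0, 6.0, "mmHg"),
    "temp": (36.8, 0.3, "degC"),
    "spo2": (97.0, 1.2, "%"),
    "gcs": (15.0, 0.0, "points"),
    "on_oxygen": (0.0, 0.0, "flag"),
    "platelets": (250.0, 45.0, "1e9/L"),
    "bilirubin": (10.0, 4.0, "umol/L"),
    "creatinine": (72.0, 14.0, "umol/L"),
    "lactate": (1.2, 0.3, "mmol/L"),
    "pao2_fio2": (430.0, 35.0, "mmHg"),
    "sodium": (139.0, 3.0, "mmol/L"),
    "potassium": (4.1, 0.35, "mmol/L"),
    "chloride": (103.0, 3.0, "mmol/L"),
    "bicarbonate": (24.0, 2.0, "mmol/L"),
    "urea": (6.0, 2.0, "mmol/L"),
    "glucose": (6.2, 1.2, "mmol/L"),
    "calcium": (2.35, 0.1, "mmol/L"),
    "magnesium": (0.85, 0.08, "mmol/L"),
    "phosphate": (1.1, 0.2, "mmol/L"),
    "albumin": (38.0, 4.0, "g/L"),
    "crp": (12.0, 10.0, "mg/L"),
    "procalcitonin": (0.1, 0.08, "ug/L"),
    "wbc": (7.5, 2.0, "1e9/L"),
    "hemoglobin": (131.0, 14.0, "g/L"),
    "hematocrit": (0.39, 0.04, "fraction"),
    "neutrophils": (4.5, 1.5, "1e9/L"),
    "lymphocytes": (1.8, 0.6, "1e9/L"),
    "monocytes": (0.5, 0.15, "1e9/L"),
    "inr": (1.05, 0.1, "ratio"),
    "aptt": (30.0, 4.0, "s"),
    "alt": (28.0, 12.0, "U/L"),
    "ast": (26.0, 10.0, "U/L"),
    "alp": (80.0, 25.0, "U/L"),
    "ggt": (35.0, 20.0, "U/L"),
    "ldh": (180.0, 40.0, "U/L"),
    "ck": (90.0, 40.0, "U/L"),
    "troponin": (8.0, 5.0, "ng/L"),
}

# score-zero clamp bands applied to event-bearing stays at baseline
_SOFA_SAFE_BANDS = {
    "pao2_fio2": (410.0, 520.0),
    "platelets": (165.0, 420.0),
    "bilirubin": (1.0, 18.0),
    "map": (73.0, 105.0),
    "creatinine": (40.0, 104.0),
    "lactate": (0.4, 1.9),
}

# infection-response perturbation of the vital signs (step at t0, exponential
# recovery); applied for every infection-positive label
_INFECTION_VITALS = {
    "temp": +1.7,
    "heart_rate": +26.0,
    "resp_rate": +7.0,
    "sbp": -18.0,
    "crp": +160.0,
    "procalcitonin": +5.0,
    "wbc": +6.5,
}

# abnormal bands for the delta-SOFA >= 2 labels (coag 2 + renal 2 points)
_DYSFUNCTION_BANDS = {
    "platelets": (58.0, 92.0),
    "creatinine": (185.0, 285.0),
}

_SEPSIS_CODES = ("A41.9", "A41.5", "A40.0", "R65.2", "R57.2")

# Charlson-relevant code pool: (ICD-10 code, per-stay prevalence) patterned
# on the documented cohort comorbidity profile
_COMORBIDITY_POOL = (
    ("I21.9", 0.075),   # myocardial infarction
    ("I50.0", 0.132),   # congestive heart failure
    ("I70.2", 0.053),   # peripheral vascular disease
    ("I63.9", 0.070),   # cerebrovascular disease
    ("F03", 0.117),     # dementia
    ("J44.9", 0.109),   # chronic pulmonary disease
    ("M05.9", 0.019),   # rheumatic disease
    ("K25.9", 0.011),   # peptic ulcer disease
    ("K70.3", 0.043),   # mild liver disease
    ("E11.9", 0.114),   # diabetes without complications
    ("E11.2", 0.027),   # diabetes with complications
    ("N18.4", 0.136),   # renal disease
    ("C34.9", 0.133),   # malignancy
    ("K72.9", 0.015),   # moderate/severe liver disease
    ("C78.7", 0.082),   # metastatic solid tumor
    ("B20", 0.034),     # HIV
)


def _minute(ts: pd.Series | pd.Timestamp):
    if isinstance(ts, pd.Timestamp):
        return ts.floor("min")
    return ts.dt.floor("min")


def _spawn(rng: np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# stays, patients, wards


def _generate_stays(cfg: GeneratorConfig, rng: np.random.Generator):
    n = cfg.n_stays
    # patients: geometric number of stays each until n stays are covered
    counts = []
    total = 0
    while total < n:
        c = int(rng.geometric(cfg.stays_per_patient_geom_p))
        counts.append(c)
        total += c
    counts[-1] -= total - n
    patient_ids = [f"P{i:06d}" for i in range(len(counts))]

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, len(counts)), 18, 95)
    sex = np.where(rng.random(len(counts)) < cfg.male_fraction, "M", "F")

    start = pd.Timestamp(f"{cfg.calendar_start_year}-01-01", tz="UTC")
    span_days = 365.25 * cfg.calendar_years

    los_d = np.clip(
        rng.lognormal(cfg.los_log_mean_days, cfg.los_log_sd, n),
        cfg.los_min_days,
        cfg.los_max_days,
    )
    admit_off = rng.uniform(0, np.maximum(span_days - los_d - 1.0, 1.0))
    admit = _minute(pd.Series(start + pd.to_timedelta(admit_off * 24 * 60, unit="m")))
    discharge = _minute(admit + pd.to_timedelta(los_d * 24 * 60, unit="m"))

    stay_patient = np.repeat(np.arange(len(counts)), counts)
    stays = pd.DataFrame(
        {
            "stay_id": [f"S{i:06d}" for i in range(n)],
            "patient_id": [patient_ids[j] for j in stay_patient],
            "admit_ts": admit,
            "discharge_ts": discharge,
            "in_hospital_death": False,
            "death_ts": pd.Series([pd.NaT] * n, dtype="datetime64[ns, UTC]"),
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": sex,
            # birth year from age at first admission
            "birth_year": 0,
        }
    )
    first_admit_year = (
        stays.groupby("patient_id")["admit_ts"].min().dt.year.reindex(patient_ids)
    )
    patients["birth_year"] = (first_admit_year.to_numpy() - np.round(age)).astype(int)
    return patients, stays


def _generate_ward_segments(cfg: GeneratorConfig, stays: pd.DataFrame,
                            rng: np.random.Generator) -> pd.DataFrame:
    slhs_groups = ["MED", "GIS", "EMD"]
    rows = []
    u = rng.random(len(stays))
    for i, r in enumerate(stays.itertuples(index=False)):
        if u[i] < cfg.frac_limited_slhs:
            kind = "limited"
        elif u[i] < cfg.frac_limited_slhs + cfg.frac_mixed:
            kind = "mixed"
        else:
            kind = "control"
        n_seg = int(rng.integers(1, 4)) if kind != "control" else int(rng.integers(1, 3))
        if kind == "mixed":
            n_seg = max(n_seg, 2)
        # segment groups
        if kind == "limited":
            groups = list(rng.choice(slhs_groups, size=n_seg))
            if rng.random() < cfg.emd_first_fraction:
                groups[0] = "EMD"
        elif kind == "control":
            groups = ["CONTROL"] * n_seg
        else:
            n_slhs = int(rng.integers(1, n_seg))
            groups = list(rng.choice(slhs_groups, size=n_slhs)) + list(
                rng.choice(["CONTROL", "OTHER"], size=n_seg - n_slhs)
            )
            if rng.random() < cfg.emd_first_fraction:
                groups[0] = "EMD"
        # cut points at minute resolution
        span_min = (r.discharge_ts - r.admit_ts).total_seconds() / 60.0
        cuts = np.sort(rng.uniform(0.1, 0.9, n_seg - 1)) * span_min if n_seg > 1 else []
        bounds = [0.0, *cuts, span_min]
        for s in range(n_seg):
            t0 = _minute(r.admit_ts + pd.Timedelta(minutes=bounds[s]))
            t1 = _minute(r.admit_ts + pd.Timedelta(minutes=bounds[s + 1])) if s < n_seg - 1 else r.discharge_ts
            if t1 <= t0:
                continue
            g = groups[s]
            rows.append((r.stay_id, f"{g}-{int(rng.integers(1, 9))}", g, t0, t1))
    return pd.DataFrame(
        rows, columns=["stay_id", "ward_id", "ward_group", "start_ts", "end_ts"]
    )


# ---------------------------------------------------------------------------
# baseline physiology


def _baseline_observations(cfg: GeneratorConfig, stays: pd.DataFrame,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Noisy series around individual set-points at ward sampling density."""
    frames = []
    admit = stays["admit_ts"].reset_index(drop=True)
    los_h = (
        (stays["discharge_ts"] - stays["admit_ts"]).dt.total_seconds() / 3600.0
    ).to_numpy()
    n = len(stays)
    stay_ids = stays["stay_id"].to_numpy()

    def emit(concept, times_h, stay_idx):
        mean, sd, unit = CONCEPT_BASELINES[concept]
        setpoint = rng.normal(0.0, 0.5 * sd, n)[stay_idx]
        vals = mean + setpoint + rng.normal(0.0, 0.85 * sd, len(stay_idx))
        if concept == "spo2":
            vals = np.clip(vals, 70.0, 100.0)
        elif concept == "gcs":
            vals = 15.0 - (rng.random(len(stay_idx)) < 0.03)
        elif concept == "on_oxygen":
            vals = (rng.random(len(stay_idx)) < 0.08).astype(float)
        elif concept in ("bilirubin", "lactate", "creatinine", "crp",
                         "procalcitonin", "troponin"):
            vals = np.maximum(vals, 0.05)
        ts = admit.iloc[stay_idx].reset_index(drop=True) + pd.to_timedelta(
            np.round(times_h * 60.0), unit="m"
        )
        frames.append(
            pd.DataFrame(
                {
                    "stay_id": stay_ids[stay_idx],
                    "concept_id": concept,
                    "ts": ts,
                    "value": np.round(vals, 3),
                    "unit": unit,
                }
            )
        )

    # vitals every ~4 h (GCS every ~8 h), jittered
    for concept in VITAL_CONCEPTS:
        step = 8.0 if concept in ("gcs",) else 4.0
        n_samp = np.maximum((los_h / step).astype(int), 1)
        stay_idx = np.repeat(np.arange(n), n_samp)
        base = np.concatenate([np.arange(k) * step for k in n_samp])
        times = base + rng.uniform(0.2, step - 0.2, len(base)) * 0.5
        times = np.minimum(times, np.repeat(los_h, n_samp) - 0.02)
        emit(concept, times, stay_idx)

    # labs: an admission panel plus one panel per day
    for concept in LAB_CONCEPTS:
        n_samp = np.maximum((los_h / 24.0).astype(int), 0) + 1
        stay_idx = np.repeat(np.arange(n), n_samp)
        base = np.concatenate([np.arange(k) * 24.0 for k in n_samp])
        times = base + rng.uniform(0.5, 3.0, len(base))
        times = np.minimum(times, np.repeat(los_h, n_samp) - 0.02)
        emit(concept, times, stay_idx)

    obs = pd.concat(frames, ignore_index=True)
    obs["ts"] = _minute(obs["ts"])
    return obs


# ---------------------------------------------------------------------------
# sepsis episodes


def inject_sepsis_episode(
    stay: pd.Series,
    observations: pd.DataFrame,
    fine_label: FineLabel,
    t0: pd.Timestamp,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Perturb one stay's series so the injected label's defining facts hold.

    Returns ``(modified observations, new medication rows)``. The episode is
    a step perturbation at ``t0`` with exponential recovery; the label's
    defining facts are enforced by clipping into bands (delta-SOFA >= 2 for
    the sensu-lato/stricto/shock labels, vasopressor + lactate > 2 mmol/L
    for septic shock, delta-SOFA < 2 for infection-without-sepsis).
    """
    fine_label = FineLabel(fine_label)
    admit, discharge = stay["admit_ts"], stay["discharge_ts"]
    if not (admit <= t0 < discharge):
        raise ValueError(f"t0={t0} outside stay interval [{admit}, {discharge})")
    obs = observations.copy()
    end = min(t0 + pd.Timedelta(hours=cfg.episode_recovery_hours), discharge)
    tau_h = cfg.episode_recovery_hours / 3.0

    med_rows: list[tuple] = []
    if fine_label == FineLabel.NO_INFECTION:
        return obs, _med_frame(med_rows)

    in_ep = (obs["ts"] >= t0) & (obs["ts"] <= end)
    dt_h = (obs["ts"] - t0).dt.total_seconds() / 3600.0
    decay = pd.Series(np.where(in_ep, np.exp(-dt_h.clip(lower=0) / tau_h), 0.0),
                      index=obs.index)
    for concept, delta in _INFECTION_VITALS.items():
        m = in_ep & (obs["concept_id"] == concept)
        if m.any():
            obs.loc[m, "value"] = obs.loc[m, "value"] + delta * decay[m]

    dysfunction = fine_label in (
        FineLabel.SEPSIS_SENSU_LATO,
        FineLabel.SEPSIS_SENSU_STRICTO,
        FineLabel.SEPTIC_SHOCK,
    )
    if dysfunction:
        for concept, (lo, hi) in _DYSFUNCTION_BANDS.items():
            m = in_ep & (obs["concept_id"] == concept)
            if m.any():
                obs.loc[m, "value"] = rng.uniform(lo, hi, int(m.sum()))

    # sepsis work-up panel ordered at review time: guarantees post-onset
    # assessments exist whatever the routine sampling landed on
    panel_t = _minute(t0 + pd.Timedelta(hours=4))
    panel_t = min(panel_t, _minute(discharge - pd.Timedelta(minutes=2)))
    lact_t = _minute(t0 + pd.Timedelta(hours=2))
    lact_t = min(lact_t, _minute(discharge - pd.Timedelta(minutes=2)))
    workup = []

    def add(concept, value):
        workup.append(
            (stay["stay_id"], concept, panel_t, round(float(value), 3),
             CONCEPT_BASELINES[concept][2])
        )

    if dysfunction:
        add("platelets", rng.uniform(*_DYSFUNCTION_BANDS["platelets"]))
        add("creatinine", rng.uniform(*_DYSFUNCTION_BANDS["creatinine"]))
    else:
        add("platelets", rng.uniform(200, 320))
        add("creatinine", rng.uniform(55, 95))
    add("bilirubin", rng.uniform(4, 16))
    add("pao2_fio2", rng.uniform(415, 480))

    if fine_label == FineLabel.SEPTIC_SHOCK:
        lact_val = rng.uniform(2.8, 5.5)
        m = in_ep & (obs["concept_id"] == "map")
        if m.any():
            obs.loc[m, "value"] = rng.uniform(56, 67, int(m.sum()))
        med_rows.append((stay["stay_id"], "vasopressor",
                         _minute(t0 + pd.Timedelta(hours=1))))
    else:
        lact_val = rng.uniform(0.8, 1.8)
    workup.append(
        (stay["stay_id"], "lactate", lact_t, round(float(lact_val), 3),
         CONCEPT_BASELINES["lactate"][2])
    )

    workup_df = pd.DataFrame(
        workup, columns=["stay_id", "concept_id", "ts", "value", "unit"]
    )
    obs = pd.concat([obs, workup_df], ignore_index=True)
    return obs, _med_frame(med_rows)


def _med_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["stay_id", "drug_class", "admin_ts"])


def _draw_t0(admit, discharge, rng) -> pd.Timestamp:
    """Onset offset ~ Exp(mean 48 h) truncated to [2 h, LOS - 18 h]."""
    los_h = (discharge - admit).total_seconds() / 3600.0
    lo, hi = 2.0, max(los_h - 18.0, 3.0)
    hi = max(hi, lo + 0.5)
    scale = 48.0
    Flo, Fhi = 1 - np.exp(-lo / scale), 1 - np.exp(-hi / scale)
    u = rng.uniform(Flo, Fhi)
    off = -scale * np.log(1 - u)
    return _minute(admit + pd.Timedelta(hours=float(off)))


_LABEL_FLAGS = {
    # fine label -> (infection, organ_failure, alternative_etiology)
    FineLabel.NO_INFECTION: (False, False, False),
    FineLabel.INFECTION: (True, False, False),
    FineLabel.SEPSIS_LIKE: (True, True, False),
    FineLabel.SEPSIS_SENSU_LATO: (True, True, True),
    FineLabel.SEPSIS_SENSU_STRICTO: (True, True, False),
    FineLabel.SEPTIC_SHOCK: (True, True, False),
}


def _generate_events(cfg, stays, slhs_stay_ids, rng):
    """Choose event stays, labels and onset times (no physiology yet)."""
    bearing = rng.random(len(stays)) < cfg.sepsis_prevalence
    labels = list(cfg.label_mix)
    probs = np.array([cfg.label_mix[l] for l in labels])
    rows = []
    eid = 0
    for r, has in zip(stays.itertuples(index=False), bearing):
        if not has:
            continue
        fine = FineLabel(str(rng.choice(labels, p=probs)))
        t0 = _draw_t0(r.admit_ts, r.discharge_ts, rng)
        source = "orderset" if r.stay_id in slhs_stay_ids else "id_consult"
        inf, of, alt = _LABEL_FLAGS[fine]
        rows.append((f"E{eid:06d}", r.stay_id, t0, fine.value, source, inf, of, alt))
        eid += 1
        # occasional recurrent episode, same adjudication, after recovery
        los_h = (r.discharge_ts - r.admit_ts).total_seconds() / 3600.0
        t0_h = (t0 - r.admit_ts).total_seconds() / 3600.0
        if rng.random() < 0.085 and los_h - t0_h > cfg.episode_recovery_hours + 48:
            t0b = _minute(
                t0 + pd.Timedelta(hours=cfg.episode_recovery_hours + 24)
                + pd.Timedelta(hours=float(rng.uniform(0, 12)))
            )
            if t0b < r.discharge_ts - pd.Timedelta(hours=18):
                rows.append((f"E{eid:06d}", r.stay_id, t0b, fine.value, source,
                             inf, of, alt))
                eid += 1
    ev = pd.DataFrame(
        rows,
        columns=["event_id", "stay_id", "t0", "fine_label", "source",
                 "infection", "organ_failure", "alternative_etiology"],
    )
    ev["t0"] = pd.to_datetime(ev["t0"], utc=True)
    for col in ("infection", "organ_failure", "alternative_etiology"):
        ev[col] = ev[col].astype(bool)
    return ev


# ---------------------------------------------------------------------------
# coding and outcomes


def assign_icd_codes(
    stay_truth: pd.Series,
    icd_sensitivity: float,
    ps_code_rate: float,
    ns_code_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sepsis ICD-10 codes under imperfect coding sensitivity.

    ``stay_truth`` maps stay_id -> coarse truth ('NS'/'PS'/'CS'). Confirmed
    stays are coded with probability ``icd_sensitivity`` (the documented
    under-coding), possible-sepsis stays with ``ps_code_rate``, others with
    ``ns_code_rate``.
    """
    rows = []
    for stay_id, truth in stay_truth.items():
        p = {"CS": icd_sensitivity, "PS": ps_code_rate}.get(truth, ns_code_rate)
        if rng.random() < p:
            rows.append((stay_id, str(rng.choice(_SEPSIS_CODES))))
    return pd.DataFrame(rows, columns=["stay_id", "code"])


def _comorbidity_codes(stays: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n = len(stays)
    draws = rng.random((n, len(_COMORBIDITY_POOL)))
    for j, (code, prev) in enumerate(_COMORBIDITY_POOL):
        hit = np.nonzero(draws[:, j] < prev)[0]
        rows.extend((stays["stay_id"].iat[i], code) for i in hit)
    return pd.DataFrame(rows, columns=["stay_id", "code"])


def simulate_outcomes(
    stays: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw in-hospital and 90-day deaths from the logistic outcome model.

    ``covariates`` must carry stay_id, is_cs, is_ps, age, year_index and
    timely (antibiotics within 1 h; 0 where not applicable). Returns stays
    with ``in_hospital_death`` / ``death_ts`` filled; in-hospital death
    implies 90-day death by construction.
    """
    m = cfg.mortality
    cov = covariates.set_index("stay_id").reindex(stays["stay_id"]).fillna(0.0)
    lin = (
        m.beta_sepsis_cs * cov["is_cs"].to_numpy(float)
        + m.beta_sepsis_ps * cov["is_ps"].to_numpy(float)
        + m.beta_age * (cov["age"].to_numpy(float) - 65.0)
        + m.beta_year * cov["year_index"].to_numpy(float)
        + m.beta_timely * cov["timely"].to_numpy(float)
    )
    p_hosp = 1.0 / (1.0 + np.exp(-(m.intercept + lin)))
    p_90 = 1.0 / (1.0 + np.exp(-(m.intercept_90d + lin)))

    out = stays.copy()
    u = rng.random(len(out))
    died_hosp = u < p_hosp
    died_90 = ~died_hosp & (rng.random(len(out)) < p_90)

    death_ts = pd.Series([pd.NaT] * len(out), dtype="datetime64[ns, UTC]")
    admit = out["admit_ts"]
    discharge = out["discharge_ts"]
    los_min = (discharge - admit).dt.total_seconds() / 60.0
    frac = rng.uniform(0.3, 0.999, len(out))
    hosp_ts = _minute(admit + pd.to_timedelta(np.round(los_min * frac), unit="m"))
    death_ts[died_hosp] = hosp_ts[died_hosp]

    los_d = los_min / (24 * 60)
    extra = rng.uniform(1.0, np.maximum(89.0 - los_d, 2.0))
    post_ts = _minute(discharge + pd.to_timedelta(np.round(extra * 24 * 60), unit="m"))
    death_ts[died_90] = post_ts[died_90]

    out["in_hospital_death"] = died_hosp
    out["death_ts"] = death_ts
    return out


# ---------------------------------------------------------------------------
# top-level generation


def generate_registry(cfg: GeneratorConfig) -> Registry:
    """Generate a full validated registry; identical seed, identical output."""
    rng = np.random.default_rng(cfg.seed)
    patients, stays = _generate_stays(cfg, _spawn(rng))
    segments = _generate_ward_segments(cfg, stays, _spawn(rng))
    obs = _baseline_observations(cfg, stays, _spawn(rng))

    slhs_stay_ids = set(
        segments.loc[segments["ward_group"].isin(("MED", "GIS", "EMD")), "stay_id"]
    )
    ev_rng = _spawn(rng)
    events = _generate_events(cfg, stays, slhs_stay_ids, ev_rng)

    # clamp event-bearing stays into score-zero bands so the baseline SOFA is
    # exactly 0 and the injected episode alone decides the label facts
    ep_rng = _spawn(rng)
    event_stays = set(events["stay_id"]) if len(events) else set()
    if event_stays:
        in_ev = obs["stay_id"].isin(event_stays)
        for concept, (lo, hi) in _SOFA_SAFE_BANDS.items():
            m = in_ev & (obs["concept_id"] == concept)
            obs.loc[m, "value"] = obs.loc[m, "value"].clip(lo, hi)
        m = in_ev & (obs["concept_id"] == "gcs")
        obs.loc[m, "value"] = 15.0

    med_frames = []
    if len(events):
        stay_lookup = stays.set_index("stay_id")
        obs_by_stay = {
            sid: df for sid, df in obs.groupby("stay_id", sort=False)
            if sid in event_stays
        }
        rest = obs.loc[~obs["stay_id"].isin(event_stays)]
        new_frames = [rest]
        for sid, ev_grp in events.groupby("stay_id", sort=False):
            stay_row = stay_lookup.loc[sid]
            stay_series = pd.Series(
                {"stay_id": sid, "admit_ts": stay_row["admit_ts"],
                 "discharge_ts": stay_row["discharge_ts"]}
            )
            stay_obs = obs_by_stay[sid]
            for _, ev in ev_grp.iterrows():
                stay_obs, meds = inject_sepsis_episode(
                    stay_series, stay_obs, FineLabel(ev["fine_label"]), ev["t0"],
                    cfg, ep_rng,
                )
                if len(meds):
                    med_frames.append(meds)
            new_frames.append(stay_obs)
        obs = pd.concat(new_frames, ignore_index=True)

    # antibiotics: first dose t0 + Exp delay (pathway vs non-pathway), then q8h
    ab_rng = _spawn(rng)
    timely = {}
    if len(events):
        first_events = events.sort_values("t0").groupby("stay_id").first()
        for sid, ev in first_events.iterrows():
            if not ev["infection"]:
                continue
            mean_h = (cfg.tta_mean_pathway_h if ev["source"] == "orderset"
                      else cfg.tta_mean_control_h)
            delay_h = float(ab_rng.exponential(mean_h))
            discharge = stays.loc[stays["stay_id"] == sid, "discharge_ts"].iloc[0]
            t = ev["t0"] + pd.Timedelta(hours=delay_h)
            doses = []
            while t < discharge and len(doses) < 9:
                doses.append((sid, "antibiotic", _minute(t)))
                t += pd.Timedelta(hours=8)
            if doses:
                med_frames.append(_med_frame(doses))
            timely[sid] = 1.0 if delay_h <= 1.0 else 0.0
    # background antibiotic exposure in non-event stays
    non_event = stays.loc[~stays["stay_id"].isin(event_stays)]
    bg = non_event.loc[ab_rng.random(len(non_event)) < 0.10]
    if len(bg):
        frac = ab_rng.uniform(0.05, 0.9, len(bg))
        t = bg["admit_ts"] + (bg["discharge_ts"] - bg["admit_ts"]) * frac
        med_frames.append(
            _med_frame(list(zip(bg["stay_id"], ["antibiotic"] * len(bg), _minute(t))))
        )
    medications = (
        pd.concat(med_frames, ignore_index=True)
        if med_frames
        else _med_frame([])
    )
    medications["admin_ts"] = pd.to_datetime(medications["admin_ts"], utc=True)

    # ICD coding
    icd_rng = _spawn(rng)
    truth = {}
    if len(events):
        for sid, grp in events.groupby("stay_id"):
            best = max(
                (collapse_label(FineLabel(v)) for v in grp["fine_label"]),
                key=lambda c: c.severity,
            )
            truth[sid] = best.value
    truth_series = pd.Series(
        {sid: truth.get(sid, CoarseLabel.NS.value) for sid in stays["stay_id"]}
    )
    sepsis_codes = assign_icd_codes(
        truth_series.loc[truth_series != "NS"],
        cfg.icd_sensitivity, cfg.ps_code_rate, cfg.ns_code_rate, icd_rng,
    )
    ns_ids = truth_series.index[truth_series == "NS"]
    ns_codes = (
        assign_icd_codes(truth_series.loc[ns_ids], cfg.icd_sensitivity,
                         cfg.ps_code_rate, cfg.ns_code_rate, icd_rng)
        if cfg.ns_code_rate > 0
        else pd.DataFrame(columns=["stay_id", "code"])
    )
    comorb = _comorbidity_codes(stays, icd_rng)
    icd_codes = pd.concat([sepsis_codes, ns_codes, comorb], ignore_index=True)

    # outcomes
    out_rng = _spawn(rng)
    age_at_admit = (
        stays.merge(patients, on="patient_id")["admit_ts"].dt.year
        - stays.merge(patients, on="patient_id")["birth_year"]
    )
    covariates = pd.DataFrame(
        {
            "stay_id": stays["stay_id"],
            "is_cs": (truth_series.loc[stays["stay_id"]] == "CS").to_numpy(float),
            "is_ps": (truth_series.loc[stays["stay_id"]] == "PS").to_numpy(float),
            "age": age_at_admit.to_numpy(float),
            "year_index": (
                stays["admit_ts"].dt.year - cfg.calendar_start_year
            ).to_numpy(float),
            "timely": stays["stay_id"].map(timely).fillna(0.0).to_numpy(float),
        }
    )
    stays = simulate_outcomes(stays, covariates, cfg, out_rng)

    obs = obs.sort_values(["stay_id", "concept_id", "ts"], kind="mergesort").reset_index(drop=True)
    medications = medications.sort_values(["stay_id", "admin_ts"], kind="mergesort").reset_index(drop=True)
    icd_codes = icd_codes.sort_values(["stay_id", "code"], kind="mergesort").reset_index(drop=True)
    segments = segments.sort_values(["stay_id", "start_ts"], kind="mergesort").reset_index(drop=True)
    events = events.sort_values(["stay_id", "t0"], kind="mergesort").reset_index(drop=True)

    reg = Registry(
        patients=patients,
        stays=stays,
        ward_segments=segments,
        observations=obs,
        medications=medications,
        events=events,
        icd_codes=icd_codes,
    )
    return reg.validate()
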
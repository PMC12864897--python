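"""Clinical scores against independently transcribed lookup-table oracles."""

import numpy as np
import pandas as pd
import pytest

from slhs.clinical_scores import (
    DeltaSofaResult,
    ScoreSnapshot,
    charlson_index,
    delta_sofa,
    news2_score,
    sofa_total,
)

from conftest import ts


# ---------------------------------------------------------------------------
# oracle transcriptions (kept independent of the implementation: plain
# interval lists evaluated by linear scan)

INF = float("inf")

SOFA_ORACLE_BANDS = {
    "respiration": [(0, 100, 4), (100, 200, 3), (200, 300, 2), (300, 400, 1),
                    (400, INF, 0)],                      # P/F, upper-exclusive
    "coagulation": [(0, 20, 4), (20, 50, 3), (50, 100, 2), (100, 150, 1),
                    (150, INF, 0)],                      # platelets
    # bilirubin: >204 umol/L (>12 mg/dL) scores 4, 204 itself scores 3
    "liver": [(0, 20, 0), (20, 33, 1), (33, 102, 2), (102, 204 + 1e-9, 3),
              (204 + 1e-9, INF, 4)],
    "cns": [(3, 6, 4), (6, 10, 3), (10, 13, 2), (13, 15, 1), (15, 16, 0)],
    # creatinine: >440 umol/L (>5.0 mg/dL) scores 4, 440 itself scores 3
    "renal": [(0, 110, 0), (110, 171, 1), (171, 300, 2), (300, 440 + 1e-9, 3),
              (440 + 1e-9, INF, 4)],
}


def _band(bands, value):
    for lo, hi, pts in bands:
        if lo <= value < hi:
            return pts
    raise AssertionError(f"value {value} escaped oracle bands")


def sofa_oracle(snap: ScoreSnapshot) -> int:
    total = 0
    if snap.pao2_fio2 is not None:
        total += _band(SOFA_ORACLE_BANDS["respiration"], snap.pao2_fio2)
    if snap.platelets is not None:
        total += _band(SOFA_ORACLE_BANDS["coagulation"], snap.platelets)
    if snap.bilirubin is not None:
        total += _band(SOFA_ORACLE_BANDS["liver"], snap.bilirubin)
    vaso_pts = {"none": 0, "low": 2, "mid": 3, "high": 4}[snap.vasopressor_dose_class]
    if vaso_pts:
        total += vaso_pts
    elif snap.map is not None and snap.map < 70:
        total += 1
    if snap.gcs is not None:
        total += _band(SOFA_ORACLE_BANDS["cns"], snap.gcs)
    renal = 0
    if snap.creatinine is not None:
        renal = _band(SOFA_ORACLE_BANDS["renal"], snap.creatinine)
    if snap.urine_output_24h is not None:
        if snap.urine_output_24h < 200:
            renal = max(renal, 4)
        elif snap.urine_output_24h < 500:
            renal = max(renal, 3)
    total += renal
    return total


NEWS2_ORACLE = {
    "resp_rate": [(0, 8.5, 3), (8.5, 11.5, 1), (11.5, 20.5, 0), (20.5, 24.5, 2),
                  (24.5, INF, 3)],
    "spo2": [(0, 91.5, 3), (91.5, 93.5, 2), (93.5, 95.5, 1), (95.5, 101, 0)],
    "temp": [(0, 35.05, 3), (35.05, 36.05, 1), (36.05, 38.05, 0),
             (38.05, 39.05, 1), (39.05, INF, 2)],
    "sbp": [(0, 90.5, 3), (90.5, 100.5, 2), (100.5, 110.5, 1), (110.5, 219.5, 0),
            (219.5, INF, 3)],
    "heart_rate": [(0, 40.5, 3), (40.5, 50.5, 1), (50.5, 90.5, 0),
                   (90.5, 110.5, 1), (110.5, 130.5, 2), (130.5, INF, 3)],
}


def news2_oracle(snap: ScoreSnapshot) -> int:
    # oracle sampled on integer-ish vitals: half-point band edges reproduce
    # the printed integer tables exactly
    total = 0
    for name in ("resp_rate", "spo2", "temp", "sbp", "heart_rate"):
        v = getattr(snap, name)
        if v is not None:
            total += _band(NEWS2_ORACLE[name], v)
    if snap.on_oxygen:
        total += 2
    if snap.altered_consciousness:
        total += 3
    return total


def random_sofa_snapshot(rng) -> ScoreSnapshot:
    def maybe(sampler, p=0.85):
        return sampler() if rng.random() < p else None

    return ScoreSnapshot(
        pao2_fio2=maybe(lambda: float(rng.uniform(40, 600))),
        platelets=maybe(lambda: float(rng.uniform(1, 600))),
        bilirubin=maybe(lambda: float(rng.uniform(1, 400))),
        map=maybe(lambda: float(rng.uniform(40, 130))),
        vasopressor_dose_class=str(rng.choice(["none", "none", "low", "mid", "high"])),
        gcs=maybe(lambda: float(rng.integers(3, 16))),
        creatinine=maybe(lambda: float(rng.uniform(20, 700))),
        urine_output_24h=maybe(lambda: float(rng.uniform(0, 3000)), p=0.2),
    )


def random_news2_snapshot(rng) -> ScoreSnapshot:
    def maybe(sampler, p=0.9):
        return sampler() if rng.random() < p else None

    return ScoreSnapshot(
        resp_rate=maybe(lambda: float(rng.integers(4, 45))),
        spo2=maybe(lambda: float(rng.integers(75, 101))),
        on_oxygen=bool(rng.random() < 0.2),
        temp=maybe(lambda: float(np.round(rng.uniform(33, 41.5), 1))),
        sbp=maybe(lambda: float(rng.integers(60, 250))),
        heart_rate=maybe(lambda: float(rng.integers(25, 190))),
        altered_consciousness=bool(rng.random() < 0.1),
    )


# ---------------------------------------------------------------------------
# SOFA


def test_sofa_all_normal_is_zero():
    snap = ScoreSnapshot(pao2_fio2=450, platelets=250, bilirubin=10, map=85,
                         gcs=15, creatinine=70)
    res = sofa_total(snap)
    assert res.total == 0
    assert all(v == 0 for v in res.subscores.values())
    assert not res.imputed


@pytest.mark.parametrize(
    "kwargs, organ, expected",
    [
        ({"platelets": 90}, "coagulation", 2),
        ({"gcs": 5}, "cns", 4),
        ({"pao2_fio2": 150}, "respiration", 3),
        ({"bilirubin": 204}, "liver", 3),
        ({"bilirubin": 205}, "liver", 4),
        ({"creatinine": 300}, "renal", 3),
        ({"map": 65}, "cardiovascular", 1),
        ({"vasopressor_dose_class": "high"}, "cardiovascular", 4),
    ],
)
def test_sofa_single_organ_lookup(kwargs, organ, expected):
    base = dict(pao2_fio2=450, platelets=250, bilirubin=10, map=85, gcs=15,
                creatinine=70)
    base.update(kwargs)
    res = sofa_total(ScoreSnapshot(**base))
    assert res.subscores[organ] == expected
    assert res.total == expected


def test_sofa_matches_oracle_on_random_snapshots(rng):
    for _ in range(2000):
        snap = random_sofa_snapshot(rng)
        assert sofa_total(snap).total == sofa_oracle(snap)


def test_sofa_missing_organ_flagged():
    res = sofa_total(ScoreSnapshot(platelets=90))
    assert res.subscores["coagulation"] == 2
    assert "respiration" in res.imputed and "renal" in res.imputed
    assert res.n_imputed == 5


def test_sofa_monotone_in_each_input():
    # worsening direction per organ: score never decreases
    worsening = {
        "pao2_fio2": np.linspace(500, 50, 30),
        "platelets": np.linspace(400, 5, 30),
        "bilirubin": np.linspace(5, 300, 30),
        "map": np.linspace(100, 45, 30),
        "gcs": np.arange(15, 2, -1),
        "creatinine": np.linspace(50, 600, 30),
    }
    for name, ray in worsening.items():
        prev = -1
        for v in ray:
            total = sofa_total(ScoreSnapshot(**{name: float(v)})).total
            assert total >= prev, f"{name} not monotone at {v}"
            prev = total


def test_sofa_out_of_range_rejected():
    with pytest.raises(ValueError, match="gcs"):
        ScoreSnapshot(gcs=2)
    with pytest.raises(ValueError, match="spo2"):
        ScoreSnapshot(spo2=130)


# ---------------------------------------------------------------------------
# NEWS2


def test_news2_all_normal_is_zero():
    snap = ScoreSnapshot(resp_rate=16, spo2=97, on_oxygen=False, temp=37.0,
                         sbp=120, heart_rate=70, altered_consciousness=False)
    assert news2_score(snap).total == 0


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        ({"resp_rate": 25}, 3),
        ({"sbp": 85}, 3),
        ({"spo2": 93}, 2),
        ({"heart_rate": 115}, 2),
        ({"temp": 39.5}, 2),
        ({"on_oxygen": True}, 2),
        ({"altered_consciousness": True}, 3),
    ],
)
def test_news2_single_band_lookup(kwargs, expected):
    base = dict(resp_rate=16, spo2=97, on_oxygen=False, temp=37.0, sbp=120,
                heart_rate=70, altered_consciousness=False)
    base.update(kwargs)
    assert news2_score(ScoreSnapshot(**base)).total == expected


def test_news2_matches_oracle_on_random_snapshots(rng):
    for _ in range(2000):
        snap = random_news2_snapshot(rng)
        assert news2_score(snap).total == news2_oracle(snap)


def test_news2_monotone_in_worsening_vitals():
    rays = {
        "resp_rate": np.arange(16, 40),
        "heart_rate": np.arange(70, 180, 4),
        "sbp": np.arange(120, 60, -3),
        "spo2": np.arange(99, 80, -1),
    }
    for name, ray in rays.items():
        prev = -1
        for v in ray:
            total = news2_score(ScoreSnapshot(**{name: float(v)})).total
            assert total >= prev
            prev = total


# ---------------------------------------------------------------------------
# delta-SOFA


def _obs(rows):
    return pd.DataFrame(rows, columns=["stay_id", "concept_id", "ts", "value", "unit"])


def test_delta_sofa_basic_rise():
    rows = [
        ("S", "platelets", ts("2022-01-01 06:00"), 250.0, ""),
        ("S", "platelets", ts("2022-01-02 12:00"), 60.0, ""),
        ("S", "creatinine", ts("2022-01-01 06:00"), 70.0, ""),
        ("S", "creatinine", ts("2022-01-02 12:00"), 200.0, ""),
    ]
    res = delta_sofa(_obs(rows), ts("2022-01-02 00:00"), max_imputed_organs=4)
    assert not res.missing
    assert res.baseline == 0
    assert res.value == 4  # coagulation 2 + renal 2


def test_delta_sofa_zero_baseline_policy():
    # no pre-onset observations at all: baseline scored 0 by convention
    rows = [("S", "platelets", ts("2022-01-02 12:00"), 90.0, "")]
    res = delta_sofa(_obs(rows), ts("2022-01-02 00:00"), max_imputed_organs=5)
    assert res.baseline == 0
    assert res.value == res.post_max


def test_delta_sofa_no_post_observations_is_missing():
    rows = [("S", "platelets", ts("2022-01-01 00:00"), 90.0, "")]
    res = delta_sofa(_obs(rows), ts("2022-01-02 00:00"))
    assert res.missing
    assert res.value is None  # explicit marker, never 0


def test_delta_sofa_t0_outside_stay_rejected():
    rows = [("S", "platelets", ts("2022-01-01 00:00"), 250.0, "")]
    with pytest.raises(ValueError, match="outside stay"):
        delta_sofa(_obs(rows), ts("2022-01-05 00:00"),
                   stay_interval=(ts("2022-01-01"), ts("2022-01-03")))


def test_delta_sofa_never_negative():
    # improvement after onset clamps at 0
    rows = [
        ("S", "platelets", ts("2022-01-01 23:00"), 60.0, ""),
        ("S", "platelets", ts("2022-01-02 06:00"), 250.0, ""),
    ]
    res = delta_sofa(_obs(rows), ts("2022-01-02 00:00"), max_imputed_organs=5)
    assert res.value == 0 and not res.missing


# ---------------------------------------------------------------------------
# Charlson

CHARLSON_ORACLE_WEIGHTS = [
    # (example codes, independent weight) from the original index
    (["I21.0"], 1),                      # myocardial infarction
    (["I50.9"], 1),                      # congestive heart failure
    (["E11.9"], 1),                      # diabetes w/o complications
    (["E11.2"], 2),                      # diabetes with complications
    (["N18.5"], 2),                      # renal disease
    (["C34.9"], 2),                      # malignancy
    (["K70.3"], 1),                      # mild liver disease
    (["K72.9"], 3),                      # moderate/severe liver disease
    (["C78.7"], 6),                      # metastatic solid tumor
    (["B20"], 6),                        # HIV/AIDS
]


def test_charlson_empty_is_zero():
    assert charlson_index([]) == 0


@pytest.mark.parametrize("codes, expected", CHARLSON_ORACLE_WEIGHTS)
def test_charlson_single_category_weights(codes, expected):
    assert charlson_index(codes) == expected


def test_charlson_mi_plus_diabetes():
    assert charlson_index(["I21.0", "E11.9"]) == 2


def test_charlson_hierarchies():
    # severe supersedes mild; metastatic supersedes malignancy
    assert charlson_index(["K70.3", "K72.9"]) == 3
    assert charlson_index(["C34.9", "C78.7"]) == 6
    assert charlson_index(["E11.9", "E11.2"]) == 2


def test_charlson_duplication_and_order_invariant(rng):
    pool = [c for codes, _ in CHARLSON_ORACLE_WEIGHTS for c in codes] + [
        "Z99.9", "A41.9", "XX1"  # unknown/ignored codes
    ]
    for _ in range(300):
        k = int(rng.integers(0, 6))
        codes = list(rng.choice(pool, size=k)) if k else []
        base = charlson_index(codes)
        dup = charlson_index(codes + codes)
        shuffled = list(codes)
        rng.shuffle(shuffled)
        assert charlson_index(shuffled) == base == dup


def test_charlson_matches_category_oracle(rng):
    # independent oracle: map each known example code to its weight, apply
    # hierarchy triples explicitly, sum distinct categories
    code_weight = {c: w for codes, w in CHARLSON_ORACLE_WEIGHTS for c in codes}
    hierarchy = [("E11.2", "E11.9"), ("K72.9", "K70.3"), ("C78.7", "C34.9")]
    pool = list(code_weight) + ["Z99.9", "UNKNOWN"]
    for _ in range(1000):
        k = int(rng.integers(0, 7))
        codes = list(rng.choice(pool, size=k)) if k else []
        present = {c for c in codes if c in code_weight}
        for severe, mild in hierarchy:
            if severe in present:
                present.discard(mild)
        assert charlson_index(codes) == sum(code_weight[c] for c in present)
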
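"""Window grid, rolling aggregates and sequence tensors."""

import numpy as np
import pandas as pd
import pytest

from slhs.config import RunConfig
from slhs.feature_engineering import (
    build_grid,
    build_sequence,
    build_sequences_matrix,
    build_tracks,
    feature_names,
    rolling_features,
    rolling_features_matrix,
)

from conftest import ts


def _stay(admit="2022-01-01 00:00", discharge="2022-01-08 00:00"):
    return pd.Series(
        {"stay_id": "S", "admit_ts": ts(admit), "discharge_ts": ts(discharge)}
    )


def _obs(rows):
    return pd.DataFrame(rows, columns=["stay_id", "concept_id", "ts", "value", "unit"])


def test_grid_half_open_window_membership():
    obs = _obs([("S", "heart_rate", ts("2022-01-01 05:00"), 80.0, "")])
    track = build_grid(_stay(), obs, concepts=["heart_rate"])
    assert track.values[0, 0] == 80.0         # t = admit + 5 h -> window 0
    assert np.isnan(track.values[1:, 0]).all()
    assert track.n_windows == 28              # 7 days at 6 h


def test_grid_boundary_lands_in_next_window():
    obs = _obs([("S", "heart_rate", ts("2022-01-01 06:00"), 80.0, "")])
    track = build_grid(_stay(), obs, concepts=["heart_rate"])
    assert np.isnan(track.values[0, 0])
    assert track.values[1, 0] == 80.0


def test_grid_last_value_wins_within_window():
    obs = _obs([
        ("S", "heart_rate", ts("2022-01-01 01:00"), 80.0, ""),
        ("S", "heart_rate", ts("2022-01-01 05:00"), 100.0, ""),
    ])
    track = build_grid(_stay(), obs, concepts=["heart_rate"])
    assert track.values[0, 0] == 100.0


def test_grid_absent_concept_all_missing():
    obs = _obs([("S", "heart_rate", ts("2022-01-01 01:00"), 80.0, "")])
    track = build_grid(_stay(), obs, concepts=["heart_rate", "lactate"])
    assert np.isnan(track.values[:, 1]).all()


def test_grid_medication_counts():
    obs = _obs([("S", "heart_rate", ts("2022-01-01 01:00"), 80.0, "")])
    meds = pd.DataFrame(
        {
            "stay_id": ["S", "S", "S"],
            "drug_class": ["antibiotic", "antibiotic", "vasopressor"],
            "admin_ts": [ts("2022-01-01 01:00"), ts("2022-01-01 02:00"),
                         ts("2022-01-01 10:00")],
        }
    )
    track = build_grid(_stay(), obs, meds,
                       concepts=["heart_rate", "antibiotic", "vasopressor"])
    assert track.values[0, 1] == 2.0
    assert track.values[1, 2] == 1.0


def test_grid_rejects_bad_window_hours():
    with pytest.raises(ValueError, match="divide 24"):
        build_grid(_stay(), _obs([]), window_hours=7, concepts=["heart_rate"])


# ---------------------------------------------------------------------------
# rolling features


def test_rolling_constant_series_aggregators_agree():
    rows = [("S", "hr", ts("2022-01-01") + pd.Timedelta(hours=6 * k + 1), 88.0, "")
            for k in range(8)]
    track = build_grid(_stay(), _obs(rows), concepts=["hr"])
    reg = [("hr", ("last", "min", "max", "mean", "count", "slope"))]
    v = rolling_features(track, 7, feature_registry=reg)
    last, vmin, vmax, mean, count, slope = v[:6]
    assert last == vmin == vmax == mean == 88.0
    assert count == 8
    assert slope == 0.0


def test_rolling_count_zero_when_absent():
    track = build_grid(_stay(), _obs([]), concepts=["hr"])
    reg = [("hr", ("count",))]
    assert rolling_features(track, 5, feature_registry=reg)[0] == 0.0


def test_rolling_slope_matches_least_squares():
    vals = [1.0, 2.0, 3.0, 4.0]
    rows = [("S", "hr", ts("2022-01-01") + pd.Timedelta(hours=6 * k + 1), v, "")
            for k, v in enumerate(vals)]
    track = build_grid(_stay(), _obs(rows), concepts=["hr"])
    reg = [("hr", ("slope",))]
    got = rolling_features(track, 3, feature_registry=reg)[0]
    # closed-form least squares over window index within the trailing span:
    # points land at span steps 24..27
    x = np.array([24, 25, 26, 27], dtype=float)
    y = np.array(vals)
    expected = np.polyfit(x, y, 1)[0]
    assert got == pytest.approx(expected)
    assert got > 0


def test_rolling_fill_value_used_for_empty_span():
    track = build_grid(_stay(), _obs([]), concepts=["hr"])
    reg = [("hr", ("last", "mean"))]
    v = rolling_features(track, 0, feature_registry=reg, fill_values={"hr": 75.0})
    assert tuple(v[:2]) == (75.0, 75.0)


def test_feature_dimension_formula(small_registry, run_config):
    tracks = build_tracks(small_registry, run_config)
    names = feature_names(run_config.feature_registry)
    n_expected = sum(len(a) for _, a in run_config.feature_registry) + 2
    assert len(names) == n_expected
    track = next(iter(tracks.values()))
    X = rolling_features_matrix(track, feature_registry=run_config.feature_registry)
    assert X.shape == (track.n_windows, n_expected)
    assert np.isfinite(X).all()


def test_shift_invariance_whole_days():
    """Translating all timestamps by whole days leaves features unchanged."""
    rows = [("S", "hr", ts("2022-01-01") + pd.Timedelta(hours=h), 70.0 + h, "")
            for h in (1.0, 9.0, 26.0, 50.0)]
    reg = [("hr", ("last", "min", "max", "mean", "count", "slope"))]
    track_a = build_grid(_stay(), _obs(rows), concepts=["hr"])
    shifted = _obs(
        [(s, c, t + pd.Timedelta(days=3), v, u) for s, c, t, v, u in
         _obs(rows).itertuples(index=False)]
    )
    track_b = build_grid(
        _stay("2022-01-04 00:00", "2022-01-11 00:00"), shifted, concepts=["hr"]
    )
    Xa = rolling_features_matrix(track_a, feature_registry=reg)
    Xb = rolling_features_matrix(track_b, feature_registry=reg)
    np.testing.assert_allclose(Xa, Xb)


def test_out_of_range_window_index_rejected():
    track = build_grid(_stay(), _obs([]), concepts=["hr"])
    with pytest.raises(IndexError):
        rolling_features(track, 999, feature_registry=[("hr", ("count",))])


# ---------------------------------------------------------------------------
# sequence tensors


def test_sequence_shape_and_padding():
    track = build_grid(_stay(), _obs([]), concepts=["hr"])
    seq = build_sequence(track, 0, sequence_concepts=["hr"])
    assert seq.shape == (28, 2)               # 7 days x 4 windows, value+mask
    # k = 0: 27 pre-admission padded steps, one real step
    assert (seq[:27] == 0).all()


def test_sequence_mask_counts_observations():
    rows = [
        ("S", "hr", ts("2022-01-01 01:00"), 70.0, ""),
        ("S", "hr", ts("2022-01-01 13:00"), 75.0, ""),
        ("S", "sbp", ts("2022-01-02 01:00"), 120.0, ""),
    ]
    track = build_grid(_stay(), _obs(rows), concepts=["hr", "sbp"])
    seq = build_sequence(track, 27, sequence_concepts=["hr", "sbp"])
    # mask channels are the last 2; brute-force count of observed pairs
    assert seq[:, 2:].sum() == 3


def test_sequence_forward_fill_limited_and_masked():
    rows = [("S", "hr", ts("2022-01-01 01:00"), 70.0, "")]
    track = build_grid(_stay(), _obs(rows), concepts=["hr"])
    seqs = build_sequences_matrix(track, sequence_concepts=["hr"],
                                  fill_values={"hr": 99.0})
    k = 27
    seq = seqs[k]
    # step 0 of the span = window 0 (observed); next 8 windows forward-filled
    assert seq[0, 0] == 70.0 and seq[0, 1] == 1.0
    assert seq[1, 0] == 70.0 and seq[1, 1] == 0.0   # imputed, mask 0
    assert seq[8, 0] == 70.0
    # beyond the 48 h limit: population fill value
    assert seq[9, 0] == 99.0


def test_imputation_preserves_observed_windows(small_registry, run_config):
    tracks = build_tracks(small_registry, run_config)
    track = max(tracks.values(), key=lambda t: t.n_windows)
    concepts = list(run_config.sequence_concepts)
    seqs = build_sequences_matrix(track, sequence_concepts=concepts)
    k = track.n_windows - 1
    j = [track._concept_idx[c] for c in concepts]
    raw = track.values[:, j]
    span = raw[max(0, k - 27):k + 1]
    n_obs = (~np.isnan(span)).sum()
    C = len(concepts)
    masks = seqs[k][:, C:]
    assert masks.sum() == n_obs
    # observed entries keep their raw values
    offset = 28 - span.shape[0]
    wi, ci = np.nonzero(~np.isnan(span))
    np.testing.assert_allclose(seqs[k][wi + offset, ci], span[wi, ci])


def test_build_tracks_matches_build_grid(micro_registry, run_config):
    tracks = build_tracks(micro_registry, run_config)
    stay = micro_registry.stays.iloc[0]
    sid = stay["stay_id"]
    obs = micro_registry.observations.query("stay_id == @sid")
    meds = micro_registry.medications.query("stay_id == @sid")
    solo = build_grid(stay, obs, meds,
                      concepts=[c for c, _ in run_config.feature_registry])
    np.testing.assert_array_equal(
        np.nan_to_num(solo.values, nan=-1), np.nan_to_num(tracks[sid].values, nan=-1)
    )
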
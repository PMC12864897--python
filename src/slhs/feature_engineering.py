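"""Window grid, rolling-window features, and sequence tensors.

Each stay is cut into contiguous half-open 6-hour windows anchored at
admission and covering ``[admit_ts, discharge_ts)``. Two embeddings are
derived per window ``k``:

* a fixed-order feature vector for the tree sub-model — per concept, six
  aggregators (last, min, max, mean, count, slope) over the trailing
  7-day span ``(k - 27 .. k]`` clipped at admission, plus age and sex;
* a right-aligned sequence tensor for the recurrent sub-model — 28 steps
  (7 days x 4 windows/day) of per-concept values with observed-mask
  channels, pre-admission steps zero-padded with mask 0.

Missing data: sequence values are forward-filled within the stay up to
48 h, then filled with a population-level per-concept value; every imputed
entry keeps mask 0 so models can learn missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "WindowTrack",
    "build_grid",
    "build_tracks",
    "rolling_features",
    "rolling_features_matrix",
    "build_sequence",
    "build_sequences_matrix",
    "feature_names",
]

#: forward-fill horizon for sequence channels, in hours
FFILL_LIMIT_HOURS = 48


@dataclass
class WindowTrack:
    """Resampled 6-hour grid of one stay."""

    stay_id: str
    admit_ts: pd.Timestamp
    window_hours: int
    concepts: list[str]
    values: np.ndarray          # (n_windows, n_concepts); NaN = unobserved
    age: float = np.nan
    sex_male: float = np.nan
    labels: np.ndarray | None = None        # per-window coarse labels
    probs: np.ndarray | None = None         # per-window (NS, PS, CS) triples
    _concept_idx: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._concept_idx = {c: i for i, c in enumerate(self.concepts)}

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def window_start(self, k: int) -> pd.Timestamp:
        return self.admit_ts + pd.Timedelta(hours=self.window_hours * k)

    def window_starts(self) -> pd.Series:
        return pd.Series(
            self.admit_ts
            + pd.to_timedelta(np.arange(self.n_windows) * self.window_hours, unit="h")
        )

    @property
    def obs_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _n_windows(admit_ts, discharge_ts, window_hours: int) -> int:
    span_h = (discharge_ts - admit_ts).total_seconds() / 3600.0
    return max(int(np.ceil(span_h / window_hours)), 1)


def build_grid(
    stay: pd.Series,
    observations: pd.DataFrame,
    medications: pd.DataFrame | None = None,
    *,
    window_hours: int = 6,
    concepts: list[str] | None = None,
) -> WindowTrack:
    """Resample one stay's observations onto the 6-hour grid.

    Per window and concept the *last* observed value wins (vitals/labs);
    medication channels carry per-window administration counts. Windows
    with no observation of a concept hold NaN.
    """
    if 24 % window_hours != 0:
        raise ValueError(f"window_hours={window_hours} must divide 24")
    admit, discharge = stay["admit_ts"], stay["discharge_ts"]
    W = _n_windows(admit, discharge, window_hours)

    if concepts is None:
        concepts = sorted(observations["concept_id"].unique())
        if medications is not None and len(medications):
            concepts = sorted(set(concepts) | set(medications["drug_class"].unique()))
    idx = {c: i for i, c in enumerate(concepts)}
    vals = np.full((W, len(concepts)), np.nan)

    obs = observations.loc[observations["concept_id"].isin(idx)]
    if len(obs):
        k = ((obs["ts"] - admit).dt.total_seconds() // (3600 * window_hours)).astype(int)
        ok = (k >= 0) & (k < W)
        obs = obs.loc[ok].assign(_k=k[ok]).sort_values("ts")
        last = obs.groupby(["concept_id", "_k"])["value"].last()
        for (c, kk), v in last.items():
            vals[kk, idx[c]] = v

    if medications is not None and len(medications):
        med = medications.loc[medications["drug_class"].isin(idx)]
        if len(med):
            k = ((med["admin_ts"] - admit).dt.total_seconds()
                 // (3600 * window_hours)).astype(int)
            ok = (k >= 0) & (k < W)
            counts = med.loc[ok].assign(_k=k[ok]).groupby(["drug_class", "_k"]).size()
            for (c, kk), n in counts.items():
                vals[kk, idx[c]] = n

    return WindowTrack(
        stay_id=str(stay["stay_id"]),
        admit_ts=admit,
        window_hours=window_hours,
        concepts=list(concepts),
        values=vals,
    )


def build_tracks(registry, config: RunConfig) -> dict[str, WindowTrack]:
    """Vectorized grid construction for every stay of a registry.

    Produces the same tracks as :func:`build_grid` per stay, in one pass
    over the observation table. Age at admission and sex are attached for
    the demographic feature terms.
    """
    concepts = [c for c, _ in config.feature_registry]
    idx = {c: i for i, c in enumerate(concepts)}
    wh = config.window_hours

    stays = registry.stays.merge(registry.patients, on="patient_id", how="left")
    stays = stays.assign(
        n_win=[_n_windows(a, d, wh) for a, d in zip(stays["admit_ts"],
                                                    stays["discharge_ts"])],
        age_adm=stays["admit_ts"].dt.year - stays["birth_year"],
        male=(stays["sex"] == "M").astype(float),
    )
    admit_map = dict(zip(stays["stay_id"], stays["admit_ts"]))
    W_map = dict(zip(stays["stay_id"], stays["n_win"]))

    tracks: dict[str, WindowTrack] = {}
    for r in stays.itertuples(index=False):
        tracks[r.stay_id] = WindowTrack(
            stay_id=r.stay_id,
            admit_ts=r.admit_ts,
            window_hours=wh,
            concepts=concepts,
            values=np.full((r.n_win, len(concepts)), np.nan),
            age=float(r.age_adm),
            sex_male=float(r.male),
        )

    obs = registry.observations
    obs = obs.loc[obs["concept_id"].isin(idx)].copy()
    if len(obs):
        obs["_admit"] = obs["stay_id"].map(admit_map)
        obs["_k"] = ((obs["ts"] - obs["_admit"]).dt.total_seconds()
                     // (3600 * wh)).astype(int)
        obs["_Wmax"] = obs["stay_id"].map(W_map)
        obs = obs.loc[(obs["_k"] >= 0) & (obs["_k"] < obs["_Wmax"])]
        obs = obs.sort_values("ts")
        last = obs.groupby(["stay_id", "concept_id", "_k"], sort=False)["value"].last()
        sid = last.index.get_level_values(0).to_numpy()
        cid = np.array([idx[c] for c in last.index.get_level_values(1)])
        kk = last.index.get_level_values(2).to_numpy()
        vv = last.to_numpy()
        for s, c, k, v in zip(sid, cid, kk, vv):
            tracks[s].values[k, c] = v

    med = registry.medications
    med = med.loc[med["drug_class"].isin(idx)].copy()
    if len(med):
        med["_admit"] = med["stay_id"].map(admit_map)
        med["_k"] = ((med["admin_ts"] - med["_admit"]).dt.total_seconds()
                     // (3600 * wh)).astype(int)
        med["_Wmax"] = med["stay_id"].map(W_map)
        med = med.loc[(med["_k"] >= 0) & (med["_k"] < med["_Wmax"])]
        counts = med.groupby(["stay_id", "drug_class", "_k"], sort=False).size()
        for (s, c, k), n in counts.items():
            tracks[s].values[k, idx[c]] = n

    return tracks


# ---------------------------------------------------------------------------
# rolling aggregate features (tree sub-model)

AGG_NAMES = ("last", "min", "max", "mean", "count", "slope")


def feature_names(feature_registry) -> list[str]:
    names = [f"{c}__{agg}" for c, aggs in feature_registry for agg in aggs]
    return names + ["age", "sex_male"]


def _trailing_view(values: np.ndarray, span: int) -> np.ndarray:
    """(W, span, C) trailing view: row k holds windows (k-span+1 .. k]."""
    W, C = values.shape
    padded = np.full((W + span - 1, C), np.nan)
    padded[span - 1:] = values
    return np.lib.stride_tricks.sliding_window_view(padded, span, axis=0).transpose(
        0, 2, 1
    )


def rolling_features_matrix(
    track: WindowTrack,
    *,
    lookback_windows: int = 28,
    feature_registry=None,
    fill_values: dict[str, float] | None = None,
) -> np.ndarray:
    """(n_windows, n_features) aggregate features for every window at once.

    Aggregators run over the trailing ``lookback_windows`` span clipped at
    admission. Value aggregates of concepts unobserved in the span are
    filled from ``fill_values`` (population medians; 0 if absent); ``count``
    doubles as the missingness indicator.
    """
    if feature_registry is None:
        feature_registry = [(c, AGG_NAMES) for c in track.concepts]
    fill_values = fill_values or {}

    view = _trailing_view(track.values, lookback_windows)  # (W, S, C)
    W, S, C = view.shape
    observed = ~np.isnan(view)
    count = observed.sum(axis=1).astype(float)              # (W, C)
    any_obs = count > 0

    with np.errstate(all="ignore"):
        vmin = np.where(any_obs, np.where(observed, view, np.inf).min(axis=1), np.nan)
        vmax = np.where(any_obs, np.where(observed, view, -np.inf).max(axis=1), np.nan)
        vmean = np.where(observed, view, 0.0).sum(axis=1) / np.where(any_obs, count, np.nan)

    # last observed value in the span
    step_idx = np.arange(S)[None, :, None]
    last_pos = np.where(observed, step_idx, -1).max(axis=1)  # (W, C)
    vlast = np.full((W, C), np.nan)
    wi, ci = np.nonzero(last_pos >= 0)
    vlast[wi, ci] = view[wi, last_pos[wi, ci], ci]

    # least-squares slope of value on window index, observed points only
    x = np.arange(S, dtype=float)[None, :, None]
    xm = np.where(observed, x, 0.0)
    ym = np.where(observed, view, 0.0)
    n = count
    with np.errstate(all="ignore"):
        xbar = xm.sum(axis=1) / n
        ybar = ym.sum(axis=1) / n
        sxy = (np.where(observed, (x - xbar[:, None, :]) * (view - ybar[:, None, :]), 0.0)).sum(axis=1)
        sxx = (np.where(observed, (x - xbar[:, None, :]) ** 2, 0.0)).sum(axis=1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    slope = np.where(n >= 2, slope, 0.0)

    agg_arrays = {"last": vlast, "min": vmin, "max": vmax, "mean": vmean,
                  "count": count, "slope": slope}

    cols = []
    cidx = {c: i for i, c in enumerate(track.concepts)}
    for concept, aggs in feature_registry:
        j = cidx[concept]
        fill = fill_values.get(concept, 0.0)
        for agg in aggs:
            col = agg_arrays[agg][:, j].copy()
            if agg in ("last", "min", "max", "mean"):
                col[np.isnan(col)] = fill
            cols.append(col)
    cols.append(np.full(W, track.age))
    cols.append(np.full(W, track.sex_male))
    return np.column_stack(cols)


def rolling_features(
    track: WindowTrack,
    k: int,
    *,
    lookback_windows: int = 28,
    feature_registry=None,
    fill_values: dict[str, float] | None = None,
) -> np.ndarray:
    """Feature vector of window ``k`` (row ``k`` of the full matrix)."""
    if not (0 <= k < track.n_windows):
        raise IndexError(f"window index {k} out of range [0, {track.n_windows})")
    return rolling_features_matrix(
        track,
        lookback_windows=lookback_windows,
        feature_registry=feature_registry,
        fill_values=fill_values,
    )[k]


# ---------------------------------------------------------------------------
# sequence tensors (recurrent sub-model)


def _ffilled_values(track: WindowTrack, concepts: list[str],
                    fill_values: dict[str, float] | None) -> tuple[np.ndarray, np.ndarray]:
    fill_values = fill_values or {}
    j = [track._concept_idx[c] for c in concepts]
    raw = track.values[:, j]
    mask = ~np.isnan(raw)
    limit = max(int(FFILL_LIMIT_HOURS // track.window_hours), 1)
    filled = (
        pd.DataFrame(raw).ffill(limit=limit).to_numpy()
    )
    fills = np.array([fill_values.get(c, 0.0) for c in concepts])
    filled = np.where(np.isnan(filled), fills[None, :], filled)
    return filled, mask


def build_sequence(
    track: WindowTrack,
    k: int,
    *,
    sequence_concepts: list[str] | None = None,
    lookback_windows: int = 28,
    fill_values: dict[str, float] | None = None,
) -> np.ndarray:
    """(steps, 2 x n_concepts) tensor for window ``k``.

    Steps are the trailing ``lookback_windows`` windows ending at ``k``,
    right-aligned; steps before admission are zero with mask 0. Channels:
    forward-filled/imputed values followed by observed masks.
    """
    if not (0 <= k < track.n_windows):
        raise IndexError(f"window index {k} out of range [0, {track.n_windows})")
    return build_sequences_matrix(
        track,
        sequence_concepts=sequence_concepts,
        lookback_windows=lookback_windows,
        fill_values=fill_values,
    )[k]


def build_sequences_matrix(
    track: WindowTrack,
    *,
    sequence_concepts: list[str] | None = None,
    lookback_windows: int = 28,
    fill_values: dict[str, float] | None = None,
) -> np.ndarray:
    """(n_windows, steps, 2 x n_concepts) tensors for all windows."""
    concepts = list(sequence_concepts or track.concepts)
    filled, mask = _ffilled_values(track, concepts, fill_values)
    W, C = filled.shape
    S = lookback_windows

    pad_vals = np.zeros((W + S - 1, C))
    pad_vals[S - 1:] = filled
    pad_mask = np.zeros((W + S - 1, C))
    pad_mask[S - 1:] = mask

    val_view = np.lib.stride_tricks.sliding_window_view(pad_vals, S, axis=0)
    mask_view = np.lib.stride_tricks.sliding_window_view(pad_mask, S, axis=0)
    # -> (W, C, S) -> (W, S, C)
    val_view = val_view.transpose(0, 2, 1)
    mask_view = mask_view.transpose(0, 2, 1)
    # zero out value channels on pre-admission padding steps
    steps = np.arange(S)
    real = (steps[None, :] >= (S - 1 - np.arange(W))[:, None]).astype(float)
    out = np.concatenate(
        [val_view * real[:, :, None], mask_view * real[:, :, None]], axis=2
    )
    return out
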
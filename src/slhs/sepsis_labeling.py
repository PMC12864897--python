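"""Training-label logic for suspected-sepsis events.

Every adjudicated event carries one of six fine labels, informed by the
Sepsis-3 consensus definitions:

======================  ====================================================
``0_no_infection``      no infection
``0_infection``         infection without organ failure, delta-SOFA < 2
``1a_sepsis_like``      infection with organ dysfunction signal but the
                        delta-SOFA criterion unmet or unassessable
``1b_sepsis_sensu_lato`` infection, delta-SOFA >= 2, but an alternative
                        etiology explains the organ dysfunction
``2a_sepsis_sensu_stricto`` infection + organ failure + delta-SOFA >= 2,
                        no alternative etiology
``2b_septic_shock``     sepsis sensu stricto + vasopressor + lactate > 2
======================  ====================================================

Fine labels collapse to the coarse three-class target NS < PS < CS
(no / possible / confirmed sepsis) the classifier is trained on. Windows of
the 6-hour grid are labeled by the most severe event whose onset time t0
falls inside the window's trailing lookback span.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "FineLabel",
    "CoarseLabel",
    "EventFacts",
    "InconsistentFactsError",
    "classify_event",
    "collapse_label",
    "label_windows",
    "derive_event_facts",
    "stay_truth_label",
]


class FineLabel(str, Enum):
    NO_INFECTION = "0_no_infection"
    INFECTION = "0_infection"
    SEPSIS_LIKE = "1a_sepsis_like"
    SEPSIS_SENSU_LATO = "1b_sepsis_sensu_lato"
    SEPSIS_SENSU_STRICTO = "2a_sepsis_sensu_stricto"
    SEPTIC_SHOCK = "2b_septic_shock"

    @property
    def severity(self) -> int:
        return _FINE_SEVERITY[self]


_FINE_SEVERITY = {
    FineLabel.NO_INFECTION: 0,
    FineLabel.INFECTION: 1,
    FineLabel.SEPSIS_LIKE: 2,
    FineLabel.SEPSIS_SENSU_LATO: 3,
    FineLabel.SEPSIS_SENSU_STRICTO: 4,
    FineLabel.SEPTIC_SHOCK: 5,
}


class CoarseLabel(str, Enum):
    NS = "NS"  # no sepsis
    PS = "PS"  # possible sepsis
    CS = "CS"  # confirmed sepsis

    @property
    def severity(self) -> int:
        return {"NS": 0, "PS": 1, "CS": 2}[self.value]


class InconsistentFactsError(ValueError):
    """The adjudicated facts contradict each other."""


@dataclass(frozen=True)
class EventFacts:
    """Adjudicated and measured facts feeding the label decision."""

    infection: bool                 # suspected or confirmed infection
    organ_failure: bool             # organ failure attributed to the infection
    delta_sofa: int | None          # None = missing SOFA information
    alternative_etiology: bool      # alternative explanation for dysfunction
    vasopressor_given: bool
    lactate_gt_2: bool

    def __post_init__(self) -> None:
        if self.delta_sofa is not None and self.delta_sofa < 0:
            raise ValueError("delta_sofa must be >= 0 when present")


def classify_event(facts: EventFacts) -> FineLabel:
    """Map adjudicated facts to the six-way fine label.

    Deterministic; when several rows could be read as matching, the most
    severe applicable label wins. Facts that attribute organ failure to an
    absent infection are rejected as inconsistent.
    """
    if not facts.infection:
        if facts.organ_failure:
            raise InconsistentFactsError(
                "organ failure attributed to infection, but no infection recorded"
            )
        return FineLabel.NO_INFECTION

    d = facts.delta_sofa
    if d is not None and d >= 2:
        if facts.alternative_etiology:
            return FineLabel.SEPSIS_SENSU_LATO
        if facts.organ_failure:
            if facts.vasopressor_given and facts.lactate_gt_2:
                return FineLabel.SEPTIC_SHOCK
            return FineLabel.SEPSIS_SENSU_STRICTO
        # acute SOFA rise not attributed to the infection by the reviewer:
        # organ-dysfunction signal without the sensu-stricto attribution
        return FineLabel.SEPSIS_LIKE
    if d is None:
        return FineLabel.SEPSIS_LIKE  # missing SOFA information
    if facts.organ_failure:
        return FineLabel.SEPSIS_LIKE  # clinical organ failure, delta < 2
    return FineLabel.INFECTION


def collapse_label(fine: FineLabel) -> CoarseLabel:
    """Six-way fine label -> NS / PS / CS coarse class."""
    fine = FineLabel(fine)
    if fine in (FineLabel.NO_INFECTION, FineLabel.INFECTION):
        return CoarseLabel.NS
    if fine in (FineLabel.SEPSIS_LIKE, FineLabel.SEPSIS_SENSU_LATO):
        return CoarseLabel.PS
    return CoarseLabel.CS


def derive_event_facts(
    event: pd.Series,
    observations: pd.DataFrame,
    medications: pd.DataFrame,
    *,
    stay_interval: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    post_hours: float = 72.0,
) -> EventFacts:
    """Recompute an event's measured facts from the registry data.

    The adjudication flags (infection, organ failure attribution,
    alternative etiology) come from the event's review-form fields; the
    measured facts (delta-SOFA, post-onset vasopressor, post-onset lactate
    > 2 mmol/L) are recomputed from observations and medications.
    """
    from .clinical_scores import delta_sofa as _delta_sofa

    t0 = event["t0"]
    end = t0 + pd.Timedelta(hours=post_hours)
    if stay_interval is not None:
        end = min(end, stay_interval[1])

    ds = _delta_sofa(
        observations, t0, medications=medications, stay_interval=stay_interval,
        post_hours=post_hours,
    )
    vaso = bool(
        (
            (medications["drug_class"] == "vasopressor")
            & (medications["admin_ts"] >= t0)
            & (medications["admin_ts"] <= end)
        ).any()
    )
    lact = observations.loc[
        (observations["concept_id"] == "lactate")
        & (observations["ts"] >= t0)
        & (observations["ts"] <= end)
    ]
    lact_gt2 = bool((lact["value"] > 2.0).any())

    return EventFacts(
        infection=bool(event["infection"]),
        organ_failure=bool(event["organ_failure"]),
        delta_sofa=None if ds.missing else int(ds.value),
        alternative_etiology=bool(event["alternative_etiology"]),
        vasopressor_given=vaso,
        lactate_gt_2=lact_gt2,
    )


def label_windows(
    window_starts: pd.Series | np.ndarray,
    events: pd.DataFrame,
    *,
    window_hours: int = 6,
    lookback_days: int = 7,
) -> np.ndarray:
    """Per-window coarse labels from event onset times.

    A window is labeled with the collapsed most-severe fine label among
    events whose t0 falls in the trailing lookback span
    ``(window_end - lookback, window_end]``; windows overlapping no onset
    are NS.
    """
    starts = pd.to_datetime(pd.Series(np.asarray(window_starts)), utc=True)
    ends = starts + pd.Timedelta(hours=window_hours)
    lookback = pd.Timedelta(days=lookback_days)
    out = np.array([CoarseLabel.NS.value] * len(starts), dtype=object)
    if events is None or not len(events):
        return out
    sev = np.zeros(len(starts), dtype=int)
    for _, ev in events.iterrows():
        coarse = collapse_label(FineLabel(ev["fine_label"]))
        t0 = ev["t0"]
        hit = ((ends - lookback) < t0) & (t0 <= ends)
        sev = np.where(hit.to_numpy() & (coarse.severity > sev), coarse.severity, sev)
    lut = {0: "NS", 1: "PS", 2: "CS"}
    return np.array([lut[s] for s in sev], dtype=object)


def stay_truth_label(events: pd.DataFrame) -> CoarseLabel:
    """Most severe event-derived coarse label of a stay (NS if no events)."""
    if events is None or not len(events):
        return CoarseLabel.NS
    best = max(
        (collapse_label(FineLabel(v)) for v in events["fine_label"]),
        key=lambda c: c.severity,
    )
    return best
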
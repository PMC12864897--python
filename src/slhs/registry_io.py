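"""Tabular sepsis-registry container, validation, and on-disk round trip.

The registry is the study universe: patients, stays, ward segments,
timestamped observations, medication administrations, clinician-adjudicated
suspected-sepsis events, ICD-10 discharge codes. Storage is one CSV per
table with ISO-8601 UTC timestamps at minute resolution; all intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Registry",
    "RegistryError",
    "MissingFileError",
    "SchemaError",
    "IntegrityError",
    "read_registry",
    "write_registry",
    "write_report",
]


class RegistryError(Exception):
    """Base class for registry validation failures."""


class MissingFileError(RegistryError):
    """A registry table file is absent."""


class SchemaError(RegistryError):
    """A table does not conform to the documented column schema."""


class IntegrityError(RegistryError):
    """A referential-integrity or interval invariant is violated."""


# table -> {column: kind}; kinds: str, int, float, bool, ts, ts?
SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {"patient_id": "str", "sex": "str", "birth_year": "int"},
    "stays": {
        "stay_id": "str",
        "patient_id": "str",
        "admit_ts": "ts",
        "discharge_ts": "ts",
        "in_hospital_death": "bool",
        "death_ts": "ts?",
    },
    "ward_segments": {
        "stay_id": "str",
        "ward_id": "str",
        "ward_group": "str",
        "start_ts": "ts",
        "end_ts": "ts",
    },
    "observations": {
        "stay_id": "str",
        "concept_id": "str",
        "ts": "ts",
        "value": "float",
        "unit": "str",
    },
    "medications": {"stay_id": "str", "drug_class": "str", "admin_ts": "ts"},
    "events": {
        "event_id": "str",
        "stay_id": "str",
        "t0": "ts",
        "fine_label": "str",
        "source": "str",
        "infection": "bool",
        "organ_failure": "bool",
        "alternative_etiology": "bool",
    },
    "icd_codes": {"stay_id": "str", "code": "str"},
}

WARD_GROUPS = ("MED", "GIS", "EMD", "CONTROL", "OTHER")
DRUG_CLASSES = ("antibiotic", "vasopressor", "other")
EVENT_SOURCES = ("orderset", "id_consult")


@dataclass
class Registry:
    """In-memory registry: one DataFrame per table (see :data:`SCHEMAS`)."""

    patients: pd.DataFrame
    stays: pd.DataFrame
    ward_segments: pd.DataFrame
    observations: pd.DataFrame
    medications: pd.DataFrame
    events: pd.DataFrame
    icd_codes: pd.DataFrame

    def table_names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def validate(self) -> "Registry":
        """Check schemas and all structural invariants; raise on violation."""
        for name in self.table_names():
            _check_schema(name, getattr(self, name))
        _check_integrity(self)
        return self

    def __eq__(self, other) -> bool:  # structural equality for round trips
        if not isinstance(other, Registry):
            return NotImplemented
        for name in self.table_names():
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            try:
                pd.testing.assert_frame_equal(a, b, check_dtype=False)
            except AssertionError:
                return False
        return True


def _check_schema(name: str, df: pd.DataFrame) -> None:
    spec = SCHEMAS[name]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{name}' lacks column(s): {', '.join(missing)}")
    for col, kind in spec.items():
        s = df[col]
        if kind in ("ts", "ts?"):
            if not pd.api.types.is_datetime64_any_dtype(s):
                raise SchemaError(f"table '{name}' column '{col}' is not datetime")
            if kind == "ts" and s.isna().any():
                row = int(s.index[s.isna()][0])
                raise SchemaError(
                    f"table '{name}' column '{col}' has a null timestamp at row {row}"
                )
        elif kind == "float":
            if not pd.api.types.is_numeric_dtype(s):
                raise SchemaError(f"table '{name}' column '{col}' is not numeric")
        elif kind == "int":
            if not pd.api.types.is_integer_dtype(s):
                raise SchemaError(f"table '{name}' column '{col}' is not integer")
        elif kind == "bool":
            if not pd.api.types.is_bool_dtype(s):
                raise SchemaError(f"table '{name}' column '{col}' is not boolean")


def _check_integrity(reg: Registry) -> None:
    stays = reg.stays
    known_stays = set(stays["stay_id"])
    known_patients = set(reg.patients["patient_id"])

    orphans = stays.loc[~stays["patient_id"].isin(known_patients)]
    if len(orphans):
        r = orphans.iloc[0]
        raise IntegrityError(
            f"stays row for stay_id={r['stay_id']!r} cites unknown "
            f"patient_id={r['patient_id']!r}"
        )
    bad = stays.loc[~(stays["admit_ts"] < stays["discharge_ts"])]
    if len(bad):
        raise IntegrityError(
            f"stay {bad.iloc[0]['stay_id']!r}: admit_ts is not before discharge_ts"
        )
    # death_ts present iff a death is recorded (in-hospital or post-discharge)
    bad = stays.loc[stays["in_hospital_death"] & stays["death_ts"].isna()]
    if len(bad):
        raise IntegrityError(
            f"stay {bad.iloc[0]['stay_id']!r}: in_hospital_death without death_ts"
        )

    for name in ("ward_segments", "observations", "medications", "events", "icd_codes"):
        df = getattr(reg, name)
        unknown = df.loc[~df["stay_id"].isin(known_stays)]
        if len(unknown):
            idx = int(unknown.index[0])
            raise IntegrityError(
                f"table '{name}' row {idx} cites unknown "
                f"stay_id={unknown.iloc[0]['stay_id']!r}"
            )

    # ward segments: within stay and non-overlapping
    seg = reg.ward_segments.merge(
        stays[["stay_id", "admit_ts", "discharge_ts"]], on="stay_id", how="left"
    )
    bad = seg.loc[(seg["start_ts"] < seg["admit_ts"]) | (seg["end_ts"] > seg["discharge_ts"])
                  | (seg["start_ts"] >= seg["end_ts"])]
    if len(bad):
        raise IntegrityError(
            f"ward segment of stay {bad.iloc[0]['stay_id']!r} outside "
            "[admit_ts, discharge_ts) or empty"
        )
    srt = reg.ward_segments.sort_values(["stay_id", "start_ts"])
    prev_end = srt.groupby("stay_id")["end_ts"].shift()
    overlap = srt.loc[prev_end.notna() & (srt["start_ts"] < prev_end)]
    if len(overlap):
        raise IntegrityError(
            f"overlapping ward segments in stay {overlap.iloc[0]['stay_id']!r}"
        )
    bad_group = reg.ward_segments.loc[~reg.ward_segments["ward_group"].isin(WARD_GROUPS)]
    if len(bad_group):
        raise SchemaError(
            f"unknown ward_group {bad_group.iloc[0]['ward_group']!r} in ward_segments"
        )

    # events: t0 inside the stay interval
    ev = reg.events.merge(
        stays[["stay_id", "admit_ts", "discharge_ts"]], on="stay_id", how="left"
    )
    bad = ev.loc[(ev["t0"] < ev["admit_ts"]) | (ev["t0"] >= ev["discharge_ts"])]
    if len(bad):
        raise IntegrityError(
            f"event {bad.iloc[0]['event_id']!r}: t0 outside its stay interval"
        )


def _parse_table(name: str, path: Path) -> pd.DataFrame:
    if not path.exists():
        raise MissingFileError(f"registry table '{name}' missing: {path}")
    spec = SCHEMAS[name]
    df = pd.read_csv(path)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table '{name}' ({path.name}) lacks column(s): {', '.join(missing)}"
        )
    for col, kind in spec.items():
        if kind in ("ts", "ts?"):
            df[col] = pd.to_datetime(df[col], format="ISO8601", utc=True)
        elif kind == "bool":
            df[col] = df[col].astype(bool)
        elif kind == "int":
            df[col] = df[col].astype(np.int64)
        elif kind == "float":
            df[col] = df[col].astype(float)
        else:
            df[col] = df[col].astype(str)
    return df[list(spec)]


def read_registry(path) -> Registry:
    """Load and validate a registry from a directory of per-table CSVs."""
    path = Path(path)
    tables = {name: _parse_table(name, path / f"{name}.csv") for name in SCHEMAS}
    return Registry(**tables).validate()


def write_registry(registry: Registry, path) -> None:
    """Write one CSV per table; timestamps serialized ISO-8601 UTC (minutes)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in registry.table_names():
        df = getattr(registry, name).copy()
        for col, kind in SCHEMAS[name].items():
            if kind in ("ts", "ts?"):
                df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        df.to_csv(path / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# report writing


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(impact, evaluation, path) -> None:
    """Emit the run report: machine-readable JSON plus a text summary.

    ``impact`` / ``evaluation`` are the ``to_dict()`` forms of an
    ImpactReport and a MetricsReport (either may be ``None``). Output is
    deterministic: identical inputs give byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "impact": _jsonable(impact) if impact is not None else "not computed",
        "evaluation": _jsonable(evaluation) if evaluation is not None else "not computed",
    }
    with open(path / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    buf = io.StringIO()
    buf.write("SLHS run report\n===============\n\n")
    buf.write("Model evaluation\n----------------\n")
    if evaluation is None:
        buf.write("not computed\n")
    else:
        for key, val in sorted(_jsonable(evaluation).items()):
            buf.write(f"{key}: {val}\n")
    buf.write("\nImpact indicators\n-----------------\n")
    if impact is None:
        buf.write("not computed\n")
    else:
        for key, val in sorted(_jsonable(impact).items()):
            buf.write(f"{key}: {val}\n")
    (path / "report.txt").write_text(buf.getvalue())
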
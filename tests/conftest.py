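"""Shared fixtures: small generated registries and a hand-built micro-registry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from slhs.config import GeneratorConfig, RunConfig
from slhs.registry_io import Registry
from slhs.synthetic_registry import generate_registry


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s, tz="UTC")


@pytest.fixture(scope="session")
def small_registry() -> Registry:
    """120-stay generated registry used across modules."""
    return generate_registry(GeneratorConfig(seed=2024, n_stays=120))


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=2024)


def make_micro_registry() -> Registry:
    """Two patients, two stays, hand-countable content."""
    patients = pd.DataFrame(
        {"patient_id": ["P0", "P1"], "sex": ["M", "F"], "birth_year": [1950, 1980]}
    )
    stays = pd.DataFrame(
        {
            "stay_id": ["S0", "S1"],
            "patient_id": ["P0", "P1"],
            "admit_ts": [ts("2022-01-01 08:00"), ts("2022-02-01 00:00")],
            "discharge_ts": [ts("2022-01-05 08:00"), ts("2022-02-03 12:00")],
            "in_hospital_death": [False, False],
            "death_ts": pd.Series([pd.NaT, pd.NaT], dtype="datetime64[ns, UTC]"),
        }
    )
    ward_segments = pd.DataFrame(
        {
            "stay_id": ["S0", "S0", "S1"],
            "ward_id": ["EMD-1", "MED-2", "CONTROL-1"],
            "ward_group": ["EMD", "MED", "CONTROL"],
            "start_ts": [ts("2022-01-01 08:00"), ts("2022-01-02 00:00"),
                         ts("2022-02-01 00:00")],
            "end_ts": [ts("2022-01-02 00:00"), ts("2022-01-05 08:00"),
                       ts("2022-02-03 12:00")],
        }
    )
    observations = pd.DataFrame(
        {
            "stay_id": ["S0"] * 4 + ["S1"] * 2,
            "concept_id": ["heart_rate", "heart_rate", "lactate", "platelets",
                           "heart_rate", "creatinine"],
            "ts": [ts("2022-01-01 09:00"), ts("2022-01-01 13:30"),
                   ts("2022-01-02 10:00"), ts("2022-01-01 10:00"),
                   ts("2022-02-01 04:00"), ts("2022-02-01 06:00")],
            "value": [80.0, 100.0, 1.1, 250.0, 72.0, 70.0],
            "unit": ["/min", "/min", "mmol/L", "1e9/L", "/min", "umol/L"],
        }
    )
    medications = pd.DataFrame(
        {
            "stay_id": ["S0"],
            "drug_class": ["antibiotic"],
            "admin_ts": [ts("2022-01-02 12:00")],
        }
    )
    events = pd.DataFrame(
        {
            "event_id": ["E0"],
            "stay_id": ["S0"],
            "t0": [ts("2022-01-02 09:00")],
            "fine_label": ["2a_sepsis_sensu_stricto"],
            "source": ["orderset"],
            "infection": [True],
            "organ_failure": [True],
            "alternative_etiology": [False],
        }
    )
    icd_codes = pd.DataFrame(
        {"stay_id": ["S0", "S0"], "code": ["A41.9", "I21.0"]}
    )
    return Registry(
        patients=patients,
        stays=stays,
        ward_segments=ward_segments,
        observations=observations,
        medications=medications,
        events=events,
        icd_codes=icd_codes,
    ).validate()


@pytest.fixture()
def micro_registry() -> Registry:
    return make_micro_registry()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
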
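"""Shared fixtures: tiny hand-built cohorts and standard simulated ones."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mousedls.simulate import (
    ReadoutModel,
    default_readout_models,
    default_sim_config,
    simulate_cohort,
)
from mousedls.types import (
    CohortDataset,
    Direction,
    RDoCDomain,
    ReadoutCriterion,
    ReadoutSpec,
)


def make_frame(rows):
    """rows: (animal_id, group, readout, session_day, value)."""
    return pd.DataFrame(
        [
            {
                "animal_id": a,
                "group": g,
                "sex": "unspecified",
                "readout": r,
                "session_day": float(d),
                "value": float(v),
            }
            for a, g, r, d, v in rows
        ]
    )


def simple_spec(name, criterion=ReadoutCriterion.BIOLOGICAL,
                direction=Direction.HIGHER_IS_IMPAIRED, symptom="",
                longitudinal=False):
    return ReadoutSpec(
        readout=name,
        criterion=criterion,
        direction=direction,
        rdoc_domain=RDoCDomain.NEGATIVE_VALENCE,
        symptom_label=symptom,
        longitudinal=longitudinal,
    )


@pytest.fixture
def tiny_dataset():
    """2 read-outs x 2 groups x 3 animals, single session, valid."""
    rows = []
    for i, v in enumerate([10.0, 12.0, 14.0]):
        rows.append((f"I{i}", "interest", "cort", 0, v + 3))
        rows.append((f"C{i}", "control", "cort", 0, v))
        rows.append((f"I{i}", "interest", "sucrose", 0, 0.6 + 0.05 * i))
        rows.append((f"C{i}", "control", "sucrose", 0, 0.8 + 0.05 * i))
    specs = [
        simple_spec("cort", symptom="hpa"),
        simple_spec(
            "sucrose",
            criterion=ReadoutCriterion.ANHEDONIA,
            direction=Direction.LOWER_IS_IMPAIRED,
            symptom="anhedonia",
        ),
    ]
    return CohortDataset(make_frame(rows), specs)


@pytest.fixture(scope="session")
def strong_cohort():
    """Default study conditions: d = 1.5 everywhere, n = 12, 8-day span."""
    return simulate_cohort(default_sim_config(seed=123))


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(default_sim_config(effect_d=0.0, seed=456))


def models_with_effects(effect_by_readout: dict[str, float], base_d: float = 1.5):
    """Default panel with per-read-out effect overrides."""
    models = default_readout_models(base_d)
    return {
        name: dataclasses.replace(m, effect_d=effect_by_readout.get(name, m.effect_d))
        for name, m in models.items()
    }
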
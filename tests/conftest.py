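"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ramanidh import CohortConfig, SpectraSet, generate_cohort
from ramanidh.benchmarks import (  # noqa: F401  (re-exported for tests)
    ALL_CATALOGUE_SHIFTS as ALL_TEST_SHIFTS,
    NEUTRAL_SHIFTS,
    PLANTED_SHIFTS,
    SHARED_SHIFTS,
    planted_cohort_config,
    planted_peak_specs,
    planted_peak_table,
)


def noiseless_config(seed: int = 0, **overrides) -> CohortConfig:
    base = dict(
        n_patients_per_class=3,
        spectra_per_patient=4,
        baseline_coeff_scale=0.0,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        noise_sd=0.0,
        cosmic_ray_rate=0.0,
        patient_effect_sd=0.0,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort() -> SpectraSet:
    """100 spectra, 10 patients, default artefacts — the workhorse fixture."""
    return generate_cohort(
        CohortConfig(n_patients_per_class=5, spectra_per_patient=10, seed=11)
    )


@pytest.fixture(scope="session")
def clean_cohort() -> SpectraSet:
    """Artefact-free cohort: spectra equal the noise-free band model."""
    return generate_cohort(noiseless_config(seed=3))


def flat_set(n: int = 20, level: float = 1.0, n_points: int = 200) -> SpectraSet:
    """n identical flat spectra — degenerate input for filter steps."""
    axis = np.linspace(400.0, 1750.0, n_points)
    meta = pd.DataFrame(
        {
            "point_id": [f"p{i}" for i in range(n)],
            "sample_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"s{i}" for i in range(n)],
            "label": ["unknown"] * n,
        }
    )
    return SpectraSet(axis, np.full((n, n_points), level), meta)
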
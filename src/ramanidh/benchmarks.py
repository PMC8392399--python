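"""Reference synthetic study designs for validating the pipeline end to end.

Two fixtures, used by the test-bench and the analysis drivers:

* the *planted* design — 20 well-separated bands, ten of which carry a
  doubled IDH-MUT amplitude, on top of strong class-shared bands.  The
  shared mass matters: multiplicative scatter correction regresses every
  spectrum on the cohort mean, and when class-specific bands dominate
  the total spectral mass the fitted slope soaks up part of the class
  effect and smears it (with opposite sign) onto neutral bands.  Tissue
  spectra are dominated by class-shared structure, so the fixture is
  too.
* the *exchangeable null* design — the same bands with more patients,
  fewer spectra each, and no patient-level intensity effect, used for
  permutation-null calibration where spectrum-level predictions must be
  exchangeable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import anova_f_scores, select_top_k
from .features import FeatureMatrix, PeakTable, extract_features
from .preprocess import run_pipeline
from .synthetic import CohortConfig, PeakSpec, generate_cohort

__all__ = [
    "PLANTED_SHIFTS",
    "NEUTRAL_SHIFTS",
    "SHARED_SHIFTS",
    "planted_peak_specs",
    "planted_cohort_config",
    "null_cohort_config",
    "planted_peak_table",
    "planted_feature_matrix",
    "selection_recovery",
    "permute_patient_labels",
]

#: bands carrying a class effect (amplitude x mut_factor in IDH-MUT)
PLANTED_SHIFTS = tuple(float(s) for s in range(450, 1650, 120))
#: bands with identical amplitude in both classes
NEUTRAL_SHIFTS = tuple(float(s) for s in range(510, 1710, 120))
#: strong class-shared bands dominating the total spectral mass
SHARED_SHIFTS = (480.0, 720.0, 960.0, 1200.0, 1444.0, 1680.0)

ALL_CATALOGUE_SHIFTS = tuple(sorted(PLANTED_SHIFTS + NEUTRAL_SHIFTS))


def planted_peak_specs(mut_factor: float = 2.0) -> tuple[PeakSpec, ...]:
    specs = [PeakSpec(center=s, base_amplitude=30.0, width=5.0, mut_factor=mut_factor)
             for s in PLANTED_SHIFTS]
    specs += [PeakSpec(center=s, base_amplitude=30.0, width=5.0) for s in NEUTRAL_SHIFTS]
    specs += [PeakSpec(center=s, base_amplitude=150.0, width=8.0) for s in SHARED_SHIFTS]
    # phenylalanine anchor for the signal-to-noise gate
    specs.append(PeakSpec(center=1004.0, base_amplitude=60.0, width=4.0))
    return tuple(sorted(specs, key=lambda p: p.center))


def planted_cohort_config(
    seed: int,
    n_patients: int = 10,
    spectra_per_patient: int = 12,
    mut_factor: float = 2.0,
    **overrides,
) -> CohortConfig:
    """20-patient (default) two-class design with 10 planted bands."""
    base = dict(
        n_patients_per_class=n_patients,
        spectra_per_patient=spectra_per_patient,
        peak_specs=planted_peak_specs(mut_factor),
        baseline_order=3,
        baseline_coeff_scale=20.0,
        scatter_slope_sd=0.05,
        scatter_offset_sd=1.0,
        noise_sd=0.5,
        cosmic_ray_rate=0.05,
        cosmic_ray_amplitude=300.0,
        patient_effect_sd=0.1,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def null_cohort_config(seed: int) -> CohortConfig:
    """Permutation-null design: many patients, exchangeable spectra.

    No patient-level intensity effect, so under a label permutation the
    spectrum-level predictions carry no block correlation and pooled
    accuracy concentrates near one half.
    """
    return planted_cohort_config(
        seed, n_patients=25, spectra_per_patient=4, patient_effect_sd=0.0
    )


def planted_peak_table() -> PeakTable:
    """Featurization catalogue for the 20 class-informative/neutral bands."""
    return PeakTable(
        pd.DataFrame(
            {
                "shift_cm1": list(ALL_CATALOGUE_SHIFTS),
                "assignment": ["synthetic band"] * len(ALL_CATALOGUE_SHIFTS),
                "mut_direction": [
                    "higher_in_mut" if s in PLANTED_SHIFTS else "unspecified"
                    for s in ALL_CATALOGUE_SHIFTS
                ],
            }
        )
    )


def planted_feature_matrix(config: CohortConfig) -> FeatureMatrix:
    """Generate -> preprocess -> featurize one planted cohort."""
    processed, _ = run_pipeline(generate_cohort(config))
    return extract_features(processed, planted_peak_table())


def selection_recovery(fm: FeatureMatrix, k: int = 10) -> int:
    """How many of the planted bands the top-k ANOVA-F selection finds."""
    scores = anova_f_scores(fm.values, fm.labels)
    sel = select_top_k(scores, k=k, shifts=fm.shift_labels)
    return len(set(float(s) for s in fm.shift_labels[sel]) & set(PLANTED_SHIFTS))


def permute_patient_labels(fm: FeatureMatrix, rng: np.random.Generator) -> FeatureMatrix:
    """Permute class labels at the patient level (class counts preserved)."""
    patients = np.unique(fm.groups)
    label_of = {p: fm.labels[fm.groups == p][0] for p in patients}
    perm = rng.permutation(patients)
    new_map = {p: label_of[q] for p, q in zip(patients, perm)}
    new_labels = np.array([new_map[g] for g in fm.groups])
    return FeatureMatrix(fm.values, fm.shift_labels, new_labels, fm.groups, fm.point_ids)
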
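"""Synthetic two-class Raman cohort generator.

Emulates the statistical structure of ex-vivo glioma biopsy spectra so
the whole pipeline is testable without clinical data: Lorentzian bands
at the catalogued Raman shifts with class-dependent amplitudes
(IDH-MUT-elevated bands carry a multiplicative factor > 1), a per-patient
log-normal intensity effect, smooth non-negative polynomial fluorescence
baselines, per-spectrum affine scatter distortion, additive Gaussian
noise, and sparse single-bin cosmic-ray spikes.

The patient hierarchy (several spectra per patient, one sample per
patient) is what makes leave-one-patient-out evaluation differ from
spectrum-level cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import LABEL_MUT, LABEL_WT, SpectraSet

__all__ = [
    "PeakSpec",
    "CohortConfig",
    "default_peak_specs",
    "clean_spectrum",
    "generate_cohort",
    "MUT_ELEVATED_SHIFTS",
]

#: Raman shifts (cm^-1) reported as more intense in IDH-MUT than IDH-WT
#: tissue: the cholesterol / cholesterol-ester group (419/421/430), tyrosine
#: and cysteine bands, the triglyceride / fatty-acid and CH2/CH3 deformation
#: region (1300-1445), amide III, nucleic-acid bands and the heme band.
MUT_ELEVATED_SHIFTS = frozenset(
    {
        419, 421, 430, 635, 640, 1059, 1064, 1126, 1174, 1175, 1225, 1245, 1250,
        1265, 1266, 1275, 1300, 1305, 1308, 1330, 1337, 1342, 1372, 1376,
        1397, 1401, 1439, 1440, 1441, 1445, 1454, 1740,
    }
)

# (center cm^-1, base amplitude a.u., HWHM cm^-1) for the catalogued bands.
# Amplitudes are loosely scaled to the visual prominence of tissue spectra:
# the CH2/CH3 deformation (~1440) and protein/lipid (~1300) regions dominate,
# the phenylalanine anchor at 1004 is strong, minor bands sit near 10-25.
_BAND_TABLE = [
    (419, 22.0, 5.0), (421, 18.0, 5.0), (424, 12.0, 5.0), (430, 20.0, 5.0),
    (608, 14.0, 5.0), (633, 10.0, 5.0), (635, 16.0, 5.0), (640, 16.0, 5.0),
    (700, 18.0, 5.0), (719, 20.0, 5.0), (720, 20.0, 5.0), (743, 12.0, 5.0),
    (808, 10.0, 5.0), (1004, 60.0, 4.0), (1059, 24.0, 6.0), (1064, 24.0, 6.0),
    (1126, 16.0, 6.0), (1174, 14.0, 6.0), (1175, 14.0, 6.0), (1215, 12.0, 6.0),
    (1225, 16.0, 7.0), (1245, 20.0, 7.0), (1250, 20.0, 7.0), (1255, 18.0, 7.0),
    (1265, 18.0, 7.0), (1266, 18.0, 7.0), (1275, 16.0, 7.0), (1300, 55.0, 8.0),
    (1305, 50.0, 8.0), (1308, 40.0, 8.0), (1330, 30.0, 8.0), (1337, 28.0, 8.0),
    (1342, 26.0, 8.0), (1354, 12.0, 7.0), (1366, 12.0, 7.0), (1372, 16.0, 7.0),
    (1376, 16.0, 7.0), (1385, 10.0, 7.0), (1390, 10.0, 7.0), (1397, 14.0, 7.0),
    (1401, 14.0, 7.0), (1412, 12.0, 7.0), (1439, 60.0, 8.0), (1440, 65.0, 8.0),
    (1441, 60.0, 8.0), (1445, 55.0, 8.0), (1454, 30.0, 7.0), (1495, 10.0, 7.0),
    (1502, 10.0, 7.0), (1522, 12.0, 7.0), (1532, 14.0, 7.0), (1554, 14.0, 7.0),
    (1705, 10.0, 7.0), (1740, 16.0, 6.0),
]

_DEFAULT_MUT_FACTOR = 1.25


@dataclass(frozen=True)
class PeakSpec:
    """One synthetic Raman band.

    ``mut_factor`` multiplies the amplitude for IDH-MUT spectra; 1 means
    the band does not discriminate.  ``width`` is the Lorentzian
    half-width at half-maximum.
    """

    center: float
    base_amplitude: float
    width: float
    mut_factor: float = 1.0
    shape: str = "lorentzian"  # or "pseudo_voigt"
    voigt_eta: float = 0.5  # Lorentzian fraction when shape == "pseudo_voigt"

    def __post_init__(self) -> None:
        if self.base_amplitude <= 0:
            raise ValueError(f"base_amplitude must be > 0, got {self.base_amplitude}")
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.mut_factor < 0:
            raise ValueError(f"mut_factor must be >= 0, got {self.mut_factor}")
        if self.shape not in ("lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown line shape {self.shape!r}")


def default_peak_specs() -> list[PeakSpec]:
    """Catalogue of synthetic bands: one per catalogued tissue Raman shift.

    Bands reported as IDH-MUT-elevated carry ``mut_factor`` > 1; every
    other band, including the 1004 cm^-1 phenylalanine anchor used by
    the signal-to-noise gate, has ``mut_factor`` = 1.
    """
    return [
        PeakSpec(
            center=float(c),
            base_amplitude=a,
            width=w,
            mut_factor=_DEFAULT_MUT_FACTOR if c in MUT_ELEVATED_SHIFTS else 1.0,
        )
        for c, a, w in _BAND_TABLE
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for :func:`generate_cohort`.

    ``spectra_per_patient`` is either a fixed count or an inclusive
    ``(lo, hi)`` range sampled uniformly per patient (clinical
    acquisitions ranged 35-66 points per sample).  ``patient_effect_sd``
    is the log-scale standard deviation of the per-patient multiplicative
    intensity effect.
    """

    n_patients_per_class: int = 10
    spectra_per_patient: int | tuple[int, int] = (35, 66)
    axis_start: float = 350.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    peak_specs: tuple[PeakSpec, ...] = field(default_factory=lambda: tuple(default_peak_specs()))
    baseline_order: int = 4
    baseline_coeff_scale: float = 40.0
    scatter_slope_sd: float = 0.15
    scatter_offset_sd: float = 2.0
    noise_sd: float = 1.0
    cosmic_ray_rate: float = 0.05
    cosmic_ray_amplitude: float = 500.0
    patient_effect_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_per_class < 1:
            raise ValueError("n_patients_per_class must be >= 1")
        spp = self.spectra_per_patient
        if isinstance(spp, tuple):
            if len(spp) != 2 or spp[0] < 1 or spp[1] < spp[0]:
                raise ValueError("spectra_per_patient range must be (lo, hi) with 1 <= lo <= hi")
        elif spp < 1:
            raise ValueError("spectra_per_patient must be >= 1")
        if not self.axis_start < self.axis_stop:
            raise ValueError("axis_start must be < axis_stop")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        for name in (
            "baseline_coeff_scale", "scatter_slope_sd", "scatter_offset_sd",
            "noise_sd", "cosmic_ray_rate", "cosmic_ray_amplitude", "patient_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.axis_start, self.axis_stop
        for p in self.peak_specs:
            if not (lo <= p.center <= hi):
                raise ValueError(f"peak_specs: center {p.center} outside axis [{lo}, {hi}]")

    def axis(self) -> np.ndarray:
        n = int(np.floor((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def _line_shape(axis: np.ndarray, peak: PeakSpec) -> np.ndarray:
    """Unit-height line profile at the peak's center."""
    d2 = (axis - peak.center) ** 2
    lorentz = peak.width**2 / (d2 + peak.width**2)
    if peak.shape == "lorentzian":
        return lorentz
    gauss = np.exp(-np.log(2.0) * d2 / peak.width**2)
    return peak.voigt_eta * lorentz + (1.0 - peak.voigt_eta) * gauss


def clean_spectrum(
    axis: np.ndarray,
    peaks: list[PeakSpec] | tuple[PeakSpec, ...],
    class_label: str,
    patient_multiplier: float = 1.0,
) -> np.ndarray:
    """Noise-free signal: sum of bands with class- and patient-scaled amplitudes.

    IDH-MUT spectra multiply each band's amplitude by its ``mut_factor``;
    the whole spectrum scales by ``patient_multiplier``.  Deterministic.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or (axis.size > 1 and not np.all(np.diff(axis) > 0)):
        raise ValueError("axis must be 1-D and strictly ascending")
    out = np.zeros_like(axis)
    is_mut = class_label == LABEL_MUT
    for p in peaks:
        amp = p.base_amplitude * (p.mut_factor if is_mut else 1.0) * patient_multiplier
        out += amp * _line_shape(axis, p)
    return out


def _random_baseline(axis: np.ndarray, order: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth non-negative fluorescence-like polynomial baseline."""
    if scale == 0:
        return np.zeros_like(axis)
    x = np.linspace(-1.0, 1.0, axis.size)
    coeffs = rng.normal(0.0, scale, size=order + 1)
    base = np.polynomial.polynomial.polyval(x, coeffs)
    # shift so the minimum sits at a small non-negative pedestal: stays a
    # polynomial of the same degree and fluorescence is never negative
    return base - base.min() + abs(rng.normal(0.0, 0.1 * scale))


def generate_cohort(config: CohortConfig) -> SpectraSet:
    """Generate a labelled two-class cohort with patient hierarchy and artefacts.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    peaks = list(config.peak_specs)

    rows, meta_rows = [], []
    for label, prefix in ((LABEL_MUT, "MUT"), (LABEL_WT, "WT")):
        for ip in range(config.n_patients_per_class):
            patient_id = f"{prefix}{ip + 1:02d}"
            patient_multiplier = float(
                np.exp(rng.normal(0.0, config.patient_effect_sd))
            )
            clean = clean_spectrum(axis, peaks, label, patient_multiplier)
            spp = config.spectra_per_patient
            n_spec = (
                int(rng.integers(spp[0], spp[1] + 1)) if isinstance(spp, tuple) else int(spp)
            )
            for js in range(n_spec):
                y = clean + _random_baseline(
                    axis, config.baseline_order, config.baseline_coeff_scale, rng
                )
                slope = rng.normal(0.0, config.scatter_slope_sd)
                offset = rng.normal(0.0, config.scatter_offset_sd)
                y = (1.0 + slope) * y + offset
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, size=axis.size)
                n_spikes = rng.poisson(config.cosmic_ray_rate)
                for _ in range(n_spikes):
                    bin_i = int(rng.integers(0, axis.size))
                    y[bin_i] += config.cosmic_ray_amplitude * rng.uniform(0.8, 1.2)
                rows.append(y)
                meta_rows.append(
                    {
                        "point_id": f"{patient_id}_pt{js:03d}",
                        "sample_id": patient_id,
                        "patient_id": patient_id,
                        "label": label,
                    }
                )

    return SpectraSet(
        axis,
        np.asarray(rows),
        pd.DataFrame(meta_rows),
        provenance=f"synthetic cohort, seed={config.seed}",
    )
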
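"""Shift catalogue and spectra -> feature-matrix conversion.

The default catalogue lists the tissue Raman shifts with proposed
biochemical assignments used throughout this pipeline (cholesterol and
cholesterol-ester bands around 419-430, amide III around 1225-1275, the
CH2/CH3 deformation region around 1439-1445, nucleic-acid bands, the
heme band at 1454, ...) together with the reported class direction:
``higher_in_mut`` where the band was found more intense in IDH-mutant
tissue, else ``unspecified``.

Featurization takes the intensity of each preprocessed spectrum at each
catalogued shift (nearest grid point, or a local maximum in a small
window) to build the spectra x shifts matrix the classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SpectraSet
from .synthetic import MUT_ELEVATED_SHIFTS

__all__ = ["PeakTable", "FeatureMatrix", "default_peak_table", "extract_features"]

HIGHER_IN_MUT = "higher_in_mut"
HIGHER_IN_WT = "higher_in_wt"
UNSPECIFIED = "unspecified"
_DIRECTIONS = (HIGHER_IN_MUT, HIGHER_IN_WT, UNSPECIFIED)

# shift (cm^-1) -> proposed biochemical assignment
_CATALOGUE: list[tuple[int, str]] = [
    (419, "Cholesterol"),
    (421, "Cholesterol"),
    (424, "Undefined"),
    (430, "Cholesterol/cholesterol ester"),
    (608, "Cholesterol"),
    (633, "Undefined"),
    (635, "Tyrosine"),
    (640, "Cysteine, tyrosine"),
    (700, "Cholesterol"),
    (719, "Choline in the head group of sphingomyelin and phosphatidylcholine, phosphatidylethanolamine"),
    (720, "DNA"),
    (743, "Adenin, DNA, Heme"),
    (808, "Undefined"),
    (1059, "Triglycerides/fatty acids"),
    (1064, "Lipids [C-O stretch and C-O-C symmetric stretch, C-C stretch of phospholipids (side chains specifically) and cholesterol]"),
    (1174, "Proteins"),
    (1175, "Proteins"),
    (1215, "Undefined"),
    (1225, "Amide III band"),
    (1245, "Amide III band"),
    (1250, "Amide III, proteins"),
    (1255, "Lipids"),
    (1265, "Amide III band"),
    (1266, "Lipids"),
    (1275, "Amide III"),
    (1300, "Phospholipids, fatty acid, cholesterol"),
    (1305, "Triglycerides/fatty acids"),
    (1308, "C-N asymmetric stretching in asymmetric aromatic amines"),
    (1330, "C-H deformation or CH2 bend (proteins)"),
    (1337, "Lipids and proteins"),
    (1342, "Nucleic acids"),
    (1354, "Undefined"),
    (1366, "Undefined"),
    (1372, "Nucleic acids"),
    (1376, "Nucleic acids, DNA"),
    (1385, "Undefined"),
    (1390, "Undefined"),
    (1397, "CH2/CH3 deformation of lipids and proteins"),
    (1401, "Protein"),
    (1412, "amino acids: aspartic & glutamic acid"),
    (1439, "CH2/CH3 deformation of lipids side chains, proteins, amino acids, cholesterol/cholesterol ester"),
    (1440, "CH2/CH3 deformation of lipids side chains, proteins, amino acids, cholesterol/cholesterol ester"),
    (1441, "Lipids and Proteins"),
    (1445, "Lipid"),
    (1454, "Heme groups"),
    (1495, "Undefined"),
    (1502, "Undefined"),
    (1522, "Proteins"),
    (1532, "Carotenoid"),
    (1554, "Tryptophan"),
    (1705, "Undefined"),
    (1740, "Lipids"),
]


@dataclass
class PeakTable:
    """Catalogue of Raman shifts with assignment and class direction."""

    table: pd.DataFrame  # columns: shift_cm1, assignment, mut_direction

    def __post_init__(self) -> None:
        required = ["shift_cm1", "assignment", "mut_direction"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"PeakTable missing columns: {missing}")
        shifts = self.table["shift_cm1"].to_numpy(dtype=float)
        if len(np.unique(shifts)) != len(shifts):
            raise ValueError("shifts must be unique")
        if not np.all(np.diff(shifts) > 0):
            raise ValueError("shifts must be sorted ascending")
        bad_dir = set(self.table["mut_direction"]) - set(_DIRECTIONS)
        if bad_dir:
            raise ValueError(f"invalid mut_direction values: {sorted(bad_dir)}")

    @property
    def shifts(self) -> np.ndarray:
        return self.table["shift_cm1"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> Path:
        self.table.to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeakTable":
        return cls(pd.read_csv(path, sep="\t"))


def default_peak_table() -> PeakTable:
    """The built-in shift catalogue with assignments and directions."""
    rows = [
        {
            "shift_cm1": shift,
            "assignment": assignment,
            "mut_direction": HIGHER_IN_MUT if shift in MUT_ELEVATED_SHIFTS else UNSPECIFIED,
        }
        for shift, assignment in _CATALOGUE
    ]
    return PeakTable(pd.DataFrame(rows))


@dataclass
class FeatureMatrix:
    """Spectra x shifts intensity matrix with labels and patient grouping."""

    values: np.ndarray
    shift_labels: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    point_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.shift_labels = np.asarray(self.shift_labels, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        self.point_ids = np.asarray(self.point_ids)
        n, k = self.values.shape
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if not (len(self.labels) == len(self.groups) == len(self.point_ids) == n):
            raise ValueError("row metadata length mismatch")
        if len(self.shift_labels) != k:
            raise ValueError("shift_labels length mismatch")

    def __len__(self) -> int:
        return self.values.shape[0]

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            self.values[idx], self.shift_labels, self.labels[idx],
            self.groups[idx], self.point_ids[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"{s:g}" for s in self.shift_labels]
        )
        df.insert(0, "point_id", self.point_ids)
        df.insert(1, "patient_id", self.groups)
        df.insert(2, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta_cols = ["point_id", "patient_id", "label"]
        shift_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            values=df[shift_cols].to_numpy(dtype=float),
            shift_labels=np.array([float(c) for c in shift_cols]),
            labels=df["label"].to_numpy(),
            groups=df["patient_id"].to_numpy(),
            point_ids=df["point_id"].to_numpy(),
        )


def extract_features(
    spectra: SpectraSet,
    peaks: PeakTable | None = None,
    mode: str = "nearest",
    halfwindow: float = 2.0,
) -> FeatureMatrix:
    """Read off per-shift intensities to build the feature matrix.

    ``nearest`` takes the intensity at the grid point closest to each
    shift (ties resolved toward the lower wavenumber); ``local_max``
    takes the maximum within shift +/- halfwindow.
    """
    peaks = peaks or default_peak_table()
    axis = spectra.axis
    shifts = peaks.shifts
    outside = [float(s) for s in shifts if s < axis[0] or s > axis[-1]]
    if outside:
        raise ValueError(f"shifts outside axis range [{axis[0]}, {axis[-1]}]: {outside}")

    if mode == "nearest":
        cols = np.empty((len(spectra), len(shifts)))
        for j, s in enumerate(shifts):
            dist = np.abs(axis - s)
            # argmin returns the first (= lower-wavenumber) index on ties
            cols[:, j] = spectra.intensities[:, int(np.argmin(dist))]
    elif mode == "local_max":
        cols = np.empty((len(spectra), len(shifts)))
        for j, s in enumerate(shifts):
            if halfwindow == 0:
                idx = np.array([int(np.argmin(np.abs(axis - s)))])
            else:
                idx = np.flatnonzero((axis >= s - halfwindow) & (axis <= s + halfwindow))
            if idx.size == 0:
                raise ValueError(f"no axis points within {halfwindow} of shift {s}")
            cols[:, j] = spectra.intensities[:, idx].max(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return FeatureMatrix(
        values=cols,
        shift_labels=shifts,
        labels=spectra.labels,
        groups=spectra.patient_ids,
        point_ids=spectra.point_ids,
    )
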
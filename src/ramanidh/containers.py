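"""Core in-memory containers for Raman spectra.

A :class:`Spectrum` is a single acquisition point: a wavenumber axis
(cm^-1), one intensity vector, and provenance (sample, patient, class
label).  A :class:`SpectraSet` is a homogeneous collection of spectra
sharing one axis, stored as an ``(n_spectra, n_points)`` matrix plus a
pandas metadata table — the shape every pipeline stage operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

LABEL_MUT = "IDH-MUT"
LABEL_WT = "IDH-WT"
LABEL_UNKNOWN = "unknown"
VALID_LABELS = frozenset({LABEL_MUT, LABEL_WT, LABEL_UNKNOWN})

#: metadata columns every SpectraSet carries, in canonical order
META_COLUMNS = ("point_id", "sample_id", "patient_id", "label")


def _validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be a 1-D array with at least 2 points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    if not np.all(np.isfinite(axis)):
        raise ValueError("axis must be finite")
    return axis


@dataclass
class Spectrum:
    """One acquisition point's spectrum with provenance metadata."""

    axis: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    patient_id: str = ""
    label: str = LABEL_UNKNOWN
    point_id: str = ""
    acquisition_meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.axis.shape:
            raise ValueError(
                f"intensities length {self.intensities.size} != axis length {self.axis.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}")


class SpectraSet:
    """Spectra sharing one wavenumber axis, with per-point metadata.

    Parameters
    ----------
    axis
        Strictly increasing wavenumber grid (cm^-1), shared by all spectra.
    intensities
        ``(n_spectra, n_points)`` matrix, row *i* belonging to metadata row *i*.
    meta
        DataFrame with columns ``point_id, sample_id, patient_id, label``.
        ``point_id`` must be unique; each ``sample_id`` must map to a single
        ``patient_id`` and a single ``label``.
    provenance
        Free-text description of where the data came from.
    """

    def __init__(
        self,
        axis: np.ndarray,
        intensities: np.ndarray,
        meta: pd.DataFrame,
        provenance: str = "",
    ) -> None:
        self.axis = _validate_axis(axis)
        intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        if intensities.shape[0] == 0:
            intensities = intensities.reshape(0, self.axis.size)
        if intensities.shape[1] != self.axis.size:
            raise ValueError(
                f"intensity matrix has {intensities.shape[1]} columns, axis has {self.axis.size}"
            )
        if not np.all(np.isfinite(intensities)):
            raise ValueError("intensities must be finite")
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        meta = meta.reset_index(drop=True)[list(META_COLUMNS)].astype(str)
        if len(meta) != intensities.shape[0]:
            raise ValueError(
                f"{len(meta)} metadata rows for {intensities.shape[0]} spectra"
            )
        if meta["point_id"].duplicated().any():
            dups = meta.loc[meta["point_id"].duplicated(), "point_id"].tolist()
            raise ValueError(f"duplicate point ids: {dups}")
        bad = set(meta["label"]) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid labels: {sorted(bad)}")
        for col in ("patient_id", "label"):
            n_per_sample = meta.groupby("sample_id")[col].nunique()
            conflicted = n_per_sample[n_per_sample > 1]
            if len(conflicted):
                raise ValueError(
                    f"sample ids map to multiple {col} values: {list(conflicted.index)}"
                )
        self.intensities = intensities
        self.meta = meta
        self.provenance = provenance

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            axis=self.axis,
            intensities=self.intensities[i],
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            label=row["label"],
            point_id=row["point_id"],
        )

    # -- convenience views ----------------------------------------------
    @property
    def point_ids(self) -> np.ndarray:
        return self.meta["point_id"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.meta["patient_id"].to_numpy()

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "SpectraSet":
        """Return a new set restricted to the given spectrum rows."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.axis,
            self.intensities[idx],
            self.meta.iloc[idx],
            provenance if provenance is not None else self.provenance,
        )

    def with_intensities(self, intensities: np.ndarray, axis: np.ndarray | None = None) -> "SpectraSet":
        """Return a copy with intensities (and optionally the axis) replaced."""
        return SpectraSet(
            self.axis if axis is None else axis,
            intensities,
            self.meta,
            self.provenance,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraSet):
            return NotImplemented
        return (
            np.array_equal(self.axis, other.axis)
            and np.array_equal(self.intensities, other.intensities)
            and self.meta.equals(other.meta)
        )
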
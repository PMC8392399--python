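"""Plain-text I/O for spectra and metadata.

Spectra travel as a *wide* CSV — first column ``wavenumber_cm1``, one
column per acquisition point with the point id as header — and metadata
as a sidecar TSV with columns ``point_id, sample_id, patient_id, label``.
Both files are UTF-8 with ``.`` as decimal separator.  Intensities are
written with 12 significant digits so a write/read round-trip is tight
(<= 1e-9 relative).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SpectraSet, Spectrum, LABEL_UNKNOWN

META_TSV_COLUMNS = ["point_id", "sample_id", "patient_id", "label"]


def read_spectra(path_spectra: str | Path, path_meta: str | Path) -> SpectraSet:
    """Read a wide spectra CSV plus metadata TSV into a validated SpectraSet.

    Raises
    ------
    ValueError
        If the axis is not strictly increasing, a point id has no
        metadata row, or a cell is non-numeric.
    """
    df = pd.read_csv(path_spectra)
    if df.columns[0] != "wavenumber_cm1":
        raise ValueError(
            f"first column of {path_spectra} must be 'wavenumber_cm1', got {df.columns[0]!r}"
        )
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell in {path_spectra} at row {row + 2}, column {col!r}"
            )
    axis = df["wavenumber_cm1"].to_numpy(dtype=float)
    if axis.size >= 2 and not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis is not strictly increasing")

    meta = pd.read_csv(path_meta, sep="\t", dtype=str)
    missing_cols = [c for c in META_TSV_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata file missing columns: {missing_cols}")

    point_ids = [str(c) for c in df.columns[1:]]
    known = set(meta["point_id"])
    orphans = [p for p in point_ids if p not in known]
    if orphans:
        raise ValueError(f"point ids without metadata: {orphans}")

    meta = meta.set_index("point_id", drop=False).loc[point_ids].reset_index(drop=True)
    meta["label"] = meta["label"].fillna(LABEL_UNKNOWN)
    intensities = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectraSet(axis, intensities, meta, provenance=f"read from {path_spectra}")


def write_spectra(
    spectra: SpectraSet, path_spectra: str | Path, path_meta: str | Path
) -> tuple[Path, Path]:
    """Write a SpectraSet in the dialect accepted by :func:`read_spectra`.

    Point columns are written in sorted point-id order so output is
    deterministic regardless of in-memory ordering.
    """
    path_spectra, path_meta = Path(path_spectra), Path(path_meta)
    order = np.argsort(spectra.point_ids, kind="stable")
    columns = {"wavenumber_cm1": spectra.axis}
    columns.update({spectra.point_ids[i]: spectra.intensities[i] for i in order})
    pd.DataFrame(columns).to_csv(path_spectra, index=False, float_format="%.12g")
    spectra.meta.iloc[order].to_csv(path_meta, sep="\t", index=False)
    return path_spectra, path_meta


def read_two_column(path: str | Path, **spectrum_kwargs) -> Spectrum:
    """Read a single spectrum from a plain two-column (shift, intensity) text file.

    Interoperability helper for common instrument exports; whitespace or
    comma delimited, `#` comments allowed.
    """
    arr = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path} is not a two-column file")
    return Spectrum(axis=arr[:, 0], intensities=arr[:, 1], **spectrum_kwargs)


def _is_whitespace(path: str | Path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True
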
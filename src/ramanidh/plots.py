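"""Plotting helpers: class median spectra with interquartile bands."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import LABEL_MUT, LABEL_WT, SpectraSet

_CLASS_COLORS = {LABEL_MUT: "crimson", LABEL_WT: "steelblue"}


def median_spectra_with_iqr(spectra: SpectraSet, ax=None, mark_shifts=None):
    """Plot per-class median spectra with shaded Q1-Q3 bands.

    Returns the matplotlib axes.  ``mark_shifts`` optionally draws
    vertical markers at catalogued Raman shifts.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    for label in (LABEL_WT, LABEL_MUT):
        rows = spectra.intensities[spectra.labels == label]
        if rows.shape[0] == 0:
            continue
        med = np.median(rows, axis=0)
        q1, q3 = np.percentile(rows, [25, 75], axis=0)
        color = _CLASS_COLORS[label]
        ax.plot(spectra.axis, med, color=color, lw=1.2, label=f"{label} median (n={rows.shape[0]})")
        ax.fill_between(spectra.axis, q1, q3, color=color, alpha=0.25, lw=0)
    if mark_shifts is not None:
        for s in mark_shifts:
            ax.axvline(s, color="gray", lw=0.4, alpha=0.5)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("normalized intensity (a.u.)")
    ax.legend(frameon=False)
    return ax


def save_median_plot(spectra: SpectraSet, path: str | Path, mark_shifts=None) -> Path:
    import matplotlib.pyplot as plt

    ax = median_spectra_with_iqr(spectra, mark_shifts=mark_shifts)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
    return Path(path)
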
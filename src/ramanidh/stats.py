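"""Per-shift nonparametric statistics.

For each Raman shift the two class distributions (IDH-WT vs IDH-MUT
feature intensities) are compared with a two-tailed Mann-Whitney test,
after a Shapiro-Wilk normality screen (reported, but never used to gate
the rank test).  The group-1 convention is IDH-WT first: U is the
rank-sum-derived statistic for the WT group, so n1 is the WT count and
n2 the MUT count.  No multiplicity adjustment is applied to the primary
p-values; a Benjamini-Hochberg column is emitted alongside as a clearly
marked extension, since dozens of simultaneous tests otherwise invite
misreading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import LABEL_MUT, LABEL_WT
from .features import FeatureMatrix, HIGHER_IN_MUT, HIGHER_IN_WT, UNSPECIFIED

__all__ = ["ShiftStat", "mann_whitney", "shapiro_wilk", "shift_report", "shift_report_frame"]

#: largest n1*n2 for which the exact tie-free null distribution is enumerated
EXACT_LIMIT = 400


@dataclass
class ShiftStat:
    shift: float
    U: float
    U_complement: float
    p: float
    p_bh: float  # Benjamini-Hochberg adjusted (extension, not primary)
    n1: int  # IDH-WT spectra
    n2: int  # IDH-MUT spectra
    direction: str
    shapiro_p_wt: float
    shapiro_p_mut: float


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney test, returning (U, p) for the first sample.

    U = R1 - n1(n1+1)/2 with midranks for ties.  The p-value is exact
    (full enumeration of the null distribution) when n1*n2 <= 400 and
    there are no ties, otherwise a tie-corrected normal approximation
    with continuity correction.  If every pooled value is identical the
    convention U = n1*n2/2, p = 1 applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2.0)

    if np.all(pooled == pooled[0]):
        return n1 * n2 / 2.0, 1.0

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 * n2 <= EXACT_LIMIT:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return u, float(res.pvalue)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test: (W, p).  Requires 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk p-value approximation unreliable beyond n=5000")
    if np.all(x == x[0]):
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _safe_shapiro_p(values: np.ndarray) -> float:
    try:
        return shapiro_wilk(values)[1]
    except ValueError:
        return math.nan


def shift_report(fm: FeatureMatrix, shifts=None) -> list[ShiftStat]:
    """One ShiftStat per requested shift (default: every column of ``fm``).

    Group 1 is IDH-WT, group 2 IDH-MUT; the same n1/n2 are echoed in
    every row since all tests share the class split.
    """
    wt_mask = fm.labels == LABEL_WT
    mut_mask = fm.labels == LABEL_MUT
    n1, n2 = int(wt_mask.sum()), int(mut_mask.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("shift_report requires spectra from both classes")

    if shifts is None:
        shifts = fm.shift_labels
    shifts = np.asarray(shifts, dtype=float)
    col_of = {float(s): j for j, s in enumerate(fm.shift_labels)}
    missing = [s for s in shifts if float(s) not in col_of]
    if missing:
        raise ValueError(f"shifts not in feature matrix: {missing}")

    rows = []
    for s in shifts:
        col = fm.values[:, col_of[float(s)]]
        wt, mut = col[wt_mask], col[mut_mask]
        u, p = mann_whitney(wt, mut)
        med_diff = np.median(mut) - np.median(wt)
        direction = (
            HIGHER_IN_MUT if med_diff > 0 else HIGHER_IN_WT if med_diff < 0 else UNSPECIFIED
        )
        rows.append(
            ShiftStat(
                shift=float(s),
                U=u,
                U_complement=n1 * n2 - u,
                p=p,
                p_bh=math.nan,  # filled in below over the whole family
                n1=n1,
                n2=n2,
                direction=direction,
                shapiro_p_wt=_safe_shapiro_p(wt),
                shapiro_p_mut=_safe_shapiro_p(mut),
            )
        )
    p_bh = multipletests([r.p for r in rows], method="fdr_bh")[1]
    for r, adj in zip(rows, p_bh):
        r.p_bh = float(adj)
    return rows


def shift_report_frame(fm: FeatureMatrix, shifts=None):
    """``shift_report`` as a tidy DataFrame (TSV-ready)."""
    import pandas as pd

    rows = shift_report(fm, shifts)
    return pd.DataFrame(
        [
            {
                "shift_cm1": r.shift,
                "U": r.U,
                "U_complement": r.U_complement,
                "p": r.p,
                "p_bh": r.p_bh,
                "n1": r.n1,
                "n2": r.n2,
                "direction": r.direction,
                "shapiro_p_wt": r.shapiro_p_wt,
                "shapiro_p_mut": r.shapiro_p_mut,
            }
            for r in rows
        ]
    )
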
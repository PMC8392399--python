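"""Spectral conditioning chain for tissue Raman spectra.

Steps, each independently callable and composed by :func:`run_pipeline`
(default order): cosmic-ray despiking -> truncation to 400-1750 cm^-1 ->
interquartile outlier removal -> multiplicative scatter correction (MSC)
-> signal-to-noise gate at the 1004 cm^-1 phenylalanine band ->
iterative-polynomial fluorescence background subtraction (Vancouver
Raman Algorithm) -> Savitzky-Golay smoothing (3rd order, 9 points) ->
global min-max normalization.

Conventions worth noting because the steps are often described loosely
in the literature:

* The IQR outlier statistic is each spectrum's total integrated
  intensity (trapezoid over the axis); fences are Q1 - k*IQR and
  Q3 + k*IQR over the cohort.
* S2N = (peak maximum above a local linear baseline) / sigma, with
  sigma a robust noise scale estimated from successive differences in a
  quiet window (default 1700-1750 cm^-1):
  sigma = median(|diff|) / (0.6745 * sqrt(2)).
* The Vancouver Raman Algorithm iteratively re-fits a polynomial after
  clamping the working signal at fit + DEV, which peels peaks off the
  fluorescence baseline; DEV is the residual standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectraSet

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "despike",
    "truncate",
    "iqr_outlier_filter",
    "msc_normalize",
    "s2n_filter",
    "vra_baseline",
    "savgol_smooth",
    "minmax_normalize",
    "run_pipeline",
    "DEFAULT_STEP_ORDER",
]

DEFAULT_STEP_ORDER = (
    "despike",
    "truncate",
    "iqr_outlier_filter",
    "msc_normalize",
    "s2n_filter",
    "vra_baseline",
    "savgol_smooth",
    "minmax_normalize",
)


@dataclass(frozen=True)
class PreprocessConfig:
    trunc_lo: float = 400.0
    trunc_hi: float = 1750.0
    iqr_k: float = 1.5
    s2n_threshold: float = 3.5
    s2n_peak_center: float = 1004.0
    s2n_peak_halfwindow: float = 10.0
    noise_window: tuple[float, float] = (1700.0, 1750.0)
    vra_order: int = 5
    vra_max_iter: int = 100
    vra_tol: float = 1e-4
    sg_order: int = 3
    sg_window: int = 9
    minmax_scope: str = "global"  # or "per_spectrum"
    despike_zthresh: float = 8.0
    step_order: tuple[str, ...] = DEFAULT_STEP_ORDER

    def __post_init__(self) -> None:
        if not self.trunc_lo < self.trunc_hi:
            raise ValueError("trunc_lo must be < trunc_hi")
        if self.s2n_threshold <= 0:
            raise ValueError("s2n_threshold must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        if self.vra_order < 1:
            raise ValueError("vra_order must be >= 1")
        if self.minmax_scope not in ("global", "per_spectrum"):
            raise ValueError("minmax_scope must be 'global' or 'per_spectrum'")


@dataclass
class PreprocessReport:
    """Bookkeeping of how many spectra survive each gate, and why not."""

    n_input: int = 0
    n_after_outlier: int = 0
    n_after_s2n: int = 0
    s2n: dict[str, float] = field(default_factory=dict)
    rejections: list[dict[str, str]] = field(default_factory=list)
    vra_converged: bool = True

    def reject(self, point_id: str, reason: str) -> None:
        assert reason in ("iqr_outlier", "low_s2n")
        self.rejections.append({"point_id": point_id, "reason": reason})

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_outlier": self.n_after_outlier,
            "n_after_s2n": self.n_after_s2n,
            "rejections": self.rejections,
            "s2n": self.s2n,
        }


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def despike(y: np.ndarray, zthresh: float = 8.0) -> np.ndarray:
    """Remove single-bin cosmic-ray spikes from one intensity vector.

    Bins flagged by a modified z-score of the first difference
    (robust scale = 1.4826 * MAD) exceeding ``zthresh`` are replaced by
    the mean of the nearest non-spike neighbours on each side.
    """
    y = np.asarray(y, dtype=float)
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0:
        scale = np.std(d)
        if scale == 0:
            return y.copy()
    else:
        scale = 1.4826 * mad
    z = (d - np.median(d)) / scale
    # diff element i sits between bins i and i+1; an extreme difference
    # implicates both of its endpoints
    spike = np.zeros(y.size, dtype=bool)
    hot = np.abs(z) > zthresh
    spike[:-1] |= hot
    spike[1:] |= hot
    if not spike.any():
        return y.copy()
    out = y.copy()
    good = np.flatnonzero(~spike)
    if good.size == 0:
        return out
    for i in np.flatnonzero(spike):
        left = good[good < i]
        right = good[good > i]
        neighbours = []
        if left.size:
            neighbours.append(y[left[-1]])
        if right.size:
            neighbours.append(y[right[0]])
        out[i] = float(np.mean(neighbours))
    return out


def despike_set(spectra: SpectraSet, zthresh: float = 8.0) -> SpectraSet:
    """Apply :func:`despike` to every spectrum in the set."""
    cleaned = np.vstack([despike(row, zthresh) for row in spectra.intensities])
    return spectra.with_intensities(cleaned)


def truncate(spectra: SpectraSet, lo: float = 400.0, hi: float = 1750.0) -> SpectraSet:
    """Restrict to axis points in the closed interval [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    mask = (spectra.axis >= lo) & (spectra.axis <= hi)
    if not mask.any():
        raise ValueError(f"truncation to [{lo}, {hi}] leaves no axis points")
    return spectra.with_intensities(spectra.intensities[:, mask], axis=spectra.axis[mask])


def integrated_intensity(spectra: SpectraSet) -> np.ndarray:
    """Per-spectrum total integrated intensity (trapezoid over the axis)."""
    return np.trapezoid(spectra.intensities, spectra.axis, axis=1)


def iqr_outlier_filter(
    spectra: SpectraSet, k: float = 1.5
) -> tuple[SpectraSet, list[str]]:
    """Drop spectra whose integrated intensity falls outside Tukey fences.

    Fences are Q1 - k*IQR and Q3 + k*IQR computed over the whole set.
    Returns the retained set and the rejected point ids.
    """
    if len(spectra) < 4:
        raise ValueError("iqr_outlier_filter needs at least 4 spectra")
    t = integrated_intensity(spectra)
    q1, q3 = np.percentile(t, [25, 75])
    iqr = q3 - q1
    keep = (t >= q1 - k * iqr) & (t <= q3 + k * iqr)
    rejected = [str(p) for p in spectra.point_ids[~keep]]
    return spectra.subset(np.flatnonzero(keep)), rejected


def msc_normalize(
    spectra: SpectraSet, reference: np.ndarray | None = None
) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum y is regressed y = a + b*ref by ordinary least squares
    over the full axis and replaced by (y - a)/b, inverting the additive
    and multiplicative scatter distortion exactly when the model holds.
    Reference defaults to the point-wise mean spectrum of the set.
    """
    if len(spectra) < 2 and reference is None:
        raise ValueError("msc_normalize needs >= 2 spectra or an explicit reference")
    ref = spectra.intensities.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != spectra.axis.shape:
        raise ValueError("reference length does not match axis")
    design = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(design, spectra.intensities.T, rcond=None)
    a, b = coef[0], coef[1]
    if np.any(b == 0):
        bad = spectra.point_ids[b == 0].tolist()
        raise ValueError(f"MSC slope estimate is zero for spectra: {bad}")
    corrected = (spectra.intensities - a[:, None]) / b[:, None]
    return spectra.with_intensities(corrected)


def robust_noise_sigma(axis: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> float:
    """Noise scale from median absolute successive difference in a quiet window.

    For white noise of sd s, successive differences have sd s*sqrt(2) and
    the median absolute value of a centred normal is 0.6745 of its sd.
    """
    mask = (axis >= window[0]) & (axis <= window[1])
    seg = y[mask]
    if seg.size < 3:
        raise ValueError(f"noise window {window} covers fewer than 3 axis points")
    return float(np.median(np.abs(np.diff(seg))) / (0.6745 * np.sqrt(2.0)))


def s2n_value(
    axis: np.ndarray,
    y: np.ndarray,
    center: float = 1004.0,
    halfwindow: float = 10.0,
    noise_window: tuple[float, float] = (1700.0, 1750.0),
) -> float:
    """Signal-to-noise of the band at ``center``: (P - B) / sigma.

    P is the maximum intensity within center +/- halfwindow; B is the
    local linear baseline interpolated between the window endpoints,
    evaluated at the peak position; sigma from :func:`robust_noise_sigma`.
    sigma == 0 gives +inf (a noiseless spectrum always passes the gate).
    """
    mask = (axis >= center - halfwindow) & (axis <= center + halfwindow)
    if not mask.any():
        raise ValueError(f"axis does not cover the peak window around {center}")
    idx = np.flatnonzero(mask)
    i_pk = idx[np.argmax(y[idx])]
    x0, x1 = axis[idx[0]], axis[idx[-1]]
    y0, y1 = y[idx[0]], y[idx[-1]]
    b = y0 if x1 == x0 else y0 + (y1 - y0) * (axis[i_pk] - x0) / (x1 - x0)
    p = y[i_pk]
    sigma = robust_noise_sigma(axis, y, noise_window)
    if sigma == 0:
        return float("inf")
    return float((p - b) / sigma)


def s2n_filter(
    spectra: SpectraSet, cfg: PreprocessConfig | None = None
) -> tuple[SpectraSet, dict[str, float]]:
    """Keep spectra whose phenylalanine-band S2N meets the threshold."""
    cfg = cfg or PreprocessConfig()
    values = {
        str(pid): s2n_value(
            spectra.axis, row, cfg.s2n_peak_center, cfg.s2n_peak_halfwindow, cfg.noise_window
        )
        for pid, row in zip(spectra.point_ids, spectra.intensities)
    }
    keep = [i for i, pid in enumerate(spectra.point_ids) if values[str(pid)] >= cfg.s2n_threshold]
    return spectra.subset(keep), values


def vra_baseline(
    y: np.ndarray,
    axis: np.ndarray | None = None,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iterative modified-polynomial fluorescence baseline estimation.

    Fits a degree-``order`` polynomial p to the working signal s, computes
    DEV = std(s - p), clamps s at p + DEV (peeling off peaks) and re-fits,
    stopping when the relative change in DEV drops below ``tol``.  On the
    first pass, points more than one DEV *above* the fit are replaced by
    the fit itself so strong peaks never drag the initial estimate up.
    After the iteration, the final polynomial is re-fit on the non-peak
    bins only (original signal within 2 DEV of the iterated fit), which
    removes the residual upward bias that clustered band wings would
    otherwise leave in the baseline.

    Returns ``(baseline, corrected, converged)``; corrected = y - baseline,
    unclipped.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} points, got {n}")
    x = np.linspace(-1.0, 1.0, n) if axis is None else np.asarray(axis, float)

    s = y.copy()
    prev_dev = None
    converged = False
    fitted = np.zeros_like(y)
    for it in range(max_iter):
        series = np.polynomial.Polynomial.fit(x, s, order)
        fitted = series(x)
        dev = float(np.std(s - fitted))
        if dev <= 1e-12 * max(1.0, float(np.ptp(y))):
            converged = True
            break
        if it == 0:
            # strip obvious peaks before the iteration proper
            s = np.where(s > fitted + dev, fitted, s)
        else:
            s = np.minimum(s, fitted + dev)
        if prev_dev is not None and abs(prev_dev - dev) / dev < tol:
            converged = True
            break
        prev_dev = dev
    if prev_dev is not None:
        dev = float(np.std(s - fitted))
        non_peak = (y - fitted) <= 2.0 * dev
        if int(non_peak.sum()) > order + 1:
            series = np.polynomial.Polynomial.fit(x[non_peak], y[non_peak], order)
            fitted = series(x)
    baseline = fitted
    return baseline, y - baseline, converged


def vra_baseline_set(spectra: SpectraSet, order: int = 5, max_iter: int = 100, tol: float = 1e-4) -> tuple[SpectraSet, bool]:
    """Subtract a Vancouver-style baseline from every spectrum in the set."""
    out = np.empty_like(spectra.intensities)
    all_converged = True
    for i, row in enumerate(spectra.intensities):
        _, corrected, conv = vra_baseline(row, spectra.axis, order, max_iter, tol)
        out[i] = corrected
        all_converged &= conv
    return spectra.with_intensities(out), all_converged


def savgol_smooth(y: np.ndarray, order: int = 3, window: int = 9) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing.

    Edges use scipy's polynomial-interpolation handling so that signals
    of degree <= order are reproduced exactly over the whole axis.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    if y.size < window:
        raise ValueError(f"need at least {window} points, got {y.size}")
    return savgol_filter(y, window_length=window, polyorder=order, mode="interp")


def savgol_smooth_set(spectra: SpectraSet, order: int = 3, window: int = 9) -> SpectraSet:
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and > order")
    smoothed = savgol_filter(
        spectra.intensities, window_length=window, polyorder=order, axis=1, mode="interp"
    )
    return spectra.with_intensities(smoothed)


def minmax_normalize(spectra: SpectraSet, scope: str = "global") -> SpectraSet:
    """Scale intensities to [0, 1].

    ``global`` uses one (min, max) over all retained spectra jointly, so
    between-spectrum intensity relations are preserved and 0 and 1 are
    each attained somewhere in the set; ``per_spectrum`` rescales each
    spectrum to its own extrema.
    """
    v = spectra.intensities
    if scope == "global":
        m, big = v.min(), v.max()
        if big == m:
            raise ValueError("min equals max; cannot min-max normalize")
        return spectra.with_intensities((v - m) / (big - m))
    if scope == "per_spectrum":
        m = v.min(axis=1, keepdims=True)
        big = v.max(axis=1, keepdims=True)
        if np.any(big == m):
            flat = spectra.point_ids[(big == m).ravel()].tolist()
            raise ValueError(f"constant spectra cannot be min-max normalized: {flat}")
        return spectra.with_intensities((v - m) / (big - m))
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    spectra: SpectraSet, cfg: PreprocessConfig | None = None
) -> tuple[SpectraSet, PreprocessReport]:
    """Run the conditioning steps in ``cfg.step_order``; log survival counts."""
    cfg = cfg or PreprocessConfig()
    report = PreprocessReport(n_input=len(spectra))
    report.n_after_outlier = len(spectra)
    report.n_after_s2n = len(spectra)

    current = spectra
    for step in cfg.step_order:
        if step == "despike":
            current = despike_set(current, cfg.despike_zthresh)
        elif step == "truncate":
            current = truncate(current, cfg.trunc_lo, cfg.trunc_hi)
        elif step == "iqr_outlier_filter":
            current, rejected = iqr_outlier_filter(current, cfg.iqr_k)
            for pid in rejected:
                report.reject(pid, "iqr_outlier")
            report.n_after_outlier = len(current)
            report.n_after_s2n = len(current)
        elif step == "msc_normalize":
            current = msc_normalize(current)
        elif step == "s2n_filter":
            kept, values = s2n_filter(current, cfg)
            report.s2n.update(values)
            kept_ids = set(kept.point_ids)
            for pid in current.point_ids:
                if pid not in kept_ids:
                    report.reject(str(pid), "low_s2n")
            current = kept
            report.n_after_s2n = len(current)
        elif step == "vra_baseline":
            current, conv = vra_baseline_set(current, cfg.vra_order, cfg.vra_max_iter, cfg.vra_tol)
            report.vra_converged = conv
        elif step == "savgol_smooth":
            current = savgol_smooth_set(current, cfg.sg_order, cfg.sg_window)
        elif step == "minmax_normalize":
            current = minmax_normalize(current, cfg.minmax_scope)
        else:
            raise ValueError(f"unknown pipeline step {step!r}")
    return current, report
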
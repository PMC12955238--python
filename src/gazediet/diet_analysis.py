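"""Convergence of the local spectral diet toward global scene statistics.

The "spectral diet" of a foveal cone is the distribution of its excitations
accumulated over viewing time.  For each end frame n (50 ... 15,000 by
default) the log10 excitations of the first n foveal samples are histogrammed
and correlated (Pearson) against the histogram of log10 excitations over the
entire scene, using matched equal-width bins whose count follows the
Freedman–Diaconis rule applied to the local sample.  The default frame range
yields 14,951 coefficients per cone class.

Zero excitations are floored at ``floor_frac`` times the global maximum
before taking logs (real radiances are strictly positive; the floor only
guards synthetic degenerate inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .retinal_sampling import ConeImage

__all__ = [
    "DietHistogram",
    "CorrelationCurve",
    "fd_bin_count",
    "matched_histograms",
    "local_global_r",
    "correlation_curve",
    "average_curves",
]

CONE_CLASSES = ("L", "M", "S")


@dataclass(frozen=True)
class DietHistogram:
    """Relative-frequency histogram of log10 cone excitations."""

    edges: np.ndarray
    rel_freq: np.ndarray
    n: int
    cone_class: str = ""

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        freq = np.asarray(self.rel_freq, dtype=float)
        if freq.size != edges.size - 1:
            raise ValueError("rel_freq must have len(edges) - 1 entries")
        if np.any(freq < 0) or abs(freq.sum() - 1.0) > 1e-12:
            raise ValueError("rel_freq must be nonnegative and sum to 1")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "rel_freq", freq)


@dataclass(frozen=True)
class CorrelationCurve:
    """Pearson r between local and global diet histograms per end frame.

    ``r`` has shape (n_end_frames, 3) with columns L, M, S; undefined
    correlations (zero-variance histograms) are NaN.
    """

    end_frames: np.ndarray
    r: np.ndarray
    interval_s: float = 0.02
    meta: dict = field(default_factory=dict)

    @property
    def times_s(self) -> np.ndarray:
        return self.end_frames * self.interval_s


def fd_bin_count(samples, max_bins: int | None = None) -> int:
    """Freedman–Diaconis bin count: h = 2 IQR n^(-1/3), bins = ceil(range/h).

    Quartiles use linear interpolation (numpy's default, type 7).  Degenerate
    samples (zero IQR or zero range) give a single bin.  ``max_bins`` caps the
    count for near-degenerate samples whose IQR is tiny relative to their
    range (a numerical guard; the cap used by the curve analysis is
    configurable there).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    h = 2.0 * (q3 - q1) * x.size ** (-1.0 / 3.0)
    rng = x.max() - x.min()
    if h <= 0 or rng <= 0:
        return 1
    bins = int(math.ceil(rng / h))
    return bins if max_bins is None else min(bins, max_bins)


def matched_histograms(local, global_, cone_class: str = "",
                       max_bins: int | None = None) -> tuple[DietHistogram, DietHistogram]:
    """Local and global histograms on identical equal-width edges.

    The bin count follows the Freedman–Diaconis rule on the *local* sample;
    the edges span the union of the two sample ranges so both histograms
    share support.
    """
    local = np.asarray(local, dtype=float)
    global_ = np.asarray(global_, dtype=float)
    if global_.size == 0:
        raise ValueError("global sample must be non-empty")
    bins = fd_bin_count(local, max_bins)
    lo = min(local.min(), global_.min())
    hi = max(local.max(), global_.max())
    if hi <= lo:
        hi = lo + 1.0  # all values identical; single degenerate bin
    edges = np.linspace(lo, hi, bins + 1)
    lc, _ = np.histogram(local, bins=edges)
    gc, _ = np.histogram(global_, bins=edges)
    return (
        DietHistogram(edges, lc / lc.sum(), int(local.size), cone_class),
        DietHistogram(edges, gc / gc.sum(), int(global_.size), cone_class),
    )


def local_global_r(local_hist: DietHistogram, global_hist: DietHistogram) -> float:
    """Pearson product-moment correlation between the relative frequencies.

    Returns NaN (undefined, propagated as missing) when either histogram has
    zero variance across bins.
    """
    if not np.array_equal(local_hist.edges, global_hist.edges):
        raise ValueError("histograms must share identical bin edges")
    p = local_hist.rel_freq
    q = global_hist.rel_freq
    dp = p - p.mean()
    dq = q - q.mean()
    denom = np.sqrt(np.sum(dp**2) * np.sum(dq**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(dp * dq) / denom)


def _log10_floored(values: np.ndarray, floor: float) -> np.ndarray:
    return np.log10(np.maximum(values, floor))


def _prefix_quartiles(sorted_prefix: np.ndarray) -> tuple[float, float]:
    """Type-7 (linear interpolation) quartiles of an already sorted array."""
    n = sorted_prefix.size
    out = []
    for q in (0.25, 0.75):
        pos = q * (n - 1)
        f = int(pos)
        t = pos - f
        if f + 1 >= n or t == 0.0:
            out.append(sorted_prefix[f])
            continue
        a, b = sorted_prefix[f], sorted_prefix[f + 1]
        # numpy's branch-symmetric lerp, so bin counts match np.percentile exactly
        out.append(a + t * (b - a) if t < 0.5 else b - (b - a) * (1.0 - t))
    return out[0], out[1]


def _curve_one_channel(local_log: np.ndarray, global_log: np.ndarray,
                       ends: np.ndarray, max_bins: int | None) -> np.ndarray:
    """Batch-equivalent correlation curve for one cone class.

    Maintains a sorted prefix of the local samples so the per-end-frame
    Freedman–Diaconis bin count and histogram are identical to a from-scratch
    recomputation on the first n samples.
    """
    gsorted = np.sort(global_log)
    gmin, gmax, gn = gsorted[0], gsorted[-1], gsorted.size

    buf = np.empty_like(local_log)
    r_out = np.full(ends.size, np.nan)
    out_i = 0
    next_end = ends[out_i] if ends.size else None
    for n in range(1, local_log.size + 1):
        x = local_log[n - 1]
        pos = np.searchsorted(buf[: n - 1], x)
        buf[pos + 1: n] = buf[pos: n - 1].copy()
        buf[pos] = x
        if next_end is None or n != next_end:
            continue
        prefix = buf[:n]
        q1, q3 = _prefix_quartiles(prefix)
        h = 2.0 * (q3 - q1) * n ** (-1.0 / 3.0)
        lrng = prefix[-1] - prefix[0]
        bins = 1 if (h <= 0 or lrng <= 0) else int(math.ceil(lrng / h))
        if max_bins is not None:
            bins = min(bins, max_bins)
        lo = min(prefix[0], gmin)
        hi = max(prefix[-1], gmax)
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        lc = np.diff(np.searchsorted(prefix, edges, side="left")).astype(float)
        lc[-1] += np.count_nonzero(prefix == edges[-1])
        gc = np.diff(np.searchsorted(gsorted, edges, side="left")).astype(float)
        gc[-1] += np.count_nonzero(gsorted == edges[-1])
        p = lc / n
        q = gc / gn
        dp = p - p.mean()
        dq = q - q.mean()
        denom = np.sqrt(np.sum(dp**2) * np.sum(dq**2))
        if denom > 0:
            r_out[out_i] = np.sum(dp * dq) / denom
        out_i += 1
        if out_i >= ends.size:
            break
        next_end = ends[out_i]
    return r_out


def correlation_curve(series: np.ndarray, global_image: ConeImage,
                      start: int = 50, stop: int = 15000, step: int = 1,
                      floor_frac: float = 1e-6, interval_s: float = 0.02,
                      max_bins: int = 1000,
                      meta: dict | None = None) -> CorrelationCurve:
    """Local-vs-global histogram correlation for each end frame.

    ``series`` is the (n, 3) foveal excitation time series (valid samples
    only); ``global_image`` supplies the population of all scene pixels.  For
    each end frame n, both histograms are rebuilt from scratch on the first n
    local samples (matched Freedman–Diaconis bins), exactly as
    :func:`matched_histograms` + :func:`local_global_r` would.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise ValueError("series must be (n, 3) cone excitations")
    if series.shape[0] < start:
        raise ValueError(f"series shorter than the first end frame ({start})")
    if series.shape[0] < stop:
        import warnings

        warnings.warn(
            f"series has {series.shape[0]} samples; truncating stop={stop}",
            stacklevel=2,
        )
        stop = series.shape[0]
    ends = np.arange(start, stop + 1, step)

    gstack = global_image.as_stack().reshape(-1, 3)
    r = np.empty((ends.size, 3))
    for c in range(3):
        gvals = gstack[:, c]
        floor = floor_frac * gvals.max() if gvals.max() > 0 else 1.0
        llog = _log10_floored(series[:, c], floor)
        glog = _log10_floored(gvals, floor)
        r[:, c] = _curve_one_channel(llog, glog, ends, max_bins)
    return CorrelationCurve(ends, r, interval_s, meta or {})


def single_end_frame_r(series: np.ndarray, global_image: ConeImage, n: int,
                       floor_frac: float = 1e-6,
                       max_bins: int = 1000) -> np.ndarray:
    """From-scratch local-vs-global r at one end frame (reference path)."""
    series = np.asarray(series, dtype=float)
    gstack = global_image.as_stack().reshape(-1, 3)
    out = np.empty(3)
    for c in range(3):
        gvals = gstack[:, c]
        floor = floor_frac * gvals.max() if gvals.max() > 0 else 1.0
        lh, gh = matched_histograms(_log10_floored(series[:n, c], floor),
                                    _log10_floored(gvals, floor),
                                    CONE_CLASSES[c], max_bins=max_bins)
        out[c] = local_global_r(lh, gh)
    return out


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Mean curve with per-frame standard error across curves.

    Undefined (NaN) values are skipped per frame.  The result's ``meta``
    holds the per-frame SE under ``"se"`` and the curve count under ``"k"``.
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = curves[0].end_frames
    for c in curves[1:]:
        if not np.array_equal(c.end_frames, grid):
            raise ValueError("curves must share the same end-frame grid")
    stack = np.stack([c.r for c in curves])  # (k, n, 3)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        k = np.sum(~np.isnan(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
        se = np.where(k > 1, sd / np.sqrt(np.maximum(k, 1)), 0.0)
    return CorrelationCurve(grid, mean, curves[0].interval_s,
                            {"se": se, "k": len(curves)})
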
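"""Auto- and cross-correlation of photon-count traces.

Two estimators are provided: :func:`correlate_direct`, an exact
brute-force evaluation of the normalised correlation at arbitrary integer
lags (the reference oracle), and :func:`correlate_multitau`, the standard
logarithmic-lag correlator with progressive pairwise rebinning used for
production analysis. Both use the same per-lag normalisation

    G(k) = <a(t) b(t+k)> / (<a>_seg <b>_seg) - 1,

where the means are taken over the two truncated, overlapping segments.
Using per-lag segment means removes the linear-trend bias of a global-mean
estimator. Lag 0 (shot-noise dominated) is never part of a curve.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import CorrelationCurve, PhotonCountTrace

__all__ = [
    "ZeroSignalError",
    "correlate_direct",
    "correlate_multitau",
    "estimate_curve_noise",
]


class ZeroSignalError(ValueError):
    """Raised when a trace has zero mean: G is undefined."""


def _check_pair(a: PhotonCountTrace, b: PhotonCountTrace) -> None:
    if a.bin_width != b.bin_width:
        raise ValueError("traces must share the same bin width")
    if len(a.counts) != len(b.counts):
        raise ValueError("traces must have equal length")


def _curve_kind(a: PhotonCountTrace, b: PhotonCountTrace) -> str:
    if a is b or (a.channel == b.channel and np.array_equal(a.counts, b.counts)):
        return "auto_r" if a.channel.startswith("r") else "auto_g"
    return "cross"


def _g_at_lag(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Normalised correlation of float arrays x, y at integer lag k >= 1."""
    n = len(x) - k
    if n < 1:
        raise ValueError(f"lag {k} too large for trace of length {len(x)}")
    x0 = x[:n]
    y1 = y[k:]
    mx = x0.mean()
    my = y1.mean()
    if mx == 0.0 or my == 0.0:
        raise ZeroSignalError("zero-mean trace segment: correlation undefined")
    return float(np.dot(x0, y1) / n / (mx * my) - 1.0)


def correlate_direct(
    a: PhotonCountTrace,
    b: PhotonCountTrace,
    lags: Sequence[int],
) -> CorrelationCurve:
    """Exact sample correlation at the given integer bin offsets.

    O(n) per lag; intended as the reference for validating the multi-tau
    estimator and for short traces.
    """
    _check_pair(a, b)
    lag_bins = np.asarray(lags, dtype=np.int64)
    if lag_bins.size == 0:
        raise ValueError("at least one lag required")
    if lag_bins[0] < 1 or (np.diff(lag_bins) <= 0).any():
        raise ValueError("lags must be strictly increasing positive integers")
    if lag_bins[-1] >= len(a.counts):
        raise ValueError("largest lag must be smaller than the trace length")
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    g = np.array([_g_at_lag(x, y, int(k)) for k in lag_bins])
    return CorrelationCurve(
        kind=_curve_kind(a, b),
        lags=lag_bins * a.bin_width,
        g=g,
        meta={"estimator": "direct"},
    )


def _rebin(x: np.ndarray) -> np.ndarray:
    """Average adjacent pairs (drop a trailing odd sample)."""
    n = len(x) // 2
    return 0.5 * (x[: 2 * n : 2] + x[1 : 2 * n : 2])


def _multitau_eval(
    x: np.ndarray,
    y: np.ndarray,
    m: int,
    max_lag_bins: Optional[int],
):
    """Shared multi-tau engine; returns (lag_bins float, g values)."""
    lag_bins: list[float] = []
    g: list[float] = []
    # native-resolution linear part: lags 1 .. 2m
    top = min(2 * m, len(x) - 1)
    for k in range(1, top + 1):
        if max_lag_bins is not None and k > max_lag_bins:
            return np.array(lag_bins), np.array(g)
        lag_bins.append(float(k))
        g.append(_g_at_lag(x, y, k))
    width = 1.0
    while True:
        x = _rebin(x)
        y = _rebin(y)
        width *= 2.0
        if len(x) <= 2 * m:
            break
        done = False
        for j in range(m + 1, 2 * m + 1):
            lag = j * width
            if max_lag_bins is not None and lag > max_lag_bins:
                done = True
                break
            if j >= len(x):
                done = True
                break
            lag_bins.append(lag)
            g.append(_g_at_lag(x, y, j))
        if done:
            break
    return np.array(lag_bins), np.array(g)


def correlate_multitau(
    a: PhotonCountTrace,
    b: PhotonCountTrace,
    points_per_octave: int = 8,
    max_lag: Optional[float] = None,
) -> CorrelationCurve:
    """Multi-tau correlation with a quasi-logarithmic lag grid.

    The first ``2*m`` lags (m = points_per_octave) are at native bin
    resolution and equal :func:`correlate_direct` exactly; each further
    octave doubles the bin width by pairwise averaging (averaging, not
    summing, keeps the normalised estimator unchanged in expectation) and
    contributes lags ``m+1 .. 2m`` in units of the current width.

    Parameters
    ----------
    max_lag : float, optional
        Largest lag (s) to evaluate; the grid is truncated there.
    """
    _check_pair(a, b)
    m = int(points_per_octave)
    if m < 1:
        raise ValueError("points_per_octave must be >= 1")
    max_lag_bins = None if max_lag is None else max_lag / a.bin_width
    x = a.counts.astype(float)
    y = b.counts.astype(float)
    lag_bins, g = _multitau_eval(x, y, m, max_lag_bins)
    if lag_bins.size == 0:
        raise ValueError("no lags could be evaluated")
    return CorrelationCurve(
        kind=_curve_kind(a, b),
        lags=lag_bins * a.bin_width,
        g=g,
        meta={"estimator": "multitau", "m": m},
    )


def estimate_curve_noise(
    a: PhotonCountTrace,
    b: PhotonCountTrace,
    n_segments: int = 10,
    points_per_octave: int = 8,
    max_lag: Optional[float] = None,
) -> CorrelationCurve:
    """Multi-tau curve with a per-lag standard error from trace segmentation.

    The trace pair is split into ``n_segments`` equal blocks, each block is
    correlated on the full-trace lag grid, and sd(tau) is the standard
    deviation over blocks divided by sqrt(n_segments) — the standard error
    of the full-trace estimate used as a fitting weight.
    """
    _check_pair(a, b)
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    seg_len = len(a.counts) // n_segments
    if seg_len < 2:
        raise ValueError("segments too short")
    full = correlate_multitau(a, b, points_per_octave, max_lag)
    max_lag_bins = full.lags[-1] / a.bin_width
    if max_lag_bins >= seg_len:
        raise ValueError(
            f"segment length {seg_len} bins is shorter than the largest "
            f"lag ({max_lag_bins:.0f} bins); reduce max_lag or n_segments"
        )
    m = int(points_per_octave)
    per_seg = []
    for s in range(n_segments):
        xs = a.counts[s * seg_len : (s + 1) * seg_len].astype(float)
        ys = b.counts[s * seg_len : (s + 1) * seg_len].astype(float)
        lag_bins, g = _multitau_eval(xs, ys, m, max_lag_bins)
        if len(g) != len(full.g):
            raise ValueError("segment lag grid shorter than full-trace grid")
        per_seg.append(g)
    seg_matrix = np.vstack(per_seg)
    sd = seg_matrix.std(axis=0, ddof=1) / np.sqrt(n_segments)
    meta = dict(full.meta)
    meta["n_segments"] = n_segments
    return CorrelationCurve(kind=full.kind, lags=full.lags, g=full.g, sd=sd, meta=meta)
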
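"""Single-cell degradation kinetics and image line profiles.

The trace pipeline mirrors live-cell practice for anaphase-aligned
fluorescence trajectories: background-subtracted intensities are
normalised to a fixed pre-anaphase reference frame, corrected for
photobleaching (either against a translation-shutoff control trace or by
dividing out a straight line fitted to a pre-anaphase window), smoothed
with a trailing moving average, and scanned with sliding five-point
linear fits to locate the degradation onset (first window whose slope
drops strictly below a threshold) and the maximum degradation speed
(slope of the five points centred on the minimum of the first
derivative).

Frame convention: anaphase = frame 0; "N frames prior to anaphase" is
frame -N. Slopes are in normalised intensity per frame, independent of
the frame interval, so a single threshold applies across acquisition
rates; ``frame_interval`` is carried in the trace metadata for callers
who want physical rates.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .types import DegradationTrace, KineticsResult, LineProfile

__all__ = [
    "normalize_trace",
    "bleach_correct_control",
    "bleach_correct_linear",
    "moving_average",
    "smooth_trace",
    "max_degradation_speed",
    "detect_onset",
    "analyze_trace",
    "extract_line_profile",
    "minmax_scale",
    "compartment_means",
]


def _replace(trace: DegradationTrace, frames=None, intensities=None,
             background=None) -> DegradationTrace:
    return DegradationTrace(
        frames=trace.frames if frames is None else frames,
        intensities=trace.intensities if intensities is None else intensities,
        background=trace.background if background is None else background,
        compartment=trace.compartment,
        frame_interval=trace.frame_interval,
        cell_id=trace.cell_id,
    )


def normalize_trace(trace: DegradationTrace, reference_frame: int = -20,
                    subtract_background: bool = True) -> DegradationTrace:
    """Normalise to the (background-subtracted) value at a reference frame.

    The output is exactly 1 at ``reference_frame``; background is zero
    afterwards.
    """
    i_ref = trace.index_of(reference_frame)
    values = trace.intensities.astype(float)
    if subtract_background:
        values = values - trace.background_array()
    ref = values[i_ref]
    if ref <= 0:
        raise ValueError("reference value must be positive after background "
                         "subtraction")
    return _replace(trace, intensities=values / ref, background=0.0)


def bleach_correct_control(trace: DegradationTrace,
                           control: DegradationTrace) -> DegradationTrace:
    """Divide by a matched pure-bleaching control trace.

    The control comes from the same subcellular location in cells where
    both translation and degradation are blocked, so its normalised decay
    is photobleaching only.
    """
    if not np.array_equal(trace.frames, control.frames):
        raise ValueError("trace and control must cover the same frames")
    c = control.intensities.astype(float)
    if (c <= 0).any():
        raise ValueError("control trace must be strictly positive")
    return _replace(trace, intensities=trace.intensities / c)


def bleach_correct_linear(trace: DegradationTrace,
                          fit_window: Tuple[int, int] = (-30, -25)
                          ) -> DegradationTrace:
    """Divide by a straight line fitted to a pre-onset frame window.

    The window is inclusive on both ends (default -30..-25, six frames);
    the fitted line is extrapolated over the whole trace.
    """
    lo, hi = int(fit_window[0]), int(fit_window[1])
    if hi <= lo:
        raise ValueError("fit_window must satisfy first < last")
    i0, i1 = trace.index_of(lo), trace.index_of(hi)
    x = trace.frames[i0 : i1 + 1].astype(float)
    y = trace.intensities[i0 : i1 + 1].astype(float)
    slope, intercept = np.polyfit(x, y, 1)
    line = slope * trace.frames + intercept
    if (line <= 0).any():
        raise ValueError("fitted bleach line reaches <= 0 inside the trace")
    return _replace(trace, intensities=trace.intensities / line)


def moving_average(values, window: int = 4) -> np.ndarray:
    """Trailing moving average; only positions with full support are kept.

    Output element i is the mean of ``values[i .. i+window-1]`` labelled
    at the window's last position, so the result aligns with frames
    ``frames[window-1:]``.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if values.size < window:
        raise ValueError("need at least `window` values")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def smooth_trace(trace: DegradationTrace, window: int = 4) -> DegradationTrace:
    """Moving-average smoothing with frame labels preserved (trailing
    alignment: each retained frame averages itself and the window-1
    preceding frames)."""
    smoothed = moving_average(trace.intensities, window)
    frames = trace.frames[window - 1 :]
    bg = trace.background
    if np.ndim(bg) == 1:
        bg = np.asarray(bg)[window - 1 :]
    return _replace(trace, frames=frames, intensities=smoothed, background=bg)


def _window_slopes(values: np.ndarray, width: int) -> np.ndarray:
    """Least-squares slope of every sliding window of ``width`` points
    (unit x spacing). Closed form: slope = sum((x - xbar) y) / sum((x-xbar)^2).
    """
    n = values.size
    if n < width:
        raise ValueError("trace shorter than the slope window")
    xc = np.arange(width) - (width - 1) / 2.0
    denom = float(np.dot(xc, xc))
    return np.convolve(values, xc[::-1], mode="valid") / denom


def detect_onset(trace: DegradationTrace, smooth_window: int = 4,
                 slope_window: int = 5, slope_threshold: float = -0.05
                 ) -> Tuple[Optional[int], Optional[float]]:
    """Locate the degradation onset on a normalised, bleach-corrected trace.

    The trace is smoothed (trailing ``smooth_window``-point average), then
    a ``slope_window``-point least-squares line slides left to right; the
    onset is the first frame of the first window whose slope is strictly
    below ``slope_threshold``, and the initial degradation speed is that
    window's slope. A slope exactly at the threshold does not trigger.
    Returns ``(None, None)`` when no window qualifies.
    """
    smoothed = smooth_trace(trace, smooth_window)
    if len(smoothed.frames) < slope_window:
        raise ValueError("trace too short for the slope window after smoothing")
    slopes = _window_slopes(smoothed.intensities, slope_window)
    below = np.nonzero(slopes < slope_threshold)[0]
    if below.size == 0:
        return None, None
    i = int(below[0])
    return int(smoothed.frames[i]), float(slopes[i])


def max_degradation_speed(trace: DegradationTrace, smooth_window: int = 4,
                          fit_points: int = 5, derivative_on: str = "smoothed"
                          ) -> Tuple[float, int]:
    """Maximum degradation speed and the frame where it occurs.

    The first (backward) difference of the smoothed trace is minimised
    (ties broken to the earliest frame) and a least-squares line is fitted
    through the ``fit_points`` smoothed values centred on that frame,
    clamping the window at the trace ends. ``derivative_on='raw'``
    locates the minimum on the unsmoothed trace instead.
    Returns ``(max_speed, max_speed_frame)`` with speed in normalised
    intensity per frame (negative for a decaying trace).
    """
    smoothed = smooth_trace(trace, smooth_window)
    if len(smoothed.frames) < fit_points + 1:
        raise ValueError("trace too short after smoothing")
    if derivative_on == "smoothed":
        deriv_vals = np.diff(smoothed.intensities)
        deriv_frames = smoothed.frames[1:]
    elif derivative_on == "raw":
        deriv_vals = np.diff(trace.intensities)
        deriv_frames = trace.frames[1:]
    else:
        raise ValueError("derivative_on must be 'smoothed' or 'raw'")
    at = int(deriv_frames[int(np.argmin(deriv_vals))])
    centre = int(np.clip(smoothed.index_of(at) if smoothed.frames[0] <= at <= smoothed.frames[-1]
                         else np.argmin(np.abs(smoothed.frames - at)),
                         0, len(smoothed.frames) - 1))
    half = fit_points // 2
    lo = max(0, min(centre - half, len(smoothed.frames) - fit_points))
    sel = slice(lo, lo + fit_points)
    slope, _ = np.polyfit(smoothed.frames[sel].astype(float),
                          smoothed.intensities[sel], 1)
    return float(slope), at


def analyze_trace(
    trace: DegradationTrace,
    reference_frame: int = -20,
    bleach_mode: str = "linear",
    control: Optional[DegradationTrace] = None,
    bleach_fit_window: Tuple[int, int] = (-30, -25),
    smooth_window: int = 4,
    slope_window: int = 5,
    slope_threshold: float = -0.05,
    subtract_background: bool = True,
) -> KineticsResult:
    """Composite pipeline: normalise, bleach-correct, detect onset and
    maximum degradation speed."""
    norm = normalize_trace(trace, reference_frame, subtract_background)
    if bleach_mode == "control":
        if control is None:
            raise ValueError("bleach_mode='control' requires a control trace")
        corrected = bleach_correct_control(norm, control)
    elif bleach_mode == "linear":
        corrected = bleach_correct_linear(norm, bleach_fit_window)
    elif bleach_mode == "none":
        corrected = norm
    else:
        raise ValueError("bleach_mode must be 'control', 'linear' or 'none'")
    onset, initial_speed = detect_onset(corrected, smooth_window, slope_window,
                                        slope_threshold)
    max_speed, max_speed_frame = max_degradation_speed(corrected, smooth_window)
    return KineticsResult(
        onset_frame=onset,
        initial_speed=initial_speed,
        max_speed=max_speed,
        max_speed_frame=max_speed_frame,
        params={
            "reference_frame": reference_frame,
            "bleach_mode": bleach_mode,
            "bleach_fit_window": list(bleach_fit_window),
            "smooth_window": smooth_window,
            "slope_window": slope_window,
            "slope_threshold": slope_threshold,
        },
    )


def extract_line_profile(
    image: np.ndarray,
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    thickness_px: int = 10,
    background: float = 0.0,
    scale: bool = False,
) -> LineProfile:
    """Mean intensity along a thick line from p0 to p1 (x, y pixel coords).

    Samples at unit spacing along the axis; at each sample the values at
    ``thickness_px`` perpendicular offsets centred on the axis (spacing
    1 px, e.g. -4.5..+4.5 for thickness 10) are bilinearly interpolated
    and averaged. Background is subtracted before optional min-max
    scaling.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("p0 and p1 must differ")
    u = d / length  # along the axis
    perp = np.array([-u[1], u[0]])
    t = np.arange(0.0, np.floor(length) + 1.0)
    offsets = np.arange(thickness_px) - (thickness_px - 1) / 2.0
    # sample grid: (n_offsets, n_t, 2) in (x, y)
    pts = (p0[None, None, :]
           + t[None, :, None] * u[None, None, :]
           + offsets[:, None, None] * perp[None, None, :])
    ny, nx = image.shape
    x = pts[..., 0]
    y = pts[..., 1]
    if (x < 0).any() or (x > nx - 1).any() or (y < 0).any() or (y > ny - 1).any():
        raise ValueError("line (including thickness offsets) leaves the image")
    sampled = ndimage.map_coordinates(image, [y.ravel(), x.ravel()], order=1)
    values = sampled.reshape(x.shape).mean(axis=0) - background
    if scale:
        values = minmax_scale(values)
    return LineProfile(positions=t, values={"value": values},
                       thickness_px=thickness_px)


def minmax_scale(values) -> np.ndarray:
    """Scale to [0, 1] with the minimum at 0 and the maximum at 1."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax <= vmin:
        raise ValueError("min-max scaling undefined for a constant input")
    return (values - vmin) / (vmax - vmin)


def compartment_means(image: np.ndarray, mask: np.ndarray,
                      background: float = 0.0) -> Tuple[float, float]:
    """Background-subtracted mean intensity inside and outside a mask."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must match the image shape")
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        raise ValueError("mask must be non-empty and not cover the whole image")
    inside = float(image[mask].mean()) - background
    outside = float(image[~mask].mean()) - background
    return inside, outside
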
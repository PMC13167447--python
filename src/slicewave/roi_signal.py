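"""ROI trace extraction, spatial activity maps and Savitzky-Golay smoothing."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .io import FrameSequence, RoiSpec
from .preprocess import DffSequence, default_f0_window

__all__ = ["RoiTrace", "ActivityMap", "roi_trace", "activity_map", "sg_smooth"]


@dataclass
class RoiTrace:
    """A single-ROI dF/F0 time series with its acquisition context."""

    values: np.ndarray
    times: np.ndarray  # ms
    roi: RoiSpec
    channel: str
    pulse_times: tuple[float, ...] = ()
    smoothed: bool = False
    sg_params: tuple[int, int] | None = None  # (window, order) if smoothed
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have the same length")

    @property
    def frame_period_ms(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else float("nan")


@dataclass
class ActivityMap:
    """Median-filtered dF/F0 images captured at a set of instants."""

    images: np.ndarray  # (n_instants, rows, cols)
    instants_ms: tuple[float, ...]
    channel: str
    median_window: int


def roi_trace(dff: DffSequence, roi: RoiSpec) -> RoiTrace:
    """Spatial mean of the dF/F0 stack over the ROI square, per frame."""
    n_rows, n_cols = dff.data.shape[1:]
    roi.check_bounds(n_rows, n_cols)
    values = dff.data[:, roi.row_slice, roi.col_slice].mean(axis=(1, 2))
    return RoiTrace(
        values=values,
        times=dff.times_ms,
        roi=roi,
        channel=dff.channel,
        pulse_times=tuple(dff.pulse_times),
        provenance=dict(dff.provenance),
    )


def average_roi_traces(traces: Sequence[RoiTrace]) -> RoiTrace:
    """Pointwise mean of repeated-trial ROI traces (commutes with roi_trace)."""
    first = traces[0]
    for t in traces[1:]:
        if t.values.shape != first.values.shape or t.channel != first.channel:
            raise ValueError("traces must share shape and channel")
    out = replace(first)
    out.values = np.mean([t.values for t in traces], axis=0)
    out.provenance = {**first.provenance, "n_trials": len(traces)}
    return out


def activity_map(
    raw: FrameSequence,
    instants_ms: Sequence[float],
    baseline_window: tuple[int, int] | None = None,
    median_window: int = 50,
) -> ActivityMap:
    """Spatial dF/F0 images at selected instants, median filtered twice.

    For each instant the raw frame is median filtered (``median_window``
    square, reflect boundary), dF/F0 is recomputed against the equally
    filtered baseline image, and the resulting dF/F0 frame is median
    filtered again.  The double pass suppresses isolated hot pixels in both
    the counts and the ratio domain.
    """
    times = raw.times_ms
    duration = raw.duration_ms
    sign = -1.0 if raw.channel == "vm" else 1.0
    if baseline_window is None:
        baseline_window = default_f0_window(raw.frame_rate, raw.pulse_times, raw.n_frames)
    start, stop = baseline_window
    f0 = raw.data[start:stop].astype(float).mean(axis=0)
    f0_filtered = ndimage.median_filter(f0, size=median_window, mode="reflect")
    if np.any(f0_filtered <= 0):
        raise ValueError("non-positive baseline after median filtering")
    images = []
    for t in instants_ms:
        if not 0 <= t < duration:
            raise ValueError(f"instant {t} ms outside the 0..{duration} ms recording")
        idx = int(np.argmin(np.abs(times - t)))
        frame = ndimage.median_filter(raw.data[idx].astype(float), size=median_window, mode="reflect")
        dff = sign * (frame - f0_filtered) / f0_filtered
        images.append(ndimage.median_filter(dff, size=median_window, mode="reflect"))
    return ActivityMap(
        images=np.stack(images),
        instants_ms=tuple(float(t) for t in instants_ms),
        channel=raw.channel,
        median_window=median_window,
    )


def _sg_edge_fit(values: np.ndarray, window: int, order: int) -> np.ndarray:
    """Least-squares polynomial fit on the *truncated* window near each edge.

    No padding is used: for an output sample closer than half a window to a
    boundary, the polynomial is fitted to the samples that actually exist
    and evaluated at that sample.  This avoids fabricating pre-stimulus
    values by reflection.
    """
    half = window // 2
    n = values.size
    out = np.empty(2 * half)
    x_full = np.arange(n, dtype=float)
    for k, i in enumerate(list(range(half)) + list(range(n - half, n))):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        deg = min(order, hi - lo - 1)
        coeffs = np.polyfit(x_full[lo:hi] - i, values[lo:hi], deg)
        out[k] = np.polyval(coeffs, 0.0)
    return out


def sg_smooth(trace: RoiTrace, window: int = 21, order: int = 3) -> RoiTrace:
    """Savitzky-Golay smoothing: local least-squares polynomial of ``order``.

    ``window`` must be odd, larger than ``order`` and no longer than the
    trace.  The interior uses the standard convolution coefficients; near
    the boundaries the polynomial is refitted on the truncated window.  The
    original values are retained in provenance.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 0 <= order < window:
        raise ValueError(f"need window > order >= 0, got window={window}, order={order}")
    if window > trace.values.size:
        raise ValueError(f"window {window} exceeds trace length {trace.values.size}")
    smoothed = signal.savgol_filter(trace.values, window, order, mode="interp")
    half = window // 2
    if half:
        edges = _sg_edge_fit(trace.values, window, order)
        smoothed[:half] = edges[:half]
        smoothed[-half:] = edges[half:]
    out = replace(trace)
    out.values = smoothed
    out.smoothed = True
    out.sg_params = (window, order)
    out.provenance = {**trace.provenance, "unsmoothed": trace.values}
    return out
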
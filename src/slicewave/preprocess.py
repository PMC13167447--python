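"""Photobleaching correction, baseline (F0) estimation and signed dF/F0.

Signals are reported as *absolute* dF/F0: +dF/F0 for the Ca2+ channel and
-dF/F0 for the voltage channel, because membrane depolarization lowers the
voltage-dye fluorescence.  Bleach is removed by dividing the trace (or
stack) by a model curve fitted to samples outside the response windows and
normalized to its initial value, which preserves dF/F0 semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import FrameSequence

__all__ = [
    "DffSequence",
    "BleachFitError",
    "estimate_f0",
    "bleach_correct",
    "compute_dff",
    "average_trials",
]


class BleachFitError(RuntimeError):
    """Raised when the bleach model cannot be fitted to the baseline samples."""


@dataclass
class DffSequence:
    """Signed dF/F0 frames (or any dF/F0 array) with processing provenance."""

    data: np.ndarray
    frame_rate: float
    channel: str
    pulse_times: tuple[float, ...] = ()
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate * 1000.0


def estimate_f0(seq: FrameSequence, baseline_window: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel baseline fluorescence: mean over a pre-stimulus frame window.

    ``baseline_window`` is a half-open frame range ``(start, stop)``.  By
    default all frames up to 1 ms before the first stimulus are used.  The
    window must precede the first pulse and contain at least 5 frames; any
    pixel whose mean is not strictly positive is an error.
    """
    if baseline_window is None:
        baseline_window = default_f0_window(seq.frame_rate, seq.pulse_times, seq.n_frames)
    start, stop = baseline_window
    if not 0 <= start < stop <= seq.n_frames:
        raise ValueError(f"baseline window {baseline_window} outside 0..{seq.n_frames}")
    if stop - start < 5:
        raise ValueError(f"baseline window must span >= 5 frames, got {stop - start}")
    if seq.pulse_times:
        first_pulse_frame = int(np.floor(min(seq.pulse_times) / 1000.0 * seq.frame_rate))
        if stop > first_pulse_frame:
            raise ValueError(
                f"baseline window {baseline_window} overlaps the first stimulus "
                f"(frame {first_pulse_frame})"
            )
    f0 = seq.data[start:stop].astype(float).mean(axis=0)
    if np.any(f0 <= 0):
        bad = np.argwhere(f0 <= 0)[0]
        raise ValueError(f"non-positive baseline at pixel (row={bad[0]}, col={bad[1]})")
    return f0


def default_f0_window(
    frame_rate: float, pulse_times: Sequence[float], n_frames: int, guard_ms: float = 1.0
) -> tuple[int, int]:
    """All frames before the first pulse minus a short guard interval."""
    if not pulse_times:
        return (0, n_frames)
    stop = int(np.floor((min(pulse_times) - guard_ms) / 1000.0 * frame_rate))
    return (0, max(stop, 0))


def _outside_mask(times_ms: np.ndarray, exclude_windows: Iterable[tuple[float, float]]) -> np.ndarray:
    mask = np.ones(times_ms.shape, dtype=bool)
    for lo, hi in exclude_windows:
        mask &= ~((times_ms >= lo) & (times_ms < hi))
    return mask


def fit_bleach_curve(
    trace: np.ndarray,
    times_ms: np.ndarray,
    exclude_windows: Iterable[tuple[float, float]] = (),
    model: str = "monoexp",
    poly_degree: int = 2,
) -> np.ndarray:
    """Fit the bleach model to samples outside the response windows.

    Returns the model evaluated on the full time base.  The mono-exponential
    ``a * exp(-t/tau)`` is fitted by linear regression on log counts, which
    is robust for the shallow decays typical of short trials; ``model="poly"``
    fits an ordinary polynomial.
    """
    trace = np.asarray(trace, dtype=float)
    mask = _outside_mask(times_ms, exclude_windows)
    if mask.sum() < 10:
        raise ValueError(f"need >= 10 samples outside response windows, got {int(mask.sum())}")
    t, y = times_ms[mask], trace[mask]
    if model == "monoexp":
        if np.any(y <= 0):
            raise BleachFitError(
                "non-positive samples in bleach fit window; try model='poly'"
            )
        slope, intercept = np.polyfit(t, np.log(y), 1)
        fit = np.exp(intercept + slope * times_ms)
    elif model == "poly":
        coeffs = np.polyfit(t, y, poly_degree)
        fit = np.polyval(coeffs, times_ms)
    else:
        raise ValueError(f"unknown bleach model {model!r}; use 'monoexp' or 'poly'")
    if np.any(fit <= 0) or not np.all(np.isfinite(fit)):
        raise BleachFitError("bleach fit produced a non-positive curve; try model='poly'")
    return fit


def bleach_correct(
    data: np.ndarray,
    times_ms: np.ndarray,
    exclude_windows: Iterable[tuple[float, float]] = (),
    model: str = "monoexp",
    poly_degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide a trace (1-D) or stack (3-D, per-pixel) by its fitted bleach curve.

    The fitted curve is normalized to its value at the first sample, so the
    corrected data keep the original scale with a flat baseline.  Returns
    ``(corrected, fit)`` where ``fit`` is the normalized model curve (per
    pixel for stacks).
    """
    data = np.asarray(data, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if data.shape[0] != times_ms.shape[0]:
        raise ValueError("data and times_ms disagree on the number of frames")
    if data.ndim == 1:
        fit = fit_bleach_curve(data, times_ms, exclude_windows, model, poly_degree)
        norm = fit / fit[0]
        return data / norm, norm
    if data.ndim == 3:
        # per-pixel mode: fit each pixel trace independently (slow; intended
        # for map generation on a handful of frames, not the default path)
        flat = data.reshape(data.shape[0], -1)
        out = np.empty_like(flat)
        norms = np.empty_like(flat)
        for j in range(flat.shape[1]):
            fit = fit_bleach_curve(flat[:, j], times_ms, exclude_windows, model, poly_degree)
            norms[:, j] = fit / fit[0]
            out[:, j] = flat[:, j] / norms[:, j]
        return out.reshape(data.shape), norms.reshape(data.shape)
    raise ValueError("bleach_correct expects a 1-D trace or 3-D stack")


def compute_dff(seq: FrameSequence | np.ndarray, f0: np.ndarray, channel: str | None = None) -> DffSequence:
    """Signed dF/F0: ``(F - F0)/F0`` for Ca2+, ``-(F - F0)/F0`` for voltage.

    With this convention a physiological response (depolarization or Ca2+
    influx) is positive in both channels.
    """
    if isinstance(seq, FrameSequence):
        data = seq.data.astype(float)
        channel = seq.channel if channel is None else channel
        frame_rate, pulses = seq.frame_rate, seq.pulse_times
    else:
        data = np.asarray(seq, dtype=float)
        frame_rate, pulses = float("nan"), ()
    if channel not in ("vm", "ca"):
        raise ValueError(f"channel must be 'vm' or 'ca', got {channel!r}")
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != data.shape[1:]:
        raise ValueError(f"F0 shape {f0.shape} does not match frame shape {data.shape[1:]}")
    sign = -1.0 if channel == "vm" else 1.0
    dff = sign * (data - f0) / f0
    return DffSequence(
        data=dff,
        frame_rate=frame_rate,
        channel=channel,
        pulse_times=tuple(pulses),
        provenance={"sign": sign},
    )


def average_trials(trials: Sequence[DffSequence]) -> DffSequence:
    """Pointwise mean of repeated trials (same shape, channel and stimuli)."""
    if not trials:
        raise ValueError("no trials to average")
    first = trials[0]
    for t in trials[1:]:
        if t.data.shape != first.data.shape:
            raise ValueError("trials have heterogeneous shapes")
        if t.channel != first.channel:
            raise ValueError(f"cannot average channels {first.channel!r} and {t.channel!r}")
        if tuple(t.pulse_times) != tuple(first.pulse_times):
            raise ValueError("trials have different stimulus times")
    mean = np.mean([t.data for t in trials], axis=0)
    return DffSequence(
        data=mean,
        frame_rate=first.frame_rate,
        channel=first.channel,
        pulse_times=tuple(first.pulse_times),
        provenance={"n_trials": len(trials)},
    )
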
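"""End-to-end analysis: frames -> bleach-corrected dF/F0 ROI traces -> metrics.

The default path works at ROI-trace level: for each trial the raw ROI-mean
count trace is extracted, bleach-corrected (mono-exponential fitted outside
the response windows, polynomial fallback), converted to signed dF/F0
against the pre-stimulus baseline, and averaged across trials.  This is
equivalent to the per-pixel route for ROI statistics (spatial averaging
commutes with the pointwise operations) and orders of magnitude faster.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io import FrameSequence, RoiSpec
from .preprocess import BleachFitError, default_f0_window, fit_bleach_curve
from .quantify import SliceResult, quantify_slice
from .roi_signal import RoiTrace, average_roi_traces
from .synthetic import (
    GeneratorConfig,
    SessionRecording,
    StimulusProtocol,
    simulate_session,
)

__all__ = [
    "background_bleach_curve",
    "response_exclusion_windows",
    "process_trial_roi",
    "analyze_trials",
    "quantify_recording",
    "simulate_and_quantify",
    "stability_maxima",
]

# response window excluded from the Vm bleach fit, per pulse.  The
# peak-normalized EPSP kernel has a heavy tail (~10% of peak 25 ms after the
# pulse), so the mask extends well past the peak-search window to keep the
# depolarization tail from tilting the fitted bleach curve.
VM_EXCLUDE_MS = 35.0


def response_exclusion_windows(
    pulse_times: Sequence[float], channel: str, duration_ms: float
) -> list[tuple[float, float]]:
    """Time windows excluded from the bleach fit.

    Voltage responses are fast: each pulse masks ``[pulse, pulse+35] ms``.
    Ca2+ transients decay far beyond the trial, so everything from the first
    pulse to the end of the recording is excluded and the fit is anchored on
    the pre-stimulus samples alone.
    """
    if channel == "ca":
        return [(min(pulse_times), duration_ms)] if pulse_times else []
    return [(p, min(p + VM_EXCLUDE_MS, duration_ms)) for p in pulse_times]


def background_bleach_curve(
    seq: FrameSequence, background: RoiSpec, model: str = "monoexp"
) -> np.ndarray:
    """Normalized bleach curve fitted on a signal-free background region.

    Because the background carries no stimulus response, the model is
    fitted on *every* frame of the trial, which constrains the decay far
    better than the short pre-stimulus segment of a response ROI (the
    fractional bleach rate of the illuminated field is spatially uniform).
    """
    background.check_bounds(*seq.data.shape[1:])
    raw = seq.data[:, background.row_slice, background.col_slice].astype(float).mean(axis=(1, 2))
    fit = fit_bleach_curve(raw, seq.times_ms, (), model=model)
    return fit / fit[0]


def process_trial_roi(
    seq: FrameSequence,
    roi: RoiSpec,
    bleach_model: str = "monoexp",
    f0_guard_ms: float = 1.0,
    bleach_curve: np.ndarray | None = None,
) -> RoiTrace:
    """Raw ROI trace -> bleach-corrected, signed dF/F0 trace for one trial.

    ``bleach_curve`` (normalized, e.g. from :func:`background_bleach_curve`)
    overrides the in-trace fit.
    """
    roi.check_bounds(*seq.data.shape[1:])
    raw = seq.data[:, roi.row_slice, roi.col_slice].astype(float).mean(axis=(1, 2))
    times = seq.times_ms
    if bleach_curve is not None:
        corrected = raw / bleach_curve
    else:
        windows = response_exclusion_windows(seq.pulse_times, seq.channel, seq.duration_ms)
        try:
            fit = fit_bleach_curve(raw, times, windows, model=bleach_model)
        except BleachFitError:
            fit = fit_bleach_curve(raw, times, windows, model="poly", poly_degree=1)
        corrected = raw / (fit / fit[0])
    start, stop = default_f0_window(seq.frame_rate, seq.pulse_times, seq.n_frames, f0_guard_ms)
    f0 = corrected[start:stop].mean()
    if f0 <= 0:
        raise ValueError(f"non-positive baseline in ROI {roi.name!r}")
    sign = -1.0 if seq.channel == "vm" else 1.0
    return RoiTrace(
        values=sign * (corrected - f0) / f0,
        times=times,
        roi=roi,
        channel=seq.channel,
        pulse_times=tuple(seq.pulse_times),
        provenance={
            "f0_window": (start, stop),
            "bleach_model": bleach_model,
            "session_time_min": seq.session_time,
        },
    )


def analyze_trials(
    trials: Iterable[FrameSequence],
    rois: Sequence[RoiSpec],
    bleach_model: str = "monoexp",
    bleach_roi: RoiSpec | None = None,
) -> dict[tuple[str, str], RoiTrace]:
    """Per-ROI dF/F0 traces averaged over repeated trials of one channel.

    With ``bleach_roi`` the bleach curve is estimated per trial from that
    background region and shared by all ROIs; otherwise each ROI trace is
    corrected with its own in-trace fit.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials given")
    curves = [
        background_bleach_curve(seq, bleach_roi, bleach_model) if bleach_roi else None
        for seq in trials
    ]
    out: dict[tuple[str, str], RoiTrace] = {}
    for roi in rois:
        per_trial = [
            process_trial_roi(seq, roi, bleach_model, bleach_curve=curve)
            for seq, curve in zip(trials, curves)
        ]
        out[(roi.name, trials[0].channel)] = average_roi_traces(per_trial)
    return out


def quantify_recording(
    recording: SessionRecording,
    rois: Sequence[RoiSpec],
    sg_window=None,
    sg_order: int | None = None,
    bleach_roi: RoiSpec | None = None,
) -> SliceResult:
    """Quantify one paired-pulse recording (both channels) into a SliceResult."""
    traces: dict[tuple[str, str], RoiTrace] = {}
    for channel, channel_trials in recording.trials.items():
        traces.update(analyze_trials(channel_trials, rois, bleach_roi=bleach_roi))
    pulses = next(iter(recording.trials.values()))[0].pulse_times
    return quantify_slice(traces, pulses, sg_window=sg_window, sg_order=sg_order)


def simulate_and_quantify(
    config: GeneratorConfig,
    protocol: StimulusProtocol | None = None,
    seed: int = 0,
    roi_side: int = 50,
    channels: Sequence[str] = ("vm", "ca"),
    sg_window=None,
    sg_order: int | None = None,
) -> SliceResult:
    """Simulate one paired-pulse slice experiment and run the full pipeline."""
    if set(channels) != {"vm", "ca"}:
        raise ValueError("simulate_and_quantify needs both channels; use analyze_trials")
    if protocol is None:
        protocol = StimulusProtocol.paired_pulse()
    protocol_once = _single_recording(protocol)
    session = simulate_session(config, protocol_once, seed, channels=channels)
    rois = config.geometry.standard_rois(roi_side)
    return quantify_recording(
        session[0], rois, sg_window, sg_order,
        bleach_roi=config.geometry.background_roi(roi_side),
    )


def _single_recording(protocol: StimulusProtocol) -> StimulusProtocol:
    from dataclasses import replace

    return replace(protocol, session_schedule_min=(0.0,))


def stability_maxima(
    session: Sequence[SessionRecording],
    roi: RoiSpec,
    channel: str,
    sg_window=None,
    sg_order: int | None = None,
    search_ms: float | None = None,
    bleach_roi: RoiSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-recording peak amplitude of one ROI/channel across a session.

    Returns ``(times_min, maxima)``; each recording's trials are averaged
    before peak measurement (smoothed, local-baseline convention).
    """
    from .quantify import measure_transient
    from .roi_signal import sg_smooth

    times_min, maxima = [], []
    for rec in session:
        per_trial = []
        for seq in rec.trials[channel]:
            curve = background_bleach_curve(seq, bleach_roi) if bleach_roi else None
            per_trial.append(process_trial_roi(seq, roi, bleach_curve=curve))
        trace = average_roi_traces(per_trial)
        from .quantify import sg_params_for

        smoothed = sg_smooth(trace, *sg_params_for(channel, sg_window, sg_order, trace.values.size))
        m = measure_transient(smoothed, trace.pulse_times, search_ms=search_ms)
        times_min.append(rec.time_min)
        maxima.append(m.amplitudes[0])
    return np.asarray(times_min), np.asarray(maxima)
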
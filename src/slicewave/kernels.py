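"""Temporal event kernels for the synthetic movie generator.

The fast population spike is a narrow Gaussian pulse; the slower EPSP-like
depolarizations and the Ca2+ transients are peak-normalized differences of
exponentials (rise and decay time constants).  The Ca2+ decay constant is
much longer than a trial, so within the recording window the Ca2+ transient
rises to a quasi-plateau and decays slowly.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = ["gaussian_pulse", "diff_of_exp", "doe_peak_lag", "solve_rise_for_peak_lag"]


def gaussian_pulse(t: np.ndarray, t_peak: float, fwhm_ms: float) -> np.ndarray:
    """Unit-amplitude Gaussian pulse with the given full width at half maximum."""
    sigma = fwhm_ms / 2.354820045
    return np.exp(-0.5 * ((np.asarray(t, float) - t_peak) / sigma) ** 2)


def diff_of_exp(t: np.ndarray, onset: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Peak-normalized difference of exponentials, zero before ``onset``."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError(f"need 0 < tau_rise < tau_decay, got {tau_rise}, {tau_decay}")
    s = np.asarray(t, float) - onset
    s = np.where(s > 0, s, 0.0)
    k = np.exp(-s / tau_decay) - np.exp(-s / tau_rise)
    tp = doe_peak_lag(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out = k / peak
    out[np.asarray(t, float) <= onset] = 0.0
    return out


def doe_peak_lag(tau_rise: float, tau_decay: float) -> float:
    """Time from onset to the peak of the difference-of-exponentials kernel."""
    return float(np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise))


def solve_rise_for_peak_lag(peak_lag: float, tau_decay: float) -> float:
    """Rise time constant whose kernel peaks ``peak_lag`` ms after onset."""
    hi = tau_decay * 0.999
    if not 0 < peak_lag < doe_peak_lag(hi, tau_decay):
        raise ValueError(f"peak lag {peak_lag} ms unreachable with tau_decay={tau_decay} ms")
    return float(brentq(lambda tr: doe_peak_lag(tr, tau_decay) - peak_lag, 1e-6, hi, xtol=1e-9))
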
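"""Peak detection, paired-pulse ratios, latencies and pharmacology ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slicewave as sw
from slicewave.kernels import diff_of_exp
from slicewave.quantify import (
    PARAMETER_KEYS,
    delta_t,
    detect_peak,
    measure_transient,
    paired_pulse_ratio,
    pharm_compare,
    quantify_slice,
    spike_reference,
    stability_series,
    stability_slope,
)

from conftest import make_trace


def two_pulse_trace(a1, a2, tau_r=1.5, tau_d=200.0, pulses=(8.0, 58.0), n=350,
                    channel="ca", lag=0.0):
    t = np.arange(n) * 0.2
    values = a1 * diff_of_exp(t, pulses[0] + lag, tau_r, tau_d)
    values += a2 * diff_of_exp(t, pulses[1] + lag, tau_r, tau_d)
    return make_trace(values, channel=channel, pulse_times=pulses)


class TestDetectPeak:
    def test_unique_maximum(self):
        values = np.zeros(200)
        values[60] = 0.012  # 12.0 ms at 5 kHz
        t, a = detect_peak(make_trace(values), (8.0, 20.0), (0.0, 8.0))
        assert (t, a) == (12.0, 0.012)

    def test_plateau_tie_returns_first(self):
        values = np.zeros(200)
        values[[50, 51]] = 0.5  # equal maxima at 10.0 and 10.2 ms
        t, _ = detect_peak(make_trace(values), (8.0, 20.0), (0.0, 8.0))
        assert t == 10.0

    def test_baseline_subtraction(self):
        values = np.full(200, 0.2)
        values[70] = 0.7
        _, a = detect_peak(make_trace(values), (10.0, 20.0), (0.0, 8.0))
        assert a == pytest.approx(0.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty window"):
            detect_peak(make_trace(np.zeros(50)), (100.0, 120.0), (0.0, 8.0))


class TestSpikeReference:
    def test_two_pulses_two_spikes(self):
        tr = two_pulse_trace(0.012, 0.012, tau_r=0.2, tau_d=2.0, channel="vm")
        spikes = spike_reference(tr, (8.0, 58.0))
        assert 8.0 < spikes[0] < 13.0 and 58.0 < spikes[1] < 63.0

    def test_flat_trace_flagged_missing(self):
        tr = make_trace(np.zeros(350), channel="vm", pulse_times=(8.0, 58.0))
        spikes = spike_reference(tr, (8.0, 58.0))
        assert all(math.isnan(s) for s in spikes)

    def test_subthreshold_peak_flagged(self, rng):
        values = rng.normal(0, 1e-3, 350)  # noise only
        tr = make_trace(values, channel="vm", pulse_times=(8.0, 58.0))
        spikes = spike_reference(tr, (8.0, 58.0))
        assert all(math.isnan(s) for s in spikes)


class TestPairedPulseRatio:
    def test_identical_responses(self):
        tr = two_pulse_trace(0.5, 0.5, tau_d=8.0)
        # the tiny deficit is the first response's tail decaying between the
        # local baseline window and the second peak
        assert paired_pulse_ratio(tr, (8.0, 58.0)) == pytest.approx(1.0, abs=5e-3)

    def test_facilitated_response(self):
        tr = two_pulse_trace(0.40, 0.564, tau_d=8.0, channel="vm")
        assert paired_pulse_ratio(tr, (8.0, 58.0)) == pytest.approx(1.41, abs=0.01)

    def test_local_baseline_removes_residual_decay(self):
        # second response rides on the slow decay of the first; the local
        # baseline keeps the measured ratio within 5% of the amplitude ratio
        tr = two_pulse_trace(0.012, 0.0132, tau_r=1.5, tau_d=200.0)
        assert paired_pulse_ratio(tr, (8.0, 58.0)) == pytest.approx(1.1, rel=0.05)

    def test_wrong_pulse_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            paired_pulse_ratio(make_trace(np.zeros(350)), (8.0,))

    def test_no_first_response_flagged(self):
        tr = make_trace(np.zeros(350), pulse_times=(8.0, 58.0))
        assert math.isnan(paired_pulse_ratio(tr, (8.0, 58.0)))


class TestDeltaT:
    def test_plain_difference(self):
        assert delta_t(15.3, 8.6) == pytest.approx(6.7)

    def test_coincident_peak(self):
        assert delta_t(8.6, 8.6) == 0.0

    def test_missing_spike_propagates(self):
        assert math.isnan(delta_t(15.3, math.nan))


class TestQuantifySlice:
    def build_traces(self, truth):
        return {k: tr for k, tr in truth.traces.items()}

    def test_fifteen_core_parameters(self, paper_truth):
        res = quantify_slice(self.build_traces(paper_truth), (8.0, 58.0))
        assert tuple(res.parameters) == PARAMETER_KEYS
        assert len(res.parameters) == 15
        assert all(np.isfinite(v) for v in res.parameters.values())

    def test_missing_roi_named(self, paper_truth):
        traces = self.build_traces(paper_truth)
        traces.pop(("roi2", "ca"))
        with pytest.raises(KeyError, match="roi2"):
            quantify_slice(traces, (8.0, 58.0))

    def test_ttx_slice_all_missing(self, paired_protocol):
        cfg = sw.make_config("ttx", desk_scale=True)
        truth = sw.ground_truth(cfg, paired_protocol)
        res = quantify_slice(dict(truth.traces), (8.0, 58.0))
        assert res.flags["spikes_missing"]
        assert all(math.isnan(v) for v in res.parameters.values())


class TestStabilitySeries:
    def test_constant_session(self):
        out = stability_series([0.01, 0.01, 0.01])
        assert np.allclose(out, 1.0)

    def test_first_recording_normalizes_to_one(self):
        out = stability_series([0.02, 0.01, 0.03])
        assert out[0] == 1.0

    def test_linear_runup_slope(self):
        times = np.array([0, 1, 2, 15, 16, 17, 30, 31, 32], float)
        maxima = 1.0 + 0.016 * times  # +8% per 5 min
        norm = stability_series(maxima, times)
        assert stability_slope(norm, times) * 100 == pytest.approx(8.0, abs=1e-9)

    def test_zero_first_maximum_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            stability_series([0.0, 0.01])


class TestPharmCompare:
    def test_identity_gives_unit_ratios(self, paper_truth):
        res = quantify_slice(dict(paper_truth.traces), (8.0, 58.0))
        table = pharm_compare(res, res)
        assert np.allclose(table["maxR"], 1.0)
        finite = table["p_pRR"].dropna()
        assert np.allclose(finite, 1.0)

    def test_iglur_block_pattern(self, desk_config, paired_protocol):
        # receptor blockade: stimulated-site metrics untouched, EPSPs gone,
        # downstream Ca2+ reduced (presynaptic residue) with smaller p-pR
        # and shorter delay
        before = quantify_slice(
            dict(sw.ground_truth(desk_config, paired_protocol).traces), (8.0, 58.0)
        )
        blocked = sw.make_config("iglur_block", desk_scale=True)
        after = quantify_slice(
            dict(sw.ground_truth(blocked, paired_protocol).traces), (8.0, 58.0)
        )
        table = pharm_compare(before, after).set_index(["roi", "channel"])
        assert table.loc[("roi1", "ca"), "maxR"] == pytest.approx(1.0, abs=0.01)
        assert table.loc[("roi1", "vm"), "maxR"] == pytest.approx(1.0, abs=0.01)
        for roi in ("roi2", "roi3"):
            assert table.loc[(roi, "vm"), "maxR"] == pytest.approx(0.0, abs=0.01)
            assert 0.0 < table.loc[(roi, "ca"), "maxR"] < 1.0
            assert table.loc[(roi, "ca"), "p_pRR"] < 1.0
            assert table.loc[(roi, "ca"), "dtR"] < 1.0

    def test_mismatched_rois_rejected(self, paper_truth):
        res = quantify_slice(dict(paper_truth.traces), (8.0, 58.0))
        import copy

        other = copy.deepcopy(res)
        other.metrics.pop(("roi3", "ca"))
        with pytest.raises(ValueError, match="mismatched"):
            pharm_compare(res, other)


@settings(deadline=None, max_examples=25)
@given(scale=st.floats(0.1, 20.0), shift=st.floats(-3.0, 3.0))
def test_scale_and_shift_invariance(scale, shift):
    """p-pR is invariant to trace gain; dt to joint time shifts."""
    tr = two_pulse_trace(0.01, 0.014, tau_d=8.0)
    scaled = make_trace(scale * tr.values, pulse_times=tr.pulse_times)
    assert paired_pulse_ratio(scaled, (8.0, 58.0)) == pytest.approx(
        paired_pulse_ratio(tr, (8.0, 58.0))
    )
    m = measure_transient(tr, (8.0, 58.0))
    assert delta_t(m.peak_times[0] + shift, 8.6 + shift) == pytest.approx(
        delta_t(m.peak_times[0], 8.6)
    )
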
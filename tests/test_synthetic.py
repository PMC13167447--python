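"""Movie generator: determinism, polarity, noise statistics, pharmacology."""

from dataclasses import replace

import numpy as np
import pytest

import slicewave as sw
from slicewave.synthetic import (
    SliceGeometry,
    StimulusProtocol,
    build_components,
    ground_truth,
    list_presets,
    make_config,
    simulate_session,
    simulate_trial,
    stability_scale,
)

TINY = StimulusProtocol.single_pulse(n_trials_vm=1, n_trials_ca=1)


def tiny_config(desk_config, **optics_kw):
    """Desk config with optional optics overrides (events untouched)."""
    return replace(desk_config, optics=replace(desk_config.optics, **optics_kw))


class TestConfig:
    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="paper_table_s1"):
            make_config("no_such_dye")

    def test_presets_ship_with_package(self):
        names = list_presets()
        for expected in ("paper_table_s1", "ttx", "iglur_block", "cal520",
                         "fluo4", "fluo8", "calbryte520"):
            assert expected in names

    def test_ttx_preset_zeroes_all_truth(self, paired_protocol):
        cfg = make_config("ttx", desk_scale=True)
        truth = ground_truth(cfg, paired_protocol)
        for tr in truth.traces.values():
            assert np.allclose(tr.values, 0.0)

    def test_cal520_schedule_slope(self):
        # +8% of the initial amplitude per 5 minutes, linear
        assert stability_scale("cal520", "ca", 30.0) == pytest.approx(1.48)
        assert stability_scale("cal520", "ca", 0.0) == 1.0
        assert stability_scale("cal520", "vm", 30.0) == 1.0

    def test_rundown_dyes_step_down_after_15min(self):
        for dye in ("fluo4", "fluo8"):
            assert stability_scale(dye, "ca", 14.9) == 1.0
            assert stability_scale(dye, "ca", 15.0) < 1.0

    def test_geometry_rejects_clipped_roi(self):
        with pytest.raises(ValueError, match="does not fit"):
            SliceGeometry(field_rows=80, field_cols=200, stim_site=(40, 40),
                          roi_centers={"roi1": (40, 190)}, roi_margin=100)

    def test_paired_protocol_enforces_50ms_interval(self):
        with pytest.raises(ValueError, match="50-ms"):
            StimulusProtocol(pulse_times_ms=(8.0, 48.0))

    def test_yaml_round_trip(self, desk_config, tmp_path):
        path = desk_config.to_yaml(tmp_path / "cfg.yaml")
        loaded = sw.GeneratorConfig.from_yaml(path)
        assert loaded.geometry == desk_config.geometry
        assert loaded.events == desk_config.events
        assert loaded.optics == desk_config.optics


class TestSimulateTrial:
    def test_identical_seed_identical_stack(self, desk_config):
        a = simulate_trial(desk_config, TINY, "ca", seed=42)
        b = simulate_trial(desk_config, TINY, "ca", seed=42)
        assert np.array_equal(a.data, b.data)
        c = simulate_trial(desk_config, TINY, "ca", seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_invalid_channel_rejected(self, desk_config):
        with pytest.raises(ValueError, match="channel"):
            simulate_trial(desk_config, TINY, "gfp", seed=0)

    def test_nonpositive_photon_scale_rejected(self, desk_config):
        from slicewave.synthetic import OpticsModel

        with pytest.raises(ValueError, match="photon_scale"):
            OpticsModel(photon_scale=0.0)
        with pytest.raises(ValueError, match="f0_mean"):
            OpticsModel(f0_mean={"vm": -1.0, "ca": 100.0})

    def test_polarity(self, desk_config):
        # noise-free render: a depolarization lowers Vm-channel counts at the
        # stimulated site; a Ca2+ event raises Ca-channel counts
        roi = desk_config.geometry.standard_rois(50)[0]
        for channel, comparator in (("vm", np.less), ("ca", np.greater)):
            seq = simulate_trial(desk_config, TINY, channel, 0,
                                 shot_noise=False, quantize=False)
            trace = seq.data[:, roi.row_slice, roi.col_slice].mean(axis=(1, 2))
            baseline = trace[:35].mean()
            peak_region = trace[45:80]
            assert comparator(peak_region.min() if channel == "vm" else peak_region.max(),
                              baseline)

    def test_null_config_mean_dff_zero(self, desk_config, rng):
        # all event amplitudes zero -> ROI dF/F0 is pure shot noise around 0
        from slicewave.pipeline import process_trial_roi

        cfg = replace(desk_config, events=replace(desk_config.events, pharm="ttx"))
        seq = simulate_trial(cfg, TINY, "ca", seed=5)
        roi = cfg.geometry.standard_rois(50)[0]
        tr = process_trial_roi(seq, roi)
        sd = tr.values.std()
        assert abs(tr.values.mean()) < 3 * sd / np.sqrt(tr.values.size)
        # shot-noise prediction: 1/sqrt(F0 * photons_per_count * area)
        expected_sd = 1.0 / np.sqrt(
            cfg.optics.f0_mean["ca"] * cfg.optics.photon_scale * 50 * 50
        )
        assert sd == pytest.approx(expected_sd, rel=0.2)

    def test_shot_noise_scales_with_photon_budget(self, desk_config):
        # x4 photons per count -> ROI-trace noise SD halves (Monte Carlo)
        from slicewave.pipeline import process_trial_roi

        roi = desk_config.geometry.standard_rois(50)[0]
        cfg_ttx = replace(desk_config, events=replace(desk_config.events, pharm="ttx"))
        sds = {}
        for scale in (1.0, 4.0):
            cfg = tiny_config(cfg_ttx, photon_scale=desk_config.optics.photon_scale * scale)
            sds[scale] = np.mean([
                process_trial_roi(simulate_trial(cfg, TINY, "ca", seed=s), roi).values.std()
                for s in range(8)
            ])
        assert sds[4.0] / sds[1.0] == pytest.approx(0.5, rel=0.1)

    def test_quantized_output_is_8bit(self, desk_config):
        seq = simulate_trial(desk_config, TINY, "vm", seed=1)
        assert seq.data.dtype == np.uint8
        assert seq.bit_depth == 8


class TestCrosstalk:
    # a voltage-dye-only preparation imaged in the Ca2+ spectral window:
    # without crosstalk the green channel must carry no trace of the events
    NO_BLEACH = {"vm": 1e9, "ca": 1e9}

    def vsd_only(self, desk_config, c=0.0):
        return replace(
            desk_config,
            events=replace(desk_config.events, ca_amp_direct=0.0,
                           ca_amp_pre={}, ca_amp_post={}),
            optics=replace(desk_config.optics, bleach_tau_s=self.NO_BLEACH,
                           crosstalk_vm_into_ca=c),
        )

    def test_zero_crosstalk_means_zero_contamination(self, desk_config):
        cfg = self.vsd_only(desk_config, c=0.0)
        seq = simulate_trial(cfg, TINY, "ca", 0, shot_noise=False, quantize=False)
        assert np.allclose(seq.data, seq.data[0], atol=1e-6)

    def test_contamination_scales_linearly(self, desk_config):
        # noise-free contamination amplitude in the Ca channel is linear in c
        roi = desk_config.geometry.standard_rois(50)[0]
        amps = {}
        for c in (0.2, 0.4):
            seq = simulate_trial(self.vsd_only(desk_config, c), TINY, "ca", 0,
                                 shot_noise=False, quantize=False)
            trace = seq.data[:, roi.row_slice, roi.col_slice].mean(axis=(1, 2))
            amps[c] = trace[:35].mean() - trace.min()  # negative-going leak
        assert amps[0.2] > 1e-4  # the leak is actually present
        assert amps[0.4] / amps[0.2] == pytest.approx(2.0, rel=0.01)


class TestPharmacology:
    def test_iglur_block_component_logic(self, desk_config):
        ev = replace(desk_config.events, pharm="iglur_block")
        vm_kinds = {c.kind for c in build_components(ev, "vm")}
        ca_kinds = {c.kind for c in build_components(ev, "ca")}
        assert vm_kinds == {"spike"}
        assert ca_kinds == {"ca_direct", "ca_pre"}

    def test_iglur_block_truth_pattern(self, desk_config, paired_protocol):
        # stimulated-site truth identical to control; distal Vm zeroed;
        # distal Ca reduced but not abolished (presynaptic residue)
        control = ground_truth(desk_config, paired_protocol)
        blocked = ground_truth(desk_config.with_pharm("iglur_block"), paired_protocol)
        # atol 1e-6 dF/F0: the distal footprints' far tails graze roi1
        assert np.allclose(blocked.traces[("roi1", "vm")].values,
                           control.traces[("roi1", "vm")].values, atol=1e-6)
        assert np.allclose(blocked.traces[("roi1", "ca")].values,
                           control.traces[("roi1", "ca")].values, atol=1e-6)
        for roi in ("roi2", "roi3"):
            assert np.allclose(blocked.traces[(roi, "vm")].values, 0.0, atol=1e-6)
            residual = blocked.traces[(roi, "ca")].values.max()
            assert 0.0 < residual < control.traces[(roi, "ca")].values.max()


class TestSession:
    def test_calbryte_truth_maxima_flat(self, desk_config, paired_protocol):
        amps = [
            ground_truth(desk_config, paired_protocol, session_time_min=t)
            .metrics[("roi1", "ca")].amplitudes[0]
            for t in (0.0, 15.0, 30.0)
        ]
        assert np.allclose(amps, amps[0])

    def test_fluo4_truth_maxima_step_down(self, paired_protocol):
        cfg = make_config("fluo4", desk_scale=True)
        t0 = ground_truth(cfg, paired_protocol, session_time_min=0.0)
        t15 = ground_truth(cfg, paired_protocol, session_time_min=15.0)
        a0 = t0.metrics[("roi1", "ca")].amplitudes[0]
        a15 = t15.metrics[("roi1", "ca")].amplitudes[0]
        assert a15 < a0
        assert a15 / a0 == pytest.approx(0.6, abs=0.02)

    def test_cal520_truth_maximum_at_30min(self, paired_protocol):
        cfg = make_config("cal520", desk_scale=True)
        a0 = ground_truth(cfg, paired_protocol, 0.0).metrics[("roi1", "ca")].amplitudes[0]
        a30 = ground_truth(cfg, paired_protocol, 30.0).metrics[("roi1", "ca")].amplitudes[0]
        assert a30 / a0 == pytest.approx(1.48, abs=0.01)

    def test_session_structure_and_substreams(self, desk_config):
        proto = StimulusProtocol.stability(session_schedule_min=(0.0, 1.0))
        session = simulate_session(desk_config, proto, seed=9, channels=("ca",))
        assert [rec.time_min for rec in session] == [0.0, 1.0]
        assert all(len(rec.trials["ca"]) == 1 for rec in session)
        # distinct recordings draw from distinct RNG substreams
        assert not np.array_equal(session[0].trials["ca"][0].data,
                                  session[1].trials["ca"][0].data)
        # and the whole session is reproducible
        again = simulate_session(desk_config, proto, seed=9, channels=("ca",))
        assert np.array_equal(session[1].trials["ca"][0].data,
                              again[1].trials["ca"][0].data)

    def test_empty_schedule_rejected(self, desk_config):
        proto = StimulusProtocol.stability(session_schedule_min=())
        with pytest.raises(ValueError, match="schedule"):
            simulate_session(desk_config, proto, seed=0)


class TestGroundTruthConsistency:
    def test_quantify_on_noise_free_frames_matches_truth(
        self, desk_config, paired_protocol, paper_truth
    ):
        # the full pipeline applied to a noise-free render reproduces the
        # analytic truth metrics to one frame period / ~1e-3 on ratios
        from slicewave.pipeline import quantify_recording
        from slicewave.synthetic import SessionRecording

        frame_ms = 1000.0 / paired_protocol.frame_rate
        nf = {
            ch: simulate_trial(desk_config, paired_protocol, ch, 1,
                               shot_noise=False, quantize=False)
            for ch in ("vm", "ca")
        }
        res = quantify_recording(
            SessionRecording(0.0, {c: [nf[c]] for c in nf}),
            desk_config.geometry.standard_rois(50),
            bleach_roi=desk_config.geometry.background_roi(50),
        )
        for key, truth_value in paper_truth.parameters.items():
            tol = frame_ms + 1e-9 if "dt" in key else 1e-3
            assert res.parameters[key] == pytest.approx(truth_value, abs=tol), key

    def test_truth_deterministic(self, desk_config, paired_protocol, paper_truth):
        again = ground_truth(desk_config, paired_protocol)
        for key in paper_truth.parameters:
            assert again.parameters[key] == paper_truth.parameters[key]
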
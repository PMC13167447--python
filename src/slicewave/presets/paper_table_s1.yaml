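# Reference configuration for a paired-pulse CA3->CA1 slice experiment with
# EF-630 (voltage) and Calbryte520 (Ca2+).  Event kinetics and facilitation
# factors are calibrated at load time so that the noise-free ground-truth
# metrics reproduce the target table below.
geometry:
  field_rows: 251
  field_cols: 760
  pixel_size_um: 1.0
  stim_site: [125, 80]
  roi_centers:
    roi1: [125, 80]
    roi2: [125, 280]
    roi3: [125, 480]
  roi_margin: 100
  background_site: [125, 710]
optics:
  f0_mean: {vm: 120.0, ca: 110.0}
  bleach_tau_s: {vm: 0.66, ca: 2.0}
  photon_scale: 16.0
  bit_depth: 8
  vsd_gain: 1.0
  ca_gain: 1.0
  crosstalk_vm_into_ca: 0.0
  crosstalk_ca_into_vm: 0.0
  texture_sigma: 0.08
  texture_seed: 20260920
  dye: calbryte520
events:
  spike_amplitude: 0.012
  spike_width_ms: 2.0
  spike_latency_ms: 0.6
  epsp_amplitude: {roi2: 0.005, roi3: 0.004}
  epsp_decay_ms: 8.0
  ca_amp_direct: 0.015
  ca_amp_pre: {roi2: 0.0048, roi3: 0.0040}
  ca_amp_post: {roi2: 0.0072, roi3: 0.0060}
  ca_decay_ms: 200.0
  spatial_plateau_um: 36.0
  spatial_sigma_um: 30.0
  pharm: none
# noise-free calibration targets: paired-pulse ratios and spike-to-peak
# delays (ms, per pulse) at the stimulated (roi1) and downstream ROIs
targets:
  vm_ppr: {roi2: 1.41, roi3: 1.62}
  ca_ppr: {roi1: 1.00, roi2: 1.11, roi3: 1.22}
  vm_dt: {roi2: [4.1, 4.3], roi3: [4.9, 5.1]}
  ca_dt: {roi1: [6.7, 6.4], roi2: [8.4, 8.7], roi3: [10.0, 9.6]}
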
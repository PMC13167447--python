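# Methods

`slicewave` analyzes — and, for testing, synthesizes — wide-field
fluorescence movies of electrically stimulated hippocampal slices recorded
with a voltage-sensitive dye (VSD, red/IR channel, "vm") and a
green-emitting Ca²⁺ indicator ("ca").  This note documents the model behind
the synthetic generator, the measurement conventions of the quantification
pipeline, the calibration that ties the two together, and the limits of
what the synthetic benchmarks can demonstrate.

## The activation model

A stimulus pulse in the CA3 *stratum lucidum* triggers a sequential cascade
that the event model reproduces site by site:

1. a synchronized population spike in directly stimulated cells at the
   electrode (`roi1`), visible as a fast negative-going VSD transient;
2. spike-evoked Ca²⁺ influx through voltage-gated channels at the same
   site (positive-going Ca²⁺ transient);
3. EPSP-like depolarizations at downstream sites ~200 µm (`roi2`) and
   ~400 µm (`roi3`) along the CA1 direction, delayed by conduction;
4. Ca²⁺ transients at the downstream sites with two components: a
   *presynaptic* part (axonal influx driven by the propagating spike) and a
   *postsynaptic* part (glutamatergic transmission), only the latter showing
   paired-pulse facilitation.

Each event is a separable product of a spatial footprint and a temporal
kernel, scaled by a peak ΔF/F₀ amplitude:

* **Spatial footprint** — flat core (radius 36 µm, so a 50×50 µm ROI
  centered on the site sees the full amplitude) with Gaussian falloff
  (σ = 30 µm).  Footprints of neighboring sites 200 µm apart overlap at the
  <10⁻⁶ level.
* **Population spike** — causal difference-of-exponentials pulse, decay
  2 ms, rise solved so the peak occurs 0.6 ms after the stimulus.  A
  Gaussian of matching width was rejected because its non-causal rising
  tail contaminates the pre-stimulus baseline used for spike detection.
* **EPSP** — difference of exponentials, decay 8 ms, rise calibrated
  (≈2 ms); onset delayed by a linear conduction term (0.004 ms/µm, set by
  the growth of the voltage delay between `roi2` and `roi3`).
* **Ca²⁺ transient** — difference of exponentials with decay 200 ms, far
  beyond the 85-ms trial, so within a recording it rises to a quasi-plateau.
  Direct and presynaptic components share one rise constant; the
  postsynaptic component has a slower, per-site rise so that the *mixture's*
  measured peak reproduces the target delays.

Second-pulse responses (50-ms interval) are the same kernels scaled by
per-site facilitation factors and shifted by small per-site latency offsets;
both are calibrated (below).  Default amplitudes: spike 1.2% ΔF/F₀, EPSPs
0.5/0.4%, direct Ca²⁺ 1.5%, downstream Ca²⁺ 1.2/1.0% split 40% pre / 60%
post — matching the reported >1% spike and ≤0.5% EPSP scales and the
pharmacological observation that downstream Ca²⁺ is reduced but not
abolished by glutamate-receptor blockade.

**Pharmacology switches.**  `ttx` (Na⁺-channel block) removes every event.
`iglur_block` (AMPA+NMDA block) removes EPSPs and postsynaptic Ca²⁺ while
sparing the direct spike, direct Ca²⁺, and presynaptic Ca²⁺.

**Dye stability schedules.**  Session-time amplitude factors per Ca²⁺ dye:
Calbryte520 flat; Cal520 linear run-up of +8% of the initial amplitude per
5 min (the linear reading of "~8% every 5 min"; at 30 min the factor is
1.48 — a compounding variant would give 1.60 and can be swapped in
`stability_scale`); Fluo-4/Fluo-8 step down to 60% from the 15-min
recordings onward (the rundown magnitude is not reported anywhere; 60% is a
placeholder chosen to be unambiguous, and only the *direction* of the
effect is asserted).  The VSD is stable throughout.

## Optics and noise

Expected counts per pixel are

    F(t, x) = F0 · texture(x) · exp(−t/τ_bleach) · (1 + m(t, x)),

where `m` is the summed signed modulation (voltage events *decrease*
counts, Ca²⁺ events increase them, plus an optional linear crosstalk leak
of the other channel's field, default 0).  `texture` is a static lognormal
staining inhomogeneity (σ = 0.08, unit mean, fixed seed per slice) — it
makes 8-bit quantization average out across an ROI instead of rounding
coherently.  Counts are Poisson draws at `photon_scale` = 16 photons per
camera count (baselines 120/110 counts), rounded half-up and clipped to
8 bit.  The resulting single-trial ROI noise, ~5×10⁻⁴ ΔF/F₀ SD for a 50×50
ROI, leaves the 1.2% spike clearly visible in single trials and the 0.4%
EPSPs clean after seven-trial averaging, consistent with the published
traces.  Bleach constants (0.66 s for the laser-excited VSD — ~3% over
20 ms — and 2 s for the LED-excited Ca²⁺ channel) are plausible
placeholders; no bleach rate is reported.

## The measurement pipeline

For each trial and ROI: the raw ROI-mean count trace is divided by a
normalized mono-exponential bleach curve, converted to signed ΔF/F₀
(+(F−F₀)/F₀ for Ca²⁺, −(F−F₀)/F₀ for voltage) against the mean of the
pre-stimulus frames (first pulse minus a 1-ms guard), and averaged across
trials (7 voltage, 2 Ca²⁺ by default).

**Bleach estimation.**  Two modes.  (a) *Background-referenced* (default
when the field provides a signal-free region): the curve is fitted to the
full-length trace of a quiet region far from all activity footprints —
since no response needs masking, all frames constrain the fit and the
extrapolation error is negligible.  (b) *In-trace*: the fit uses samples
outside response-exclusion windows — each pulse masks 35 ms for the voltage
channel (the peak-normalized EPSP kernel still holds ~10% of its peak 25 ms
out, enough to tilt the fit), and everything from the first pulse to the end
of the trace for Ca²⁺ (the transient never returns within the trial), so
the Ca²⁺ fit is anchored on pre-stimulus samples only.  Mode (b) is what a
generic TIFF-directory analysis without a designated background ROI falls
back to; its Ca²⁺ extrapolation noise (~10⁻³ ΔF/F₀ over the trace) is the
main reason mode (a) is the default.  The mono-exponential is fitted
log-linearly; a polynomial fallback handles non-positive samples.

**Smoothing.**  Savitzky–Golay, order 3, interior via the standard
convolution and boundaries by refitting the polynomial on the truncated
window (no padding — reflection would fabricate pre-stimulus structure).
Window defaults are per channel: 21 samples (4.2 ms at 5 kHz) for voltage,
71 samples (14.2 ms) for Ca²⁺.  The wide Ca²⁺ window is deliberate: the
transient's peak sits on a quasi-plateau (decay 200 ms), and the argmax of
a lightly smoothed plateau wanders by milliseconds under shot noise; a
14-ms window — still an order of magnitude faster than the decay — turns
the peak into a single well-defined hump whose maximum is stable to a
fraction of a millisecond even at post-blockade amplitudes.  The smoothing
convention follows the source: the stimulated-ROI voltage trace (spike) is
quantified unsmoothed; the stimulated-ROI Ca²⁺ trace and all downstream
traces are smoothed.

**Metrics.**  Peak amplitude = maximum within a post-pulse search window
(15 ms voltage, 25 ms Ca²⁺) minus the mean of the 2 ms immediately before
that pulse; the local baseline removes the residual decay of the first
Ca²⁺ transient under the second response.  Peak time = argmax (first index
on ties).  Spike reference = unsmoothed stimulated-ROI voltage maximum
within 5 ms of each pulse.  Δt = signal peak time − same-pulse spike time.
p-pR = second/first amplitude.  A trace "responds" when its *unsmoothed*
first-pulse amplitude exceeds 5 pre-stimulus noise SDs (the unsmoothed
values are used because smoothed residual noise is correlated and a short
baseline would underestimate its SD); non-responses are flagged, not
reported as near-zero ratios.  A paired-pulse experiment yields 15 core
parameters: Ca²⁺ p-pR and two Δt at `roi1`, and per downstream ROI the
voltage and Ca²⁺ p-pR plus two Δt each.

**Stability sessions** (single-pulse, single-trial recordings at 0, 1, 2,
15, 16, 17, 30, 31, 32 min) are summarized by per-recording maxima
normalized to the first recording; the run-up/run-down rate is the
least-squares slope of the normalized series versus time.

**Pharmacology** is summarized by after/before ratios: maxR (first-pulse
amplitudes, kept even when the after-response is sub-threshold so complete
block appears as maxR ≈ 0), p-pRR and ΔtR (NaN when either condition has
no detectable response).  Single-slice ΔtR of the small presynaptic
residue is noise-dominated; conclusions are drawn from across-slice means,
mirroring the original paired-test design.

**Statistics.**  Two-sided paired t-tests with p-values from the
incomplete-beta tail relation; mean ± sample SD summaries.  No
multiple-testing correction, matching the reporting style of the source
experiments.

## Calibration of the reference preset

`make_config("paper_table_s1")` solves the free kinetic and facilitation
parameters so that the noise-free ground truth — *measured with exactly the
pipeline conventions above*, on a 0.02-ms grid with smoothing windows
mapped to their 5-kHz time spans — reproduces the reference table:
Ca²⁺ p-pR 1.00 / 1.11 / 1.22 and Vm p-pR 1.41 / 1.62; Δt (pulse 1, pulse 2)
of 6.7/6.4 ms (roi1 Ca), 4.1/4.3 and 4.9/5.1 ms (Vm), 8.4/8.7 and
10.0/9.6 ms (Ca).  Conduction delay comes from the voltage-delay growth in
closed form; rise constants by bisection on the measured pulse-1 peak time;
facilitation factors and second-pulse latency shifts by fixed-point
iteration on the measured p-pR and pulse-2 peak time.  Measuring through
the full convention matters: smoothing and the local-baseline rule shift
measured peaks and ratios by amounts that closed-form kernel inversion
misses.  Solutions are cached per preset; `ground_truth` then reproduces
the targets to one frame period (0.2 ms) on delays and ≲0.01 on ratios,
and the pipeline applied to a noise-free, unquantized render matches the
ground truth to one frame / ~10⁻⁶ on ratios.

## Problem sizes

The default geometry is the native field: 251×760 px at 1 µm/px, 5 kHz,
8 bit, with ROIs at 0/200/400 µm from the electrode and a background
region at ~630 µm.  `make_config(..., desk_scale=True)` swaps in a reduced
60×720-px field with identical ROI layout, noise and background — about
3× faster to render — which is what the test suite simulates; the
acceptance script uses the full field.  The paired-pulse recording lasts
85 ms (pulses at 8 and 58 ms) so that both pulses get the complete 25-ms
Ca²⁺ peak-search window; 70 ms would strand the second Ca²⁺ peak in the
smoothing boundary region.

## What the synthetic benchmarks do and do not show

Passing the recovery suites shows the pipeline is *internally consistent*
(it returns what the generator put in, under realistic shot noise, bleach,
texture and quantization) and that its estimators are stable at the
published effect sizes.  The generator does not emulate: motion or focus
drift, dark/flat-field structure, spatially varying bleach, correlated
biological trial-to-trial variability (asynchronous firing is folded into
the EPSP amplitude rather than modeled as discrete events), polysynaptic
activity, or dye-specific waveform differences.  Agreement on synthetic
data therefore validates the analysis chain, not the biology; parameters
estimated from real recordings inherit none of these guarantees.

## Known limitations

* Kernel shapes are minimal parameterizations; only peak amplitudes,
  delays and ratios are calibrated, not full waveforms.
* The Fluo-4/Fluo-8 rundown step (60%) and the bleach constants are
  unreported quantities; tests assert directions/significance, not values.
* The second-pulse latency shifts are phenomenological offsets that absorb
  whatever mechanism changes facilitated-response timing.
* The Ca²⁺ Δt convention (wide smoothing window, argmax) carries a
  deterministic shape-dependent offset; it is shared by truth and pipeline,
  but comparing absolute Δt against other analyses requires matching the
  convention.
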
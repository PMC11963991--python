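# Methods

## The problem

A five-pad chest wearable records 30 mechanical channels (five pads × 3-axis
acceleration + 3-axis rotation) plus ECG at 200 Hz. The pad over the heart
(pad 5) acquires the cardiac mechanical signals — seismocardiogram (SCG) on
its accelerometer, gyrocardiogram (GCG) on its gyroscope — but during
movement those signals are buried under motion artifacts. The four peripheral
pads record almost pure motion, which makes the artifact on pad 5
predictable from them. The pipeline is: compensate → recognize motion state →
filter adaptively → extract fiducials and timing metrics → classify heart
condition.

No public five-pad corpus exists, so a synthetic generator defines the study
conditions and supplies exact ground truth for every stage.

## Synthetic data

**Cardiac templates.** Each fiducial (ECG P, Q, R, S, T; SCG MC, AO, AC, MO;
GCG g_I..g_L) is a Gaussian bump at a configured offset — ground-truth-exact,
differentiable, and sufficient for timing work; waveform realism beyond peak
morphology is not modeled. Default timings at the 0.8-s reference cycle:
Q at R−40 ms, QT = 290 ms, EMD (Q→MC) = 80 ms, PEP (Q→AO) = 120 ms,
LVET (AO→AC) = 300 ms; GCG mirrors SCG with small offsets. Intervals measured
from Q contract as the cycle shortens with per-group exponents on
s = RR/0.8 s: QT and ejection intervals scale as s^0.5 (Bazett-like), the
pre-ejection intervals as s^0.7. With these exponents the full sweep over the
heart-rate presets (sitting 60 → running 150 bpm) yields rising HR with
monotonically falling QT, SDRR, EMD, PEP and PEP/LVET — the standard exercise
physiology. RR intervals are i.i.d. normal with state-dependent CV
(0.05 at rest, down to 0.02 running).

**Motion artifacts.** Stride-locked harmonic series (4 harmonics, geometric
decay 0.5, random per-pad/axis phases) at the state's cadence plus
band-limited (0.5–25 Hz) broadband noise. Defaults: sitting noise-only at
0.02 RMS; walking 1.8 Hz / amp 1.0; jogging 2.4 Hz / 2.5; running
2.8 Hz / 5.0 with broadband 0.10 / 0.25 / 0.50. These were chosen once to
satisfy the qualitative structure the pipeline assumes — artifact energy
strictly monotone in intensity, running Z-acceleration energy >10× sitting,
and 15–25 Hz content growing ≥5× from sitting to running.

**Pad mixing.** Pad 5's artifact is a per-axis weighted sum of the four
pads' clean artifacts (default weights 0.4/0.3/0.2/0.1, row-stochastic), so
compensation has a recoverable ground truth. Pads 1–4 carry their own
artifact, a cardiac leakage fraction (~0.3 amplitude, giving the observed
~5–15× resting band-power contrast between pad 5 and the peripheral pads)
and sensor noise (0.01 RMS per channel).

**Phenotypes.** Deltas on the normal template: A-Fib — P amplitude 0,
RR CV 0.15; MI — Q ×1.5 (deeper), T ×0.5 (flattened); HF — SCG/GCG
amplitudes ×0.4 (a ~60 % contraction-amplitude reduction) and aortic opening
delayed 20 ms. Directions follow the clinical picture; only the HF amplitude
reduction has a quantitative anchor, the rest are fixed design values.

**Benchmarks.** `make_motion_dataset` / `make_diagnosis_dataset` emulate a
multi-subject study: each "subject" is one 50-s recording (5 segments) with
jittered template (±10 % amplitudes, ±10 % mean RR, ±5–10 ms intervals) and,
for motion, jittered cadence/amplitude (±20 %). Train/test splits are by
recording, so evaluation is always on unseen subjects. Defaults: 200
segments per class, 25 % of subjects held out.

**What the generator does not model:** respiration and baseline wander
(beyond an optional drift term), sensor saturation, electrode motion on the
ECG, non-stationary gait, and realistic SCG/GCG waveshape detail. Passing
tests therefore demonstrate that the pipeline recovers what the model
contains — not clinical performance on real patients.

## Compensation ("vector synthesis")

Per acquisition-pad axis, ordinary ridge regression on the 24 reference-pad
channels over a calibration interval (closed-form normal equations; ridge
= 1e-3 × mean regressor power, intercept on, optional shared integer-lag
search in ±max_lag samples, off by default since the generator mixes with
zero lag). Rigid-body superposition justifies linearity. With zero noise and
no cardiac leakage the mixing weights are identified exactly (< 1e-12); with
default noise, running artifacts are attenuated ≥ 10 dB. The cardiac signal
is distorted only through its finite-sample correlation with the
regressors, which shrinks with calibration length. ECG is not compensated.

## Motion recognition and diagnosis

**Features.** Each 2000-sample segment is block-pooled: one timestep per
`pooling_factor` raw samples carrying per-channel block mean, SD, min and
max. Pooling 10 gives the 200-timestamp evaluation sequences; training draws
random contiguous 50-timestamp crops of those same sequences (truncation for
efficiency), with positional encodings kept at the crop's true offset so
train and evaluation positions coincide. Features are z-normalized with
training-set statistics stored on the model.

**Model.** A pre-norm transformer encoder written in numpy with explicit
backprop (gradients verified against central finite differences): linear
projection → sinusoidal positions → encoder layers (multi-head
self-attention + ReLU feed-forward) → final layer norm → temporal mean
pool → linear classifier; softmax cross-entropy, AdamW (decoupled decay on
matrices only), stratified batches. Two presets:

| preset | proj | layers | heads | ffn | batch | iters | lr |
|--------|-----:|-------:|------:|----:|------:|------:|-----|
| desk (default) | 64 | 2 | 2 | 128 | 64 | 1500 | 1e-3 |
| full | 512 | 8 | 4 | 1024 | 1500 | 10000 | 1e-4 |

The desk preset is sized for single-CPU training in minutes; its iteration
count was set to where the held-out benchmarks saturate. Float32 arithmetic
is used for speed; everything is reproducible from one seed. Baselines
(decision tree, random forest, feed-forward network) come from scikit-learn
and consume time-pooled summary statistics (mean + SD over timesteps).

**Diagnosis** reuses the same machinery on the cardiac channels only
(ECG electrode, pad-5 accelerometer = SCG, pad-5 gyroscope = GCG;
7 channels for the trimodal model). The ablation harness retrains one model
per modality subset on identical segments with an identical budget
(600 iterations by default) so subsets are directly comparable. By
construction the unimodal ceilings are real: ECG alone cannot see the HF
mechanical deltas, and SCG/GCG alone cannot see the MI electrical deltas —
combining modalities is genuinely required, mirroring the motivating
finding.

## Adaptive combination filtering

Per state, a zero-phase 4th-order Butterworth band-pass (sitting 0.5–45 Hz;
walking 3–45; jogging 4–45; running 5–45) cascaded with narrow notches
(Q = 35) at the first three cadence harmonics for locomotion states. The
rising low edge and notches track the artifact fundamental and harmonics.
Combination acts on filter *outputs* weighted by the composite
probabilities — mixing IIR coefficients is unstable in general. Zero-phase
(forward–backward) application preserves fiducial peak positions within
±1 sample on the clean cardiac component; a causal single-pass mode exists
for streaming. Construction-time verification checks ≥ −3 dB across each
passband (tolerance −3.1 dB: Butterworth edges sit at −3.0103 dB and notch
skirts add a few hundredths) and ≥ 20 dB one octave outside the band.

## Fiducials and metrics

R peaks: band-pass 5–25 Hz, squared derivative, 150-ms moving integration,
adaptive relative threshold (25 % of the 99.5th percentile), 200-ms
refractory, refinement to the raw-ECG extremum. All thresholds are relative,
so detection is invariant to amplitude scaling; a flat signal returns zero
beats rather than raising. Q = minimum in [R−60, R−5] ms; T = maximum in
[R+100, R+min(0.6·RR, 450)] ms; P analogous before R.

Mechanical fiducials are ECG-gated. The dominant opening peak (AO / g_J) is
located first in (R+20, R+150] ms; the first peak (MC / g_I) then in
[R, min(AO−20 ms, R+60 ms)]; closure (AC / g_K) in [R+200, R+500] ms clamped
before the next beat; MO / g_L within 150 ms after closure. A beat is
flagged invalid for any fiducial whose window maximum falls below 15 % of
the median post-R amplitude. At very high heart rates MC and AO approach to
within ~25 ms and their kernels overlap, which biases MC by a few
milliseconds; the bias is small enough to preserve the sweep monotonicity
and the 5-ms recovery bound at resting rates. GCG is detected on a
configurable axis (default Rot.Y; the principal rotation axis of the
template), SCG on Acc.Z.

Metrics follow the stated conventions: HR = 60/mean RR, SDRR = SD of RR,
QT = mean(T−Q), MC–MO, g_I–g_L, EMD = mean(MC−Q), PEP = mean(AO−Q),
LVET = mean(AC−AO), PEP/LVET; SDS1 and SDg_J are the SDs of the
beat-to-beat MC and g_J intervals (mechanical analogs of SDRR). Fewer than
two beats yields NaNs with a warning, never an exception. Per-window
aggregation assigns beats by R time.

## I/O

CSV (time column + one column per channel) is lossless. EDF uses the
classic 16-bit layout with 1-s records; the writer/reader pair is minimal
and self-contained, round-trips within the quantization step implied by the
declared physical range, and files are cross-checked against an independent
EDF reader in the tests. Ground truth serializes to JSON (per-beat fiducial
indices, state intervals, mixing weights, label).

## Numerical and design notes

- Segmentation uses half-open windows [start, start+W) with sample 0 at
  t = 0; default stride = window; segment labels by majority overlap, ties
  to the earlier-starting interval.
- Buffered transmission: fs / buffer = 200/20 = 10 packets/s.
- SNR = 10·log10(P_signal/P_noise); zero noise → inf with a warning.
- Band power uses a boxcar periodogram so disjoint bands sum to total power.
- The rank-deficient, zero-ridge compensation fit raises with advice to add
  a ridge term rather than silently pseudo-inverting.
- Problem sizes used by the test suite and the acceptance script (60–120-s
  recordings, 200 segments per class, desk-preset training) were chosen so
  the whole suite runs on one CPU in minutes while keeping all the margins
  reported above.

## Known limitations

- The generator's Gaussian-bump morphology makes fiducial detection easier
  than on real SCG/GCG; the detector's windows and thresholds are
  configurable but tuned to this morphology.
- Compensation assumes linear, (near-)instantaneous mixing; real coupling
  may be dispersive (the optional lag search covers small delays only).
- The classifiers are validated on synthetic subjects; no claim transfers
  to patient data.
- The EDF writer targets the classic single-rate layout only (no EDF+
  annotations, no per-channel rates).
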
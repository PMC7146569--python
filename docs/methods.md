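# Methods

This note documents the models and numerical choices behind `tdhr`: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and the known structural limitations.

## Signal model and conditioning

The raw wrist PPG is modelled as a weak quasi-periodic pulse train (tens of
counts) on a large, slowly wandering baseline (~11,100 counts at 14 bits,
f_s = 32 Hz), with additive sensor noise and occasional large motion
transients. Conditioning extracts the zero-mean heart-band component with a
cascade of second-order recursive sections (biquads, direct form I):

    y_i = (b0 x_i + b1 x_{i-1} + b2 x_{i-2} − a1 y_{i-1} − a2 y_{i-2}) / a0

Both stages share the 0.5–2.5 Hz band (0.5 Hz keeps rates down to
30 bpm in principle; 2.5 Hz rejects the second harmonic of mid-range rates
and most motion energy). The design family is not dictated by the
architecture; we use Butterworth prototypes with the bilinear transform —
stage 1 a single second-order band-pass section, stage 2 a fourth-order
band-pass split into two sections — because a maximally-flat response is
the natural "typical band-pass" and satisfies the frequency contract
asserted in the tests (flat within 3 dB over 0.7–2.0 Hz, ≥20 dB down at
0.05 Hz and 10 Hz).

**The limiter.** Stage 1 clamps its output to `[L_L, L_H]` *inside* the
recursion: the clamped value is stored as y_{i} and used by subsequent
samples. This is the essential nonlinearity — post-hoc clipping would let a
3000-count baseline jump charge the recursion and ring for seconds at
amplitudes far above the pulse, whereas the internal clamp bounds the
stored state at ±150 and the chain recovers within a few hundred
milliseconds. Defaults ±150 counts suit a pulse of 30–50 raw counts
(stage-1 gain ≈ 2 at band centre); `calibrate_limiter` optionally sets
bounds at 1.25× a robust per-cycle amplitude estimate from a calm stretch,
implementing the 100–150 %-of-amplitude guidance. The unlimited comparison
chain runs the identical direct-form-I loop with infinite bounds, so the
two are bit-identical whenever the limiter never engages.

Start-up: all filter states are zero; the first `ceil(2 f_s / f_low)`
samples (4 s at defaults) are treated as warm-up and peaks inside them are
discarded for the first window.

## Binary multiscale peak detection

The local-maxima scalogram (LMS) cell for scale k and sample j is 0 iff
`x[j] > x[j−k]` and `x[j] > x[j+k]` (0-based; the defining formulas are
printed 1-based with the tested sample at i−1 — the mapping is documented
in `ampd.py`). Cells whose comparison partners fall outside the window hold
the "otherwise" value 1. Only `λ_max = 17` rows are stored — the
memory-saving modification — and entries are single bits, not the
random-valued reals of the original formulation.

With out-of-range cells at 1, each row sum satisfies `γ_k = N − z_k` where
z_k is the row's zero count, so the selected scale λ = argmin γ (smallest
index on ties) is the scale with the most scale-k maxima. For a periodic
signal of period T samples this is k ≈ T/2: at that lag the two comparison
samples coincide one half-period away, and every sample in the upper half
of the cycle qualifies. Peaks are columns with `s_i = Σ_{k≤λ} m'_{k,i} = 0`
— samples dominating both neighbours at *every* stored scale up to λ —
which for pulse-like signals is the one crest sample per beat.

**Quality gate.** Only λ_max rows exist, so a minimising scale beyond the
truncation is observable exactly as argmin γ = λ_max; such windows are
declared too noisy (`valid = False`) and excluded. Two consequences worth
stating plainly (both verified by the test suite):

- The gate is a *periodicity-scale* check, not a whiteness check. White or
  broadband noise produces the most strict local maxima at scale 1, so γ is
  minimised at small k and noise windows pass the gate; they are caught
  downstream by the plausibility and minimum-peak-count rules instead.
- Clean slow rhythms are gated out: at 32 Hz a 45 bpm signal has
  T/2 ≈ 21 > 17, so its windows read as "too noisy" even when noiseless.
  The measurable range of the gated detector at the standard configuration
  is ≈57–210 bpm, narrower than the nominal BPM_min = 40 floor implies.
  Near ≈165–175 bpm the 3T/2 harmonic of the half-period ambiguity can
  also land on the boundary and invalidate clean windows.

**Flat peaks.** Weak signals sampled near a crest can yield two equal
samples, invisible to strict-inequality maxima. The signature in the column
sums — `s_{i-2} > 1, s_{i-1} = 1, s_i = 1, s_{i+1} > 1` — is rescued as a
peak at the midpoint, half a sample between the two equal samples; the
half-sample positions flow through all downstream period arithmetic.
Midpoints within one sample of an integer peak are treated as duplicates
and dropped. The rule is evaluated on the raw column-sum sequence.

**Reference detector.** The original real-valued AMPD (full
`L = ⌈N/2⌉ − 1` rows, cells `r + 1` with r uniform on [0,1], column
standard deviation σ_i = 0 as the peak criterion) is implemented as a
validation reference only. Because the 0-cells of both formulations share
one comparison condition, `σ_i = 0 ⇔ s_i = 0` whenever both select the same
λ; the tests assert exact peak-set agreement in that case. For λ = 1 the
sample standard deviation is undefined and the zero-cell criterion is
applied directly.

## Motion masking

The movement indicator is the norm of the first-differenced 3-axis
acceleration, normalised by `G = 2·full_range·√3` — the largest possible
single-step change (a rail-to-rail jump on all three axes), which makes
`d_i ∈ [0,1]` tight. `d_1 = 0` by convention. Thresholding at `H = 0.0025`
(tuned for ±2 g) gives the binary flag V; the time filter then clears
movement runs *shorter* than `T_s = 500 ms`. The description of the time
filter admits two readings — remove long indications or remove short ones —
and the debounce reading is the default because eliminating long movement
indications would defeat artifact rejection; the literal alternative is
available as `spike_mode="remove-long"`.

A consecutive peak pair (p, q) keeps its period iff no flagged sample lies
in `[⌈p⌉, ⌊q⌋]` (half-sample positions round inward). Short clear gaps
between movement runs are not bridged.

## Heart-rate estimation

`bpm = 60 f_s / median(kept periods)`; the even-count median is the mean of
the two central order statistics. Validity requires (a) the quality gate,
(b) at least `P = ⌊N·BPM_min/(60 f_s)⌋` movement-free peaks — counted after
motion exclusion by default, because excluded peaks cannot support the
estimate — and (c) at least one kept period. Estimates above 220 bpm are
marked invalid as doubled-peak pathologies. The stream is conditioned once
(the filters are stateful and streaming); detection runs per window of N
samples advancing by 2 s, each estimate timestamped at its window's
trailing edge.

## Evaluation

MAE over windows matched to the reference series by nearest timestamp
within ±1 s on the 2-second grid. The metric takes the absolute value of
each window error (a signed mean would cancel) and is reported in two
modes: hold-last substitution over all windows, or valid-only together with
the valid fraction. `aggregate` rolls per-recording results into
mean ± SD, the usual per-subject summary.

## Synthetic generator

The generator states a world and keeps it fixed: baseline 11,100 counts,
pulse amplitude 40 counts (the wrist regime), log-normal pulse bump with
systolic rise at 15 % of the period, beat-to-beat jitter 2 % of the period,
white noise SD 1 count and random-walk drift SD 0.5 counts/sample by
default (visible but not dominant wander, within the high-pass rejection
band), accelerometer at rest = gravity on Z plus 2 mg noise. Motion bursts
add an in-band oscillatory transient to the PPG and a simultaneous
broadband shake (smoothed white noise under a short-taper Tukey envelope —
a pure tone would be unrealistically narrowband and its periodic
zero-derivative instants would fragment the motion flag) to all three accel
axes. Everything is deterministic per seed; samples are rounded and clipped
to 14 bits.

Not modelled: optics and hemodynamics (no dicrotic notch, no
amplitude modulation with posture), sensor-specific noise spectra, and
PPG/accel artifact correlation structure beyond simultaneity. A green test
therefore establishes that the pipeline recovers beat timing from signals
of realistic amplitude, bandwidth and disturbance structure — not
performance on any particular device or dataset.

## Known limitations

- **Rate floor from λ_max.** As derived above, clean rates below ≈57 bpm at
  32 Hz are structurally invalid under the λ_max = 17 gate. Raising λ_max
  (a config key) widens the floor at the cost of the memory bound.
- **Quantisation at high rates.** Peak positions are integer (or
  half-integer) samples; at 160+ bpm the beat period is ~11–12 samples and
  the median period moves in steps worth several bpm. Expect ~5 bpm error
  bands near rates whose true period falls midway between integers.
- **Long windows smear transitions.** At N = 1024 each estimate summarises
  32 s; step changes in the true rate produce transiently large errors
  against a 2-second-grid reference.
- The per-subject container reader expects the published layout (64 Hz
  wrist BVP, 32 Hz ±2 g wrist accel, labels every 2 s) and nearest-sample
  holds the accelerometer onto the 32 Hz timebase.
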
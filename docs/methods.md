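# Methods

## The problem

Block-averaged fNIRS analysis assumes every repetition of a task has the
same duration, so that epochs can be averaged sample-by-sample.  In
self-paced protocols (walking a fixed distance, repeating a movement "as
fast as possible") the task duration varies from repetition to
repetition, and sample-by-sample averaging misaligns the hemodynamic
responses.  This package time-normalizes each epoch onto a common
percent-of-trial axis before averaging, so that 0% is always the epoch
start, the task onset/offset fall at comparable positions, and 100% is
the epoch end, regardless of the repetition's raw duration.

## Epoching

Each stim event (onset `t0`, duration `d`) defines an epoch
`[t0 − Δt_base, t0 + d + Δt_post]`, split into a baseline phase of
`Δt_base` seconds, the task phase of `d` seconds, and a post-task phase
of `Δt_post` seconds.  `Δt = [Δt_base, Δt_post]` is user-set (default
`[2, 3]` s); `Δt_post = 0` drops the post-task phase.  Samples are
selected on the closed epoch interval; phase boundaries are kept as
continuous seconds and never snapped to samples (the spline stage, not
the epoching stage, defines the output grid).  Epochs that would extend
past the recording edges are dropped with a warning rather than
zero-padded — padding would fabricate baseline data that baseline
correction later consumes.  At least two surviving repetitions are
required; fewer is an error.  Overlap between one epoch's post-task
window and the next epoch's baseline is allowed but logged.

## Time-normalization

The number of normalized samples for a phase of nominal duration `T` is
`round(C · T)` with `C` a density constant (default 50 samples per
second of nominal duration; round-half-to-even).  For the task phase the
nominal duration is `m`, the arithmetic mean of the repetitions' task
durations within the analyzed set — so every repetition receives the same
task-phase sample count even though its raw duration differs.

Two variants:

* **Version 1 (phase-wise).**  Baseline, task and post-task are
  interpolated separately, each onto `n_phase` evenly spaced query points
  over its own span, and reassembled.  Phases are concatenated half-open
  — each phase contributes points over `[start, end)` and a single
  terminal point (the epoch end) is appended — so no abscissa is
  duplicated and the grid has `n_base + n_task + n_post + 1` points.
  The task onset sits at grid index `n_base` and the offset at
  `n_base + n_task` in *every* repetition, so the onset/offset percent
  positions have exactly zero spread across repetitions.
* **Version 2 (whole-trial).**  Each epoch is interpolated in a single
  pass onto `round(C · (Δt_base + m + Δt_post))` evenly spaced points
  over its full span.  The onset/offset percentages then depend on each
  repetition's own duration
  (`onset_r = 100·Δt_base/(Δt_base + d_r + Δt_post)`), and the reported
  set-level values are their across-repetition averages (averaged as
  percentages, not sample indices).

Interpolation is a cubic spline with not-a-knot end conditions — the
default of MATLAB's `spline`, for reproducibility of endpoint behaviour
— which passes through every raw sample exactly; this knot pass-through
is what preserves the signal shape.  A nominal phase boundary generally
falls between raw samples, so query points may overshoot a phase's own
knot range by up to one sample period; the end cubic is extended over
that sub-sample gap (again matching MATLAB `spline` evaluation) rather
than clamped, because clamping would flatten the last fraction of every
phase.  Overshoot beyond one knot spacing is treated as genuine
extrapolation and is an error.  Every phase with nonzero nominal
duration needs at least 4 raw samples and at least 4 normalized samples
(`round(C·T) ≥ 4`, otherwise "increase C").

Entirely-NaN channel traces (channels pruned upstream) are carried
through as NaN and excluded from metrics; scattered NaN inside an
otherwise finite trace is rejected at read time, since interpolating
over hidden gaps would silently fabricate data.

## Averaging and baseline correction

The HRF is the point-wise arithmetic mean over repetitions on the common
grid, with the sample SD (n−1 denominator; the choice is a convention
and is only a scale factor on the spread band).  Baseline correction is
applied *after* averaging: per channel and chromophore, the mean of the
grid points strictly before the task onset is subtracted from the whole
trace, making the baseline-segment mean 0 µM (to ~1e-16 in practice;
the onset point itself belongs to the task).  The correction is
shift-only; the SD is untouched.  A per-repetition correction variant
(`correct_trials`) exists for display purposes only.

## Validation metrics

* **Peak preservation.**  For each repetition the position and amplitude
  of the maximum and minimum are compared between the raw epoch and the
  normalized one mapped back to epoch seconds.  "Position" is ambiguous
  as a single number, so three quantities are reported: |Δt| in seconds,
  |Δamplitude| in µM, and the 2-component Euclidean norm on the raw
  (seconds, µM) pair without rescaling.  The Euclidean norm (averaged
  over both extrema and all finite channel/chromophore traces) is the
  error measure of the C sweep.  Note that the time of an extremum is
  only meaningful when the extremum is isolated: on a noise-free
  synthetic trace the non-evoked extremum (e.g. the maximum of HbR) is a
  flat-zero baseline plateau whose argmax position is arbitrary.
* **Smoothness index.**  Sample SD of the first differences of a trace,
  taken on the uniform normalized grid (unit index spacing — the axis is
  percent, not seconds).  Lower is smoother.  Whole-trial interpolation
  (version 2) produces systematically smoother traces than phase-wise
  reassembly, whose phase joints are only C0-continuous.
* **Onset/offset table.**  Per-repetition and summary onset/offset
  percentages for both versions.  Version-1 SDs are exactly zero; to
  report that exactly in floating point, SDs are computed on
  first-element-shifted values (SD is shift-invariant, and identical
  values then give exactly 0 rather than a ~1e-14 artifact of the
  floating mean).
* **Wilcoxon signed-rank test.**  Used to compare the two versions'
  smoothness and boundary-identification errors.  Zeros are dropped,
  ties midranked.  For n ≤ 25 the two-sided p is exact, computed by a
  convolution over doubled midranks (equivalent to enumerating all 2^n
  sign assignments); above that, the normal approximation with tie
  correction.  The reported statistic is min(W+, W−).
* **C sweep.**  The mean peak Euclidean error as a function of
  C ∈ {10, …, 100}; the stability flag is the first C after which every
  successive relative change stays below 5%.  On the default synthetic
  fixture the flag fires at C = 40, supporting C = 50 as the default.

## Synthetic recordings

The generator emulates a self-paced motor block at the concentration
level (the stage this tool consumes):

| parameter | default | meaning |
|---|---|---|
| `fs` | 10.27 Hz | sampling rate |
| `n_reps` | 6 | task repetitions |
| `duration_mean`, `duration_sd` | 6.60, 1.30 s | task durations ~ truncated normal (±3 SD, floor 0.5 s) |
| `iti_mean` | 25 s | rest between task offset and next onset (±20% uniform jitter) |
| `amplitude_hbo` | 0.5 µM | evoked HbO2 peak |
| `hbr_ratio`, `hbr_delay_s` | −1/3, 1 s | HbR = ratio × delayed HbO2 evoked part |
| noise | cardiac 1 Hz/0.05 µM, respiration 0.25 Hz/0.05 µM, Mayer 0.1 Hz/0.08 µM, drift 0.02 µM/min, white SD 0.03 µM | physiological + sensor noise (HbR at half amplitude) |

The evoked HbO2 response is a canonical double-gamma kernel (peak ≈ 5 s,
undershoot ≈ 15 s, ratio 1/6) convolved with the task boxcar and scaled
so the recording's noise-free peak equals `amplitude_hbo`; HbT is the
sum of the generated HbO2 and HbR.  The 25 s inter-trial interval lets
the undershoot decay before the next epoch's baseline.  Everything is
reproducible bit-for-bit from the seed, including the SNIRF fixture
bytes (HDF5 timestamps disabled).

What the generator does **not** emulate: the upstream pre-processing
chain (optical-density conversion, motion-artifact correction, and in
particular the 0.01–0.2 Hz band-pass filter real pipelines apply before
this stage).  The synthetic white-noise term is therefore broader-band
than real pre-processed concentration data, which inflates absolute
peak-position errors relative to what filtered recordings show; passing
tests demonstrate the algorithm's properties under these harsher
conditions, not the absolute error levels of any particular study.
Motion artifacts and channel-specific optical coupling are also not
modelled.

## Numerical choices and degenerate inputs

* Rounding of sample counts: round-half-to-even (`np.round`).
* `Δt_post = 0`: the post-task phase gets zero grid points and the
  offset coincides with 100%.
* The nominal task offset may fall up to one sample period after the
  last retained sample (discrete grid vs continuous boundary); this is
  accepted.
* Amplitude recovery is assessed against a noise-free oracle measured
  directly on the regenerated continuous signal (per-trial
  baseline-relative peak, averaged), never through the
  spline/averaging path being tested.  The recovered peak is searched
  over the full response window (task + post-task), because the
  hemodynamic peak lags the stimulus and typically lands near or after
  the task offset.
* Problem sizes in the test suite and acceptance script (6-repetition
  recordings, 1–2 channels, 50 seeded sets for the smoothness
  comparison) are chosen so the full pipeline runs in seconds while
  keeping every across-repetition statistic meaningful.

## Known limitations

* The half-open phase-concatenation convention (grid size
  `n_base + n_task + n_post + 1`) is one of several defensible
  boundary-bookkeeping schemes; onset/offset percentages shift by a
  fraction of a grid step between schemes.
* Version 1's phase joints are only value-continuous; derivative-based
  analyses should prefer version 2 or operate per phase.
* Dynamic-time-warping alignment is out of scope by design.
* Group-level statistics beyond simple HRF averaging are not provided.
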
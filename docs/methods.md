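# Methods

This note documents the models, conventions and numerical choices behind
`dancedsp`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Task model

A trial presents a sequence of L dance-mat directions (default L = 6, the
standard DSP range is 3–7) by lighting placeholders in turn, then shows a
Go or NoGo cue.  Timing template (ms): fixation 1000, stimulus 750 each,
pre-cue interval 1500, NoGo wait 3000, feedback 1000.  The cue of a 6-step
trial therefore lands at 7000 ms from trial start.

Blocks hold `n_go_per_seq` Go trials of each of the two trained sequences
plus `n_nogo` NoGo trials (defaults 24/24/4 → 52 trials, 92% Go when
rounded).  The NoGo trials are **additional** to the 48 Go trials; the
alternative reading (4 of 48 replaced) is not used.  The whole 52-trial
multiset is shuffled once with a seeded generator; no adjacency or
alternation constraint is imposed, and NoGo trials alternate which
sequence they display.  A 30 s break follows trial 24 of each block; 180 s
separate blocks, with a 600 s break after block 4.  Sessions have
`n_training` blocks (default 4) and `n_test` blocks (default 2: one
familiar, one novel pair, familiar first for even participant indices).

**Rotation counterbalancing** remaps every direction by a common clockwise
quarter turn (left→up→right→down→left), fixed by the task's worked example
(←→↑↓→← → ↑↓→←↓↑) and self-tested at import.  Participant *p* receives
rotation *p* mod 4 of both base sequences — a deterministic rule chosen
here; the original task description counterbalances positions without
prescribing the assignment.  The default novel test pair is the reversed
base sequences: same direction composition, different serial order, and
verifiably not a rotation of either trained sequence.

**Scoring.** A response before the Go cue (or any response on a NoGo
trial) voids the trial ("Too early!"); voided trials are not re-queued.
Otherwise each step is compared element-wise and feedback is "Good" or
"Wrong steps: i,j" (1-based).  Step-level RT is the first-step latency
from the cue plus inter-step intervals for steps 2..L — the standard DSP
convention; no device-onset delay is subtracted by default (hardware
response-onset latency is assumed compensated upstream).  Block summaries
report the mean step RT of accurate trials and the percentage of Go trials
with any mistake.

## Synthetic-session generator

The generator exists to give the analysis pipeline a ground truth; its
defaults are the study conditions the package is validated under.

* **Behavior.** Step RT of the t-th Go trial: `300 + 280·exp(−0.025·t)` ms
  plus Gaussian noise (SD 50 ms), truncated above 50 ms.  The asymptote,
  gain and decay were chosen analytically so the session mean step RT is
  ≈ 358 ms, matching the published pilot mean for this task; the decay
  puts most learning inside the first two blocks, as pilot learning curves
  show.  Each step is independently wrong with probability 0.05.
* **EEG.** 22 channels at 500 Hz (both configurable).  Each channel is a
  6 Hz sinusoid of 10 µV amplitude with a channel-specific random phase.
  During cue/step segment *k* of every complete Go trial the amplitude is
  multiplied by `sqrt(1 + ERD/S_k/100)` — *power-correct* scaling, so the
  programmed percentages are the exact expected band-power changes, which
  keeps recovery tests sharp.  The modulation spans each step's preceding
  marker to its own marker, matching the analysis segmentation exactly, so
  truth and pipeline share one definition of "per-step".  Broadband 1/f
  noise (spectrally shaped white noise, PSD ∝ 1/f flattened below 1 Hz,
  SD 7 µV) yields a theta-band amplitude SNR ≈ 3.  Default truth profile:
  (−30, −20, −10, +10, +20, +30)% — desynchronization over the early
  steps turning into synchronization late in the sequence.
* **Kinematics.** CoM displacement at 100 Hz: each response adds an
  out-and-back cubic smoothstep excursion along its direction's vector
  (±0.30 m on x for left/right, ±0.30 m on y for up/down, +0.03 m on z
  for every step), ramp duration T = min(0.4 s, neighbouring inter-step
  intervals), outbound ramp ending at the response timestamp.  Peak ramp
  speed is 1.5·|D|/T.
* One master seed drives three independent child generators (behavior,
  EEG, kinematics); identical seeds give bit-identical sessions.

**What the generator does not emulate:** volume conduction or any EEG
forward model (channels are exchangeable up to phase), movement or ocular
artifacts beyond broadband noise, RT autocorrelation beyond the learning
curve, too-early responses, biomechanical gait or balance dynamics.
Passing recovery tests therefore demonstrates that the pipeline's
*arithmetic and segmentation* are correct at realistic SNR and trial
counts — not that it is robust to real-world artifacts, which the
pluggable artifact-removal hook is left open for.

## Epoching and synchronization

Streams share one clock up to a constant per-stream offset (`align_streams`;
no drift model — adequate for file-based recordings).  Epochs anchor at the
Go cue and span `[cue − 0.1 − 0.2 s, last step + 0.1 s]`: 200 ms pre-cue
baseline plus 100 ms anti-edge padding per side.  Marker times map to
sample indices by nearest-sample rounding (error ≤ half a sample period);
windows are half-open.  Cue anchoring yields exactly six analysis segments
(cue→s1, s1→s2, …, s5→s6), which is why it is the default over first-step
anchoring; the segmentation API takes an arbitrary ordered edge list, so a
five-segment first-step reading works too (300 bins → 5 × 60).

Epochs cut from a continuous recording carry up to 1 s of real surrounding
signal as *context*.  The Morlet transform runs over context + epoch and
crops the context afterwards, so the wavelet sees genuine data at the epoch
boundaries; without context (synthetic stand-alone epochs) the data is
reflect-extended instead.  This matters quantitatively: with only 100 ms of
padding, boundary extension artifacts otherwise bias the short baseline
window by several percent, which propagates into every ERD/S value.

## Theta ERD/S analysis

Preprocessing: zero-phase Butterworth band-pass 0.3–30 Hz (order 4 per
direction; passband/stopband behavior asserted in tests), average
reference, and an artifact-removal hook that defaults to identity
(component-based cleaning such as ICA is intentionally out of scope and
pluggable).

Morlet parameters: 5 frequencies at 1 Hz spacing across 4–8 Hz, 5 cycles —
a conventional choice; both exposed.  Band power is calibrated against a
unit-amplitude sinusoid at the band centre so values are in µV²
(wavelet-gain conventions differ between implementations; ERD/S ratios are
unaffected).  The 100 ms padding is trimmed after the transform.

**Time normalization.** The execution span is reduced to `n_bins = 300`
values: equally spaced bin edges, each sample assigned to the bin
containing its midpoint (ties to the lower bin), each bin replaced by its
mean.  Default mode `per_step` aligns bins to the six cue/step segments
(50 bins each), retaining step-level structure; `global` mode spreads the
300 bins across the whole span irrespective of step boundaries.  Both
readings are defensible; `per_step` is the default because the six-step
averages are the analysis target.  A segment shorter than one sample fills
its bins from the nearest sample with a warning.  When the sample count
divides evenly, binning conserves the series mean exactly, and global mode
is verified against an explicit brute-force index-window oracle.

**Baseline and ratio.** Baseline = mean band power over [−200, 0) ms
relative to the cue (the window is fixed by the task design; the mean is
our choice of statistic).  ERD/S per step = `(P_step − P_base)/P_base·100`.

**Order of averaging.** Per-epoch ERD/S profiles are available, but the
across-epoch aggregator defaults to *pooling*: mean step power and mean
baseline power across epochs first, ratio second.  The
ratio-then-average estimator is biased upward at realistic SNR because the
noisy 200 ms baseline sits in the denominator (Jensen's inequality) — on
the default synthetic conditions the bias exceeds +20 percentage points,
versus ≈ 6 points of residual (smoothing-dominated) error for pooling.

Residual recovery error is dominated by wavelet temporal smoothing
(σ ≈ 0.1 s in power) across step boundaries ~0.3–0.6 s apart, which mixes
adjacent segments and leaks the first step's modulation into the baseline
window.  This is inherent to Morlet analysis at these time scales, affects
real data identically, and is why the acceptance bar is a mean absolute
error ≤ 10 percentage points rather than exactness.

## Kinematics

Velocity and acceleration use central differences (one-sided at the ends):
second-order accurate, exact for linear ramps, and inverted by trapezoidal
integration to O(h²) on smooth traces.  Per-step windows are identical to
the EEG segments and tile the execution span without gaps or overlaps.
Axis convention follows the simulator manifest (x left–right, y
forward–back, z vertical); real motion-capture exports may differ, so the
mapping is a configuration concern.  Because the published summary
statistic is ambiguous between signed and absolute mean velocity, both are
exported.  Block averages default to accurate trials only, mirroring the
behavioral convention.

## Formats, pipeline, determinism

Recordings travel as a plain-text CSV bundle (one CSV per stream + markers
CSV + `meta.json`); XDF ingestion is available behind the optional
`pyxdf` dependency.  The pipeline (schedule → simulate/read → preprocess →
epoch → ERD/S + kinematics + behavior tables) writes tidy CSVs keyed
(participant, block, channel/axis, step) plus a JSON manifest with the
config snapshot, seed, per-stage trial counts (scheduled / responded /
epoched / analyzed, making attrition auditable) and SHA-256 hashes of all
outputs.  Fixed seeds reproduce every output byte-for-byte.

## Problem sizes

The test suite validates recovery on deliberately small sessions: the
end-to-end ERD/S recovery uses 2 training blocks at full trial counts
(~96 epochs) with 6 EEG channels — channels are statistically exchangeable
in the generator, so recovery is insensitive to channel count — and the
acceptance script runs the same experiment at the full 22 channels.
Behavioral recovery uses the full 4-block, 192-trial learning phase.

## Known limitations

* No ICA or artifact repair; the hook only delegates.
* No clock-drift correction (constant offsets only).
* No biomechanical model behind the CoM traces; no anticipatory postural
  adjustment measures.
* ERD/S per-step estimates are smoothed across neighbouring segments by
  the wavelet's temporal support; sharper per-step separation would need
  fewer cycles (worse frequency resolution) or longer inter-step
  intervals.
* Statistical modelling across participants (mixed-effects models,
  questionnaire data) is out of scope; the tables are designed to feed
  standard statistics packages.
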
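# Methods

This note documents the models and procedures implemented in `hdsemg`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
demonstrate about real recordings.

## 1. Recording setup being emulated

Two 64-contact electrode grids (8 × 8, 10 mm pitch) over the extensor and
flexor compartments of the forearm, sampled at 2048 Hz; nine strain gauges
(four for D2–D5 finger flexion/extension, two for thumb
flexion/extension and abduction/adduction, three for wrist
flexion/extension, pronation/supination and radial/ulnar deviation)
sampled at 200 Hz on a second device.  The force transducers output 0–5 V
for ±100 N with 2.5 V at rest (`force = volts·40 − 100 [N]`).  A TTL
channel with 0.2 s pulses every 2 s is recorded by both devices and is the
only time reference shared between them.

The cue protocol presents movement blocks of five repetitions, 5 s hold and
5 s rest; the full session comprises 66 blocks (65 unique gestures, one
gesture scheduled twice).  Each movement decomposes into a subset of 16
basis DoFs through a 66 × 16 Boolean table.  Antagonist pairs
(flexion+extension of one joint, abduction+adduction,
pronation+supination) never co-occur in a row, because their net isometric
force would cancel at the gauge.

Movement codes: the stored class codes span 0–65 (0 = rest).  Because the
protocol has 66 blocks but 65 unique gestures, the default full-session
schedule reuses code 58 (D2–D5 extension, the duplicated gesture) for the
final block.  The complete code-to-gesture mapping of the original
supplementary table is not reconstructible from public text, so the bundled
table pins the rows that are derivable (the 16 basis movements as codes
1–16, and codes 31, 32, 33, 58, 60) and fills the remainder with
rule-respecting placeholder gestures tagged `user-supplied`; the exact
original table can be substituted as a CSV
(`movement_code, name, <16 DoF columns>`).

## 2. Synthetic force model

Each gauge idles at 2.5 V.  During an entry, every active DoF adds a signed
plateau (default 1 V ≈ 40 N) on its gauge, with 0.2 s linear rise and fall
ramps **centered on the true event times**: the envelope crosses its 50 %
level exactly at the ground-truth onset/cessation.  This makes the
generator consistent with the re-labelling detector's definition of an
event, so the noiseless invariant "re-labelling recovers every true event
within one sample" is well-posed.  White sensor noise (default SD 5 mV) is
added and the result clipped to 0–5 V (flagged in the ground truth).

Reaction latencies are drawn from truncated normals with the dataset-level
defaults of the emulated protocol: onset mean 0.24 s (SD 0.33 s),
cessation mean 0.56 s (SD 0.46 s), truncated to [−0.5, 2] s so that events
stay inside the detector's search windows.  (Reported summaries of the
emulated protocol give the mean cessation latency as both 0.56 s and
0.7 s; 0.56 s is used.)  Negative lags emulate the
anticipatory onsets that rhythmic cueing produces.

## 3. Synthetic EMG model

The generator is deliberately phenomenological — it reproduces the spatial
statistics the validation stages measure, not motor-unit physiology:

* Each active DoF owns a source under its grid (flexion-like DoFs under the
  volar grid, extension-like under the dorsal grid), at an across-fiber
  center spread over the array, depth 4 mm.
* A source is a pool of 8 band-limited Gaussian carriers (20–450 Hz,
  4th-order Butterworth), standing in for motor-unit pools.  Each carrier
  has its own conduction velocity drawn uniformly from 4 ± 1 m/s
  (physiological mid-range) and its own Gaussian territory along the fiber
  axis (SD 3 electrode pitches).
* A carrier's potential at a contact combines a **travelling** component,
  time-shifted along the fiber axis by (along-distance)/velocity using
  frequency-domain fractional-sample shifts (10 mm / 4 m/s = 2.5 ms ≈ 5.1
  samples, so sub-sample accuracy matters), and a **non-propagating
  far-field** component (fraction 0.5) that fiber-end effects project
  synchronously along the array.
* Amplitude scales as `exp(−d/λ)` with `d` the 3-D source–contact distance
  and λ = 15 mm.
* Additive per-contact white noise (SD 0.02 in the generator's arbitrary
  amplitude units — the hardware's 150× amplification chain leaves no
  published absolute scale), plus a common-phase 50 Hz interference whose
  amplitude varies by ±20 % across contacts (a perfectly common sinusoid
  would cancel exactly under bipolar derivation and leave the notch filter
  nothing to do).
* Bad contacts (configurable mask) receive Poisson-timed (10 /s during
  movement epochs) biphasic ~12 ms transients at 10–20× the array's
  movement-epoch RMS, plus 5× elevated 50 Hz pickup — the two signatures of
  a failing skin-electrode interface.

Why the far-field and territory terms: with a pure delay-plus-attenuation
model, the zero-lag correlation of along-fiber pairs collapses to the
estimation noise floor within one electrode pitch, because a 20–450 Hz
carrier decorrelates in ~0.5 ms ≪ the 2.5 ms inter-electrode delay — and
the residual carrier autocorrelation oscillates in sign with distance.
Real grids instead show a *gradual, monotone* along-fiber decay.  The
non-propagating component and finite territories are the standard
mechanisms behind that behaviour; averaging over the velocity-jittered pool
additionally damps the oscillatory part of the carrier autocorrelation.
With the defaults, mean R² decays monotonically on both axes over all
seven realizable distances and is larger across fibers than along them at
every distance, which is the pattern the QC stage is designed to verify.

All randomness descends from one seed through `numpy.random.SeedSequence`
substreams (forces; carriers; velocities/territories; sensor noise; line
noise; artifacts), so a session is byte-reproducible, and scaling all
source gains scales the noise-free EMG linearly.

## 4. Preprocessing

**Differential derivation.** `ch_k = contact_{k+1} − contact_k` within each
electrode; the last channel of an electrode wraps to the first contact of
the next.  Channel 128 (which would wrap cyclically to contact 1) is
computed but flagged invalid — it is not referenced like the others.  The
derivation is linear and telescopes exactly.

**Grid layout.** The deposited arrays are L × 8 × 8 with the second index
along the forearm.  The default layout places channels 1–8 along the first
along-forearm line (consistent with differentiation along the fibers); the
exact pinout of the physical connector is not publicly documented in
machine-readable form, so the layout is configurable via CSV
(`row, col, channel`).

**Line-noise filter.** The original offline filter is specified as a
Butterworth "band-pass" centered at 50 Hz with 4 Hz width, yet its purpose
is to *remove* power-line interference; it is implemented as the
corresponding band-**stop** (3rd-order, 48–52 Hz) applied forward–backward
(`sosfiltfilt`, reflective padding) for zero phase.  Steady-state
attenuation at 50 Hz exceeds 40 dB; at 100 Hz the response is within 1 dB
of unity.  Harmonics are deliberately left untouched, mirroring the
original processing.

## 5. Synchronization and resampling

Pulse edges are timestamped at the first sample at-or-above (below) 50 %
of the channel's min–max range; no sub-sample interpolation, since the
coarse chain's 5 ms quantization is negligible against 5 s epochs.  Both
chains are truncated to [first leading edge, last trailing edge] and their
pulse counts must agree (a dropped pulse means lost data); equal counts
with a divergent inter-pulse interval produce a warning, not a failure.

The 200 Hz chain is then resampled to 2048 Hz: linear interpolation for
analog channels, **zero-order hold for categorical timelines** (class,
repetition, labels).  The original processing passed everything through a
single interpolation routine; linearly interpolating class codes would
manufacture meaningless fractional classes, so the hold semantics are a
deliberate deviation — categorical resampling can never emit a code absent
from its input.

## 6. Temporal re-labelling

The seven-step procedure, per protocol entry, on the summed rectified
baseline-subtracted activity signal (computed from raw volts — baseline
subtraction and rectification make the result invariant to the affine
volts→newtons conversion, and to any positive rescaling of the forces):

1. rest baseline = per-channel mean over [cue_on − 1 s, cue_on);
2. subtract the current baseline sample-by-sample, switching baselines at
   each cue onset (samples before the first cue use the first baseline);
3. rectify and sum the nine channels;
4. m = activity minimum over [cue_on − 1, cue_on), M = maximum over
   [cue_on, cue_on + 5];
5. onset = first sample in [cue_on − 1, cue_on + 5] strictly above
   m + 0.5 (M − m) — the search starts one second before the cue to admit
   anticipatory onsets;
6–7. symmetrically for cessation (maximum before cue-off, minimum after,
   first sample below the 50 % level).

**Noise floor.** An entry with M − m below 10× the MAD of rest-period
activity is reported *not detected* and keeps its cue timing (no data is
silently dropped).  The multiplier is set by the statistics of the
detector itself: the max-minus-min of pure sensor noise over the 1 s + 5 s
windows is ≈ 6 noise SDs ≈ 9 MADs, so a 5× floor would "detect" movements
in noise.

**Interval semantics.** Adjusted intervals are half-open [onset,
cessation) on the target grid, partitioning the timeline with rest; if an
onset precedes the previous cessation the earlier interval is truncated
and flagged.  Adjusted labels are taken from the entry's cue-interval
label row, adjusted classes/repetitions from the protocol entry; adjusted
class codes are always a subset of the cue-based codes.

**Operating regime.** The algorithm assumes a clean pre-cue baseline
window.  An onset earlier than the cue (anticipation) leaks plateau into
its own baseline window, after which the 50 % threshold is computed
against a corrupted reference — no implementation of the printed steps can
recover such events to one sample.  The parameter-recovery validation is
therefore stated over non-anticipatory lags (truncated to [0.1, 2] s),
while the generator's default latency model keeps anticipatory onsets, as
real sessions contain them.

## 7. Channel quality control

**Outlier scores.** Per channel, p⁹⁹ = 99th percentile of rectified
voltage over the whole session (robust against sparse spikes deciding the
maximum).  Q1/Q3 are taken over the eligible channels of *both* grids of
one session pooled (one recording session is one pool), with the
linear-interpolation quantile convention.  T = Q3 + 1.5·IQR;
Oᵢ = max(0, p⁹⁹ᵢ − T)/IQR; when IQR = 0 every score is 0 (identical
channels cannot be outliers relative to one another), and fewer than four
eligible channels is an error.  Eligibility excludes the eight channels
per grid whose bipolar pair spans the grid boundary (multiples of 8) plus
channel 128 — 112 eligible channels.  (Published counts for this exclusion
rule state 114 channels, but the rule as stated yields 112; the rule is
followed.)  Scores are exactly invariant under rescaling all channels
by any positive constant.

**Spectra.** Welch PSD per channel (1 s Hann window, 50 % overlap —
unstated in the source, both configurable), summarized as frequency-wise
25/50/75 % quantile curves, which satisfy q25 ≤ q50 ≤ q75 pointwise by
construction.  Notched sessions show the expected local minimum in the
48–52 Hz bins.

**Correlation vs distance.** Squared zero-lag Pearson correlation for
every channel pair within one line of one grid (pairs never cross grids or
lines), grouped by integer distance 1–7 — the separations realizable among
8 collinear cells — with mean and 25th/75th percentiles per distance.
Constant channels are skipped with a warning.  On the derived differential
grids the boundary-spanning channels sit physically outside their nominal
grid column, which injects a spurious correlation bump at distance 7; the
generator-structure validation therefore measures the profiles on
monopolar grids, where every cell is at its nominal position.

## 8. Session records

Thirteen variables, names exactly as deposited (the on-disk name `class`
maps to the in-memory field `class_timeline`).  Files are written as
MATLAB v7.3 (HDF5) containers — hour-long 128-channel sessions exceed the
classic format's 2 GB limit — with the 512-byte MATLAB header and
column-major dataset order, `MATLAB_class` attributes (`double`, `uint8`,
`logical`), so both MATLAB and h5py read them.  The reader accepts classic
and 7.3 dialects, infers L from the class vector, and re-orients arrays so
time is always the first axis.  Validation checks shapes, ranges
(class 0–65, repetition 0–5), Boolean labels, label/rest consistency and
nonnegative outlier grids, reporting every violation with field and index
rather than raising.  Round trips are exact for integer arrays and
bit-exact for float64 arrays.

## 9. Problem sizes in the validation suite

The test and analysis runs use scaled-down sessions chosen to exercise
every stage with comfortable statistics: 2–8 movements × 1–2 repetitions
(tens of seconds to ~2 minutes of signal) for EMG-bearing checks, the full
330-entry schedule for protocol arithmetic and latency sampling, 16 basis
movements × 5 repetitions (80 events) for latency parameter recovery, and
20 seeded sessions for the bad-contact detection rate.  A full-scale
session (≈ 3300 s × 2048 Hz × 128 channels ≈ 7 GB as float64) is supported
by the same code paths but is not materialized in the suite.

## 10. Limitations

* The EMG generator reproduces second-order spatial statistics (amplitude
  maps, delay structure, artifact signatures), not motor-unit recruitment,
  firing statistics, force-EMG nonlinearity, or fatigue; passing its tests
  shows the *pipeline* is correct, not that the simulator is a substitute
  for real recordings.
* Amplitudes are in arbitrary units; no absolute-voltage claims are made.
* No clock drift between the two chains is modelled (the shared TTL makes
  drift unobservable at epoch scale in the original setup as well).
* The placeholder rows of the bundled DoF table are plausible gestures,
  not ground truth; analyses that depend on the exact code-to-gesture map
  must supply the original table.
* Latency statistics computed on synthetic sessions estimate the
  *generator's* truncated-normal parameters, not any human population
  value.
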
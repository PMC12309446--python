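# Methods

This note documents the models and procedures `eegqc` implements, the
parameters that matter, the design choices made where the method
definitions left room, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signal model and preprocessing

A recording is an M × T matrix in microvolts with sampling rate fs
(protocol default: M = 16 channels of the 10–20 system, fs = 256 Hz,
3 minutes per condition — eyes closed, eyes open, or a cognitive
task). No unit conversion happens silently: EDF channels declared in
volts are converted to microvolts on read, CSV is stored in
microvolts.

Before any detection the signal is high-pass filtered at 0.5 Hz and
cut into contiguous, non-overlapping 2 s epochs (trailing partial
epoch discarded). Filters are zero-phase FIR: Hamming-window designs
applied forward–backward (`filtfilt`), with reflect padding of one
filter length so startup transients stay out of the first epoch.
Transition widths are ≤ 0.5 Hz for the 0.5 Hz high-pass (≈ 1691 taps
at 256 Hz) and ≤ 5 Hz for the 50 Hz low-pass used by the PREP
noisiness split (≈ 169 taps). The high-pass taps are re-centred to
put an exact null at DC; the resulting broadband gain shift
(~taps.sum()/ntaps) is orders of magnitude below the passband ripple.
Zero-phase filtering was chosen so channel- and epoch-level criteria
computed on the filtered signal stay sample-aligned with the raw
recording; the cost is a doubled effective filter order, which only
sharpens the bands. The band split returns high = original − low, so
the two components sum back to the input exactly.

## FASTER criteria (threshold |Z| > 3)

Each criterion computes one statistic per channel (or epoch),
standardizes the vector of statistics into Z-scores using the sample
SD (ddof = 1), and flags entries with |Z| above 3. A zero or
undefined spread yields all-zero Z-scores: identical channels are not
evidence of badness. The criteria are written as magnitude tests
(two-sided); the per-run metadata records this choice.

Channel criteria:

* **correlation** — mean |Pearson r| of each channel against all
  others, computed on the full filtered recording, no distance
  weighting. Either tail is suspicious after standardization: an
  electrode that has lost scalp contact decorrelates, while a bridge
  or shared-artifact pair over-correlates.
* **variance** — per-channel signal variance.
* **Hurst exponent** — classical rescaled-range (R/S) analysis:
  non-overlapping blocks of dyadic sizes from 16 up to a quarter of
  the series; per block, the range of the cumulative mean-deviation
  divided by the block sample SD; H is the slope of log mean(R/S)
  against log block size. White noise gives H ≈ 0.5 (with a small,
  well-known upward small-sample bias — the estimator reads ~0.54 at
  n = 65536), EEG-like persistent signals read higher; channels whose
  H is an outlier are non-physiological. A constant channel has no
  defined H and is excluded from the standardization (the correlation
  and variance criteria still see it). Block range and the estimator
  parameters live in `QCConfig` so a DFA-style alternative can be
  swapped in.
* **powerline** — mean Welch PSD over 48–62 Hz, a band that covers
  both 50 and 60 Hz mains; the same Welch settings as the spectral
  module, for consistency of the estimator across the package.

Epoch criteria: amplitude range (max − min) and within-epoch
variance, each averaged across channels; and the deviation parameter
— the epoch-mean of each channel minus that channel's average
epoch-mean, averaged across channels. The deviation reference is
channel-wise (each channel's own epoch-mean average), not the grand
mean; the alternative reading exists and the choice is recorded in
the result metadata. Each N-vector is Z-scored over epochs.

## PREP criteria (robust threshold 5)

The robust SD is (Q3 − Q1) × 0.7413 with linear-interpolation
quartiles; 0.7413 is 1/(2 Φ⁻¹(3/4)), the constant that makes an IQR
agree with the SD for Gaussian data (verified to four decimals by the
test suite and the acceptance script). The robust Z is
(value − median)/robust SD, with the same all-zeros degenerate rule.

Channel criteria:

* **flat/NaN** — any NaN; or peak-to-peak amplitude below 1×10⁻¹⁵ µV
  over the whole channel; or flat in more than 1 % of 2 s windows.
  This criterion is absolute-scale by definition and is the only one
  that is not gain-invariant.
* **amplitude** — robust SD of the full filtered signal per channel,
  standardized across channels with the robust Z; flagged at
  |Z| > 5. The magnitude test covers both saturated and near-dead
  (but not strictly flat) electrodes.
* **correlation** — per 2 s non-overlapping window, each channel's
  best |Pearson r| against any other channel; flagged when that best
  correlation falls below 0.4 in more than 1 % of windows. Windows
  are 2 s to match the epoching (the classical PREP default of 1 s is
  a deliberate deviation here, recorded in run metadata).
* **noisiness** — ratio of high-band to low-band robust SD after the
  50 Hz FIR split, robust-Z standardized, flagged one-sided at
  Z > 5: only an excess of high-frequency content indicates a noisy
  electrode; an unusually clean one is not a fault.

Channels flagged flat/NaN are excluded from the cross-channel
standardization of the other criteria and as correlation partners, so
one dead channel cannot mask another; their NaNs are zeroed only
after the flag is recorded.

The epoch-level extension computes, per channel and epoch, the median
and the robust SD of the epoch's samples; standardizes each statistic
across the channel's epochs with the robust Z; takes the larger
magnitude of the two as the epoch–channel score; and flags an epoch
when its maximum score over channels exceeds 5. Standardizing both
location and scale covers slow drifts as well as bursts, and the two
components are exposed separately in the result (`location`,
`scale`) so either single-statistic reading can be recovered.

## Spectral analysis

Welch PSD: Hann taper, 2 s window, 50 % overlap, density scaling —
0.5 Hz resolution. The peak alpha frequency is the frequency of the
maximum PSD bin with 7 ≤ f ≤ 12 Hz (endpoints inclusive, ties to the
lower frequency, no interpolation — the peak is read directly off the
grid). Per-channel peaks are picked first and averaged; the peak of
the channel-averaged spectrum is reported separately since both
conventions are in use. PAF is defined on the eyes-closed condition;
other conditions produce a warning, not an error.

## Group statistics

Per-recording quality is the percentage of flagged channels and
epochs (so one bad electrode of 16 reads 6.25 %, of 64 reads 1.6 % at
one decimal). Groups are summarized as mean ± SEM (SD/√n, ddof = 1).
Unequal-size comparisons use the averaged-p bootstrap: draw
|benchmark| values from the field group without replacement, run a
two-sided t test against the benchmark, repeat (default 50
iterations) and report the mean p. With one iteration and equal sizes
this is exactly one t test. Within-cohort contrasts (sex,
indoor/outdoor, team, condition) use plain two-sided t tests per
unordered level pair. All t tests are Welch (unequal variances) —
slightly conservative relative to the pooled-variance test and the
safer default; the choice is recorded in the comparison object. No
multiple-testing correction is applied across the contrast grid.
Every stochastic operation takes an explicit seed and records it.

## Dashboard

The daily report aggregates per-recording summaries into rows for
overall, each condition, each team and each device, with on-date and
year-to-date (same calendar year, up to and including the report
date) columns: recording counts, nonstandard and missing electrode
counts (out of the expected 16), and bad-channel/bad-epoch
percentages. Table cells use pooled percentages — total flagged over
total counted across the scope, i.e. channel-count weighted — which
makes team rows exactly partition the overall row and makes
aggregation associative (batch-then-pool equals pool-then-batch); the
unweighted mean of per-recording percentages is emitted in separate
columns since both conventions are in field use. The montage check
classifies each label as one of the 16 standard sites or a listed
alternate (used when hair obstructs a site); the shipped
`data/montage.yaml` documents the assumed electrode names and is
user-overridable, since the canonical montage is a deployment choice.

## Synthetic data: what it emulates, and what it does not

The generator targets the default field protocol: 16 channels,
256 Hz, 180 s. Background: `n_sources` (default 4) shared pink-noise
(1/f^β, default β = 1) sources, mixed into every channel with unit
loading on the first source and uniform ±0.3 loadings on the rest,
rescaled to 20 µV, plus a 5 % white-noise floor. The shared sources
give clean channels windowed pairwise correlations well above the
0.4 PREP floor, as real EEG shows. Alpha: a sinusoid at the requested
peak (default 10 Hz) under a slow (≤ 0.2 Hz) amplitude envelope —
narrow enough that the spectral peak stays on its 0.5 Hz bin —
weighted 1.0/0.7/0.4 across posterior/central/frontal sites (larger
simulated caps cycle the same three weights). Optional mains
contamination adds a 50 or 60 Hz sinusoid to a channel subset.

Artifact magnitudes in real field data are unreported, so the
defaults are calibration choices, not measured facts: noisy channel =
added white noise at 5× the background amplitude; uncorrelated
channel = independent pink noise at matched variance; burst = a
Hann-windowed transient at 20× the channel SD covering ~40 % of one
epoch; blink = a ~0.4 s biphasic (derivative-of-Gaussian, ≈ 0.5–2 Hz
content) deflection of 200 µV on frontal channels — a typical
frontal eyeblink amplitude. All randomness flows through one seeded
generator; identical specs and seeds give bit-identical recordings.
Specs serialize to YAML.

What passing tests show: the detectors recover these injected,
well-separated artifact classes at the stated thresholds with few
false flags, the arithmetic and aggregation are correct, and the
implementations agree exactly with naive loop-based references. What
they do not show: detection performance on real field artifacts —
impedance drift, sweat bridges, chewing, partially detached
electrodes — whose statistics are messier and graded rather than
injected; nor anything about biophysical realism (no head model, no
task-evoked activity).

The module also contains an exact fractional-Gaussian-noise generator
(Davies–Harte circulant embedding), used solely as an independent
oracle for the Hurst estimator: fGn with H = 0.8 must be read back
within ±0.1, white noise within [0.45, 0.60].

## Numerical choices and degenerate inputs

* Any Z- or robust-Z standardization with zero spread returns all
  zeros (nothing flagged).
* Channel statistics ignore NaNs only where the flat/NaN criterion
  has already flagged the channel; elsewhere NaNs propagate and are
  a data error.
* Quartiles use numpy's linear interpolation (so robust_std of
  [0, 1, 2, 3] is exactly 1.5 × 0.7413).
* Epoching floors to whole epochs; recordings shorter than one epoch
  or shorter than the filter transient raise explicit errors.
* Cross-channel criteria require M ≥ 4 and cross-epoch criteria
  N ≥ 4; fewer makes standardization meaningless and raises.
* EDF output encodes each channel over its own physical range in 16
  bits; round trips are exact only to ~range/2¹⁵ — CSV is the
  loss-free interchange format.

## Test and acceptance problem sizes

The suite and the acceptance script run the study protocol at reduced
durations chosen as a deliberate scale: 60 s recordings for detector
recovery (20 seeded cohorts), 30 s for the 50-recording peak-alpha
sweep (PSD resolution depends on the 2 s Welch window, not the
duration), 4-channel × 8-epoch toys for the 100-seed loop-oracle
equivalence, and n = 600/60 with 200 iterations for bootstrap
calibration. Nothing in the method depends on duration beyond the
number of epochs entering the standardizations.
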
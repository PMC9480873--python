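# Methods

This note documents the models and procedures `oscpipe` implements, the
parameters that matter, the synthetic generator used to validate them,
and the numerical choices made where the design was genuinely open.

## Task structure and time conventions

All analyses assume epochs locked to the first cue of a four-event
trial (cue → sample → cue → probe) with a fixed stimulus onset
asynchrony of 1.5 s; epoch time 0 is first-cue onset and the canonical
epoch spans −1 to 7 s at 300 Hz. Window specifications are in seconds
and are half-open, `[start, end)`, when converted to samples, which
removes off-by-one ambiguity at window boundaries. Per-trial metadata
carry cue condition (`pre` / `retro`: whether the informative cue came
before or after the sample), the task-relevant feature, the sample's
class labels, reaction time (missing for no-response trials) and
correctness.

## Preprocessing

Notch (line frequency and harmonics, second-order IIR sections,
Q = 30) and low-pass (4th-order Butterworth) filters are applied
forward–backward, giving zero phase response: the decoding analyses use
instantaneous spatial patterns, and phase distortion would smear them
across time. Downsampling is band-limited polyphase resampling.
An optional variance-outlier trial filter z-scores each trial's pooled
broadband variance and drops trials beyond a configurable threshold
(default 4); the threshold is a configuration choice, not a calibrated
constant.

## Event-related fields and channel selection

Single trials are baseline-corrected (−0.1 to 0 s mean per channel).
The planar-gradient transform estimates, per sensor, the two orthogonal
spatial derivatives of the field by a least-squares plane fit over the
sensor and its layout neighbours, and reports their magnitude. The
"nearest-neighbour" planar method is named in the field without a fixed
fitting rule; the least-squares realization used here is testable
against finite differences (exact on linear fields at interior sensors)
and is invariant to spatially constant offsets. "Maximal post-stimulus
ERF" channels are the k = 20 sensors with the largest RMS of the
planar-transformed grand ERF in the 200 ms after sample onset; the
selection window is stated only graphically in the source protocol, so
0–0.2 s post-sample is used. Whether selection should use planar or
axial amplitude is likewise unstated; planar magnitude is chosen
because it is positive and peaks above sources, making "maximal"
well defined. Ties in the top-k are broken by channel label, for
determinism. Evoked subtraction removes each trial's group-mean ERF
(groups of ≥ 2 trials; a singleton group would zero its trial and is an
error), leaving group means exactly zero.

## Spectra, peaks, and time–frequency power

Power spectra are trial-averaged Hanning-tapered FFT power on a 1 Hz
grid (1–30 Hz) from 1 s windows, amplitude-calibrated so a unit tone
yields power 0.5. Spectra for peak detection are computed per trial and
averaged (computing on concatenated data was the alternative; per-trial
averaging is the variance-reducing choice consistent with the rest of
the pipeline), over the participant's 20 selected channels.

The alpha peak is the highest *strict* local maximum within 7–14 Hz;
band-edge bins are ineligible and a monotone in-band spectrum returns
an explicit no-peak result rather than an edge value. The beta peak is
detected after subtracting a least-squares line fit to log power
against *linear* frequency over 15–30 Hz (log-linear, not log-log — the
stated form of the detrend), which recovers bumps that the 1/f slope
hides from the raw spectrum. Ties across equal-height maxima resolve
toward the lower frequency. Both detectors are invariant to global
rescaling of the spectrum.

The time–frequency transform uses an adaptive sliding window of five
cycles per frequency (Δt = 5/f), Hanning-tapered, stepped every 20 ms,
with windows centered on the output time stamp. Cells whose centered
window does not fit inside the epoch are undefined (NaN) — never
silently zero — and undefined cells propagate as *excluded* through
band averaging and normalization, so edge artifacts cannot masquerade
as effects. Band time courses average TFR rows within ±bandwidth/2 of
an individualized peak (bandwidths 2 Hz for alpha, 4 Hz for beta).
Normalization is ratio-based: against mean baseline power (−0.4 to
−0.2 s) for condition contrasts, or against the across-bin mean (which
makes the across-bin mean exactly 1 at every cell) for bin contrasts.

## Intertrial phase coherence

ITC at a (channel, frequency, time) cell is the resultant length of the
across-trial unit phase vectors, with phases taken from the same
5-cycle Hanning windows as the TFR. It is 1 for identical phases and,
for uniform phases at finite N, has expectation √π/2 · N^(−1/2) (the
finite-sample floor used by the calibration tests). Slow-band ITC is
averaged over 1–6 Hz. Because ITC discards amplitude, it is invariant
to per-trial amplitude scaling; the evoked-subtraction control in the
test suite verifies that ITC inflation caused purely by additive evoked
components disappears after `subtract_evoked`, while genuine phase
resets survive it.

## Across-trial phase–amplitude coupling

PAC is measured across trials rather than across time: at each sliding
1 s window (0.1 s default step), the fast-band amplitude-envelope
samples of all trials are pooled and binned by the concurrent slow-band
phase, and the normalized Kullback–Leibler modulation index
MI = (log K − H(p)) / log K is computed from the phase-binned
mean-amplitude distribution (K = 18 bins). MI is 0 for
phase-independent amplitude, 1 when all amplitude mass falls in one
bin, and invariant to global amplitude scaling. The estimator variant,
bin count and surrogate scheme are not pinned down by the source
protocol (only the toolbox family is named); the normalized-MI default
is chosen because it is bounded, monotone in coupling depth, and
surrogate-friendly. Phase is extracted on a 1 Hz grid within 1–3 Hz
(zero-phase band-pass ± 1 Hz, then the analytic signal), amplitude on a
1 Hz grid within 30–35 Hz (band-pass ± 3 Hz — wide enough to carry
modulation sidebands at the slow frequencies). Significance uses
trial-shuffle surrogates (amplitude trials permuted against phase
trials), which preserve both marginals while destroying their
coupling. Cells with an empty phase bin are undefined, reported as NaN.
The analysis runs on an ROI-averaged virtual channel; in synthetic
layouts the "occipital" ROI is the posterior rows of the grid, since
anatomical labels do not exist for simulated sensors.

## Cluster-based permutation statistics

Condition contrasts are paired t maps over subjects, thresholded at the
two-tailed t critical value for cell-level p < 0.05 (df = n − 1).
Supra-threshold cells are partitioned into maximal connected
components — positive and negative cells separately — under an
adjacency that joins cells sharing all coordinates but neighbouring
sensors (sensor graph), or sharing the sensor but adjacent in time or
frequency. Sensor neighbourhoods come from a Delaunay triangulation of
the layout with edges capped at 1.5× the median edge length; without a
layout every axis is an ordered lattice (rook adjacency), which covers
time-only AUC contrasts, train × test matrices, and PAC comodulograms.
Each cluster's summed t is scored against the permutation distribution
of the maximum |cluster sum| under within-subject condition
randomization, i.e. sign flips of the paired differences. With ≤ 12
subjects and a sufficient permutation budget the full 2^n flip set is
enumerated and p-values are exact; otherwise flips are sampled and
Monte-Carlo p-values use the plus-one correction, so p is never 0. Both
tails are tested against a shared max-|sum| null (the tail convention
is a declared default; the source protocol does not state it).

One numerical subtlety: the observed t map inside the permutation test
is computed with the same one-pass variance formula as the permuted
maps, so the identity flip reproduces the observed cluster sums exactly
and exhaustive p-values are well defined even on cells with extreme t.
Zero-variance cells are undefined (NaN) and excluded from clustering.

## Binning

RT and prestimulus-power bins are quantile partitions computed within
participant (group statistics then take one map per bin per
participant). Bin sizes follow the `np.array_split` partition — sizes
differ by at most one, larger bins first (393 trials → 79/79/79/78/78)
— and ties resolve by stable order of occurrence. Trials with missing
values (e.g. no-response RTs) are excluded from binning. Prestimulus
band power is single-trial Hanning-tapered FFT power averaged over the
ROI channels and in-band bins; power binning defaults to canonical
fixed bands (theta 4–7, alpha 8–12, beta 15–25 Hz) with individualized
peak-centered bands available by configuration.

## Decoding

At each time point a linear L2-regularized logistic regression is
trained on the channel vector under stratified 4-fold cross-validation
and evaluated by the AUC of the pooled held-out probabilistic scores
against the true labels, so chance is 0.5 regardless of class balance.
The regularization strength is fixed at unit inverse-penalty and
features are standardized per training fold (statistics estimated on
training folds only, avoiding leakage); the source protocol states L2
regularization without a value, so these are declared defaults. AUC is
computed by the rank (Mann–Whitney) formula with ties counted one half;
it equals exhaustive pair enumeration exactly and is invariant under
strictly monotone transforms of the scores. Inputs are low-passed at
35 Hz upstream. Label-shuffle nulls repeat the full cross-validation
per shuffle and use plus-one p-values.

Leave-one-out cross-validation provides unbiased single-trial scores
(each trial scored by a model that never saw it; verified to match a
from-scratch refit loop exactly). Binned decoding applies quantile bins
to these held-out scores — no refitting — and recomputes AUC within
each bin; a bin lacking one class at a time point is undefined there.
The lowest/highest-bin AUC time courses feed the cluster test with
temporal-only adjacency. Temporal generalization trains at each time
and tests at all times within the same folds, so its diagonal equals
the time-resolved AUC; the train × test surface is optionally averaged
over the first 0.3 s of training time after sample onset, and binned
train-window-averaged curves are built from the held-out score tensor.

## The synthetic generator

`simulate()` builds each trial as a sum of:

1. **1/f^χ background** (χ = 1 by default) via FFT shaping of white
   noise, flat below 1 Hz; an independent component per channel plus a
   shared, spatially smooth component (40% by default), because real
   sensor data are spatially correlated and the cluster test's
   adjacency behaviour must be exercised under correlated noise.
2. **Alpha and beta oscillations** at configurable peak frequencies
   (10 and 20 Hz defaults) with random phase per trial and channel,
   posterior-weighted topographies, log-normal trial-to-trial power
   (σ = 0.5 on the latent z), and piecewise-constant segment gains per
   cue condition: the informative cue (first cue on precue trials,
   second on retro-cue trials) is followed by a 40–45% amplitude
   decrease. These gains are the injected "cueing effect" that the
   recovery tests must detect.
3. **A slow 2 Hz oscillator** that runs freely between events and is
   partially phase-reset at each event: the phase *at* the event is
   drawn von Mises(0, κ) with κ per event and condition (the
   informative retro-cue resets more strongly, κ = 2.5 vs 1.0). Resets
   are applied by cross-fading the old and new oscillations over
   0.25 s, producing ITC transients without injecting evoked energy —
   which is what lets the ITC-versus-ERF controls be tested
   independently.
4. **A 32.5 Hz carrier** whose envelope is `a₀(1 + m cos φ_slow)`,
   with coupling depth m depending on the trial's latent RT class
   (0.6 fast / 0.2 slow by default) — the injected PAC effect.
5. **Evoked templates** (a Gaussian-windowed biphasic wave) added
   phase-locked at each event with condition-dependent amplitudes, as
   separate additive components so `subtract_evoked` provably removes
   them.
6. **Class patterns**: spatially smooth topographies whose sign follows
   a binary label column and whose amplitude is
   `base · max(0, 1 + β·z_power)`, linking decodability to prestimulus
   band power. Defaults: cue-instruction pattern (0.1–0.5 s) gated
   *negatively* by alpha power (β = −0.5), a sustained sample
   spatial-frequency pattern (1.55–3.55 s) gated *positively* by beta
   power (β = +0.5), and a transient orientation pattern.
7. **An RT model**: RT = 0.65 + 0.08·z_alpha + 0.04·z_beta +
   0.04·(1 − cos δ_probe) + 0.18·[slow class] + noise (σ = 0.08 s),
   clipped at 150 ms; accuracy declines logistically with RT; 2% of
   trials are no-response (missing RT). The power→RT and
   power→decodability couplings have no published effect sizes; these
   defaults were chosen once for testability and are free parameters
   of the generator, not estimates.

All randomness derives from one named stream per participant
(`default_rng([seed, participant])`), so any participant is
bit-reproducible in isolation. Every latent draw — event phases, band
power z-scores, pattern amplitudes, RT class, RT — is logged in the
`GroundTruth` table.

What the generator does *not* emulate: biophysical forward models and
realistic head geometry, eye/cardiac artifacts, non-stationary 1/f
slopes, heteroskedastic sensor noise, and between-participant
anatomical variability. Passing recovery tests therefore demonstrates
that the estimators measure what they claim on data satisfying their
assumptions — not that those assumptions hold for any particular real
recording.

## Problem sizes used in tests and calibration

The generator's default configuration (10 participants × 400 trials ×
64 channels at 300 Hz, −1..7 s epochs) is the desk-scale study shape.
The validation suites run reduced instances chosen as the smallest
sizes at which each property is meaningfully testable: recovery tests
use 1–8 participants, 48–208 trials, 16 channels at 150 Hz with epochs
cropped to the interval each effect occupies; the chance-calibration
target uses 20 noise datasets of 400 × 20 × 50; the family-wise-error
target uses 200 null experiments of 10 subjects over 64 × 50 maps with
500 permutations. The decoding chance level is insensitive to problem
size; cluster-test error control is exercised at full spatial scale
because adjacency structure is what the test must respect.

## Known limitations

- The PAC time resolution is bounded below by the 1 s pooling window;
  effects shorter than the window are diluted.
- Exhaustive sign-flip p-values have resolution 2^(−n); with few
  subjects (< 6) no cluster can reach conventional significance.
- LOOCV refits one model per trial and time point; it is exact but
  O(n²) in trials, so the pipeline applies it to cropped, decimated
  windows.
- The 1 Hz spectral grid quantizes peak estimates; sub-Hz peak
  resolution would require longer windows than the 1 s prestimulus
  interval provides.
- Bandwise decimation before decoding assumes the 35 Hz low-pass has
  removed content above the decimated Nyquist; very aggressive
  decimation settings can alias residual high-beta power.
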
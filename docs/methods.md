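# Methods

`alphaphase` pairs a generative model of a lateralized visual-simultaneity
EEG experiment with the full analysis chain that such an experiment calls
for. Because the generator's assumptions are exactly the assumptions the
analysis makes, every stage can be validated by parameter recovery and by
type-I-error calibration on data whose ground truth is known. This note
describes the model, the analysis decisions, the defaults, and what the
validation does and does not establish.

## The generative model

One session simulates one participant performing 680 trials of a
two-flash simultaneity judgement under spatial cueing, split
420/140/90/30 over the cue-validity x synchrony cells (correctly cued
trials are 75% of the total). Per trial the generator produces a
multi-channel record (30 scalp channels of the 10-20 system plus
VEOG/HEOG) at 500 Hz spanning a configurable window around first-LED
onset (default −1.5 s to +0.45 s).

**Background EEG.** Each channel carries independent Gaussian noise with
a 1/f^β spectrum (β = 1, knee at 1 Hz) mixed with a 30% white floor,
total SD 10 µV. This matches broadband EEG statistics well enough for the
purposes here without committing to a biophysical model.

**Alpha.** Each participant has an individual alpha frequency (IAF) drawn
uniformly from 8–13 Hz. Alpha is a constant-frequency sinusoid with
trial-random uniform phase and a slow (< 2 Hz) multiplicative amplitude
jitter, shared across channels with a posterior-dominant topography
(frontal rows ×0.4, central ×0.7, posterior ×1.0) and a per-participant
lognormal base amplitude (CV 0.2). Uniform trial-random phase is what
makes onset phase Rayleigh-uniform, the property the control analyses
verify. Because one oscillation drives all channels, phases agree across
electrodes up to channel noise — which is also what makes a cluster-level
(electrode-averaged) phase analysis meaningful.

**Attention.** On the five left-posterior sites C3, CP3, P3, P7, O1 the
alpha amplitude is 10 µV when the cue directs attention to the
contralateral (right) hemifield and 13 µV otherwise; every other channel
sits at the 11.5 µV midpoint. The 30% suppression yields paired-t power
well above 0.9 at 20 participants. Only the left hemisphere is modulated,
reproducing a left-lateralized suppression topography.

**Phase → response coupling.** On asynchronous trials the probability of
an "asynchronous" response is modulated by the true alpha phase φ at
first-LED onset,

    P(asynchronous) = base(SOA) + m · cos(φ − φ_pref),

with φ_pref = 270° (the alpha trough, under the convention 90° = peak)
and default depth m = 0.022 — the value implied by the response-proportion
gap the analysis is meant to detect (≈ .51 vs .49 between opposite phase
bins). m is a tunable, not an empirical fact. In the default "staircase"
mode, base(SOA) is a logistic psychometric function (midpoint 39 ± 2 ms
by cue validity, between-participant SD 6 ms, slope 0.15/ms) and the SOA
follows a 1-up/1-down ±5 ms staircase per validity condition starting at
50 ms; the staircase pins overall hit rate near .5 while the phase term
rides on top. A "fixed" mode uses P = p0 + m·cos(φ − φ_pref) at constant
SOA, which is the form the closed-form generator tests use. Simultaneous
trials respond "asynchronous" at a fixed, phase-independent false-alarm
rate (.043).

**Ocular artifacts.** VEOG blinks are raised-cosine pulses (150–400 ms,
250 µV, positive by default) at 6/min — a realistic overall rate — but
suppressed within ±0.5 s of stimulus onset with probability .85, because
participants withhold blinks around the judgement. This is what keeps the
trial-rejection fraction low while letting blink energy dominate the VEOG
variance, the regime the z-score template procedure assumes. HEOG
saccades are ±120 µV steps with 20 ms ramps at 1.5/min. Ground-truth
windows and events are recorded. A 30-trial calibration task (one saccade
per trial, amplitude jittered 10%) feeds the individualized saccade
threshold.

**Evoked response.** A fixed biphasic component (5 µV positive bump at
100 ms, negative at 170 ms, posterior topography) is added after onset,
identical for both perceptual outcomes — so the ERP control has a
realistic evoked signal and a true null difference.

**Response times** are shifted lognormal (shift 200 ms, shape 0.4) with
condition means 523/583 ms, participant speed offsets (SD 40 ms) and a
jittered validity benefit (SD 50 ms).

**Seeding.** One master seed; per-participant streams derived through
`numpy` SeedSequence spawn keys. The same (seed, participant) pair is
bit-reproducible.

## The analysis chain

**Filtering.** Forward–backward Butterworth: first-order high-pass at
0.1 Hz and fourth-order low-pass at 30 Hz, each pass designed half-power
at its cutoff so the two passes give half-*amplitude* there (and double
the roll-off to 12 and 48 dB/octave respectively). scipy's `sosfiltfilt`
supplies the zero-phase application with odd-reflection padding. The
filter runs on the full per-trial records — EOG included — before any
screening or epoching; interior-window equivalence with filtering a
longer record is tested.

**Artifact screen.** (1) Saccades: threshold = 20% of the participant's
mean calibration-saccade amplitude; a 200-sample window slides one sample
at a time over the HEOG of a −1350…+250 ms epoch and the trial is
rejected for all electrodes if |mean(samples 101–200) − mean(1–100)|
exceeds threshold. (2) Blinks: the whole VEOG record is z-scored once;
|z| > 2 regions (runs separated by < 50 ms merged — one blink crosses a
noisy threshold several times but is one artifact) are duration-filtered
(duration z within ±2, per polarity), aligned at their extremum,
zero-padded to a common length and averaged into per-polarity templates.
Each template's support (samples covered by at least half the regions)
slides over the record; within each run of Pearson r > 0.7 the best
position is kept, and — provided the matched segment's extremum itself
exceeds the |z| > 2 criterion — the window grows outward from that
extremum to the nearest samples with |z| < 0.5. Trials whose ±400 ms
onset window overlaps any raw supra-threshold region or matched window
are rejected for all electrodes. (3) Any remaining epoch exceeding
±75 µV at an electrode is rejected for that electrode only.
Participants with more than 20% saccade-contaminated trials are excluded
(configurable gate).

**Epochs and spectra.** Analysis epochs run from −300 ms to +100 ms
around first-LED onset: 201 samples, onset at sample 150, Tukey-tapered
with 50-sample raised-cosine ramps, leaving −200…0 ms untapered. The
tapered epoch is zero-padded to 512 points; single-sided FFT amplitudes
(2/N scaling, N = 201) are averaged over bins 8–13 (7.813–12.695 Hz,
0.977 Hz spacing) to give single-trial alpha amplitude. The IAF is the
in-band bin with the largest magnitude averaged over clean asynchronous
trials and then over the electrodes of a region (frontal and posterior
estimated separately); a peak/mean ratio below 1.2 flags low confidence.

**Instantaneous phase.** A complex Gabor atom at the electrode's regional
IAF (Gaussian envelope SD 1.5 IAF cycles) is convolved with the tapered
epoch ('same' mode, zero extension); phase is arg(output) + 90°, so a
cosine peak reads 90° and a trough 270°. At 8–13 Hz a ±3 SD atom is
longer than the 402 ms epoch, so the default atom is truncated to the
epoch length; for a sinusoid the recovered phase is exact regardless of
the (symmetric) envelope, and the onset-phase estimates are shown to be
stable for envelope SDs of 1–2 cycles. Only the −200…0 ms samples are
consumed downstream.

**Circular statistics.** All angles are radians internally, reported in
(−π, π]. First-order means are vector averages; the second-order mean of
(angle, resultant) pairs is the Cartesian mean of the r·(cosθ, sinθ)
vectors. Moore's nonparametric paired statistic R′ ranks the
per-participant difference vectors by length and takes
R′ = |Σ rankᵢ·e^{iθᵢ}| / n^{3/2}; p values come from a seeded sign-flip
permutation null (condition swap within participant; ranks are invariant
under the flip), with the exact large-sample tail
p ≈ exp(−R′²n³/Σrank²) as a consistency check. Rank ties break by a
seeded random perturbation. The Rayleigh test uses the standard finite-n
corrected p. Phase bins bisect the circle at the two arc midpoints
between condition means (boundaries antipodal by construction; a phase on
a boundary belongs to the arc that starts there). Polarity is negative on
(180°, 360°].

**Cluster permutation.** Electrode-space: paired t per electrode,
two-tailed entry at p < .05, same-sign clusters over a neighbour graph
derived from schematic 10-20 positions (distance threshold 1.6 head
units), cluster mass = summed t, null = within-participant condition
flips scored by maximum |mass|. Time-course: Moore R′ per sample with a
permutation schedule shared across samples; entry by rank of the observed
statistic within the per-sample permutation distribution (so entry and
cluster nulls agree); contiguous supra-threshold runs scored by summed
R′ against the permuted maximum-run null. An electrode × time variant
(adjacent = same electrode & consecutive sample, or neighbour electrodes
& same sample) serves the all-electrode sweep. The t-max check scores the
maximum |paired t| over 0–400 ms post onset against its flip null.
Reported p values use (1 + exceedances)/(1 + n_permutations); with
n = 999 or 1999 the attained level of "p ≤ .05" is exactly .05.

**Phase–outcome analysis.** Asynchronous trials only, cluster electrodes
only, attention conditions collapsed. Per participant and electrode the
larger response class is subsampled (seeded, without replacement) to the
smaller's count; first-order circular means per time sample are combined
across electrodes by the second-order mean, giving per-participant
(angle, r) trajectories per outcome; Moore-R′ cluster permutation runs
over −200…0 ms. Subsampling is done once per seed. The onset bisection is
built from the across-participant second-order onset means, and the
preferred-phase estimate is the angle of the across-participant mean
difference vector (asynchronous − simultaneous), which uses both outcome
classes and halves the angular variance of a one-class estimate.

**Proportion analyses.** For each cluster electrode, usable asynchronous
trials with targets contralateral to the electrode are binned by onset
phase; proportions of correct ("asynchronous") responses per cell are
averaged across electrodes per participant. 2×2 fully-within ANOVAs test
phase bin × cue validity and phase bin × amplitude (median split of
single-trial alpha amplitude, attention pooled; ties fall to the "low"
half). Polarity paired t-tests (negative vs positive half-cycle) run at
the IAF and with a fixed 10 Hz filter. ANOVA effects report F, df,
partial η², and Greenhouse–Geisser ε (from the eigenvalues of the
double-centred covariance, bounded to [1/(k−1), 1]) applied to factors
with more than two levels; t-tests report Hedges-corrected d_av
(d_av × (1 − 3/(4·df − 1))). Within-subject standard errors use the
Cousineau–Morey normalization with the k/(k−1) variance correction.
Extreme hit/false-alarm rates are adjusted by 1/(2N) before the normal
quantile transform.

## Problem sizes used in validation

The validation suite runs at sizes chosen to give adequate Monte-Carlo
precision on a single CPU:

* type-I calibration of the Moore test, both cluster permutations and the
  t-max check: 1000 null simulations each at the study's dimensions
  (n = 20; 24 electrodes / 101 samples), 999 permutations per test;
* parameter recovery: 100 simulated studies at half-size sessions (340
  trials in the study's 75/25 cell proportions, 20 participants, lateral
  electrodes, artifact processes off, 1999 permutations) with coupling
  depth m = 0.1;
* the uniformity Monte Carlo: 10,000 replicates of 100 cells × 640
  uniform phases, cross-checked against 1 − BinomCDF(3; 100, .05);
* the staircase check: 20 observers × 560 trials.

The full-size analysis (680-trial sessions, artifact screens on, 2000
permutations) lives in the numbered `analysis/` drivers.

## What passing these tests shows — and what it does not

The generator contains, by construction, exactly one phase-coupling
mechanism, sinusoidal in φ with a single preferred phase common to all
participants; alpha is strictly stationary in frequency; channel noise is
independent across electrodes; artifacts are stereotyped. Recovery and
calibration on such data establish that the code implements the intended
estimators and that the inference is honest under the assumed model. They
do not establish robustness to properties real EEG has and the generator
lacks: non-sinusoidal and drifting alpha, spatially correlated noise,
volume-conducted artifact residue, between-participant heterogeneity in
preferred phase, or coupling shapes other than cosine. The off-frequency
specificity check is likewise bounded by physics: a 402 ms epoch cannot
spectrally separate 13–15 Hz from a strong 8–13 Hz effect (the truncated
Gabor bandwidths overlap), so specificity holds at moderate coupling
depths, not arbitrarily strong ones.

Three control analyses behave differently on this generator than one
would expect of recordings, for model reasons rather than code reasons.
First, alpha here is a single source common to all channels, so the
response coupling is present (attenuated) at every electrode, and at full
study size the all-electrode sweep can detect it — in recordings, phase
relationships decohere across the scalp. Second, participants whose IAF
falls near the top of the 8–13 Hz range are captured by a 13 Hz Gabor, so
the 13 Hz sweep inherits their true effect. Third, the constant-frequency
alpha makes the onset-phase difference between outcome classes persist
into the post-stimulus window, so at full size the ERP t-max check can
flag this small genuine class difference — the situation the check is
designed to warn about.

## Numerical and degenerate-input choices

Zero-resultant circular means carry an explicit undefined flag rather
than an arbitrary angle. Zero-length Moore difference vectors receive the
lowest ranks with seeded random tie-breaks. A bisection of identical
means raises. Blink-template construction with no supra-threshold runs
returns an empty template whose matcher is a no-op; window expansion
truncates at record boundaries. Epoch extraction outside the recorded
span raises rather than padding. The permutation estimator never reports
p = 0. Records are processed in float32 end to end (the statistics are
formed in float64); the second-order oracle equivalence is asserted at
1e−12 in float64.
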
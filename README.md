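# alphaphase

Does the phase of ongoing alpha (8–13 Hz) EEG at the moment two visual
stimuli appear predict whether they are perceived as simultaneous or
asynchronous — independently of spatial attention and of alpha amplitude?
`alphaphase` implements the complete analysis pipeline for that question
as a tested, reusable library, together with a synthetic-data generator
that produces EEG + EOG + behaviour sessions with the exact statistical
structure the analysis assumes. Every stage is therefore verifiable by
parameter recovery and type-I calibration, with no external recordings.

It is aimed at EEG researchers working on pre-stimulus oscillatory phase
effects who want the full inferential chain — individualized artifact
screening, Gabor instantaneous phase at the individual alpha frequency
(IAF), second-order circular statistics, and cluster-based permutation
correction — as importable, unit-tested pieces.

## The model and the statistics

A simulated session is a lateralized two-flash simultaneity task: 680
trials (420/140/90/30 across cue-validity × synchrony cells), stimulus
onset asynchronies driven by a ±5 ms 1-up/1-down staircase per cue
condition, 30 scalp channels + VEOG/HEOG at 500 Hz. Alpha at a
per-participant IAF has trial-random uniform phase φ at first-LED onset;
on asynchronous trials

&nbsp;&nbsp;&nbsp;&nbsp;P(judged asynchronous) = base(SOA) + m·cos(φ − φ_pref),

with φ_pref = 270° (the alpha trough; convention 90° = peak) and
depth m = 0.022 by default. Attention suppresses alpha amplitude at the
left-posterior sites C3/CP3/P3/P7/O1 when the cue is contralateral.

The analysis recovers this structure in the order a real study would:
zero-phase Butterworth filtering (0.1–30 Hz half-amplitude), a
three-stage ocular/amplitude artifact screen (individualized saccade
thresholds, VEOG blink-template matching, ±75 µV), Tukey-tapered 402 ms
epochs, zero-padded FFT alpha amplitude (bins 7.813–12.695 Hz), an
electrode-cluster permutation test of attentional suppression,
IAF-centred Gabor phase, per-outcome first/second-order circular means,
Moore's nonparametric paired R′ statistic

&nbsp;&nbsp;&nbsp;&nbsp;R′ = |Σᵢ rankᵢ·e^{iθᵢ}| / n^{3/2}

under cluster permutation over the −200…0 ms window, onset-phase
bisection, 2×2 repeated-measures ANOVAs on response proportions (phase ×
attention, phase × amplitude median split), and the control analyses
(t-max ERP check, Rayleigh uniformity with its Monte-Carlo reference,
all-electrode and off-frequency sweeps).

## Worked example

The numbered drivers under `analysis/` run one full-size simulated study
(20 participants, all artifact processes on, 2000 permutations) end to
end, writing tables to `results/`:

```bash
python analysis/01_simulate_and_screen.py
python analysis/02_behaviour.py
python analysis/03_attention_amplitude.py
python analysis/04_phase_outcome.py
python analysis/05_proportions.py
python analysis/06_controls.py
```

Output of a run (master seed 2016):

```text
01: mean saccade-rejected 5.05%, mean blink-rejected 5.13%,
    mean clean trials/electrode 603.0
02: hit rate 0.504 (SD 0.003); FA 0.040; d' 1.809
    SOA 37 ms; RT valid 532 vs invalid 575 ms
    (t(19) = -4.27, p = 4.13e-04, g_av = -0.91)
03: suppression cluster: ['C3', 'CP3', 'O1', 'P3', 'P7', 'TP7']
    (Monte Carlo p = 0.0005)
    left hemisphere attention effect: F(1,19) = 381.1, p < .0001
    right hemisphere attention effect: F(1,19) = 8.27, p = 0.0097
04: phase cluster -200 ms to 0 ms relative to onset (Monte Carlo p = 0.0035)
    onset means: asynchronous 317 deg, simultaneous 124 deg;
    R'19 = 1.226, p = 0.0070
05: P(correct | async-defined bin) = 0.529 vs 0.482 in the other bin
    phase main effect: F(1,19) = 7.641, p = 0.0123, partial-eta2 = 0.287
    attention main effect: p = 0.189; interaction: p = 0.723
    amplitude main effect: p = 0.271; phase x amplitude interaction: p = 0.362
06: ERP check (filtered): t_max = 3.844, p = 0.028
    Rayleigh: 5 uncorrected / 0 Bonferroni flags
    off-frequency cluster p: {5 Hz: 1.0, 7 Hz: 1.0, 13 Hz: 0.002, 15 Hz: 1.0}
    all-electrode sweep: mc_p = 0.006
```

Reading it: the staircase held performance at threshold (hit rate ≈ .50),
attention was deployed (faster valid-cue RTs), and the amplitude analysis
found the injected left-posterior suppression cluster (plus one chance
neighbour, TP7; the right-hemisphere follow-up effect at p = .0097 is a
chance finding of this particular simulated study — across seeds it is
null). The phase analysis separated the two perceptual outcomes
(near-opposite onset phases, trough-side phases favouring "asynchronous"),
the phase bin defined by asynchronous responses carried a higher
proportion of correct responses (.529 vs .482), and neither attention nor
alpha amplitude interacted with the phase effect. Three controls read
differently than they would on recordings, for generator reasons
discussed in `docs/methods.md`: the 13 Hz sweep and the all-electrode
sweep pick up the true effect (alpha is a single source shared across
channels, and IAFs near 12.7 Hz fall inside a 13 Hz Gabor's band), and
the ERP check flags the small genuine post-stimulus trace difference that
phase-coupled responses create when alpha is perfectly stationary.

## Layout

```
src/alphaphase/     library: synth, preprocess, artifacts, spectral,
                    circstats, permtests, behaviour, pipeline, io, montage
analysis/           numbered drivers for the full simulated study
tests/              unit, property and study-level validation suites
scripts/            acceptance.py
docs/methods.md     model, estimators, defaults, limitations
```
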
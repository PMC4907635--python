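"""Configuration objects for simulation and analysis.

All angles are radians internally; degrees appear only at I/O.  All voltages
are µV, times are seconds unless a field name says otherwise (ms).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band specification.

    Each pass is designed half-power at the cutoff; the forward-backward
    application squares the magnitude response, giving half-amplitude at the
    cutoff and doubling the effective roll-off.
    """

    hp_order: int = 1
    hp_cutoff: float = 0.1     # Hz
    lp_order: int = 4
    lp_cutoff: float = 30.0    # Hz

    def validate(self, fs: float) -> None:
        for c in (self.hp_cutoff, self.lp_cutoff):
            if not 0.0 < c < fs / 2:
                raise ValueError(f"cutoff {c} Hz outside (0, fs/2)")
        if self.hp_cutoff >= self.lp_cutoff:
            raise ValueError("high-pass cutoff must lie below low-pass cutoff")


@dataclass(frozen=True)
class EpochSpec:
    """Analysis-epoch geometry relative to first-LED onset (0-based samples).

    The default window runs from 150 samples (300 ms at 500 Hz) before onset
    to 50 samples (100 ms) after, i.e. 201 samples spanning 402 ms, with
    onset at sample index 150.  Tukey ramps of ``taper_ramp`` samples are
    applied at both ends.
    """

    start_offset: int = -150   # samples, relative to onset
    length: int = 201          # samples
    taper_ramp: int = 50       # samples; 0 disables tapering

    @property
    def onset_index(self) -> int:
        return -self.start_offset

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("epoch length must be positive")
        if self.taper_ramp < 0:
            raise ValueError("taper ramp must be >= 0")
        if self.taper_ramp and self.length <= 2 * self.taper_ramp:
            raise ValueError("epoch length must exceed twice the taper ramp")
        if not 0 <= self.onset_index < self.length:
            raise ValueError("onset must fall inside the epoch")


@dataclass(frozen=True)
class SpectralSpec:
    """Zero-padded FFT and alpha-band geometry.

    With ``nfft`` = 512 at 500 Hz the bin spacing is 500/512 = 0.977 Hz and
    the analysed alpha bins 8..13 sit at 7.813–12.695 Hz.
    """

    nfft: int = 512
    fs: float = 500.0
    band_bins: tuple[int, int] = (8, 13)    # inclusive FFT bin indices
    gabor_n_cycles_sd: float = 1.5          # Gaussian-envelope SD in IAF cycles

    @property
    def bin_spacing(self) -> float:
        return self.fs / self.nfft

    @property
    def band_frequencies(self):
        lo, hi = self.band_bins
        return tuple((k * self.fs / self.nfft) for k in range(lo, hi + 1))

    def validate(self) -> None:
        lo, hi = self.band_bins
        if not (0 < lo <= hi < self.nfft // 2):
            raise ValueError("band bins outside the FFT half-spectrum")


@dataclass(frozen=True)
class SimConfig:
    """Study-level generative settings for synthetic sessions.

    The defaults are the study conditions the analysis assumes: 20
    participants, 680 trials split 420/140/90/30 over the cue-validity x
    synchrony cells (75% correctly cued), 500 Hz sampling, alpha at a
    per-participant individual frequency drawn from 8-13 Hz whose onset
    phase modulates asynchronous responses, attention-dependent alpha
    suppression over the left-posterior sites, and a +-5 ms 1-up/1-down
    staircase keeping asynchronous hit rate near .5.
    """

    n_participants: int = 20
    fs: float = 500.0
    # (valid async, invalid async, valid simultaneous, invalid simultaneous)
    n_trials_by_cell: tuple[int, int, int, int] = (420, 140, 90, 30)
    iaf_range: tuple[float, float] = (8.0, 13.0)

    # alpha amplitude (µV) at the left-posterior suppression sites
    alpha_amp_attended: float = 10.0
    alpha_amp_unattended: float = 13.0
    # multiplicative alpha topography by row (other channels use the midpoint
    # of the attended/unattended levels times this gain)
    frontal_alpha_gain: float = 0.4
    central_alpha_gain: float = 0.7
    posterior_alpha_gain: float = 1.0
    alpha_amp_cv: float = 0.2          # between-participant lognormal CV
    amp_jitter: float = 0.2            # slow within-epoch envelope jitter

    # broadband noise
    noise_sd: float = 10.0             # µV total background SD
    noise_exponent: float = 1.0        # 1/f^beta slope of the coloured part
    white_fraction: float = 0.3        # share of noise variance that is white

    # phase -> response coupling: p(async) = p0 + m*cos(phase - phi_pref)
    phase_effect_depth: float = 0.022  # m
    preferred_phase: float = 1.5 * math.pi   # 270 deg = alpha trough
    base_p_async: float = 0.496        # p0 (fixed-SOA response mode)
    false_alarm_rate: float = 0.043    # P(async | simultaneous trial)

    # oculogram artifacts.  Blinks occur at a realistic overall rate but are
    # suppressed near stimulus onset (participants withhold blinks around
    # the judgement), which is what keeps the trial-rejection fraction low
    # and lets blink energy dominate the VEOG variance as the template
    # procedure assumes.
    blink_rate: float = 6.0            # events / minute of trial time
    blink_amp: float = 250.0           # µV
    blink_positive_prob: float = 1.0   # probability an injected blink is positive
    blink_avoid_halfspan: float = 0.5  # s around onset that blinks avoid
    blink_avoid_prob: float = 0.85     # probability a blink respects the gap
    saccade_rate: float = 1.5          # events / minute of trial time
    saccade_amp: float = 120.0         # µV HEOG step size
    eog_noise_sd: float = 12.0         # µV EOG channel background SD

    # psychometric observer + staircase
    psychometric_midpoint: float = 39.0        # ms (mean of the two conditions)
    psychometric_midpoint_shift: float = 4.0   # ms, invalid minus valid
    psychometric_midpoint_sd: float = 6.0      # ms between-participant SD
    psychometric_slope: float = 0.15           # 1/ms logistic slope
    staircase_start: float = 50.0              # ms
    staircase_step: float = 5.0                # ms
    soa_mode: str = "staircase"                # "staircase" | "fixed"
    fixed_soa: float = 40.0                    # ms, used when soa_mode == "fixed"

    # response times: shifted lognormal, means by cue validity, with
    # between-participant variability in overall speed and validity benefit
    rt_shift: float = 200.0            # ms
    rt_mean_valid: float = 523.0       # ms
    rt_mean_invalid: float = 583.0     # ms
    rt_sigma: float = 0.4              # lognormal shape
    rt_subject_sd: float = 40.0        # ms SD of participant speed offsets
    rt_validity_sd: float = 50.0       # ms SD of the validity benefit

    # evoked response (identical across perceptual outcomes)
    erp_amp: float = 5.0               # µV

    # per-trial record span relative to first-LED onset (s)
    epoch_span: tuple[float, float] = (-1.5, 0.45)

    seed: int = 0

    @property
    def n_trials(self) -> int:
        return sum(self.n_trials_by_cell)

    def validate(self) -> None:
        m, p0 = self.phase_effect_depth, self.base_p_async
        if not 0.0 <= m < 0.5:
            raise ValueError("phase_effect_depth must lie in [0, 0.5)")
        if not (0.0 <= p0 - m and p0 + m <= 1.0):
            raise ValueError("p0 +- m must stay inside [0, 1]")
        for r in (self.blink_rate, self.saccade_rate):
            if r < 0:
                raise ValueError("event rates must be >= 0")
        if self.fs <= 2 * max(self.iaf_range):
            raise ValueError("sampling rate must exceed twice the top of iaf_range")
        if min(self.n_trials_by_cell) < 0:
            raise ValueError("trial counts must be non-negative")
        if self.soa_mode not in ("staircase", "fixed"):
            raise ValueError("soa_mode must be 'staircase' or 'fixed'")
        if self.epoch_span[0] >= self.epoch_span[1]:
            raise ValueError("epoch_span must be increasing")


@dataclass(frozen=True)
class StudyConfig:
    """Everything the orchestrated analysis needs, seeds included."""

    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    epoch: EpochSpec = field(default_factory=EpochSpec)
    spectral: SpectralSpec = field(default_factory=SpectralSpec)

    # artifact-screen thresholds
    saccade_threshold_fraction: float = 0.20   # of mean calibration amplitude
    template_r_threshold: float = 0.7
    amplitude_threshold: float = 75.0          # µV, per electrode
    blink_epoch_halfspan: float = 0.4          # s around first-LED onset
    participant_exclusion_fraction: float = 0.20  # saccade-contaminated trials
    run_artifact_screen: bool = True

    # permutation settings
    n_perm_electrode: int = 10_000
    n_perm_time: int = 10_000
    n_perm_moore: int = 10_000
    cluster_entry_alpha: float = 0.05

    # analysis extras
    min_trials_per_response: int = 20
    fallback_electrodes: tuple[str, ...] = ("C3", "CP3", "P3", "P7", "O1")
    off_frequencies: tuple[float, ...] = (5.0, 7.0, 13.0, 15.0)
    polarity_fixed_freq: float = 10.0
    uniformity_reps: int = 100_000

    analysis_seed: int = 12345

    def validate(self) -> None:
        self.sim.validate()
        self.filter.validate(self.sim.fs)
        self.epoch.validate()
        self.spectral.validate()
        for thr in (self.saccade_threshold_fraction, self.template_r_threshold,
                    self.amplitude_threshold, self.blink_epoch_halfspan):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        if min(self.n_perm_electrode, self.n_perm_time,
               self.n_perm_moore) < 1000 or self.uniformity_reps < 1000:
            raise ValueError("permutation/Monte-Carlo counts must be >= 1000")


def _asdict(obj):
    return dataclasses.asdict(obj)


def to_json(config, path=None) -> str:
    """Serialize any of the config dataclasses to JSON."""
    text = json.dumps({"type": type(config).__name__, **_asdict(config)},
                      indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


_TYPES = {"FilterSpec": FilterSpec, "EpochSpec": EpochSpec,
          "SpectralSpec": SpectralSpec, "SimConfig": SimConfig}


def _build(cls, payload):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        v = payload[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def from_json(text_or_path) -> object:
    """Rebuild a config dataclass from `to_json` output (text or file path)."""
    try:
        payload = json.loads(text_or_path)
    except (ValueError, TypeError):
        with open(text_or_path) as fh:
            payload = json.load(fh)
    name = payload.pop("type")
    if name == "StudyConfig":
        sub = {k: _build(_TYPES[t], payload.pop(k))
               for k, t in (("sim", "SimConfig"), ("filter", "FilterSpec"),
                            ("epoch", "EpochSpec"), ("spectral", "SpectralSpec"))}
        return _build(StudyConfig, {**payload, **sub})
    return _build(_TYPES[name], payload)
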
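"""Synthetic EEG + EOG + behaviour sessions with known ground truth.

Every downstream stage of the analysis is validated against sessions drawn
from this generator, whose statistical structure is exactly what the
analysis assumes:

* scalp channels carry 1/f^beta Gaussian background (plus a white floor)
  and an alpha sinusoid at the participant's individual alpha frequency
  with trial-random uniform phase and slow amplitude jitter — onset phase
  is therefore uniform across trials;
* visuospatial attention suppresses alpha amplitude at the left-posterior
  sites (C3, CP3, P3, P7, O1) when the cue directs attention to the
  contralateral (right) visual field;
* on asynchronous trials the probability of an "asynchronous" response is
  modulated by the alpha phase at first-LED onset,
  p = base + m * cos(phase - phi_pref); simultaneous trials respond
  "asynchronous" at a fixed false-alarm rate independent of phase;
* SOAs come from a +-step 1-up/1-down staircase run separately for the two
  cue-validity conditions (phase modulation rides on top of the logistic
  observer, so the staircase keeps hit rate near .5 without erasing the
  phase effect);
* VEOG carries stereotyped blink pulses and HEOG step-like saccades at
  Poisson times, with ground-truth windows returned.

Phase convention everywhere: 90 deg = alpha (cosine) peak, 270 deg =
trough, matching the analysis side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import montage
from .config import SimConfig
from .io import EpochSet


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def pink_noise(shape, fs, beta=1.0, white_fraction=0.3, sd=1.0, rng=None,
               dtype=np.float32):
    """Gaussian 1/f^beta noise plus a white floor, total SD ``sd``.

    The coloured component is white noise shaped in the frequency domain by
    |f|^(-beta/2) (DC removed, knee at 1 Hz to keep the spectrum finite),
    renormalised empirically to unit variance before mixing.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = shape[-1]
    white = rng.standard_normal(shape, dtype=np.float32)
    if white_fraction >= 1.0 or beta == 0.0:
        return np.asarray(sd * white, dtype=dtype)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weights = (np.maximum(freqs, 1.0) ** (-beta / 2.0)).astype(np.float32)
    weights[0] = 0.0
    # draw the coloured component directly in the frequency domain
    fshape = shape[:-1] + (freqs.size,)
    spec = (rng.standard_normal(fshape, dtype=np.float32)
            + 1j * rng.standard_normal(fshape, dtype=np.float32))
    shaped = np.fft.irfft(spec * weights, n=n, axis=-1)
    norm = float(shaped.std())
    if norm > 0:
        shaped = shaped / norm
    out = (math.sqrt(1.0 - white_fraction) * shaped
           + math.sqrt(white_fraction) * white)
    return np.asarray(sd * out, dtype=dtype)


# ---------------------------------------------------------------------------
# EOG event injection
# ---------------------------------------------------------------------------

def inject_blinks(veog, rate, fs, rng=None, amp=250.0,
                  duration_range=(0.15, 0.40), positive_prob=1.0,
                  avoid=None, avoid_prob=0.0):
    """Add stereotyped monophasic blink pulses at Poisson times.

    Each pulse is a raised-cosine bump with duration drawn uniformly from
    ``duration_range`` seconds, amplitude ``amp`` (sign drawn with
    ``positive_prob``), centred at a uniform time.  ``avoid`` is an
    optional (start, stop) sample interval that each pulse steers clear of
    with probability ``avoid_prob`` (blink suppression around stimulus
    onset).  Returns (series, windows) where windows are [start, stop)
    samples covering each pulse's support.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    x = np.array(veog, dtype=float, copy=True)
    n = x.size
    windows = []
    n_events = rng.poisson(rate * (n / fs) / 60.0) if rate > 0 else 0
    for _ in range(n_events):
        dur = int(rng.uniform(*duration_range) * fs)
        dur = max(dur, 4)
        start = int(rng.integers(0, max(1, n - dur)))
        if avoid is not None and rng.random() < avoid_prob:
            for _attempt in range(20):
                if start + dur <= avoid[0] or start >= avoid[1]:
                    break
                start = int(rng.integers(0, max(1, n - dur)))
        sign = 1.0 if rng.random() < positive_prob else -1.0
        k = np.arange(dur)
        bump = sign * amp * 0.5 * (1 - np.cos(2 * np.pi * (k + 0.5) / dur))
        x[start:start + dur] += bump
        windows.append((start, start + dur))
    return x, windows


def inject_saccades(heog, rate, fs, rng=None, amp=120.0, ramp_s=0.02):
    """Add +-``amp`` step displacements with short linear ramps.

    Steps occur at Poisson times with balanced random sign.  Returns
    (series, events) with events = (onset_sample, signed_amplitude).
    """
    if amp <= 0:
        raise ValueError("amp must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    x = np.array(heog, dtype=float, copy=True)
    n = x.size
    ramp = max(int(ramp_s * fs), 1)
    events = []
    n_events = rng.poisson(rate * (n / fs) / 60.0) if rate > 0 else 0
    for _ in range(n_events):
        onset = int(rng.integers(0, n - 1))
        signed = amp * (1.0 if rng.random() < 0.5 else -1.0)
        stop = min(onset + ramp, n)
        x[onset:stop] += signed * (np.arange(stop - onset) + 1) / ramp
        x[stop:] += signed
        events.append((onset, signed))
    return x, events


# ---------------------------------------------------------------------------
# staircase
# ---------------------------------------------------------------------------

def simulate_staircase(p_correct, n_trials, start_soa, step, seed=0,
                       soa_floor=None):
    """1-up/1-down adaptive staircase against a psychometric observer.

    Parameters
    ----------
    p_correct : callable soa_ms -> probability
        Must be non-decreasing in SOA (checked on a grid).
    n_trials, start_soa, step
        Trial count, starting SOA (ms) and step size (ms); SOA is floored
        at ``soa_floor`` (default: one step).

    Returns
    -------
    soas : (n_trials,) SOA presented on each trial
    correct : (n_trials,) bool responses
    """
    if step <= 0 or start_soa <= 0:
        raise ValueError("step and start_soa must be positive")
    grid = np.linspace(step, start_soa * 3, 40)
    probs = np.array([p_correct(s) for s in grid])
    if np.any(np.diff(probs) < -1e-9):
        raise ValueError("psychometric function must be non-decreasing in SOA")
    rng = np.random.default_rng(seed)
    floor = step if soa_floor is None else soa_floor
    soa = float(start_soa)
    soas = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    for i in range(n_trials):
        soas[i] = soa
        c = rng.random() < p_correct(soa)
        correct[i] = c
        soa = max(floor, soa - step if c else soa + step)
    return soas, correct


def logistic_observer(midpoint, slope):
    """P(correct | SOA) = logistic(slope * (SOA - midpoint))."""
    def p(soa):
        return 1.0 / (1.0 + math.exp(-slope * (soa - midpoint)))
    return p


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSession:
    """One participant's simulated session plus its generative ground truth."""

    participant: int
    epochs: EpochSet                   # scalp (+ VEOG/HEOG) per-trial records
    trials: pd.DataFrame
    truth: dict = field(default_factory=dict)
    calibration_heog: np.ndarray | None = None   # (30, n_samples) saccade task


_CELLS = (("valid", "async"), ("invalid", "async"),
          ("valid", "simul"), ("invalid", "simul"))


def _trial_frame(config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for (validity, synchrony), count in zip(_CELLS, config.n_trials_by_cell):
        # counterbalance side and leading LED within the cell
        sides = np.tile(["left", "right"], count // 2 + 1)[:count]
        leads = np.tile(["top", "top", "bottom", "bottom"], count // 4 + 1)[:count]
        for side, lead in zip(sides, leads):
            target = side
            cue = side if validity == "valid" else ("right" if side == "left"
                                                   else "left")
            rows.append((validity, synchrony, cue, target,
                         lead if synchrony == "async" else ""))
    df = pd.DataFrame(rows, columns=["validity", "synchrony", "cue_side",
                                     "target_side", "leading_led"])
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "trial", np.arange(len(df)))
    return df


def _channel_alpha_gain(config: SimConfig, channels):
    """Per-channel alpha topography gain (posterior-dominant)."""
    gains = np.empty(len(channels))
    for i, ch in enumerate(channels):
        if ch in montage.EOG:
            gains[i] = 0.0
        elif ch.startswith(("FP", "F")):       # FP, F, FC, FT rows
            gains[i] = config.frontal_alpha_gain
        elif ch.startswith(("CP", "TP")):      # centro/temporo-parietal rows
            gains[i] = config.posterior_alpha_gain
        elif ch.startswith(("C", "T")):        # C, CZ, T rows
            gains[i] = config.central_alpha_gain
        else:                                  # P, PO, O rows
            gains[i] = config.posterior_alpha_gain
    return gains


def generate_session(config: SimConfig, participant_id: int,
                     channels=None, include_eog: bool = True
                     ) -> SyntheticSession:
    """Generate one participant's session; bit-reproducible in
    (config.seed, participant_id).

    ``channels`` restricts the scalp channels generated (the full montage by
    default); ``include_eog=False`` drops VEOG/HEOG and the calibration task
    (useful for large simulation batches with artifact rates of zero).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(int(participant_id),)))
    scalp = tuple(channels) if channels is not None else montage.SCALP
    all_channels = scalp + (montage.EOG if include_eog else ())
    fs = config.fs

    trials = _trial_frame(config, rng)
    n_trials = len(trials)
    iaf = float(rng.uniform(*config.iaf_range))
    onset_phase = rng.uniform(-np.pi, np.pi, size=n_trials)
    onset_phase[onset_phase == -np.pi] = np.pi

    # --- behaviour: staircases + phase-coupled responses -------------------
    m, phi = config.phase_effect_depth, config.preferred_phase
    midpoint = config.psychometric_midpoint + float(
        rng.normal(0.0, config.psychometric_midpoint_sd))
    mids = {"valid": midpoint - config.psychometric_midpoint_shift / 2.0,
            "invalid": midpoint + config.psychometric_midpoint_shift / 2.0}
    slope = config.psychometric_slope
    soa_state = {"valid": config.staircase_start,
                 "invalid": config.staircase_start}
    soas = np.zeros(n_trials)
    responses = np.empty(n_trials, dtype=object)
    correct = np.zeros(n_trials, dtype=bool)
    validity = trials["validity"].to_numpy()
    synchrony = trials["synchrony"].to_numpy()
    draws = rng.random(n_trials)
    for i in range(n_trials):
        if synchrony[i] == "simul":
            fa = draws[i] < config.false_alarm_rate
            responses[i] = "async" if fa else "simul"
            correct[i] = not fa
            continue
        phase_term = m * math.cos(onset_phase[i] - phi)
        if config.soa_mode == "staircase":
            v = validity[i]
            soa = soa_state[v]
            base = 1.0 / (1.0 + math.exp(-slope * (soa - mids[v])))
            p = min(1.0, max(0.0, base + phase_term))
            c = draws[i] < p
            soa_state[v] = max(config.staircase_step,
                               soa - config.staircase_step if c
                               else soa + config.staircase_step)
        else:
            soa = config.fixed_soa
            p = min(1.0, max(0.0, config.base_p_async + phase_term))
            c = draws[i] < p
        soas[i] = soa
        responses[i] = "async" if c else "simul"
        correct[i] = c

    rt_offset = float(rng.normal(0.0, config.rt_subject_sd))
    benefit = config.rt_mean_invalid - config.rt_mean_valid + float(
        rng.normal(0.0, config.rt_validity_sd))
    centre = 0.5 * (config.rt_mean_valid + config.rt_mean_invalid) + rt_offset
    rt_mean = np.where(validity == "valid", centre - benefit / 2.0,
                       centre + benefit / 2.0)
    rt_mean = np.maximum(rt_mean, config.rt_shift + 50.0)
    mu = np.log((rt_mean - config.rt_shift)
                / math.exp(config.rt_sigma ** 2 / 2.0))
    rts = config.rt_shift + rng.lognormal(mean=mu, sigma=config.rt_sigma)

    trials["soa_ms"] = soas
    trials["response"] = responses
    trials["correct"] = correct
    trials["rt_ms"] = np.round(rts, 1)
    trials.insert(0, "participant", participant_id)

    # --- EEG ---------------------------------------------------------------
    start_s, stop_s = config.epoch_span
    onset_index = int(round(-start_s * fs))
    n_samples = onset_index + int(round(stop_s * fs)) + 1
    t = (np.arange(n_samples) - onset_index) / fs

    n_scalp = len(scalp)
    data = pink_noise((n_scalp, n_trials, n_samples), fs,
                      beta=config.noise_exponent,
                      white_fraction=config.white_fraction,
                      sd=config.noise_sd, rng=rng)

    # alpha amplitudes: suppression sites depend on attended hemifield
    base_amp = float(rng.lognormal(mean=-config.alpha_amp_cv ** 2 / 2.0,
                                   sigma=config.alpha_amp_cv))
    gains = _channel_alpha_gain(config, scalp)
    midlevel = 0.5 * (config.alpha_amp_attended + config.alpha_amp_unattended)
    cue_side = trials["cue_side"].to_numpy()
    amp = np.empty((n_scalp, n_trials), dtype=np.float32)
    for ci, ch in enumerate(scalp):
        if ch in montage.SUPPRESSION_SITES:
            # left-hemisphere sites: contralateral attention = cue right
            level = np.where(cue_side == "right", config.alpha_amp_attended,
                             config.alpha_amp_unattended)
        else:
            level = np.full(n_trials, midlevel)
        amp[ci] = base_amp * gains[ci] * level

    # slow amplitude jitter: common smooth envelope per trial
    env = 1.0 + config.amp_jitter * _smooth_noise(rng, (n_trials, n_samples),
                                                  fs, cutoff=2.0)
    np.clip(env, 0.1, None, out=env)
    alpha_wave = np.cos(2 * np.pi * iaf * t[None, :]
                        + (onset_phase[:, None] - np.pi / 2.0))
    alpha_trial = (env * alpha_wave).astype(np.float32)
    data += amp[:, :, None] * alpha_trial[None, :, :]

    # evoked response, identical for both perceptual outcomes
    if config.erp_amp > 0:
        erp = (config.erp_amp * np.exp(-0.5 * ((t - 0.10) / 0.02) ** 2)
               - 0.8 * config.erp_amp * np.exp(-0.5 * ((t - 0.17) / 0.025) ** 2))
        post = np.where(t > 0, erp, 0.0).astype(np.float32)
        data += (gains[:, None] * post[None, :])[:, None, :]

    truth = {"iaf": iaf, "onset_phase": onset_phase,
             "phase_effect_depth": m, "preferred_phase": phi,
             "blink_windows": {}, "saccade_events": {}}

    # --- EOG ---------------------------------------------------------------
    if include_eog:
        veog = pink_noise((n_trials, n_samples), fs, beta=config.noise_exponent,
                          white_fraction=config.white_fraction,
                          sd=config.eog_noise_sd, rng=rng)
        heog = pink_noise((n_trials, n_samples), fs, beta=config.noise_exponent,
                          white_fraction=config.white_fraction,
                          sd=config.eog_noise_sd, rng=rng)
        veog = veog.astype(float)
        heog = heog.astype(float)
        for i in range(n_trials):
            if config.blink_rate > 0:
                gap = int(round(config.blink_avoid_halfspan * fs))
                veog[i], wins = inject_blinks(
                    veog[i], config.blink_rate, fs, rng=rng,
                    amp=config.blink_amp,
                    positive_prob=config.blink_positive_prob,
                    avoid=(onset_index - gap, onset_index + gap),
                    avoid_prob=config.blink_avoid_prob)
                if wins:
                    truth["blink_windows"][i] = wins
            if config.saccade_rate > 0:
                heog[i], events = inject_saccades(
                    heog[i], config.saccade_rate, fs, rng=rng,
                    amp=config.saccade_amp)
                if events:
                    truth["saccade_events"][i] = events
        data = np.concatenate([data, veog[None].astype(np.float32),
                               heog[None].astype(np.float32)], axis=0)
        calib = _calibration_task(config, rng)
    else:
        calib = None

    epochs = EpochSet(data=data, fs=fs, channel_names=all_channels,
                      onset_index=onset_index)
    return SyntheticSession(participant=participant_id, epochs=epochs,
                            trials=trials, truth=truth,
                            calibration_heog=calib)


def _smooth_noise(rng, shape, fs, cutoff=2.0):
    """Unit-SD noise low-passed below ``cutoff`` Hz (FFT brick wall)."""
    x = rng.standard_normal(shape).astype(np.float32)
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    spec[..., freqs > cutoff] = 0.0
    y = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = y.std()
    return (y / sd if sd > 0 else y).astype(np.float32)


def _calibration_task(config: SimConfig, rng, n_trials: int = 30,
                      duration: float = 1.2):
    """Pre-experiment saccade task: one saccade per trial, known amplitude."""
    n = int(duration * config.fs)
    ramp = max(int(0.02 * config.fs), 1)
    out = pink_noise((n_trials, n), config.fs, beta=config.noise_exponent,
                     white_fraction=config.white_fraction,
                     sd=config.eog_noise_sd, rng=rng).astype(float)
    amps = config.saccade_amp * rng.normal(1.0, 0.1, size=n_trials)
    for i in range(n_trials):
        onset = int(rng.integers(n // 4, 3 * n // 4))
        sign = 1.0 if i % 2 == 0 else -1.0
        stop = min(onset + ramp, n)
        out[i, onset:stop] += sign * amps[i] * (np.arange(stop - onset) + 1) / ramp
        out[i, stop:] += sign * amps[i]
    return out
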
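"""Three-stage ocular/amplitude artifact screen.

Stage 1: individualized saccade detection on HEOG.  A participant-specific
threshold is 20% of their mean saccadic amplitude from a 30-trial
calibration task; trials whose HEOG shows a windowed step above threshold
are rejected for all electrodes.

Stage 2: blink detection on VEOG by template matching.  The whole VEOG
record is z-scored once; supra-threshold (|z| > 2) runs whose durations are
typical (duration z within +-2, per polarity) are aligned at their extremum,
zero-padded to a common length and averaged into a template.  The template
slides over the record; the best position within each run of correlations
r > 0.7 marks an artifact whose window expands outward from the z extremum
to the nearest samples with |z| < 0.5.

Stage 3: per-electrode absolute-amplitude rejection at +-75 µV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve


# ---------------------------------------------------------------------------
# Saccades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaccadeThreshold:
    participant: int
    mean_saccade_amp: float      # µV
    threshold: float             # µV, fraction * mean
    n_calibration_trials: int


def windowed_step_difference(x, half: int = 100):
    """mean(x[i+half : i+2*half]) - mean(x[i : i+half]) for every i.

    Vectorized via cumulative sums; the 2*half-sample window slides one
    sample at a time.  Returns an array of length n - 2*half + 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2 * half:
        raise ValueError(f"record shorter than the {2 * half}-sample window")
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1),
                  axis=-1)
    first = (c[..., half:n - half + 1] - c[..., :n - 2 * half + 1]) / half
    second = (c[..., 2 * half:] - c[..., half:n - half + 1]) / half
    return second - first


def calibrate_saccade_threshold(calib_heog, participant: int = 0,
                                fraction: float = 0.20,
                                half: int = 100) -> SaccadeThreshold:
    """Mean absolute step amplitude over calibration trials, times fraction.

    Each calibration trial is assumed to contain one saccade; its amplitude
    is the maximum absolute windowed step difference.  Trials with no
    detectable step (flat records) are excluded with a warning.
    """
    amps = []
    for trial in calib_heog:
        diffs = windowed_step_difference(trial, half=half)
        amp = float(np.max(np.abs(diffs)))
        if amp <= 0:
            import warnings
            warnings.warn("calibration trial with no detectable saccade "
                          "excluded", stacklevel=2)
            continue
        amps.append(amp)
    if not amps:
        raise ValueError("no usable calibration trials")
    mean_amp = float(np.mean(amps))
    return SaccadeThreshold(participant=participant, mean_saccade_amp=mean_amp,
                            threshold=fraction * mean_amp,
                            n_calibration_trials=len(amps))


def detect_saccades(heog_epochs, thr: SaccadeThreshold, half: int = 100):
    """Flag trials whose HEOG contains a supra-threshold windowed step.

    heog_epochs : (n_trials, n_samples) array spanning the screening window.
    Returns boolean (n_trials,) reject flags.
    """
    diffs = windowed_step_difference(np.atleast_2d(heog_epochs), half=half)
    return np.max(np.abs(diffs), axis=-1) > thr.threshold


# ---------------------------------------------------------------------------
# Blink templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactTemplate:
    """Averaged artifact waveform in z units, extremum at the central sample.

    ``support`` is the (start, stop) slice of ``waveform`` covered by at
    least half of the contributing regions; matching correlates only over
    the support, since zero-padded flanks dilute shape information.
    """

    polarity: str                    # "positive" | "negative"
    waveform: np.ndarray             # z units, length = common padded length
    support: tuple[int, int]
    n_regions: int

    @property
    def empty(self) -> bool:
        return self.n_regions == 0

    @property
    def support_waveform(self) -> np.ndarray:
        return self.waveform[self.support[0]:self.support[1]]


def _runs(mask):
    """Maximal True runs of a boolean vector as (start, stop) pairs."""
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False]))
                                   .astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def zscore_record(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def supra_regions(z, polarity: str, threshold: float = 2.0,
                  merge_gap: int = 25):
    """Supra-threshold artifact regions for one polarity.

    Maximal runs of z > threshold (or z < -threshold), with runs separated
    by fewer than ``merge_gap`` samples merged into one region: a blink
    waveform with noise riding on it crosses the threshold several times,
    but it is one artifact.
    """
    signed = z if polarity == "positive" else -z
    runs = _runs(signed > threshold)
    merged = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def _build_template(z, polarity: str, merge_gap: int = 25) -> ArtifactTemplate:
    signed = z if polarity == "positive" else -z
    regions = supra_regions(z, polarity, merge_gap=merge_gap)
    if not regions:
        return ArtifactTemplate(polarity=polarity, waveform=np.zeros(0),
                                support=(0, 0), n_regions=0)
    durations = np.array([stop - start for start, stop in regions], dtype=float)
    if durations.std() > 0:
        dur_z = (durations - durations.mean()) / durations.std()
    else:
        dur_z = np.zeros_like(durations)
    kept = [(start, stop) for (start, stop), dz in zip(regions, dur_z)
            if -2.0 <= dz <= 2.0]
    if not kept:
        return ArtifactTemplate(polarity=polarity, waveform=np.zeros(0),
                                support=(0, 0), n_regions=0)
    # align at extremum: left/right extents around the peak sample
    exts = []
    for start, stop in kept:
        peak = start + int(np.argmax(signed[start:stop]))
        exts.append((peak - start, stop - 1 - peak, start, stop, peak))
    max_l = max(e[0] for e in exts)
    max_r = max(e[1] for e in exts)
    length = max_l + max_r + 1
    stack = np.zeros((len(exts), length))
    cover = np.zeros((len(exts), length), dtype=bool)
    for i, (l, r, start, stop, peak) in enumerate(exts):
        stack[i, max_l - l:max_l + r + 1] = z[start:stop]
        cover[i, max_l - l:max_l + r + 1] = True
    waveform = stack.mean(axis=0)
    covered = cover.sum(axis=0) >= max(1, len(exts) / 2)
    sup_runs = _runs(covered)
    # support: the covered run containing the extremum
    support = next(((a, b) for a, b in sup_runs if a <= max_l < b),
                   (0, length))
    return ArtifactTemplate(polarity=polarity, waveform=waveform,
                            support=(int(support[0]), int(support[1])),
                            n_regions=len(exts))


def build_blink_templates(veog, merge_gap: int = 25):
    """Build positive and negative blink templates from a full VEOG record.

    Returns (positive ArtifactTemplate, negative ArtifactTemplate, z record).
    Either template may be empty (no supra-threshold runs), in which case
    matching with it is a no-op.
    """
    z = zscore_record(veog)
    return (_build_template(z, "positive", merge_gap),
            _build_template(z, "negative", merge_gap), z)


# ---------------------------------------------------------------------------
# Template matching
# ---------------------------------------------------------------------------

@dataclass
class ArtifactWindows:
    """[start, stop) sample intervals with a source tag, record coordinates."""

    intervals: list = field(default_factory=list)   # (start, stop, source)

    def add(self, start: int, stop: int, source: str):
        self.intervals.append((int(start), int(stop), source))

    def overlaps(self, start: int, stop: int) -> bool:
        return any(s < stop and start < e for s, e, _ in self.intervals)


def sliding_correlation(x, w):
    """Pearson r between ``w`` and every length-len(w) window of ``x``."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    m = w.size
    n = x.size
    if n < m:
        return np.zeros(0)
    wc = w - w.mean()
    sw = np.sqrt(np.sum(wc ** 2))
    cross = fftconvolve(x, wc[::-1], mode="valid")
    c1 = np.cumsum(np.concatenate(([0.0], x)))
    c2 = np.cumsum(np.concatenate(([0.0], x ** 2)))
    wsum = c1[m:] - c1[:-m]
    wsq = c2[m:] - c2[:-m]
    var = wsq - wsum ** 2 / m
    var = np.maximum(var, 0.0)
    denom = sw * np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cross / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def match_blink_template(veog_z, template: ArtifactTemplate,
                         r_threshold: float = 0.7) -> ArtifactWindows:
    """Locate artifact windows by sliding the template over the z record.

    Within each maximal run of positions with r > threshold the best
    position is kept; the window then expands outward from the matched
    segment's z extremum to the nearest preceding/following samples with
    z < 0.5 (positive templates) or z > -0.5 (negative), truncating at the
    record boundary.

    A match is only turned into a window when the segment's extremum
    itself exceeds the |z| > 2 artifact criterion: the template stage
    exists to establish *longer* windows around genuine artifact activity,
    and correlation alone fires on sub-threshold background.
    """
    windows = ArtifactWindows()
    if template.empty:
        return windows
    z = np.asarray(veog_z, dtype=float)
    w = template.support_waveform
    r = sliding_correlation(z, w)
    if r.size == 0:
        return windows
    positive = template.polarity == "positive"
    for start, stop in _runs(r > r_threshold):
        best = start + int(np.argmax(r[start:stop]))
        seg = slice(best, best + w.size)
        signed = z[seg] if positive else -z[seg]
        peak = best + int(np.argmax(signed))
        if (z[peak] if positive else -z[peak]) <= 2.0:
            continue
        below = (z < 0.5) if positive else (z > -0.5)
        left = peak
        while left > 0 and not below[left]:
            left -= 1
        right = peak
        while right < z.size - 1 and not below[right]:
            right += 1
        source = "blink_template"
        windows.add(left, right + 1, source)
    # merge duplicate/overlapping windows from adjacent runs
    merged = []
    for s, e, src in sorted(windows.intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e), src)
        else:
            merged.append((s, e, src))
    windows.intervals = merged
    return windows


# ---------------------------------------------------------------------------
# Epoch rejection
# ---------------------------------------------------------------------------

def reject_epochs(n_trials: int, onset_index: int, fs: float,
                  eog_windows: dict, epochs=None,
                  amplitude_threshold: float = 75.0,
                  blink_halfspan: float = 0.4):
    """Combine the three screens into per-trial / per-electrode flags.

    Parameters
    ----------
    n_trials, onset_index, fs
        Record geometry: each trial record has first-LED onset at
        ``onset_index``.
    eog_windows : dict trial -> ArtifactWindows
        Blink (and saccade, if windowed) intervals in per-trial record
        coordinates; any overlap with the +-``blink_halfspan`` s window
        around onset rejects the trial for all electrodes.
    epochs : (n_channels, n_trials, n_samples) array, optional
        Scalp records for the per-electrode +-75 µV screen, applied over
        the same +-halfspan window (or the full record if shorter).

    Returns
    -------
    all_rejected : (n_trials,) bool — rejected for all electrodes
    by_electrode : (n_channels, n_trials) bool or None — amplitude screen
    """
    half = int(round(blink_halfspan * fs))
    all_rejected = np.zeros(n_trials, dtype=bool)
    for trial, windows in eog_windows.items():
        if windows is None:
            continue
        lo, hi = onset_index - half, onset_index + half + 1
        if windows.overlaps(lo, hi):
            all_rejected[trial] = True
    by_electrode = None
    if epochs is not None:
        epochs = np.asarray(epochs)
        lo = max(0, onset_index - half)
        hi = min(epochs.shape[-1], onset_index + half + 1)
        seg = epochs[..., lo:hi]
        by_electrode = np.abs(seg).max(axis=-1) > amplitude_threshold
    return all_rejected, by_electrode
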
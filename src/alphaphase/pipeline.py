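"""Orchestration: from synthetic sessions to the full analysis report.

Stages, in the order the analysis runs:

1. per-participant feature extraction (filtering, artifact screen, tapered
   analysis epochs, single-trial alpha amplitudes, regional IAFs);
2. attention -> alpha-amplitude electrode-cluster permutation test, with
   per-hemisphere 5x2 follow-up ANOVAs;
3. phase -> perceptual-outcome analysis at the cluster electrodes (response
   split, subsampling, first/second-order circular means, Moore cluster
   permutation over the pre-stimulus window, onset-phase bisection);
4. proportion ANOVAs (phase bin x attention, phase bin x amplitude median
   split) and the polarity paired t-tests (IAF and fixed 10 Hz);
5. controls (t-max ERP check, per-cell Rayleigh tests with the uniformity
   Monte Carlo, all-electrode sweep, off-frequency sweeps).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import artifacts, behaviour, circstats, montage, permtests, preprocess, spectral, synth
from .circstats import CircMean
from .config import StudyConfig

logger = logging.getLogger("alphaphase")


# ---------------------------------------------------------------------------
# per-participant features
# ---------------------------------------------------------------------------

@dataclass
class ParticipantFeatures:
    participant: int
    electrodes: tuple
    trials: pd.DataFrame                 # + rejected_all / saccade / blink flags
    clean: np.ndarray                    # (n_electrodes, n_trials) usable mask
    epochs_tapered: np.ndarray           # (n_electrodes, n_trials, 201) float32
    amplitudes: np.ndarray               # (n_electrodes, n_trials) alpha amp
    iaf: dict                            # region -> spectral.IAF
    fs: float
    onset_sample: int                    # onset index within the 201 window
    saccade_fraction: float = 0.0
    erp: dict | None = None              # {"filtered","raw","times"} windows
    truth: dict = field(default_factory=dict)

    def electrode_index(self, name: str) -> int:
        return self.electrodes.index(name)

    def iaf_for(self, electrode: str) -> float:
        region = "frontal" if electrode in montage.FRONTAL else "posterior"
        return self.iaf[region].frequency


def extract_features(session: synth.SyntheticSession, study: StudyConfig,
                     retain_erp: bool = True) -> ParticipantFeatures:
    """Filter, screen and summarise one session."""
    es = session.epochs
    scalp = tuple(ch for ch in es.channel_names if ch not in montage.EOG)
    scalp_idx = [es.channel_names.index(ch) for ch in scalp]
    records = preprocess.zero_phase_filter(
        es.data[scalp_idx], study.filter, es.fs, axis=-1)
    n_trials = records.shape[1]
    trials = session.trials.copy()

    saccade_rej = np.zeros(n_trials, dtype=bool)
    blink_rej = np.zeros(n_trials, dtype=bool)
    by_electrode = np.zeros((len(scalp), n_trials), dtype=bool)
    saccade_fraction = 0.0
    if study.run_artifact_screen and "VEOG" in es.channel_names:
        saccade_rej, blink_rej, by_electrode = _artifact_screen(
            session, study, scalp, records)
        saccade_fraction = float(saccade_rej.mean())

    trials["saccade_rejected"] = saccade_rej
    trials["blink_rejected"] = blink_rej
    trials["rejected_all"] = saccade_rej | blink_rej
    clean = ~by_electrode & ~trials["rejected_all"].to_numpy()[None, :]

    epochs = preprocess.extract_epochs(records, es.onset_index, study.epoch)
    tapered = preprocess.tukey_taper(epochs, study.epoch.taper_ramp)
    band_mags = spectral.band_magnitudes(tapered, study.spectral,
                                         study.epoch.length)
    amplitudes = band_mags.mean(axis=-1)

    async_mask = (trials["synchrony"] == "async").to_numpy()
    iaf = {}
    for region, region_chs in (("frontal", montage.FRONTAL),
                               ("posterior", montage.POSTERIOR)):
        idx = [scalp.index(ch) for ch in region_chs if ch in scalp]
        if not idx:
            continue
        # average magnitudes over clean asynchronous trials, then electrodes
        per_electrode = [band_mags[e, async_mask & clean[e]].mean(axis=0)
                         for e in idx if (async_mask & clean[e]).any()]
        if not per_electrode:
            raise ValueError(f"all trials rejected for region {region}")
        iaf[region] = spectral.iaf_from_magnitudes(
            np.mean(per_electrode, axis=0), study.spectral, region=region)

    erp = None
    if retain_erp:
        erp = _erp_windows(session, study, scalp, records)

    return ParticipantFeatures(
        participant=session.participant, electrodes=scalp, trials=trials,
        clean=clean, epochs_tapered=tapered.astype(np.float32),
        amplitudes=amplitudes.astype(np.float32), iaf=iaf, fs=es.fs,
        onset_sample=study.epoch.onset_index,
        saccade_fraction=saccade_fraction, erp=erp, truth=session.truth)


def _artifact_screen(session, study, scalp, records):
    """Saccade threshold + blink template + amplitude screens."""
    es = session.epochs
    fs = es.fs
    n_trials = records.shape[1]
    # the offline zero-phase filter precedes every screening step
    heog = preprocess.zero_phase_filter(es.channel("HEOG"), study.filter, fs)
    veog = preprocess.zero_phase_filter(es.channel("VEOG"), study.filter, fs)

    # saccade screen over -1350..+250 ms (clipped to the available record)
    thr = artifacts.calibrate_saccade_threshold(
        session.calibration_heog, participant=session.participant,
        fraction=study.saccade_threshold_fraction)
    lo = max(0, es.onset_index - int(round(1.350 * fs)))
    hi = min(records.shape[-1], es.onset_index + int(round(0.250 * fs)) + 1)
    saccade_rej = artifacts.detect_saccades(heog[:, lo:hi], thr)

    # blink templates from the whole (concatenated) VEOG record
    n_samples = veog.shape[-1]
    pos, neg, z = artifacts.build_blink_templates(veog.reshape(-1))
    eog_windows = {}

    def add_global_window(s, e, src):
        for tr in range(s // n_samples, min((e - 1) // n_samples + 1,
                                            n_trials)):
            aw = eog_windows.setdefault(tr, artifacts.ArtifactWindows())
            aw.add(max(0, s - tr * n_samples),
                   min(n_samples, e - tr * n_samples), src)

    # first screen: any overlap with raw supra-threshold (|z| > 2) activity
    for polarity in ("positive", "negative"):
        for s, e in artifacts.supra_regions(z, polarity):
            add_global_window(s, e, "blink_z")
    # second screen: template-extended windows
    for template in (pos, neg):
        if template.empty:
            continue
        wins = artifacts.match_blink_template(
            z, template, r_threshold=study.template_r_threshold)
        for s, e, src in wins.intervals:
            add_global_window(s, e, src)

    blink_rej, by_electrode = artifacts.reject_epochs(
        n_trials, es.onset_index, fs, eog_windows, epochs=records,
        amplitude_threshold=study.amplitude_threshold,
        blink_halfspan=study.blink_epoch_halfspan)
    return saccade_rej, blink_rej, by_electrode


def _erp_windows(session, study, scalp, filtered_records):
    """Baselined ERP segments (-200 ms .. +400 ms) filtered and raw."""
    es = session.epochs
    fs = es.fs
    pre = int(round(0.2 * fs))
    post = int(round(0.4 * fs))
    lo, hi = es.onset_index - pre, es.onset_index + post + 1
    if lo < 0 or hi > es.data.shape[-1]:
        return None
    scalp_idx = [es.channel_names.index(ch) for ch in scalp]
    out = {}
    for name, rec in (("filtered", filtered_records),
                      ("raw", es.data[scalp_idx])):
        seg = rec[..., lo:hi]
        baseline = seg[..., :pre + 1].mean(axis=-1, keepdims=True)
        out[name] = (seg - baseline).astype(np.float32)
    out["times"] = (np.arange(lo, hi) - es.onset_index) / fs
    return out


def simulate_features(study: StudyConfig, participants=None,
                      retain_erp: bool = True, channels=None,
                      include_eog: bool = True):
    """Generate and featurise every participant (one session in memory at
    a time)."""
    if participants is None:
        participants = range(study.sim.n_participants)
    feats = []
    for pid in participants:
        session = synth.generate_session(study.sim, pid, channels=channels,
                                         include_eog=include_eog)
        feats.append(extract_features(session, study, retain_erp=retain_erp))
    return feats


# ---------------------------------------------------------------------------
# stage 2: attention -> alpha amplitude
# ---------------------------------------------------------------------------

def _attended_mask(electrode, cue_side):
    """Attention is contralateral: left-hemisphere electrodes are 'attended'
    when the cue points right, and vice versa."""
    hemi = montage.hemisphere(electrode)
    if hemi == "midline":
        raise ValueError("midline electrodes have no attended/unattended split")
    return cue_side == ("right" if hemi == "left" else "left")


def attention_amplitude_matrix(feats, electrodes):
    """(n_participants, n_electrodes) mean alpha amplitude, attended and
    unattended, asynchronous trials only."""
    att = np.zeros((len(feats), len(electrodes)))
    unatt = np.zeros_like(att)
    for i, f in enumerate(feats):
        async_mask = (f.trials["synchrony"] == "async").to_numpy()
        cue = f.trials["cue_side"].to_numpy()
        for j, ch in enumerate(electrodes):
            e = f.electrode_index(ch)
            sel = async_mask & f.clean[e]
            attended = _attended_mask(ch, cue)
            att[i, j] = f.amplitudes[e, sel & attended].mean()
            unatt[i, j] = f.amplitudes[e, sel & ~attended].mean()
    return att, unatt


def run_attention_amplitude(feats, study: StudyConfig) -> dict:
    """Electrode-cluster permutation test of attentional alpha suppression.

    Returns the ClusterResult, the electrodes carried into the phase
    analysis (significant suppression cluster, or the configured fallback),
    and the per-hemisphere 5x2 follow-up ANOVAs.
    """
    electrodes = [ch for ch in feats[0].electrodes if ch in montage.LATERAL]
    att, unatt = attention_amplitude_matrix(feats, electrodes)
    adjacency = montage.adjacency(electrodes)
    result = permtests.cluster_perm_scalar(
        att, unatt, electrodes, adjacency, n_perm=study.n_perm_electrode,
        seed=study.analysis_seed, entry_alpha=study.cluster_entry_alpha)

    suppression = [c for c in result.significant if c.sign < 0]
    if suppression:
        cluster_electrodes = tuple(suppression[0].members)
    else:
        warnings.warn("no significant suppression cluster; falling back to "
                      f"{study.fallback_electrodes}")
        cluster_electrodes = tuple(study.fallback_electrodes)

    # hemisphere follow-ups on the (left) cluster sites and their homotopes
    left_sites = [ch for ch in cluster_electrodes
                  if montage.hemisphere(ch) == "left"]
    if not left_sites:
        left_sites = [ch for ch in study.fallback_electrodes]
    right_sites = [montage.homotopic(ch) for ch in left_sites]
    anovas = {}
    for hemi, sites in (("left", left_sites), ("right", right_sites)):
        idx = [electrodes.index(ch) for ch in sites if ch in electrodes]
        cells = np.stack([att[:, idx], unatt[:, idx]], axis=-1)  # (n, k, 2)
        anovas[hemi] = behaviour.rm_anova_kx2(cells)
    return {"cluster_result": result, "cluster_electrodes": cluster_electrodes,
            "hemisphere_anovas": anovas,
            "attended_mean": float(att.mean()),
            "unattended_mean": float(unatt.mean())}


# ---------------------------------------------------------------------------
# stage 3: phase -> perceptual outcome
# ---------------------------------------------------------------------------

def _phase_window(study: StudyConfig):
    """Sample indices of the -200..0 ms window within the analysis epoch."""
    n_pre = int(round(0.2 * study.sim.fs))
    onset = study.epoch.onset_index
    return slice(onset - n_pre, onset + 1)


def electrode_phases(f: ParticipantFeatures, study: StudyConfig,
                     electrode: str, trial_idx, freq: float | None = None):
    """Gabor phase time-courses for selected trials at one electrode.

    ``freq`` of None means the electrode's regional IAF.  Returns
    (n_sel, 101) phases over the -200..0 ms window.
    """
    if freq is None:
        freq = f.iaf_for(electrode)
    e = f.electrode_index(electrode)
    phases = spectral.gabor_phase(f.epochs_tapered[e, trial_idx],
                                  freq, f.fs,
                                  n_cycles_sd=study.spectral.gabor_n_cycles_sd)
    return phases[..., _phase_window(study)]


def participant_outcome_vectors(f: ParticipantFeatures, study: StudyConfig,
                                cluster_electrodes, freq: float | None = None,
                                rng=None):
    """Second-order per-condition mean vectors over the cluster electrodes.

    Splits asynchronous trials by perceptual outcome, subsamples the larger
    response class to the smaller one's count (without replacement), takes
    first-order circular means per electrode and time sample, then the
    second-order mean across electrodes.

    Returns (va, vb) of shape (T, 2) — asynchronous-response and
    simultaneous-response vectors — or None when either response class has
    fewer than ``study.min_trials_per_response`` usable trials at any
    electrode.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(study.analysis_seed),
                                   spawn_key=(int(f.participant), 7)))
    async_mask = (f.trials["synchrony"] == "async").to_numpy()
    resp_async = (f.trials["response"] == "async").to_numpy()
    per_cond = {"async": [], "simul": []}
    for ch in cluster_electrodes:
        e = f.electrode_index(ch)
        usable = async_mask & f.clean[e]
        idx_a = np.flatnonzero(usable & resp_async)
        idx_s = np.flatnonzero(usable & ~resp_async)
        n_min = min(idx_a.size, idx_s.size)
        if n_min < study.min_trials_per_response:
            warnings.warn(f"participant {f.participant}: too few trials per "
                          f"response at {ch} (n={n_min}); excluded")
            return None
        if idx_a.size > n_min:
            idx_a = rng.choice(idx_a, size=n_min, replace=False)
        if idx_s.size > n_min:
            idx_s = rng.choice(idx_s, size=n_min, replace=False)
        for label, idx in (("async", idx_a), ("simul", idx_s)):
            ph = electrode_phases(f, study, ch, idx, freq=freq)
            ang, r = circstats.circ_mean_arrays(ph, axis=0)
            per_cond[label].append(np.stack([r * np.cos(ang),
                                             r * np.sin(ang)], axis=-1))
    va = np.mean(per_cond["async"], axis=0)     # second-order across electrodes
    vb = np.mean(per_cond["simul"], axis=0)
    return va, vb


def run_phase_outcome(feats, study: StudyConfig, cluster_electrodes,
                      freq: float | None = None) -> dict:
    """Moore cluster permutation over the pre-stimulus window + bisection."""
    va_list, vb_list, used = [], [], []
    for f in feats:
        out = participant_outcome_vectors(f, study, cluster_electrodes,
                                          freq=freq)
        if out is None:
            continue
        va_list.append(out[0])
        vb_list.append(out[1])
        used.append(f.participant)
    if len(used) < 2:
        raise ValueError("fewer than two participants usable for the phase "
                         "analysis")
    va = np.stack(va_list)
    vb = np.stack(vb_list)
    result = permtests.cluster_perm_circular(
        va, vb, n_perm=study.n_perm_time, seed=study.analysis_seed + 1,
        entry_alpha=study.cluster_entry_alpha)

    def across(v):
        c, s = v[:, -1, :].mean(axis=0)
        r = float(np.hypot(c, s))
        return CircMean(angle=float(np.arctan2(s, c)), r=r, n=v.shape[0],
                        defined=r > 1e-12)

    mean_async = across(va)
    mean_simul = across(vb)
    binning = circstats.make_bisection(mean_async, mean_simul)
    # preferred-phase estimate: the axis separating the two outcomes,
    # i.e. the angle of the across-participant mean difference vector
    dc, ds = (va[:, -1, :] - vb[:, -1, :]).mean(axis=0)
    preferred_phase = float(np.arctan2(ds, dc))
    onset_test = circstats.moore_paired_test(
        va[:, -1, :], vb[:, -1, :], n_perm=study.n_perm_moore,
        seed=study.analysis_seed + 2)
    return {"cluster_result": result, "binning": binning,
            "participants": used, "onset_mean_async": mean_async,
            "onset_mean_simul": mean_simul, "onset_moore": onset_test,
            "preferred_phase": preferred_phase, "vectors": (va, vb)}


# ---------------------------------------------------------------------------
# stage 4: proportion analyses
# ---------------------------------------------------------------------------

def onset_phases_by_electrode(f, study, cluster_electrodes,
                              freq: float | None = None):
    """Dict electrode -> (trial indices, onset phases) for usable
    contralateral asynchronous trials."""
    async_mask = (f.trials["synchrony"] == "async").to_numpy()
    target = f.trials["target_side"].to_numpy()
    out = {}
    for ch in cluster_electrodes:
        e = f.electrode_index(ch)
        contra = target == ("right" if montage.hemisphere(ch) == "left"
                            else "left")
        idx = np.flatnonzero(async_mask & f.clean[e] & contra)
        ph = electrode_phases(f, study, ch, idx, freq=freq)[:, -1]
        out[ch] = (idx, ph)
    return out


def run_proportion_analyses(feats, study: StudyConfig, binning,
                            cluster_electrodes) -> dict:
    """Phase-bin x attention and phase-bin x amplitude ANOVAs, plus the
    polarity paired t-tests (at IAF and at a fixed 10 Hz filter)."""
    cells_attention, cells_amplitude = [], []
    polarity_iaf, polarity_fixed = [], []
    excluded = []
    for f in feats:
        phases = onset_phases_by_electrode(f, study, cluster_electrodes)
        phases10 = onset_phases_by_electrode(
            f, study, cluster_electrodes, freq=study.polarity_fixed_freq)
        correct = (f.trials["response"] == "async").to_numpy()
        validity = (f.trials["validity"] == "valid").to_numpy()
        att_cells, amp_cells, pol_i, pol_f = [], [], [], []
        ok = True
        for ch in cluster_electrodes:
            idx, ph = phases[ch]
            if idx.size == 0:
                ok = False
                break
            in_a = circstats.classify_phase(ph, binning)
            e = f.electrode_index(ch)
            amp_hi = f.amplitudes[e, idx] > np.median(f.amplitudes[e, idx])
            cell_att = np.full((2, 2), np.nan)
            cell_amp = np.full((2, 2), np.nan)
            for bi, bmask in ((0, in_a), (1, ~in_a)):
                for ai, amask in ((0, validity[idx]), (1, ~validity[idx])):
                    sel = bmask & amask
                    if sel.any():
                        cell_att[bi, ai] = correct[idx][sel].mean()
                for mi, mmask in ((0, ~amp_hi), (1, amp_hi)):
                    sel = bmask & mmask
                    if sel.any():
                        cell_amp[bi, mi] = correct[idx][sel].mean()
            neg = circstats.classify_polarity(ph)
            idx10, ph10 = phases10[ch]
            neg10 = circstats.classify_polarity(ph10)
            pol = (correct[idx][neg].mean() if neg.any() else np.nan,
                   correct[idx][~neg].mean() if (~neg).any() else np.nan)
            pol10 = (correct[idx10][neg10].mean() if neg10.any() else np.nan,
                     correct[idx10][~neg10].mean() if (~neg10).any() else np.nan)
            att_cells.append(cell_att)
            amp_cells.append(cell_amp)
            pol_i.append(pol)
            pol_f.append(pol10)
        if not ok:
            excluded.append(f.participant)
            continue
        cells_attention.append(np.nanmean(att_cells, axis=0))
        cells_amplitude.append(np.nanmean(amp_cells, axis=0))
        polarity_iaf.append(np.nanmean(pol_i, axis=0))
        polarity_fixed.append(np.nanmean(pol_f, axis=0))
    if excluded:
        logger.info("proportion analyses excluded participants: %s", excluded)

    cells_attention = np.asarray(cells_attention)
    cells_amplitude = np.asarray(cells_amplitude)
    pol_iaf = np.asarray(polarity_iaf)
    pol_fix = np.asarray(polarity_fixed)
    out = {
        "anova_phase_attention": behaviour.rm_anova_2x2(
            _drop_nan_rows(cells_attention)),
        "anova_phase_amplitude": behaviour.rm_anova_2x2(
            _drop_nan_rows(cells_amplitude)),
        "polarity_t_iaf": behaviour.paired_t(pol_iaf[:, 0], pol_iaf[:, 1]),
        "polarity_t_fixed": behaviour.paired_t(pol_fix[:, 0], pol_fix[:, 1]),
        "proportion_async_bin": float(np.nanmean(cells_attention[:, 0, :])),
        "proportion_simul_bin": float(np.nanmean(cells_attention[:, 1, :])),
        "within_subject_se": behaviour.within_subject_se(
            cells_attention.reshape(len(cells_attention), -1)),
        "excluded": excluded,
    }
    return out


def _drop_nan_rows(cells):
    flat = cells.reshape(cells.shape[0], -1)
    keep = ~np.isnan(flat).any(axis=1)
    return cells[keep]


# ---------------------------------------------------------------------------
# stage 5: controls
# ---------------------------------------------------------------------------

def run_controls(feats, study: StudyConfig, cluster_electrodes,
                 binning=None) -> dict:
    """ERP t-max check, Rayleigh uniformity + Monte Carlo, all-electrode
    sweep and off-frequency sweeps."""
    out = {}

    # t-max ERP comparison, filtered and unfiltered, 0..400 ms post onset
    if all(f.erp is not None for f in feats):
        for kind in ("filtered", "raw"):
            erp_a, erp_b = [], []
            for f in feats:
                async_mask = (f.trials["synchrony"] == "async").to_numpy()
                resp_async = (f.trials["response"] == "async").to_numpy()
                post = f.erp["times"] >= 0
                traces = {}
                for label, rmask in (("async", resp_async),
                                     ("simul", ~resp_async)):
                    per_e = []
                    for ch in cluster_electrodes:
                        e = f.electrode_index(ch)
                        sel = async_mask & rmask & f.clean[e]
                        per_e.append(f.erp[kind][e, sel].mean(axis=0))
                    traces[label] = np.mean(per_e, axis=0)[post]
                erp_a.append(traces["async"])
                erp_b.append(traces["simul"])
            t_max, p = permtests.tmax_erp_test(
                np.stack(erp_a), np.stack(erp_b), n_perm=study.n_perm_time,
                seed=study.analysis_seed + 3)
            out[f"erp_tmax_{kind}"] = {"t_max": t_max, "p": p}

    # Rayleigh per participant x electrode (+ Bonferroni across participants)
    flags = []
    counts = np.zeros((len(feats), len(cluster_electrodes)), dtype=int)
    p_table = np.ones_like(counts, dtype=float)
    for i, f in enumerate(feats):
        async_mask = (f.trials["synchrony"] == "async").to_numpy()
        for j, ch in enumerate(cluster_electrodes):
            e = f.electrode_index(ch)
            idx = np.flatnonzero(async_mask & f.clean[e])
            ph = electrode_phases(f, study, ch, idx)[:, -1]
            _, p = circstats.rayleigh_test(ph)
            p_table[i, j] = p
            counts[i, j] = idx.size
    alpha = 0.05
    out["rayleigh"] = {
        "n_uncorrected": int((p_table < alpha).sum()),
        "n_bonferroni": int((p_table < alpha / len(feats)).sum()),
        "p_table": p_table,
    }
    out["uniformity_mc"] = permtests.uniformity_mc(
        n_participants=len(feats), n_electrodes=len(cluster_electrodes),
        n_trials=counts, alpha=alpha, reps=study.uniformity_reps,
        seed=study.analysis_seed + 4)

    # off-frequency sweeps at the cluster electrodes
    out["off_frequency"] = {}
    for freq in study.off_frequencies:
        res = run_phase_outcome(feats, study, cluster_electrodes, freq=freq)
        out["off_frequency"][freq] = res["cluster_result"]
    return out


def run_all_electrode_sweep(feats, study: StudyConfig) -> permtests.ClusterResult:
    """Second-order phase test across every scalp electrode with
    spatiotemporal cluster correction (secondary analysis)."""
    electrodes = feats[0].electrodes
    va_all, vb_all = [], []
    for f in feats:
        rows_a, rows_b = [], []
        usable = True
        for ch in electrodes:
            out = participant_outcome_vectors(f, study, (ch,))
            if out is None:
                usable = False
                break
            rows_a.append(out[0])
            rows_b.append(out[1])
        if not usable:
            continue
        va_all.append(np.stack(rows_a))
        vb_all.append(np.stack(rows_b))
    va = np.stack(va_all)      # (n, E, T, 2)
    vb = np.stack(vb_all)
    return permtests.cluster_perm_spatiotemporal(
        va, vb, electrodes, montage.adjacency(electrodes),
        n_perm=study.n_perm_time, seed=study.analysis_seed + 5,
        entry_alpha=study.cluster_entry_alpha)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_study(study: StudyConfig, participants=None, retain_erp: bool = True,
              channels=None, include_eog: bool | None = None,
              stages=("behaviour", "amplitude", "phase", "proportions",
                      "controls")) -> dict:
    """Run the analysis end to end on freshly simulated sessions.

    Deterministic in (study.sim.seed, study.analysis_seed): the same
    configuration reproduces every statistic bit-identically.
    """
    study.validate()
    if include_eog is None:
        include_eog = study.run_artifact_screen
    feats = simulate_features(study, participants=participants,
                              retain_erp=retain_erp and "controls" in stages,
                              channels=channels, include_eog=include_eog)

    report = {"n_participants": len(feats)}
    # participant exclusion gate (> 20% saccade-contaminated trials)
    kept = [f for f in feats if f.saccade_fraction
            <= study.participant_exclusion_fraction]
    if len(kept) < len(feats):
        logger.info("excluded %d participants for saccade contamination",
                    len(feats) - len(kept))
    report["n_excluded_saccade"] = len(feats) - len(kept)
    report["mean_saccade_rejected"] = float(
        np.mean([f.saccade_fraction for f in kept])) if kept else float("nan")
    report["mean_blink_rejected"] = float(
        np.mean([f.trials["blink_rejected"].mean() for f in kept]))
    report["mean_clean_trials_per_electrode"] = float(
        np.mean([f.clean.sum(axis=1).mean() for f in kept]))
    feats = kept

    if "behaviour" in stages:
        summary = behaviour.behavioural_summary([f.trials for f in feats])
        report["behaviour"] = {
            "summary": summary,
            "hit_rate": float(summary["hit_rate"].mean()),
            "fa_rate": float(summary["fa_rate"].mean()),
            "d_prime": float(summary["d_prime"].mean()),
            "rt_test": behaviour.paired_t(summary["rt_valid"],
                                          summary["rt_invalid"]),
            "soa_test": behaviour.paired_t(summary["soa_valid"],
                                           summary["soa_invalid"]),
        }
    if "amplitude" in stages:
        report["amplitude"] = run_attention_amplitude(feats, study)
        cluster_electrodes = report["amplitude"]["cluster_electrodes"]
    else:
        cluster_electrodes = tuple(study.fallback_electrodes)
    if "phase" in stages:
        report["phase"] = run_phase_outcome(feats, study, cluster_electrodes)
    if "proportions" in stages and "phase" in stages:
        report["proportions"] = run_proportion_analyses(
            feats, study, report["phase"]["binning"], cluster_electrodes)
    if "controls" in stages:
        report["controls"] = run_controls(feats, study, cluster_electrodes)
    report["_features"] = feats
    return report
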
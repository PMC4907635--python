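"""Generator contracts: determinism, phase-response coupling, artifact
injection bookkeeping, staircase dynamics."""

import numpy as np
import pytest
from scipy import stats

from alphaphase import synth
from alphaphase.config import SimConfig


def _fixed_soa_config(m, n_async, seed=0, **kw):
    return SimConfig(n_participants=1, n_trials_by_cell=(n_async, 0, 0, 0),
                     phase_effect_depth=m, soa_mode="fixed",
                     epoch_span=(-0.31, 0.05), blink_rate=0.0,
                     saccade_rate=0.0, erp_amp=0.0, seed=seed, **kw)


def test_same_seed_same_participant_is_bit_identical():
    cfg = SimConfig(n_participants=2, n_trials_by_cell=(40, 16, 8, 4),
                    epoch_span=(-0.5, 0.1), seed=7)
    a = synth.generate_session(cfg, 1)
    b = synth.generate_session(cfg, 1)
    np.testing.assert_array_equal(a.epochs.data, b.epochs.data)
    assert a.trials.equals(b.trials)
    np.testing.assert_array_equal(a.truth["onset_phase"], b.truth["onset_phase"])
    c = synth.generate_session(cfg, 0)
    assert not np.array_equal(a.epochs.data, c.epochs.data)


def test_zero_depth_gives_flat_response_probability_across_phase_bins():
    ses = synth.generate_session(_fixed_soa_config(0.0, 4000), 0,
                                 include_eog=False)
    phase = ses.truth["onset_phase"]
    hit = (ses.trials["response"] == "async").to_numpy()
    edges = np.linspace(-np.pi, np.pi, 5)
    rates = [hit[(phase > lo) & (phase <= hi)].mean()
             for lo, hi in zip(edges[:-1], edges[1:])]
    n_bin = 1000
    se = np.sqrt(0.25 / n_bin)
    assert np.ptp(rates) < 6 * se       # all bins equal within binomial error


def test_phase_modulation_matches_generative_depth():
    """p(async) = p0 + m cos(phase - phi_pref): opposite 60-degree sectors
    around the preferred phase differ by 2m * sin(30)/(pi/6) = 1.91 m."""
    m = 0.2
    ses = synth.generate_session(
        _fixed_soa_config(m, 4000, preferred_phase=np.deg2rad(270)), 0,
        include_eog=False)
    phase = ses.truth["onset_phase"]
    hit = (ses.trials["response"] == "async").to_numpy()
    d_pref = np.abs(np.angle(np.exp(1j * (phase - np.deg2rad(270)))))
    d_anti = np.abs(np.angle(np.exp(1j * (phase - np.deg2rad(90)))))
    sector = np.deg2rad(30)
    p_pref = hit[d_pref < sector].mean()
    p_anti = hit[d_anti < sector].mean()
    expected = 2 * m * np.sin(sector) / sector
    n = min((d_pref < sector).sum(), (d_anti < sector).sum())
    se = np.sqrt(2 * 0.25 / n)
    assert abs((p_pref - p_anti) - expected) < 3 * se


def test_truth_phases_are_wrapped_and_uniform():
    ses = synth.generate_session(_fixed_soa_config(0.0, 2000), 0,
                                 include_eog=False)
    phase = ses.truth["onset_phase"]
    assert np.all(phase > -np.pi) and np.all(phase <= np.pi)
    # Rayleigh on 2000 uniform draws should not look concentrated
    rbar = np.abs(np.exp(1j * phase).mean())
    assert 2000 * rbar ** 2 < 12


def test_trial_cell_counts_and_counterbalance():
    cfg = SimConfig(n_trials_by_cell=(40, 16, 8, 4), epoch_span=(-0.3, 0.05),
                    blink_rate=0.0, saccade_rate=0.0, seed=3)
    ses = synth.generate_session(cfg, 0, include_eog=False)
    counts = ses.trials.groupby(["validity", "synchrony"]).size()
    assert counts[("valid", "async")] == 40
    assert counts[("invalid", "async")] == 16
    assert counts[("valid", "simul")] == 8
    assert counts[("invalid", "simul")] == 4
    async_tr = ses.trials[ses.trials["synchrony"] == "async"]
    assert set(async_tr["leading_led"]) == {"top", "bottom"}
    sides = async_tr.groupby("target_side").size()
    assert abs(sides["left"] - sides["right"]) <= 2
    # invalid cue points away from the target
    inv = ses.trials[ses.trials["validity"] == "invalid"]
    assert (inv["cue_side"] != inv["target_side"]).all()


class TestBlinkInjection:
    def test_zero_rate_is_identity(self, rng):
        x = rng.normal(size=2000)
        out, windows = synth.inject_blinks(x, 0.0, 500.0, rng=rng)
        np.testing.assert_array_equal(out, x)
        assert windows == []

    def test_each_pulse_gets_a_window_covering_its_support(self, rng):
        x = np.zeros(int(500 * 120))
        out, windows = synth.inject_blinks(x, 10.0, 500.0, rng=rng, amp=5.0)
        assert len(windows) > 0
        for s, e in windows:
            assert np.abs(out[s:e]).max() > 0
        outside = np.ones(x.size, dtype=bool)
        for s, e in windows:
            outside[s:e] = False
        assert np.all(out[outside] == 0)

    def test_pulse_at_8x_noise_sd_exceeds_zscore_2(self, rng):
        x = rng.normal(0, 1.0, int(500 * 60))
        out, windows = synth.inject_blinks(x, 6.0, 500.0, rng=rng, amp=8.0)
        z = (out - out.mean()) / out.std()
        assert len(windows) > 0
        for s, e in windows:
            assert np.abs(z[s:e]).max() > 2.0


class TestSaccadeInjection:
    def test_zero_rate_is_identity(self, rng):
        x = rng.normal(size=2000)
        out, events = synth.inject_saccades(x, 0.0, 500.0, rng=rng)
        np.testing.assert_array_equal(out, x)
        assert events == []

    def test_step_height_matches_requested_amplitude(self):
        x = np.zeros(3000)
        rng = np.random.default_rng(2)
        out, events = synth.inject_saccades(x, 1.0, 500.0, rng=rng, amp=50.0)
        while not events:
            out, events = synth.inject_saccades(x, 1.0, 500.0, rng=rng,
                                                amp=50.0)
        onset, signed = events[0]
        assert abs(abs(signed) - 50.0) < 1e-12
        if len(events) == 1 and onset + 30 < x.size:
            assert abs((out[onset + 20:].mean() if onset + 20 < x.size else
                        signed) - signed) < 1e-6

    def test_signs_are_balanced(self, rng):
        x = np.zeros(int(500 * 60))
        signs = []
        for i in range(50):
            _, events = synth.inject_saccades(
                x, 20.0, 500.0, rng=np.random.default_rng(i), amp=10.0)
            signs += [1 if s > 0 else 0 for _, s in events]
        assert len(signs) > 500
        assert stats.binomtest(sum(signs), len(signs), 0.5).pvalue > 0.01


class TestStaircase:
    def test_deterministic_observer_oscillates_around_threshold(self):
        threshold = 33.0
        observer = lambda soa: 1.0 if soa > threshold else 0.0
        soas, _ = synth.simulate_staircase(observer, 200, 60.0, 5.0, seed=0)
        tail = soas[50:]
        assert tail.min() >= threshold - 5.0
        assert tail.max() <= threshold + 5.0

    def test_logistic_observer_converges_to_half_hit_rate(self):
        observer = synth.logistic_observer(40.0, 0.15)
        rates = []
        for seed in range(10):
            _, correct = synth.simulate_staircase(observer, 560, 50.0, 5.0,
                                                  seed=seed)
            rates.append(correct[100:].mean())
        assert abs(np.mean(rates) - 0.5) < 0.03

    def test_soas_congruent_to_start_modulo_step(self):
        observer = synth.logistic_observer(40.0, 0.15)
        soas, _ = synth.simulate_staircase(observer, 300, 50.0, 5.0, seed=1)
        assert np.all(soas % 5.0 == 0.0)
        assert soas.min() >= 5.0

    def test_non_monotone_observer_rejected(self):
        bad = lambda soa: np.cos(soa / 5.0) * 0.5 + 0.5
        with pytest.raises(ValueError, match="non-decreasing"):
            synth.simulate_staircase(bad, 10, 50.0, 5.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(phase_effect_depth=0.6).validate()
    with pytest.raises(ValueError):
        SimConfig(base_p_async=0.95, phase_effect_depth=0.1).validate()
    with pytest.raises(ValueError):
        SimConfig(blink_rate=-1.0).validate()
    with pytest.raises(ValueError):
        SimConfig(fs=20.0).validate()


def test_attentional_suppression_is_present_at_left_posterior_sites(
        small_session):
    """Alpha amplitude at the suppression sites is larger when the cue is
    ipsilateral (unattended) than contralateral (attended)."""
    from alphaphase import preprocess, spectral
    from alphaphase.config import EpochSpec, SpectralSpec

    es = small_session.epochs
    trials = small_session.trials
    async_mask = (trials["synchrony"] == "async").to_numpy()
    cue = trials["cue_side"].to_numpy()
    e = es.channel_names.index("P3")
    ep = preprocess.extract_epochs(es.data[e].astype(float), es.onset_index,
                                  EpochSpec())
    amp = spectral.alpha_amplitude(preprocess.tukey_taper(ep, 50),
                                   SpectralSpec())
    attended = amp[async_mask & (cue == "right")]
    unattended = amp[async_mask & (cue == "left")]
    t, p = stats.ttest_ind(unattended, attended)
    assert t > 0 and p < 1e-6
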
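"""Signal detection, repeated-measures ANOVAs (cross-checked against
pingouin), effect sizes and within-subject errors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alphaphase import behaviour, synth
from alphaphase.config import SimConfig


def _trials(hit, fa, n_sig=560, n_noise=120, seed=0):
    rng = np.random.default_rng(seed)
    sync = np.array(["async"] * n_sig + ["simul"] * n_noise)
    resp = np.where(
        np.concatenate([rng.random(n_sig) < hit, rng.random(n_noise) < fa]),
        "async", "simul")
    return pd.DataFrame({"synchrony": sync, "response": resp})


class TestSDT:
    def test_symmetric_rates_give_zero(self):
        df = pd.DataFrame({"synchrony": ["async", "async", "simul", "simul"],
                           "response": ["async", "simul", "async", "simul"]})
        res = behaviour.sdt_metrics(df)
        assert res.d_prime == pytest.approx(0.0)
        assert res.criterion == pytest.approx(0.0)

    def test_nine_one_example(self):
        df = pd.DataFrame({
            "synchrony": ["async"] * 10 + ["simul"] * 10,
            "response": ["async"] * 9 + ["simul"] + ["async"] + ["simul"] * 9})
        res = behaviour.sdt_metrics(df)
        assert res.d_prime == pytest.approx(2 * stats.norm.ppf(0.9), abs=1e-9)

    def test_recovers_injected_sensitivity(self):
        d_true = 1.8
        hit = stats.norm.cdf(d_true / 2)
        fa = stats.norm.cdf(-d_true / 2)
        est = [behaviour.sdt_metrics(_trials(hit, fa, seed=i)).d_prime
               for i in range(30)]
        assert abs(np.mean(est) - d_true) < 0.15

    def test_extreme_rates_are_adjusted_not_infinite(self):
        df = _trials(1.0, 0.0, n_sig=50, n_noise=50, seed=1)
        df["response"] = np.where(df["synchrony"] == "async", "async", "simul")
        res = behaviour.sdt_metrics(df)
        assert np.isfinite(res.d_prime)

    def test_missing_class_rejected(self):
        df = pd.DataFrame({"synchrony": ["async"], "response": ["async"]})
        with pytest.raises(ValueError):
            behaviour.sdt_metrics(df)


class TestAnova2x2:
    def test_interaction_equals_squared_paired_t(self, rng):
        y = rng.normal(size=(16, 2, 2))
        res = behaviour.rm_anova_2x2(y)
        contrast = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])
        t = contrast.mean() / (contrast.std(ddof=1) / np.sqrt(16))
        assert res["AxB"].F == pytest.approx(t ** 2, rel=1e-9)
        for name in ("A", "B"):
            assert res[name].df1 == 1 and res[name].df2 == 15

    def test_identical_cells_give_zero_f(self):
        y = np.ones((10, 2, 2)) * np.arange(10)[:, None, None]
        res = behaviour.rm_anova_2x2(y)
        for name in ("A", "B", "AxB"):
            assert res[name].F == pytest.approx(0.0)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(12, 2, 2))
        res = behaviour.rm_anova_2x2(y)
        df = pd.DataFrame([
            {"subject": i, "A": a, "B": b, "y": y[i, a, b]}
            for i in range(12) for a in range(2) for b in range(2)])
        table = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                            subject="subject", detailed=True)
        for name, row in (("A", "A"), ("B", "B"), ("AxB", "A * B")):
            f_pg = float(table.loc[table["Source"] == row, "F"].iloc[0])
            assert res[name].F == pytest.approx(f_pg, rel=1e-6)

    def test_phase_effect_power_at_study_size(self, rng):
        """A response-proportion gap like the generative one (m tuned up)
        is detected by the phase main effect most of the time at n = 20."""
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            base = r.normal(0.5, 0.02, size=(20, 1, 1))
            y = base + r.normal(0, 0.02, size=(20, 2, 2))
            y[:, 0, :] += 0.02           # async-bin advantage
            res = behaviour.rm_anova_2x2(y)
            hits += res["A"].p < 0.05
        assert hits / 40 > 0.8


class TestAnovaKx2:
    def test_gg_epsilon_bounds_and_structure(self, rng):
        y = rng.normal(size=(20, 5, 2))
        res = behaviour.rm_anova_kx2(y)
        eps = res["AxB"].gg_epsilon
        assert 0.25 <= eps <= 1.0
        assert res["AxB"].df1 == pytest.approx(eps * 4)
        assert res["AxB"].df2 == pytest.approx(eps * 4 * 19)
        assert res["B"].df1 == 1 and res["B"].df2 == 19

    def test_spherical_data_epsilon_near_one(self, rng):
        eps = []
        for _ in range(50):
            y = rng.normal(size=(60, 5))
            eps.append(behaviour._gg_epsilon(y))
        assert np.mean(eps) > 0.9

    def test_rank_one_covariance_hits_lower_bound(self, rng):
        subj = rng.normal(size=(30, 1))
        weights = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        y = subj * weights[None, :] + 1e-9 * rng.normal(size=(30, 5))
        assert behaviour._gg_epsilon(y) == pytest.approx(0.25, abs=1e-3)

    def test_epsilon_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(15, 5)) + rng.normal(size=(15, 1))
        y[:, 0] *= 2.5
        ours = behaviour._gg_epsilon(y)
        theirs = float(pg.epsilon(pd.DataFrame(y), correction="gg"))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_main_effects_match_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(10, 5, 2)) + rng.normal(size=(10, 1, 1))
        res = behaviour.rm_anova_kx2(y)
        df = pd.DataFrame([
            {"subject": i, "A": a, "B": b, "y": y[i, a, b]}
            for i in range(10) for a in range(5) for b in range(2)])
        table = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                            subject="subject")
        for name, row in (("A", "A"), ("B", "B"), ("AxB", "A * B")):
            f_pg = float(table.loc[table["Source"] == row, "F"].iloc[0])
            assert res[name].F == pytest.approx(f_pg, rel=1e-6)


class TestEffectSizes:
    def test_identical_conditions_give_zero(self, rng):
        a = rng.normal(size=20)
        assert behaviour.hedges_g_av(a, a.copy()) == 0.0

    def test_unit_effect_limit(self, rng):
        a = rng.normal(size=5000)
        b = a - a.std(ddof=1)
        g = behaviour.hedges_g_av(a, b)
        assert g == pytest.approx(1.0, abs=0.01)

    def test_correction_factor_at_df_19(self):
        assert 1 - 3 / (4 * 19 - 1) == pytest.approx(0.96)
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = a + 1.0
        d_av = (b - a).mean() / (0.5 * (a.std(ddof=1) + b.std(ddof=1)))
        assert behaviour.hedges_g_av(b, a) == pytest.approx(0.96 * d_av)


class TestWithinSubjectSE:
    def test_pure_offsets_give_zero(self):
        base = np.array([0.4, 0.5, 0.6, 0.7])
        y = base[None, :] + np.arange(8)[:, None]
        se = behaviour.within_subject_se(y)
        np.testing.assert_allclose(se, 0.0, atol=1e-12)

    def test_no_offsets_matches_raw_se_times_correction(self, rng):
        y = rng.normal(size=(30, 4))
        se = behaviour.within_subject_se(y)
        raw = (y - y.mean(axis=1, keepdims=True) + y.mean()).std(
            axis=0, ddof=1) / np.sqrt(30)
        np.testing.assert_allclose(se, raw * np.sqrt(4 / 3))

    def test_k2_variance_correction_factor_is_two(self, rng):
        y = rng.normal(size=(25, 2))
        se = behaviour.within_subject_se(y)
        norm = y - y.mean(axis=1, keepdims=True) + y.mean()
        naive = norm.std(axis=0, ddof=1) / np.sqrt(25)
        np.testing.assert_allclose((se / naive) ** 2, 2.0)


class TestBehaviouralSummary:
    def test_validity_effect_direction_recovered(self):
        """The 60 ms cue-validity RT shift is recovered in direction in
        essentially every simulated study."""
        cfg = SimConfig(n_participants=12,
                        n_trials_by_cell=(60, 20, 12, 4),
                        epoch_span=(-0.02, 0.02), blink_rate=0.0,
                        saccade_rate=0.0, erp_amp=0.0)
        import dataclasses
        wins = 0
        for study_seed in range(10):
            c = dataclasses.replace(cfg, seed=100 + study_seed)
            tables = [synth.generate_session(c, pid, channels=("O1",),
                                             include_eog=False).trials
                      for pid in range(c.n_participants)]
            summary = behaviour.behavioural_summary(tables)
            test = behaviour.paired_t(summary["rt_valid"],
                                      summary["rt_invalid"])
            wins += (test.t < 0) and (test.p < 0.05)
        assert wins >= 9

    def test_staircase_keeps_hit_rate_near_half(self):
        cfg = SimConfig(n_participants=6, epoch_span=(-0.02, 0.02),
                        blink_rate=0.0, saccade_rate=0.0, erp_amp=0.0,
                        seed=55)
        tables = [synth.generate_session(cfg, pid, channels=("O1",),
                                         include_eog=False).trials
                  for pid in range(6)]
        summary = behaviour.behavioural_summary(tables)
        assert abs(summary["hit_rate"].mean() - 0.5) < 0.03
        assert abs(summary["fa_rate"].mean() - 0.043) < 0.03
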
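"""Circular statistics: first/second-order means, Moore's paired test,
Rayleigh uniformity, bisection binning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphaphase import circstats
from alphaphase.circstats import CircMean


class TestCircMean:
    def test_identical_angles(self):
        cm = circstats.circ_mean([0.0, 0.0])
        assert cm.angle == pytest.approx(0.0)
        assert cm.r == pytest.approx(1.0)

    def test_antipodal_angles_cancel(self):
        cm = circstats.circ_mean([0.0, np.pi])
        assert not cm.defined
        assert cm.r == 0.0

    def test_three_angle_example_matches_vector_sum(self):
        angles = np.deg2rad([10.0, 20.0, 30.0])
        cm = circstats.circ_mean(angles)
        assert math.degrees(cm.angle) == pytest.approx(20.0)
        assert cm.r == pytest.approx(math.cos(math.radians(10)) * 2 / 3 + 1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circstats.circ_mean([])


class TestSecondOrderMean:
    def test_equal_angles_full_length(self):
        means = [CircMean(1.0, 1.0, 10) for _ in range(5)]
        som = circstats.second_order_mean(means)
        assert som.angle == pytest.approx(1.0)
        assert som.r == pytest.approx(1.0)

    def test_opposite_equal_vectors_cancel(self):
        som = circstats.second_order_mean([CircMean(0.0, 0.5, 5),
                                           CircMean(np.pi, 0.5, 5)])
        assert not som.defined

    def test_equals_cartesian_mean_on_random_inputs(self, rng):
        """Brute-force oracle: the second-order mean is the plain Cartesian
        mean of (r cos, r sin) vectors."""
        for _ in range(200):
            n = rng.integers(1, 12)
            ang = rng.uniform(-np.pi, np.pi, n)
            r = rng.uniform(0, 1, n)
            means = [CircMean(a, rr, 1) for a, rr in zip(ang, r)]
            som = circstats.second_order_mean(means)
            vx, vy = (r * np.cos(ang)).mean(), (r * np.sin(ang)).mean()
            assert som.r == pytest.approx(np.hypot(vx, vy), abs=1e-12)
            if som.defined:
                assert som.angle == pytest.approx(np.arctan2(vy, vx),
                                                  abs=1e-12)


class TestMoorePairedTest:
    def test_identical_conditions_give_p_near_one(self):
        v = np.random.default_rng(0).normal(size=(12, 2))
        res = circstats.moore_paired_test(v, v.copy(), n_perm=999, seed=0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_aligned_distinct_lengths_closed_form(self):
        """All 19 difference vectors at one angle: R' = (1+...+19)/19^1.5."""
        n = 19
        lengths = np.arange(1, n + 1) / n
        va = np.stack([lengths, np.zeros(n)], axis=1)
        vb = np.zeros((n, 2))
        res = circstats.moore_paired_test(va, vb, n_perm=9999, seed=0)
        assert res.statistic == pytest.approx(190.0 / 19 ** 1.5, abs=1e-12)
        assert res.p < 0.01
        assert res.p_asymptotic < 0.01

    def test_rotation_invariance(self, rng):
        ang = rng.uniform(-np.pi, np.pi, 15)
        r = rng.uniform(0.1, 1.0, 15)
        va = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        vb = 0.3 * rng.normal(size=(15, 2))
        res = circstats.moore_paired_test(va, vb, n_perm=999, seed=4)
        delta = 1.234
        rot = np.array([[np.cos(delta), -np.sin(delta)],
                        [np.sin(delta), np.cos(delta)]])
        res_rot = circstats.moore_paired_test(va @ rot.T, vb @ rot.T,
                                              n_perm=999, seed=4)
        assert res_rot.statistic == pytest.approx(res.statistic, abs=1e-12)
        assert res_rot.p == res.p

    def test_permutation_decisions_track_asymptotic_form(self, rng):
        """On random small samples the permutation p and the exact
        large-sample tail give the same alpha=.05 decision almost always."""
        disagree = 0
        total = 200
        for i in range(total):
            n = int(rng.integers(8, 21))
            scale = rng.uniform(0.05, 0.5)
            va = rng.normal(scale=scale, size=(n, 2)) + rng.normal(0, 0.2, 2)
            vb = rng.normal(scale=scale, size=(n, 2))
            res = circstats.moore_paired_test(va, vb, n_perm=999, seed=i)
            if (res.p <= 0.05) != (res.p_asymptotic <= 0.05):
                disagree += 1
        assert disagree / total < 0.05

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        sims = 400
        for i in range(sims):
            va = rng.normal(size=(14, 2)) * 0.3
            vb = rng.normal(size=(14, 2)) * 0.3
            res = circstats.moore_paired_test(va, vb, n_perm=199, seed=i)
            rejections += res.p <= 0.05
        assert 0.02 < rejections / sims < 0.08

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            circstats.moore_paired_test(np.zeros((1, 2)), np.zeros((1, 2)))


class TestRayleigh:
    def test_identical_angles_are_maximally_concentrated(self):
        rbar, p = circstats.rayleigh_test(np.full(100, 0.7))
        assert rbar == pytest.approx(1.0)
        assert p < 1e-20

    def test_uniform_rejection_rate_near_alpha(self, rng):
        n, reps = 640, 4000
        phases = rng.uniform(0, 2 * np.pi, size=(reps, n))
        z = np.abs(np.exp(1j * phases).mean(axis=1))
        p = circstats.rayleigh_p_from_rbar(z, n)
        assert abs((p < 0.05).mean() - 0.05) < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            circstats.rayleigh_test([0.1, 0.2, 0.3])


class TestBisection:
    def test_opposite_means(self):
        b = circstats.make_bisection(CircMean(0.0, 1.0, 10),
                                     CircMean(np.pi, 1.0, 10))
        degs = sorted(round(math.degrees(x) % 360, 6) for x in b.boundaries)
        assert degs == [90.0, 270.0]

    def test_wraparound_means(self):
        b = circstats.make_bisection(CircMean(np.deg2rad(350), 1.0, 10),
                                     CircMean(np.deg2rad(10), 1.0, 10))
        degs = sorted(round(math.degrees(x) % 360, 6) for x in b.boundaries)
        assert degs == [0.0, 180.0]

    def test_boundaries_are_antipodal_to_machine_precision(self, rng):
        for _ in range(100):
            a, bb = rng.uniform(-np.pi, np.pi, 2)
            if abs(circstats.wrap_angle(a - bb)) < 1e-6:
                continue
            bn = circstats.make_bisection(CircMean(a, 0.7, 5),
                                          CircMean(bb, 0.4, 5))
            d = circstats.wrap_angle(bn.boundaries[0] - bn.boundaries[1])
            assert abs(abs(d) - np.pi) < 1e-12

    def test_each_bin_contains_its_own_mean(self, rng):
        for _ in range(100):
            a, bb = rng.uniform(-np.pi, np.pi, 2)
            if abs(circstats.wrap_angle(a - bb)) < 1e-6:
                continue
            bn = circstats.make_bisection(CircMean(a, 1.0, 5),
                                          CircMean(bb, 1.0, 5))
            assert circstats.classify_phase(a, bn)
            assert not circstats.classify_phase(bb, bn)

    def test_identical_means_rejected(self):
        with pytest.raises(ValueError):
            circstats.make_bisection(CircMean(1.0, 0.5, 5),
                                     CircMean(1.0, 0.7, 5))

    def test_boundary_assignment_is_deterministic(self):
        bn = circstats.make_bisection(CircMean(0.0, 1.0, 5),
                                      CircMean(np.pi, 1.0, 5))
        on_boundary = circstats.classify_phase(bn.boundary, bn)
        assert on_boundary       # half-open rule: boundary starts bin A


class TestPolarity:
    def test_trough_is_negative_peak_is_positive(self):
        assert circstats.classify_polarity(np.deg2rad(270.0))
        assert not circstats.classify_polarity(np.deg2rad(90.0))

    def test_boundary_rule(self):
        # (180, 360] convention: 180 positive, 0 (== 360) negative
        assert not circstats.classify_polarity(np.pi)
        assert circstats.classify_polarity(0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=30),
       st.floats(-np.pi, np.pi))
def test_rotation_shifts_mean_and_preserves_resultant(angles, delta):
    cm = circstats.circ_mean(angles)
    cm_rot = circstats.circ_mean(np.asarray(angles) + delta)
    assert cm_rot.r == pytest.approx(cm.r, abs=1e-9)
    if cm.defined and cm.r > 1e-6:
        d = circstats.wrap_angle(cm_rot.angle - cm.angle - delta)
        assert abs(d) < 1e-6
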
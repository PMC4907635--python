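"""First- and second-order circular statistics.

Angles are radians throughout and reported in (-pi, pi].  The phase
convention downstream is: 90 deg = signal (cosine) peak, 270 deg = trough,
so "negative polarity" means the waveform is in its negative half-cycle.

The second-order machinery treats each unit's (mean angle, resultant
length) as a Cartesian vector of that length, which is what both the
second-order mean and Moore's nonparametric paired test operate on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out


@dataclass(frozen=True)
class CircMean:
    """A first- or second-order circular mean.

    ``defined`` is False when the resultant length vanishes, in which case
    ``angle`` is meaningless and set to nan.
    """

    angle: float
    r: float
    n: int
    defined: bool = True

    @property
    def vector(self):
        return np.array([self.r * math.cos(self.angle),
                         self.r * math.sin(self.angle)])


_EPS_R = 1e-12


def circ_mean(angles, weights=None) -> CircMean:
    """Vector-average a set of angles (optionally weighted)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circ_mean needs at least one angle")
    if weights is None:
        c = np.cos(angles).mean()
        s = np.sin(angles).mean()
    else:
        w = np.asarray(weights, dtype=float)
        c = float(np.sum(w * np.cos(angles)) / np.sum(w))
        s = float(np.sum(w * np.sin(angles)) / np.sum(w))
    r = float(np.hypot(c, s))
    if r < _EPS_R:
        return CircMean(angle=float("nan"), r=0.0, n=angles.size, defined=False)
    return CircMean(angle=float(math.atan2(s, c)), r=r, n=angles.size)


def circ_mean_arrays(angles, axis=-1):
    """Vectorized circular mean: returns (angle, r) arrays along ``axis``."""
    z = np.exp(1j * np.asarray(angles))
    m = z.mean(axis=axis)
    return np.angle(m), np.abs(m)


def second_order_mean(means) -> CircMean:
    """Vector-average first-order means, each weighted by its resultant.

    Equivalent to the Cartesian mean of the vectors (r cos(theta),
    r sin(theta)); units with r = 0 contribute a null vector.
    """
    vecs = np.array([m.vector for m in means], dtype=float)
    if vecs.size == 0:
        raise ValueError("second_order_mean needs at least one mean")
    c, s = vecs.mean(axis=0)
    r = float(np.hypot(c, s))
    if r < _EPS_R:
        return CircMean(angle=float("nan"), r=0.0, n=len(means), defined=False)
    return CircMean(angle=float(math.atan2(s, c)), r=r, n=len(means))


# ---------------------------------------------------------------------------
# Moore's second-order paired test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MooreResult:
    statistic: float        # R'
    p: float                # permutation p (sign-flip null)
    p_asymptotic: float     # large-sample approximation, consistency check
    n: int
    n_perm: int


def moore_rank_vectors(dx, dy, rng=None):
    """Rank paired difference vectors by length and return rank-weighted
    unit-vector components.

    dx, dy : (..., n) Cartesian components of per-unit difference vectors.
    Zero-length vectors get the lowest ranks; exact ties are broken by a
    seeded random perturbation of the ordering, per nonparametric convention.

    Returns (zx, zy) with shape (..., n): rank_i * (cos, sin) of each
    difference-vector angle (zeros for zero-length vectors).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    lengths = np.hypot(dx, dy)
    if rng is None:
        rng = np.random.default_rng(0)
    # ordinal ranks with random tie-break: perturb only tied values
    jitter = rng.random(lengths.shape)
    order = np.lexsort((jitter, lengths), axis=-1)
    ranks = np.empty_like(lengths)
    np.put_along_axis(ranks, order,
                      np.broadcast_to(np.arange(1.0, lengths.shape[-1] + 1),
                                      lengths.shape).copy(), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(lengths > 0, dx / np.where(lengths > 0, lengths, 1.0), 0.0)
        uy = np.where(lengths > 0, dy / np.where(lengths > 0, lengths, 1.0), 0.0)
    return ranks * ux, ranks * uy


def moore_statistic(dx, dy, rng=None):
    """Moore's R' for paired difference vectors (last axis = units)."""
    zx, zy = moore_rank_vectors(dx, dy, rng=rng)
    n = dx.shape[-1] if hasattr(dx, "shape") else len(dx)
    return np.hypot(zx.sum(axis=-1), zy.sum(axis=-1)) / n ** 1.5


def moore_asymptotic_p(r_prime, n):
    """Large-sample tail of R' under the sign-flip null.

    Under independent sign flips E|sum rank_i e^{i theta_i}|^2 = sum rank^2,
    and the CLT makes the resultant complex-Gaussian, so
    P(R' > x) ~ exp(-x^2 n^3 / sum(rank^2)).
    """
    sumsq = n * (n + 1) * (2 * n + 1) / 6.0
    return float(np.exp(-np.asarray(r_prime) ** 2 * n ** 3 / sumsq))


def moore_paired_test(vectors_a, vectors_b, n_perm: int = 10_000,
                      seed: int = 0) -> MooreResult:
    """Second-order nonparametric paired test on per-unit mean vectors.

    Parameters
    ----------
    vectors_a, vectors_b : (n, 2) arrays or sequences of CircMean
        Paired condition mean-vectors, one row per participant.
    n_perm : int
        Random sign-flip permutations for the p value (condition labels are
        swapped within participant, negating the difference vector; ranks
        are invariant under the flip).
    """
    va = _as_vectors(vectors_a)
    vb = _as_vectors(vectors_b)
    if va.shape != vb.shape or va.ndim != 2 or va.shape[1] != 2:
        raise ValueError("paired (n, 2) vector arrays required")
    n = va.shape[0]
    if n < 2:
        raise ValueError("need at least two paired units")
    rng = np.random.default_rng(seed)
    d = va - vb
    zx, zy = moore_rank_vectors(d[:, 0], d[:, 1], rng=rng)
    obs = float(np.hypot(zx.sum(), zy.sum()) / n ** 1.5)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm = np.hypot(signs @ zx, signs @ zy) / n ** 1.5
    p = (1.0 + np.count_nonzero(perm >= obs)) / (n_perm + 1.0)
    return MooreResult(statistic=obs, p=float(p),
                       p_asymptotic=moore_asymptotic_p(obs, n),
                       n=n, n_perm=n_perm)


def _as_vectors(v):
    if len(v) and isinstance(v[0], CircMean):
        return np.array([m.vector for m in v], dtype=float)
    return np.asarray(v, dtype=float)


# ---------------------------------------------------------------------------
# Rayleigh uniformity test
# ---------------------------------------------------------------------------

def rayleigh_p_from_rbar(rbar, n):
    """Rayleigh p with the standard finite-n correction (Zar)."""
    rbar = np.asarray(rbar, dtype=float)
    z = n * rbar ** 2
    p = np.exp(-z) * (1 + (2 * z - z ** 2) / (4 * n)
                      - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4)
                      / (288 * n ** 2))
    return np.clip(p, 0.0, 1.0)


def rayleigh_test(angles):
    """Test circular uniformity; returns (rbar, p)."""
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n < 5:
        raise ValueError("Rayleigh test needs n >= 5")
    rbar = float(np.abs(np.exp(1j * angles).mean()))
    return rbar, float(rayleigh_p_from_rbar(rbar, n))


# ---------------------------------------------------------------------------
# Phase binning by circular bisection, and polarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseBinning:
    """Two half-circle bins whose boundaries bisect two condition means.

    ``boundary`` is one of the two antipodal boundary angles; membership of
    bin A (the bin containing ``mean_a``) uses the half-open rule
    d = (phase - boundary) mod 2pi, bin A iff d in [0, pi) (after orienting
    the boundary so that mean_a falls in that arc).
    """

    boundary: float      # radians; the other boundary is boundary + pi
    mean_a: float
    mean_b: float

    @property
    def boundaries(self):
        return (wrap_angle(self.boundary).item(),
                wrap_angle(self.boundary + np.pi).item())


def make_bisection(mean_a: CircMean, mean_b: CircMean) -> PhaseBinning:
    """Boundaries at the midpoints of both arcs between the two means."""
    if not (mean_a.defined and mean_b.defined):
        raise ValueError("both means must be defined (r > 0)")
    delta = wrap_angle(mean_b.angle - mean_a.angle).item()
    if abs(delta) < 1e-12:
        raise ValueError("identical means admit no bisection")
    mid = mean_a.angle + delta / 2.0          # midpoint of the short arc
    # orient so that mean_a lies in [boundary, boundary + pi)
    boundary = mid if _in_arc(mean_a.angle, mid) else mid + np.pi
    return PhaseBinning(boundary=wrap_angle(boundary).item(),
                        mean_a=mean_a.angle, mean_b=mean_b.angle)


def _in_arc(phase, boundary):
    return float((phase - boundary) % (2 * np.pi)) < np.pi


def classify_phase(phases, binning: PhaseBinning):
    """True where a phase falls in bin A (the ``mean_a`` bin).

    A phase exactly on a boundary belongs to the arc that starts there
    (half-open rule), so ``binning.boundary`` itself is in bin A.
    """
    d = (np.asarray(phases, dtype=float) - binning.boundary) % (2 * np.pi)
    return d < np.pi


def classify_polarity(phases):
    """True where the waveform is in its negative half-cycle.

    Under the 270 deg = trough convention the negative half-cycle is the arc
    (180, 360] degrees; the boundary rule puts 180 deg in the positive bin
    and 0 (== 360) deg in the negative bin.
    """
    d = np.asarray(phases, dtype=float) % (2 * np.pi)
    return (d > np.pi) | (d == 0.0)
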
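"""Cluster-based permutation inference, the t-max check, and the
uniformity Monte Carlo.

All nulls are within-participant condition-label exchanges (sign flips of
paired differences), with the permutation schedule shared across electrodes
or time samples so that entry-level and cluster-level decisions use the
same null.  Cluster mass is the sum of member statistics.  Reported
Monte-Carlo p values use the (1 + exceedances) / (1 + n_perm) estimator, so
with n_perm = 199 the attained level of "p <= .05" is exactly 10/200.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circstats import moore_rank_vectors, rayleigh_p_from_rbar


@dataclass(frozen=True)
class Cluster:
    members: tuple          # electrode labels or time-sample indices
    mass: float             # summed statistic
    p: float                # Monte-Carlo p against the max-mass null
    sign: int = 1           # +1 / -1 for signed (t) clusters


@dataclass
class ClusterResult:
    clusters: list = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0
    entry_alpha: float = 0.05

    @property
    def mc_p(self) -> float:
        """Smallest cluster p (1.0 when no cluster formed)."""
        return min((c.p for c in self.clusters), default=1.0)

    @property
    def significant(self):
        return [c for c in self.clusters if c.p <= 0.05]

    def to_dict(self):
        return {"n_perm": self.n_perm, "seed": self.seed,
                "entry_alpha": self.entry_alpha, "mc_p": self.mc_p,
                "clusters": [{"members": list(c.members), "mass": c.mass,
                              "p": c.p, "sign": c.sign}
                             for c in self.clusters]}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sign_flips(n_perm, n, rng):
    return (rng.integers(0, 2, size=(n_perm, n)) * 2 - 1).astype(np.float64)


def paired_t_flipped(d, signs):
    """Paired t for every sign-flip row.

    d : (n, k) participant differences; signs : (P, n).
    Returns (P, k) t values (row of +1s gives the observed t).
    """
    n = d.shape[0]
    mean = signs @ d / n
    ssq = np.sum(d ** 2, axis=0) / n          # invariant under flips
    var = (ssq - mean ** 2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def connected_components(members, adjacency):
    """Partition ``members`` into components of the ``adjacency`` graph."""
    members = set(members)
    comps = []
    while members:
        seed_node = members.pop()
        comp = {seed_node}
        stack = [seed_node]
        while stack:
            node = stack.pop()
            for nb in adjacency.get(node, ()):
                if nb in members:
                    members.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def _contiguous_runs(mask):
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False]))
                                   .astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def max_run_mass(stats_rows, supra_rows):
    """Max contiguous-run mass per row of (rows, T) stat/mask arrays."""
    out = np.zeros(stats_rows.shape[0])
    csum = np.cumsum(np.where(supra_rows, stats_rows, 0.0), axis=1)
    for i in range(stats_rows.shape[0]):
        best = 0.0
        for a, b in _contiguous_runs(supra_rows[i]):
            mass = csum[i, b - 1] - (csum[i, a - 1] if a > 0 else 0.0)
            # runs are separated by sub-threshold samples, whose contribution
            # to csum is zero, so the difference is the run mass exactly
            if mass > best:
                best = mass
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# scalar (electrode-space) cluster permutation
# ---------------------------------------------------------------------------

def cluster_perm_scalar(values_a, values_b, labels, adjacency,
                        n_perm=10_000, seed=0, entry_alpha=0.05
                        ) -> ClusterResult:
    """Paired-t cluster permutation over electrodes.

    values_a, values_b : (n_participants, n_electrodes) condition means.
    labels : electrode names aligned with the columns.
    adjacency : dict label -> neighbour set.  With an empty adjacency every
    electrode is its own cluster and the test reduces to t-max over
    electrodes.

    Positive and negative clusters are formed separately (same-sign
    supra-threshold members); both are measured against the permutation
    null of the maximum absolute cluster mass.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("paired (n, k) arrays required")
    n, k = a.shape
    if n < 2:
        raise ValueError("need at least two participants")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    d = a - b
    tcrit = stats.t.ppf(1 - entry_alpha / 2, df=n - 1)

    signs = np.vstack([np.ones((1, n)), _sign_flips(n_perm, n, rng)])
    tvals = paired_t_flipped(d, signs)          # (P+1, k)

    def clusters_of(trow):
        out = []
        for sign in (1, -1):
            supra = [labels[j] for j in range(k)
                     if sign * trow[j] > tcrit]
            for comp in connected_components(supra, adjacency):
                idx = [labels.index(ch) for ch in comp]
                out.append((tuple(sorted(comp)), float(trow[idx].sum()), sign))
        return out

    observed = clusters_of(tvals[0])
    null_max = np.zeros(n_perm)
    for p in range(1, n_perm + 1):
        cl = clusters_of(tvals[p])
        null_max[p - 1] = max((abs(mass) for _, mass, _ in cl), default=0.0)

    result = ClusterResult(n_perm=n_perm, seed=seed, entry_alpha=entry_alpha)
    for members, mass, sign in observed:
        pval = (1.0 + np.count_nonzero(null_max >= abs(mass))) / (n_perm + 1.0)
        result.clusters.append(Cluster(members=members, mass=mass,
                                       p=float(pval), sign=sign))
    result.clusters.sort(key=lambda c: c.p)
    return result


# ---------------------------------------------------------------------------
# circular (time-course) cluster permutation with Moore's R'
# ---------------------------------------------------------------------------

def moore_stats_flipped(dx, dy, signs, rng):
    """Moore R' per time sample for every sign-flip row.

    dx, dy : (n, T) difference-vector components per participant and time.
    signs : (P, n) flip rows (+1 row first for the observed statistic).
    Ranks are computed once per time sample (flip-invariant).
    """
    n, T = dx.shape
    zx, zy = moore_rank_vectors(dx.T, dy.T, rng=rng)    # (T, n)
    sx = signs @ zx.T                                     # (P, T)
    sy = signs @ zy.T
    return np.hypot(sx, sy) / n ** 1.5


def cluster_perm_circular(vectors_a, vectors_b, n_perm=10_000, seed=0,
                          entry_alpha=0.05) -> ClusterResult:
    """Moore-R' cluster permutation over contiguous time samples.

    vectors_a, vectors_b : (n_participants, T, 2) per-time-sample condition
    mean-vectors.  The same within-participant condition swap applies to
    every time sample of a permutation; entry-level p values are rank-based
    within the shared permutation distribution at each sample, so entry and
    cluster nulls are consistent.
    """
    va = np.asarray(vectors_a, dtype=float)
    vb = np.asarray(vectors_b, dtype=float)
    if va.shape != vb.shape or va.ndim != 3 or va.shape[2] != 2:
        raise ValueError("paired (n, T, 2) arrays required")
    n, T, _ = va.shape
    rng = np.random.default_rng(seed)
    d = va - vb
    signs = np.vstack([np.ones((1, n)), _sign_flips(n_perm, n, rng)])
    rprime = moore_stats_flipped(d[..., 0], d[..., 1], signs, rng)  # (P+1, T)

    # rank-based entry p of every row within the full permutation column
    order = np.argsort(-rprime, kind="stable", axis=0)
    ranks = np.empty_like(order)
    put = np.broadcast_to(np.arange(1, n_perm + 2)[:, None], order.shape)
    np.put_along_axis(ranks, order, put, axis=0)
    entry_p = ranks / (n_perm + 1.0)
    supra = entry_p <= entry_alpha

    null_max = max_run_mass(rprime[1:], supra[1:])
    result = ClusterResult(n_perm=n_perm, seed=seed, entry_alpha=entry_alpha)
    for a, b in _contiguous_runs(supra[0]):
        mass = float(rprime[0, a:b].sum())
        pval = (1.0 + np.count_nonzero(null_max >= mass)) / (n_perm + 1.0)
        result.clusters.append(Cluster(members=tuple(range(a, b)), mass=mass,
                                       p=float(pval)))
    result.clusters.sort(key=lambda c: c.p)
    return result


def cluster_perm_spatiotemporal(vectors_a, vectors_b, labels, adjacency,
                                n_perm=1000, seed=0, entry_alpha=0.05
                                ) -> ClusterResult:
    """Moore-R' cluster permutation over the electrode x time grid.

    vectors_a, vectors_b : (n, E, T, 2) per-participant condition
    mean-vectors.  Grid points are adjacent when they share an electrode
    and are consecutive in time, or share a time sample at neighbouring
    electrodes.  Cluster members are (electrode label, time index) pairs.
    """
    va = np.asarray(vectors_a, dtype=float)
    vb = np.asarray(vectors_b, dtype=float)
    n, E, T, _ = va.shape
    labels = list(labels)
    rng = np.random.default_rng(seed)
    d = (va - vb).reshape(n, E * T, 2)
    signs = np.vstack([np.ones((1, n)), _sign_flips(n_perm, n, rng)])
    rprime = moore_stats_flipped(d[..., 0], d[..., 1], signs, rng)
    order = np.argsort(-rprime, kind="stable", axis=0)
    ranks = np.empty_like(order)
    put = np.broadcast_to(np.arange(1, n_perm + 2)[:, None], order.shape)
    np.put_along_axis(ranks, order, put, axis=0)
    supra = (ranks / (n_perm + 1.0)) <= entry_alpha        # (P+1, E*T)

    neigh_idx = {i: [labels.index(nb) for nb in adjacency.get(lab, ())
                     if nb in labels]
                 for i, lab in enumerate(labels)}

    def grid_clusters(mask_flat, stat_flat):
        mask = mask_flat.reshape(E, T)
        seen = np.zeros((E, T), dtype=bool)
        out = []
        for e0, t0 in zip(*np.nonzero(mask)):
            if seen[e0, t0]:
                continue
            comp = []
            stack = [(e0, t0)]
            seen[e0, t0] = True
            while stack:
                e, t = stack.pop()
                comp.append((e, t))
                cands = [(e, t - 1), (e, t + 1)]
                cands += [(ne, t) for ne in neigh_idx[e]]
                for ne, nt in cands:
                    if 0 <= nt < T and mask[ne, nt] and not seen[ne, nt]:
                        seen[ne, nt] = True
                        stack.append((ne, nt))
            mass = float(sum(stat_flat[e * T + t] for e, t in comp))
            out.append((comp, mass))
        return out

    null_max = np.zeros(n_perm)
    for p in range(1, n_perm + 1):
        cl = grid_clusters(supra[p], rprime[p])
        null_max[p - 1] = max((mass for _, mass in cl), default=0.0)

    result = ClusterResult(n_perm=n_perm, seed=seed, entry_alpha=entry_alpha)
    for comp, mass in grid_clusters(supra[0], rprime[0]):
        pval = (1.0 + np.count_nonzero(null_max >= mass)) / (n_perm + 1.0)
        members = tuple(sorted((labels[e], t) for e, t in comp))
        result.clusters.append(Cluster(members=members, mass=mass,
                                       p=float(pval)))
    result.clusters.sort(key=lambda c: c.p)
    return result


# ---------------------------------------------------------------------------
# t-max ERP check
# ---------------------------------------------------------------------------

def tmax_erp_test(erp_a, erp_b, n_perm=10_000, seed=0):
    """Permutation t-max over time samples for paired ERPs.

    erp_a, erp_b : (n_participants, T).  Returns (t_max, p) where t_max is
    the maximum absolute paired t over samples and p the exceedance
    proportion of the sign-flip null of the same maximum.
    """
    a = np.asarray(erp_a, dtype=float)
    b = np.asarray(erp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("paired (n, T) arrays required")
    n = a.shape[0]
    d = a - b
    if not np.any(d):
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    signs = np.vstack([np.ones((1, n)), _sign_flips(n_perm, n, rng)])
    tvals = np.abs(paired_t_flipped(d, signs)).max(axis=1)
    t_obs = float(tvals[0])
    p = (1.0 + np.count_nonzero(tvals[1:] >= t_obs)) / (n_perm + 1.0)
    return t_obs, float(p)


# ---------------------------------------------------------------------------
# Rayleigh uniformity Monte Carlo
# ---------------------------------------------------------------------------

def uniformity_mc(n_participants=20, n_electrodes=5, n_trials=640,
                  alpha=0.05, reps=100_000, k_deviations=4,
                  j_participants=2, seed=0, chunk=100):
    """Probability of chance Rayleigh "non-uniformity" findings.

    Draws uniform phases for every participant x electrode cell
    (``n_trials`` each), Rayleigh-tests each cell, and estimates

    * P(at least ``k_deviations`` of the n_participants*n_electrodes cells
      significant at uncorrected ``alpha``), and
    * P(at least ``j_participants`` participants with >= 1 significant
      electrode).

    ``n_trials`` may be a scalar or an (n_participants, n_electrodes) array
    of per-cell counts.  Returns a dict with both probabilities and the
    Monte-Carlo standard error of the first.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    rng = np.random.default_rng(seed)
    cells = n_participants * n_electrodes
    counts = np.broadcast_to(np.asarray(n_trials),
                             (n_participants, n_electrodes)).reshape(-1)
    if alpha <= 0:
        return {"p_k_deviations": 0.0, "p_j_participants": 0.0,
                "se": 0.0, "reps": reps}
    hit_k = 0
    hit_j = 0
    done = 0
    nmax = int(counts.max())
    while done < reps:
        r = min(chunk, reps - done)
        phases = rng.uniform(0.0, 2 * np.pi,
                             size=(r, cells, nmax)).astype(np.float32)
        c = np.cos(phases)
        s = np.sin(phases)
        if np.all(counts == counts[0]):
            C = c.sum(axis=-1)
            S = s.sum(axis=-1)
        else:
            # unequal per-cell trial counts: partial sums along the trial axis
            idx = counts - 1
            C = np.take_along_axis(np.cumsum(c, axis=-1),
                                   idx[None, :, None], axis=-1)[..., 0]
            S = np.take_along_axis(np.cumsum(s, axis=-1),
                                   idx[None, :, None], axis=-1)[..., 0]
        rbar = np.hypot(C, S) / counts[None, :]
        p = rayleigh_p_from_rbar(rbar.astype(np.float64), counts[None, :])
        sig = p < alpha
        hit_k += int(np.count_nonzero(sig.sum(axis=1) >= k_deviations))
        part_any = sig.reshape(r, n_participants, n_electrodes).any(axis=2)
        hit_j += int(np.count_nonzero(part_any.sum(axis=1) >= j_participants))
        done += r
    p_k = hit_k / reps
    return {"p_k_deviations": p_k,
            "p_j_participants": hit_j / reps,
            "se": float(np.sqrt(p_k * (1 - p_k) / reps)),
            "reps": reps}
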
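"""Behavioural metrics and small repeated-measures statistics.

Signal-detection metrics, paired t with Hedges-corrected d_av, fully
within-subject 2x2 and kx2 ANOVAs (Greenhouse-Geisser corrected where a
factor has more than two levels), and Cousineau-Morey within-subject
standard errors.  The ANOVAs are written from the closed-form sums of
squares; tests cross-check them against an independent implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# signal detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDTResult:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    n_signal: int
    n_noise: int


def _adjusted_z(rate, n):
    """Normal quantile with the 1/(2N) adjustment for 0 or 1 rates."""
    if rate <= 0.0:
        rate = 1.0 / (2 * n)
    elif rate >= 1.0:
        rate = 1.0 - 1.0 / (2 * n)
    return float(stats.norm.ppf(rate))


def sdt_metrics(trials: pd.DataFrame) -> SDTResult:
    """d-prime and criterion from a trial table.

    Hits: asynchronous trials judged asynchronous.  False alarms:
    simultaneous trials judged asynchronous.
    """
    async_tr = trials[trials["synchrony"] == "async"]
    simul_tr = trials[trials["synchrony"] == "simul"]
    if len(async_tr) == 0 or len(simul_tr) == 0:
        raise ValueError("both trial classes must be present")
    hit = float((async_tr["response"] == "async").mean())
    fa = float((simul_tr["response"] == "async").mean())
    zh = _adjusted_z(hit, len(async_tr))
    zf = _adjusted_z(fa, len(simul_tr))
    return SDTResult(hit_rate=hit, fa_rate=fa, d_prime=zh - zf,
                     criterion=-(zh + zf) / 2.0,
                     n_signal=len(async_tr), n_noise=len(simul_tr))


# ---------------------------------------------------------------------------
# paired t + effect size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    g_av: float               # Hedges-corrected Cohen's d_av
    mean_a: float
    mean_b: float


def hedges_g_av(a, b) -> float:
    """Cohen's d_av (mean difference over the average SD) with the
    small-sample correction 1 - 3/(4*df - 1), df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2")
    sd_av = 0.5 * (a.std(ddof=1) + b.std(ddof=1))
    if sd_av == 0:
        return float("nan")
    d_av = float((a - b).mean() / sd_av)
    return d_av * (1.0 - 3.0 / (4.0 * (n - 1) - 1.0))


def paired_t(a, b) -> PairedTResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_rel(a, b)
    return PairedTResult(t=float(t), df=a.size - 1, p=float(p),
                         g_av=hedges_g_av(a, b),
                         mean_a=float(a.mean()), mean_b=float(b.mean()))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float = 1.0       # 1.0 when no correction applies


@dataclass
class AnovaResult:
    effects: dict = field(default_factory=dict)

    def __getitem__(self, name) -> AnovaEffect:
        return self.effects[name]


def _gg_epsilon(scores):
    """Greenhouse-Geisser epsilon from (n, k) within-factor scores.

    Uses the eigenvalues of the double-centred covariance:
    eps = (sum lambda)^2 / ((k-1) * sum lambda^2), bounded to
    [1/(k-1), 1].
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k == 2:
        return 1.0
    cov = np.cov(scores, rowvar=False, ddof=1)
    cent = np.eye(k) - np.ones((k, k)) / k
    m = cent @ cov @ cent
    lam = np.linalg.eigvalsh(m)
    lam = lam[lam > 1e-12]
    eps = lam.sum() ** 2 / ((k - 1) * np.sum(lam ** 2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _within_effect(name, cell_scores, k):
    """F test for a fully-within effect given its (n, k) score matrix
    (already averaged over the other factor / contrast-combined)."""
    y = np.asarray(cell_scores, dtype=float)
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=1, keepdims=True)
    lvl = y.mean(axis=0, keepdims=True)
    ss_effect = n * np.sum((lvl - grand) ** 2)
    resid = y - subj - lvl + grand
    ss_error = np.sum(resid ** 2)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    eps = _gg_epsilon(y)
    ms_effect = ss_effect / df1
    ms_error = ss_error / df2 if ss_error > 0 else 0.0
    F = ms_effect / ms_error if ms_error > 0 else (0.0 if ss_effect == 0
                                                   else float("inf"))
    p = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    eta = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0
    return AnovaEffect(name=name, F=float(F), df1=df1 * eps, df2=df2 * eps,
                       p=p, partial_eta_sq=float(eta), gg_epsilon=eps)


def rm_anova_2x2(cells) -> AnovaResult:
    """Fully within-subject 2x2 ANOVA.

    cells : (n, 2, 2) array indexed [participant, A level, B level].
    Each 1-df effect is algebraically a squared paired t on contrast
    scores; effects are named "A", "B", "AxB".
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("expected (n, 2, 2) cell means")
    if np.isnan(y).any():
        raise ValueError("missing cells")
    res = AnovaResult()
    res.effects["A"] = _within_effect("A", y.mean(axis=2), 2)
    res.effects["B"] = _within_effect("B", y.mean(axis=1), 2)
    inter = np.stack([(y[:, 0, 0] + y[:, 1, 1]) / 2.0,
                      (y[:, 0, 1] + y[:, 1, 0]) / 2.0], axis=1)
    res.effects["AxB"] = _within_effect("AxB", inter, 2)
    return res


def rm_anova_kx2(cells) -> AnovaResult:
    """Fully within-subject k x 2 ANOVA with GG correction on the k-level
    factor and the interaction.

    cells : (n, k, 2) array indexed [participant, A level, B level].
    Effects are named "A" (k levels), "B" (2 levels), "AxB".
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3 or y.shape[2] != 2:
        raise ValueError("expected (n, k, 2) cell means")
    k = y.shape[1]
    res = AnovaResult()
    res.effects["A"] = _within_effect("A", y.mean(axis=2), k)
    res.effects["B"] = _within_effect("B", y.mean(axis=1), 2)
    # interaction: B difference profile across the k levels of A
    res.effects["AxB"] = _interaction_kx2(y)
    return res


def _interaction_kx2(y):
    n, k, _ = y.shape
    diff = y[:, :, 0] - y[:, :, 1]              # (n, k)
    grand = diff.mean()
    subj = diff.mean(axis=1, keepdims=True)
    lvl = diff.mean(axis=0, keepdims=True)
    ss_effect = n * np.sum((lvl - grand) ** 2) / 2.0
    resid = diff - subj - lvl + grand
    ss_error = np.sum(resid ** 2) / 2.0
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    eps = _gg_epsilon(diff)
    F = (ss_effect / df1) / (ss_error / df2) if ss_error > 0 else (
        0.0 if ss_effect == 0 else float("inf"))
    p = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    eta = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0
    return AnovaEffect(name="AxB", F=float(F), df1=df1 * eps, df2=df2 * eps,
                       p=p, partial_eta_sq=float(eta), gg_epsilon=eps)


# ---------------------------------------------------------------------------
# within-subject SE, staircase summaries
# ---------------------------------------------------------------------------

def within_subject_se(cellmeans):
    """Cousineau-Morey within-subject standard error per cell.

    cellmeans : (n, k).  Each participant's mean is removed (grand mean
    added back) and the cell SEs of the normalised data are scaled by
    sqrt(k / (k - 1)).
    """
    y = np.asarray(cellmeans, dtype=float)
    n, k = y.shape
    norm = y - y.mean(axis=1, keepdims=True) + y.mean()
    se = norm.std(axis=0, ddof=1) / math.sqrt(n)
    return se * math.sqrt(k / (k - 1))


def staircase_summary(soas, correct, discard=100):
    """Mean SOA and hit rate of a staircase run after a burn-in."""
    soas = np.asarray(soas, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    keep = slice(discard, None)
    return {"mean_soa": float(soas[keep].mean()),
            "hit_rate": float(correct[keep].mean()),
            "overall_hit_rate": float(correct.mean())}


def behavioural_summary(trial_tables) -> pd.DataFrame:
    """Per-participant behavioural metrics from a list of trial tables.

    Columns: hit rates (overall / by validity), false-alarm rate, d-prime,
    criterion, mean SOA by validity, mean RT by validity.
    """
    rows = []
    for trials in trial_tables:
        async_tr = trials[trials["synchrony"] == "async"]
        sdt = sdt_metrics(trials)
        row = {"participant": trials["participant"].iloc[0],
               "hit_rate": sdt.hit_rate, "fa_rate": sdt.fa_rate,
               "d_prime": sdt.d_prime, "criterion": sdt.criterion}
        for validity in ("valid", "invalid"):
            sub = async_tr[async_tr["validity"] == validity]
            row[f"hit_rate_{validity}"] = float(
                (sub["response"] == "async").mean())
            row[f"soa_{validity}"] = float(sub["soa_ms"].mean())
            row[f"rt_{validity}"] = float(sub["rt_ms"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
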
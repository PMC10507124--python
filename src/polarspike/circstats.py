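"""Circular and permutation statistics.

Implements the non-ubiquitous tests used throughout the pipeline: the
mean resultant vector, Rayleigh's test of circular uniformity,
Wheeler-Watson's two-sample uniform-scores test, the likelihood-ratio
(G-) test for contingency tables, and label-permutation tests (Spearman
correlation, SD difference).  Standard nonparametric tests (Wilcoxon,
Mann-Whitney, Kruskal-Wallis, Binomial, Poisson tails) are delegated to
scipy throughout the package.

All permutation p-values use the plus-one correction
p = (1 + #{stat_perm >= stat}) / (n_perm + 1), so p is in (0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def wrap_angles(a) -> np.ndarray:
    """Wrap angles into [0, 2*pi)."""
    return np.mod(np.asarray(a, float), 2 * np.pi)


def circ_mean_resultant(angles) -> tuple[float, float]:
    """Mean direction (in [0, 2*pi)) and resultant length R of a circular sample.

    R is the modulus of the average unit phasor and lies in [0, 1]: 1 for
    identical angles, 0 for e.g. an antipodal pair.  For a von Mises
    sample with concentration kappa, R converges to I1(kappa)/I0(kappa).
    """
    a = wrap_angles(angles)
    if a.size < 1:
        raise ValueError("need at least one angle")
    z = np.exp(1j * a).mean()
    return float(np.mod(np.angle(z), 2 * np.pi)), float(np.abs(z))


def rayleigh_test(angles) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    Uses Z = n * R^2 with the standard finite-n series correction
    p = exp(-Z) * (1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)).
    """
    a = wrap_angles(angles)
    n = a.size
    if n < 1:
        raise ValueError("empty sample")
    _, r = circ_mean_resultant(a)
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(np.clip(p, 0.0, 1.0))


def _uniform_scores(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circular ranks (uniform scores) of two pooled samples; ties get average ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # average ranks for ties
    scores = 2 * np.pi * ranks / pooled.size
    return scores[: a.size], scores[a.size :]


def _ww_statistic(sa: np.ndarray, sb: np.ndarray) -> float:
    w = 0.0
    for s in (sa, sb):
        c, si = np.cos(s).sum(), np.sin(s).sum()
        w += (c * c + si * si) / s.size
    return 2.0 * w


def wheeler_watson_test(a, b, n_perm: int = 2000, seed: int | None = None, min_n: int = 10) -> float:
    """Wheeler-Watson two-sample test of a common circular distribution.

    Pooled angles are replaced by uniform scores (circular ranks); the
    statistic W = 2 * sum_groups (C^2 + S^2)/n is compared to chi-square
    with 2 df.  For samples smaller than ``min_n`` the chi-square
    approximation is unreliable and a label-permutation null is used
    instead.
    """
    a, b = wrap_angles(a), wrap_angles(b)
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("degenerate constant samples")
    sa, sb = _uniform_scores(a, b)
    w = _ww_statistic(sa, sb)
    if min(a.size, b.size) >= min_n:
        return float(sps.chi2.sf(w, df=2))
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([sa, sb])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _ww_statistic(perm[: a.size], perm[a.size :]) >= w:
            count += 1
    return (1 + count) / (n_perm + 1)


def g_test(table) -> tuple[float, float]:
    """Likelihood-ratio (G-) test of independence for an r x k count table.

    G = 2 * sum O * ln(O/E); cells with O = 0 contribute 0.  p from
    chi-square with (r-1)(k-1) df.
    """
    obs = np.asarray(table, float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValueError("table margins must be positive")
    exp = row * col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(g), float(sps.chi2.sf(g, df=df))


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction helper: corrected p-values and reject flags."""
    p = np.asarray(p_values, float)
    corrected = np.clip(p * p.size, 0.0, 1.0)
    return corrected, corrected < alpha


def permutation_sd_test(a, b, n_perm: int = 1000, seed: int | None = None) -> float:
    """Two-sided label-permutation test for a difference in group SDs."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    stat = abs(a.std(ddof=1) - b.std(ddof=1))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    # vectorized permutations: one shuffled index matrix
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[idx]
    pa, pb = perm[:, : a.size], perm[:, a.size :]
    stats_perm = np.abs(pa.std(ddof=1, axis=1) - pb.std(ddof=1, axis=1))
    return float((1 + np.sum(stats_perm >= stat)) / (n_perm + 1))


def perm_pvalue(stat: float, null_stats, two_sided: bool = True) -> float:
    """Plus-one-corrected permutation p-value of ``stat`` against a null sample."""
    null_stats = np.asarray(null_stats, float)
    if two_sided:
        count = np.sum(np.abs(null_stats) >= abs(stat))
    else:
        count = np.sum(null_stats >= stat)
    return float((1 + count) / (null_stats.size + 1))
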
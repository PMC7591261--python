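"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (direct mass
evaluation, naive step-up definitions, explicit risk-set sums) and stays
independent of the code paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import nbinom, poisson


def exact_test_brute(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Probability-mass two-sided exact test by direct enumeration.

    Evaluates the two group-total NB masses at an arbitrary mean (the
    conditional split law is mean-free), normalizes by the total over all
    splits, and sums the masses not exceeding the observed one.
    """
    s = s_a + s_b
    if s == 0:
        return 1.0
    mu = 1.0  # any positive mean gives the same conditional law
    k = np.arange(s + 1)
    if phi == 0:
        pa = poisson.pmf(k, n_a * mu)
        pb = poisson.pmf(s - k, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        pa = nbinom.pmf(k, r_a, r_a / (r_a + n_a * mu))
        pb = nbinom.pmf(s - k, r_b, r_b / (r_b + n_b * mu))
    mass = pa * pb
    mass = mass / mass.sum()
    obs = mass[s_a]
    return float(mass[mass <= obs * (1 + 1e-12)].sum())


def bh_naive(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from its textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_brute(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric by summing binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


def average_ranks(x) -> np.ndarray:
    """Average ranks computed by sorting, without scipy."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_rho_brute(x, y) -> float:
    """Pearson correlation of average ranks, via the explicit sums."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def logrank_brute(time, event, group) -> tuple[float, float]:
    """Log-rank chi-square over the explicit risk sets.

    Returns (chi2, p) with the standard hypergeometric variance; group is a
    boolean array marking membership of group 1.
    """
    from scipy.stats import chi2 as chi2_dist

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    U = 0.0
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = U**2 / V
    return float(chi2), float(chi2_dist.sf(chi2, df=1))
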
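"""Negative-binomial exact test between two phases.

The test conditions on a gene's total pseudo-count across both groups. Under
the null each group total is negative binomial with mean proportional to the
number of samples in the group and dispersion phi/n (sum of iid NB draws at a
common library size); the conditional split distribution is independent of
the mean, so the p-value is the summed probability of all splits whose mass
does not exceed that of the observed split (probability-mass two-sided rule).

A common dispersion is estimated per phase pair by conditional maximum
likelihood on equalized pseudo-counts; fold changes are computed on phase
mean CPM with a small prior count; FDR is Benjamini-Hochberg within each
pair's gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, DesignError, ValidationError
from .io import CountMatrix
from .norm import NormalizationResult

#: Relative tolerance for ties in the probability-mass rejection rule.
_TIE_RTOL = 1e-12


@dataclass
class DispersionEstimate:
    """Common NB dispersion (variance = mu + phi * mu**2)."""

    phi: float
    method: str = "cml_grid"
    grid_bounds: tuple[float, float] = (1e-4, 4.0)


@dataclass
class DEGConfig:
    """Differential-expression calling thresholds.

    ``fc_threshold`` is on the natural scale (1.5 means 1.5-fold);
    ``prior_count`` (CPM units) shrinks fold changes at low expression.
    """

    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValidationError("fc_threshold must be > 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.prior_count < 0:
            raise ValidationError("prior_count must be >= 0")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


def equalize_pseudocounts(counts, effective_sizes) -> tuple[np.ndarray, float]:
    """Scale each sample's counts to the geometric-mean effective size.

    Returns (pseudo_counts, common_size); pseudo-counts are real valued.
    """
    X = np.asarray(counts, dtype=float)
    sizes = np.asarray(effective_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValidationError("effective sizes must be > 0")
    common = float(np.exp(np.mean(np.log(sizes))))
    return X * (common / sizes), common


def _cml_loglik(phi: float, Y: np.ndarray, group_slices: list[np.ndarray]) -> float:
    """Summed per-gene NB conditional log-likelihood at dispersion ``phi``,
    conditioning on per-group gene totals (Dirichlet-multinomial form)."""
    r = 1.0 / phi
    total = 0.0
    for idx in group_slices:
        Z = Y[:, idx]
        n = Z.shape[1]
        z = Z.sum(axis=1)
        ll = (
            gammaln(Z + r).sum(axis=1)
            - n * gammaln(r)
            - gammaln(z + n * r)
            + gammaln(n * r)
        )
        total += float(ll.sum())
    return total


def estimate_common_dispersion(
    pseudo_counts,
    groups,
    grid_bounds: tuple[float, float] = (1e-4, 4.0),
    rel_tol: float = 1e-3,
) -> DispersionEstimate:
    """Common dispersion by conditional maximum likelihood on a log grid.

    ``groups`` is a label per sample (two groups expected, each >= 2
    samples). The likelihood conditions on per-group gene totals, treating
    pseudo-counts as equal-library NB draws; the grid maximum is refined by
    golden-section search on log(phi).
    """
    Y = np.asarray(pseudo_counts, dtype=float)
    labels = np.asarray(groups)
    group_slices = [np.where(labels == g)[0] for g in pd.unique(labels)]
    for idx in group_slices:
        if len(idx) < 2:
            raise DesignError("each group needs >= 2 samples for dispersion estimation")
    Y = Y[Y.sum(axis=1) > 0]
    if Y.shape[0] == 0:
        raise ComputationError("all genes are all-zero; cannot estimate dispersion")
    if Y.shape[0] < 50:
        warnings.warn(
            f"common dispersion estimated from only {Y.shape[0]} genes; "
            "estimates may be unstable"
        )

    def negll_log(t: float) -> float:
        return -_cml_loglik(float(np.exp(t)), Y, group_slices)

    lo, hi = grid_bounds
    grid = np.log(np.geomspace(lo, hi, 31))
    values = np.array([negll_log(t) for t in grid])
    i = int(np.argmin(values))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    # golden-section search on log(phi)
    invphi = (np.sqrt(5) - 1) / 2
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = negll_log(c), negll_log(d)
    while (b - a) > rel_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = negll_log(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = negll_log(d)
    phi = float(np.exp((a + b) / 2))
    return DispersionEstimate(phi=phi, method="cml_grid", grid_bounds=grid_bounds)


def _conditional_log_masses(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Normalized log-probabilities of all splits (k, s-k) of the total."""
    s = s_a + s_b
    k = np.arange(s + 1)
    if phi == 0:
        lp = binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        # conditional split law is free of the mean; any mu gives the same lp
        mu = s / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        p = 1.0 / (1.0 + phi * mu)
        lp = nbinom.logpmf(k, r_a, p) + nbinom.logpmf(s - k, r_b, p)
        lp = lp - logsumexp(lp)
    return lp


def nb_exact_test(pseudo_counts_a, pseudo_counts_b, phi: float) -> float:
    """Exact two-sided NB test of equal means between two groups.

    Inputs are per-sample pseudo-counts at a common library size; group
    totals are rounded to the nearest integer for the conditional
    enumeration. Splits whose probability mass is within relative 1e-12 of
    the observed mass count as ties and enter the rejection region.
    """
    a = np.asarray(pseudo_counts_a, dtype=float)
    b = np.asarray(pseudo_counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("pseudo-counts must be >= 0")
    if not np.isfinite(phi) or phi < 0:
        raise ValidationError("phi must be finite and >= 0")
    s_a = int(np.floor(a.sum() + 0.5))
    s_b = int(np.floor(b.sum() + 0.5))
    if s_a + s_b == 0:
        return 1.0
    lp = _conditional_log_masses(s_a, s_b, len(a), len(b), phi)
    lo = lp[s_a]
    reject = lp <= lo + np.log1p(_TIE_RTOL)
    p = float(np.exp(logsumexp(lp[reject])))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def log_fold_change(mean_cpm_a: float, mean_cpm_b: float, prior_count: float = 0.5):
    """Shrunken log2 fold change of b over a: log2((b + prior)/(a + prior))."""
    a = np.asarray(mean_cpm_a, dtype=float)
    b = np.asarray(mean_cpm_b, dtype=float)
    return np.log2((b + prior_count) / (a + prior_count))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_pair(
    cm: CountMatrix,
    phase_from: str,
    phase_to: str,
    norm: NormalizationResult,
    config: DEGConfig | None = None,
    dispersion: DispersionEstimate | None = None,
) -> pd.DataFrame:
    """NB exact test of every gene between two phases.

    Genes are expected to be pre-filtered for quantifiable expression. The
    log2 fold change is oriented ``phase_to`` vs ``phase_from``. Returns one
    row per gene with p-value, BH FDR (within this pair) and the DEG call.
    """
    config = config or DEGConfig()
    ids_from = cm.samples_in_phase(phase_from)
    ids_to = cm.samples_in_phase(phase_to)
    if len(ids_from) < 2 or len(ids_to) < 2:
        raise DesignError(
            f"phases {phase_from!r}/{phase_to!r} need >= 2 samples each "
            f"(got {len(ids_from)}, {len(ids_to)})"
        )
    sample_ids = ids_from + ids_to
    counts = cm.counts[sample_ids].to_numpy(dtype=float)
    eff = norm.effective_library_size[sample_ids].to_numpy()
    pseudo, _ = equalize_pseudocounts(counts, eff)
    labels = np.array([phase_from] * len(ids_from) + [phase_to] * len(ids_to))
    if dispersion is None:
        dispersion = estimate_common_dispersion(pseudo, labels)
    n_from = len(ids_from)
    p_values = np.array(
        [
            nb_exact_test(pseudo[g, :n_from], pseudo[g, n_from:], dispersion.phi)
            for g in range(pseudo.shape[0])
        ]
    )
    fdr = bh_fdr(p_values)
    mean_from = norm.cpm.loc[cm.gene_ids, ids_from].mean(axis=1).to_numpy()
    mean_to = norm.cpm.loc[cm.gene_ids, ids_to].mean(axis=1).to_numpy()
    lfc = log_fold_change(mean_from, mean_to, config.prior_count)
    thr = config.log2_fc_threshold
    call = np.where(
        (fdr < config.fdr_threshold) & (lfc >= thr),
        "up",
        np.where((fdr < config.fdr_threshold) & (lfc <= -thr), "down", "none"),
    )
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "pair": f"{phase_from}->{phase_to}",
            "from_phase": phase_from,
            "to_phase": phase_to,
            "log2fc": lfc,
            "p_value": p_values,
            "fdr": fdr,
            "mean_cpm_from": mean_from,
            "mean_cpm_to": mean_to,
            "deg_call": call,
        }
    ).set_index("gene_id", drop=False)
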
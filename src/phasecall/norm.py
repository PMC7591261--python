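"""Library-size normalization: CPM, the quantifiable-expression gate, and TMM.

The quantifiable-expression filter (CPM >= 0.075 in at least two samples) is
evaluated on CPM computed from the *raw* library sizes; TMM factors are then
estimated on the filtered matrix and define effective library sizes for the
downstream exact tests. Both choices follow the conventional count-based
differential-expression workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ComputationError, ValidationError
from .io import CountMatrix


@dataclass
class FilterConfig:
    """Quantifiable-expression gate: keep genes with CPM >= ``cpm_threshold``
    in at least ``min_samples`` samples."""

    cpm_threshold: float = 0.075
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.cpm_threshold < 0:
            raise ValidationError("cpm_threshold must be >= 0")
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")


@dataclass
class NormalizationResult:
    """Per-sample TMM factors (geometric mean 1), effective library sizes and
    the CPM matrix computed on the effective sizes."""

    tmm_factor: pd.Series
    effective_library_size: pd.Series
    cpm: pd.DataFrame


def compute_cpm(counts, effective_sizes) -> pd.DataFrame:
    """Counts-per-million: ``counts[g, j] / effective_sizes[j] * 1e6``."""
    sizes = np.asarray(effective_sizes, dtype=float)
    if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)):
        raise ValidationError("effective library sizes must be finite and > 0")
    if isinstance(counts, pd.DataFrame):
        return counts / sizes * 1e6
    return np.asarray(counts, dtype=float) / sizes * 1e6


def filter_expressed(cpm, config: FilterConfig | None = None) -> np.ndarray:
    """Boolean keep-mask over genes; comparisons are inclusive (>=)."""
    config = config or FilterConfig()
    arr = np.asarray(cpm, dtype=float)
    n_pass = (arr >= config.cpm_threshold).sum(axis=1)
    return n_pass >= config.min_samples


def _quartile_fraction(X: np.ndarray, lib: np.ndarray) -> np.ndarray:
    # upper-quartile of library-size-scaled counts, per sample (R quantile type 7)
    return np.percentile(X / lib, 75, axis=0)


def _tmm_pair(
    obs: np.ndarray,
    n_obs: float,
    ref: np.ndarray,
    n_ref: float,
    m_trim: float,
    a_trim: float,
    pair_name: tuple[str, str] | None = None,
) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ComputationError(
            f"no gene with positive counts in both samples {pair_name}"
        )
    o = obs[pos] / n_obs
    r = ref[pos] / n_ref
    M = np.log2(o / r)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    A = 0.5 * np.log2(o * r)
    # asymptotic binomial variance of M; weights below are its inverse
    v = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])
    n = len(M)
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if not keep.any() or not np.isfinite(v[keep]).all() or (v[keep] == 0).any():
        return 1.0
    return float(2 ** (np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])))


def tmm_factors(
    counts,
    library_sizes=None,
    reference: str | int = "auto",
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric-mean normalized.

    For each sample against the reference, per-gene log-ratios M of
    library-size-scaled proportions are trimmed by 30% on M and 5% on average
    abundance A; the factor is 2 to the precision-weighted mean of the
    remaining M. Genes with a zero in either sample of a pair are excluded
    from that pair. With ``reference="auto"`` the reference is the sample
    whose upper-quartile count fraction is closest to the mean.
    """
    if isinstance(counts, CountMatrix):
        sample_ids = counts.sample_ids
        library_sizes = counts.library_size.to_numpy() if library_sizes is None else library_sizes
        X = counts.counts.to_numpy(dtype=float)
    elif isinstance(counts, pd.DataFrame):
        sample_ids = list(counts.columns)
        X = counts.to_numpy(dtype=float)
    else:
        X = np.asarray(counts, dtype=float)
        sample_ids = list(range(X.shape[1]))
    if X.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    lib = X.sum(axis=0) if library_sizes is None else np.asarray(library_sizes, dtype=float)
    if reference == "auto":
        f75 = _quartile_fraction(X, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    elif isinstance(reference, (int, np.integer)):
        ref_idx = int(reference)
    else:
        ref_idx = sample_ids.index(reference)
    factors = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
        else:
            factors[j] = _tmm_pair(
                X[:, j], lib[j], X[:, ref_idx], lib[ref_idx],
                m_trim, a_trim, (sample_ids[j], sample_ids[ref_idx]),
            )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def effective_library_sizes(library_sizes, factors) -> np.ndarray:
    """Effective size = raw library size x TMM factor."""
    return np.asarray(library_sizes, dtype=float) * np.asarray(factors, dtype=float)


def normalize(cm: CountMatrix, method: str = "tmm", **tmm_kwargs) -> NormalizationResult:
    """Compute TMM factors (or unit factors for ``method="none"``), effective
    library sizes and the CPM matrix for a (filtered) count matrix."""
    if method == "tmm":
        factors = tmm_factors(cm, **tmm_kwargs)
    elif method == "none":
        factors = np.ones(len(cm.sample_ids))
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    eff = effective_library_sizes(cm.library_size.to_numpy(), factors)
    sample_index = pd.Index(cm.sample_ids, name="sample_id")
    return NormalizationResult(
        tmm_factor=pd.Series(factors, index=sample_index, name="tmm_factor"),
        effective_library_size=pd.Series(eff, index=sample_index, name="effective_library_size"),
        cpm=compute_cpm(cm.counts, eff),
    )
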
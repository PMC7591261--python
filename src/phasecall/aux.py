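"""Downstream summary statistics: downregulated-set intersection, an
anchor-gene Spearman screen, median-split Kaplan-Meier survival, and the
3C (chromosome conformation capture) interaction-frequency formula."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .difftest import bh_fdr
from .errors import ComputationError, ValidationError


def intersect_downregulated(early_down, late_down) -> list[str]:
    """Genes downregulated at both an early and a late time point, sorted."""
    return sorted(set(early_down) & set(late_down))


def _rank_rows(X: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(X, axis=1)


def _pearson_rows(R: np.ndarray, r_anchor: np.ndarray) -> np.ndarray:
    Rc = R - R.mean(axis=1, keepdims=True)
    ac = r_anchor - r_anchor.mean()
    denom = np.sqrt((Rc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Rc @ ac) / denom


def spearman_screen(
    expr: pd.DataFrame,
    anchor,
    p_cut: float = 0.01,
    fdr_cut: float = 0.05,
    exact_below_n: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation of every gene with an anchor expression vector.

    rho is the average-rank (tie-corrected) rank correlation. The p-value
    uses the t approximation for n >= ``exact_below_n`` samples and exact
    enumeration over all permutations of the anchor below that. A gene is
    significant when p < ``p_cut`` AND its BH FDR < ``fdr_cut`` (both cuts
    applied conjunctively). Constant genes have undefined rho and are
    flagged and excluded from the FDR.

    Returns (per-gene table, summary dict with the number of significant
    genes and the fraction of them positively correlated).
    """
    a = np.asarray(anchor, dtype=float)
    n = len(a)
    if n < 4:
        raise ValidationError("Spearman screen needs >= 4 samples")
    if np.ptp(a) == 0:
        raise ValidationError("anchor expression is constant")
    X = expr.to_numpy(dtype=float)
    if X.shape[1] != n:
        raise ValidationError("expression matrix and anchor disagree on sample count")

    R = _rank_rows(X)
    ra = _rank_rows(a[None, :])[0]
    rho = _pearson_rows(R, ra)
    constant = np.ptp(X, axis=1) == 0

    p = np.full(len(rho), np.nan)
    ok = ~constant
    if n >= exact_below_n:
        from scipy.stats import t as t_dist

        r = np.clip(rho[ok], -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p[ok] = 2 * t_dist.sf(np.abs(t), df=n - 2)
    else:
        perms = np.array(list(permutations(ra)))  # n! x n
        rho_perm = np.empty((ok.sum(), len(perms)))
        Rok = R[ok]
        for j, perm in enumerate(perms):
            rho_perm[:, j] = _pearson_rows(Rok, perm)
        obs = np.abs(rho[ok])[:, None]
        p[ok] = (np.abs(rho_perm) >= obs - 1e-12).sum(axis=1) / factorial(n)
    p = np.clip(p, 0.0, 1.0)

    fdr = np.full(len(rho), np.nan)
    if ok.any():
        fdr[ok] = bh_fdr(p[ok])
    significant = ok & (p < p_cut) & (fdr < fdr_cut)
    sign = np.where(constant, "0", np.where(rho > 0, "+", np.where(rho < 0, "-", "0")))
    table = pd.DataFrame(
        {
            "gene_id": expr.index,
            "rho": rho,
            "p_value": p,
            "fdr": fdr,
            "significant": significant,
            "sign": sign,
            "constant": constant,
        },
        index=expr.index,
    )
    n_sig = int(significant.sum())
    summary = {
        "n_tested": int(ok.sum()),
        "n_significant": n_sig,
        "fraction_positive": float((significant & (rho > 0)).sum() / n_sig)
        if n_sig
        else float("nan"),
    }
    return table, summary


@dataclass
class KMResult:
    """Median-split survival comparison."""

    labels: pd.Series  # "high"/"low" per sample
    curves: dict[str, pd.DataFrame]  # KM step function per group
    chi2: float
    p_value: float
    median_expression: float


def km_median_split(records: pd.DataFrame) -> KMResult:
    """Kaplan-Meier comparison of samples split at the median expression.

    ``records`` needs columns time, event, expression (see io.read_survival).
    High = expression strictly above the median; ties at the median go low.
    The two groups are compared with the standard log-rank test (chi-square
    with 1 df).
    """
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    expr = records["expression"].to_numpy(dtype=float)
    med = float(np.median(expr))
    high = expr > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValidationError(
            "median split leaves a group with < 2 samples; cannot compare"
        )
    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    labels = pd.Series(
        np.where(high, "high", "low"),
        index=records["sample_id"] if "sample_id" in records else records.index,
        name="group",
    )
    return KMResult(
        labels=labels,
        curves=curves,
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        median_expression=med,
    )


def three_c_interaction_frequency(dct_sample: float, dct_control: float) -> float:
    """3C ligation signal relative to a BAC control library:
    2 ** (dCt_sample - dCt_control)."""
    if not (np.isfinite(dct_sample) and np.isfinite(dct_control)):
        raise ValidationError("dCt values must be finite")
    return float(2.0 ** (dct_sample - dct_control))
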
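"""Circular adjacent-phase design and the two-criterion phase-specific classifier.

A gene is called specific to a phase when (1) its mean expression is strictly
highest in that phase among all five phases, and (2) it is significantly
(FDR below threshold) upregulated by at least the fold-change threshold
against BOTH circular neighbors of that phase. The phase order wraps:
G1 -> G1/S -> S -> G2 -> M -> G1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .difftest import DEGConfig
from .errors import DesignError, ValidationError
from .io import BIOTYPES, PHASES


@dataclass(frozen=True)
class PhaseDesign:
    """An ordered cycle of phases; adjacency is successor/predecessor."""

    phases: tuple[str, ...] = PHASES

    def __post_init__(self) -> None:
        if len(self.phases) < 3 or len(set(self.phases)) != len(self.phases):
            raise ValidationError("design needs >= 3 distinct phases forming a cycle")

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """All (phase, successor) pairs around the cycle, e.g. ending (M, G1)."""
        n = len(self.phases)
        return [(self.phases[i], self.phases[(i + 1) % n]) for i in range(n)]

    def neighbors(self, phase: str) -> tuple[str, str]:
        """(predecessor, successor) of a phase on the cycle."""
        if phase not in self.phases:
            raise ValidationError(f"unknown phase {phase!r}; design has {self.phases}")
        i = self.phases.index(phase)
        n = len(self.phases)
        return self.phases[(i - 1) % n], self.phases[(i + 1) % n]


DEFAULT_DESIGN = PhaseDesign()


def classify_phase_specific(
    mean_cpm_by_phase: pd.DataFrame,
    pairwise: dict[tuple[str, str], pd.DataFrame],
    config: DEGConfig | None = None,
    design: PhaseDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Assign each gene to at most one phase via the two-criterion rule.

    Parameters
    ----------
    mean_cpm_by_phase
        Genes x phases table of phase-mean CPM.
    pairwise
        One differential-test table per adjacent pair, keyed
        ``(from_phase, to_phase)``, indexed by gene id, with columns
        ``fdr`` and ``log2fc`` (to vs from).

    Ties at the maximum mean disqualify (criterion 1 is strict). The
    neighbor tests reuse the adjacent-pair results: the predecessor pair
    (prev, peak) supports the call with its log2fc as-is, the successor pair
    (peak, next) with the sign flipped toward the peak.
    """
    config = config or DEGConfig()
    phases = list(design.phases)
    missing_cols = set(phases) - set(mean_cpm_by_phase.columns)
    if missing_cols:
        raise DesignError(f"mean CPM table lacks phases {sorted(missing_cols)}")
    for pair in design.adjacent_pairs():
        if pair not in pairwise:
            raise DesignError(f"missing pairwise result for adjacent pair {pair}")

    genes = mean_cpm_by_phase.index
    M = mean_cpm_by_phase[phases].to_numpy(dtype=float)
    peak_idx = np.argmax(M, axis=1)
    is_tie = (M == M.max(axis=1, keepdims=True)).sum(axis=1) > 1
    criterion1 = ~is_tie

    # per-phase neighbor statistics, aligned to the classifier's gene index
    fdr_prev = np.full((len(genes), len(phases)), np.nan)
    lfc_prev = np.full_like(fdr_prev, np.nan)
    fdr_next = np.full_like(fdr_prev, np.nan)
    lfc_next = np.full_like(fdr_prev, np.nan)
    for qi, q in enumerate(phases):
        prev, nxt = design.neighbors(q)
        up = pairwise[(prev, q)].reindex(genes)  # toward peak = +log2fc
        dn = pairwise[(q, nxt)].reindex(genes)  # toward peak = -log2fc
        fdr_prev[:, qi] = up["fdr"].to_numpy()
        lfc_prev[:, qi] = up["log2fc"].to_numpy()
        fdr_next[:, qi] = dn["fdr"].to_numpy()
        lfc_next[:, qi] = -dn["log2fc"].to_numpy()

    rows = np.arange(len(genes))
    g_fdr_prev = fdr_prev[rows, peak_idx]
    g_lfc_prev = lfc_prev[rows, peak_idx]
    g_fdr_next = fdr_next[rows, peak_idx]
    g_lfc_next = lfc_next[rows, peak_idx]
    thr = config.log2_fc_threshold
    with np.errstate(invalid="ignore"):
        criterion2 = (
            (g_fdr_prev < config.fdr_threshold)
            & (g_lfc_prev >= thr)
            & (g_fdr_next < config.fdr_threshold)
            & (g_lfc_next >= thr)
        )
    criterion2 &= criterion1  # peak undefined on ties
    assigned = np.where(
        criterion1 & criterion2, np.array(phases, dtype=object)[peak_idx], "none"
    )
    peak_label = np.where(criterion1, np.array(phases, dtype=object)[peak_idx], "none")

    phase_names = np.array(phases, dtype=object)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "assigned_phase": assigned,
            "peak_phase_by_mean": peak_label,
            "criterion1_pass": criterion1,
            "criterion2_pass": criterion2,
            "prev_phase": [design.neighbors(p)[0] for p in phase_names[peak_idx]],
            "next_phase": [design.neighbors(p)[1] for p in phase_names[peak_idx]],
            "fdr_vs_prev": g_fdr_prev,
            "log2fc_vs_prev": g_lfc_prev,
            "fdr_vs_next": g_fdr_next,
            "log2fc_vs_next": g_lfc_next,
        },
        index=genes,
    )


def summarize_calls(
    calls: pd.DataFrame,
    annotation: dict[str, str] | None = None,
    design: PhaseDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Phase x biotype counts of assigned genes, with row/column totals.

    Genes without an annotation entry count as ``other``.
    """
    annotation = annotation or {}
    assigned = calls[calls["assigned_phase"] != "none"]
    table = pd.DataFrame(0, index=list(design.phases), columns=list(BIOTYPES))
    for gene, phase in zip(assigned["gene_id"], assigned["assigned_phase"]):
        biotype = annotation.get(gene, "other")
        table.loc[phase, biotype] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "phase"
    return table
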
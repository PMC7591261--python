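"""Hypergeometric over-representation of a query gene list against gene sets.

One-sided upper-tail test of the overlap between a query list (e.g. the
S-phase-specific genes) and each gene set, with the quantifiable-gene
universe as background and Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .difftest import bh_fdr
from .errors import ValidationError
from .io import GeneSetCollection


def hypergeometric_enrichment(
    query,
    sets: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.05,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Over-representation p-values for every gene set.

    p = P(X >= k) for X ~ Hypergeom(N population, K set size, n query size),
    all counts taken after intersecting query and sets with the universe.
    Results are sorted by p-value then set id.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
    query &= universe
    if not query:
        raise ValidationError("query is empty after intersection with universe")

    restricted = sets.restricted_to(universe)
    kept, dropped = [], []
    for gs in restricted.sets:
        (kept if len(gs.members) >= min_set_size else dropped).append(gs)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sets smaller than {min_set_size} after "
            "universe intersection"
        )

    N, n = len(universe), len(query)
    rows = []
    for gs in kept:
        members = set(gs.members)
        K = len(members)
        overlap = sorted(members & query)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))  # stable upper tail P(X >= k)
        rows.append(
            {
                "set_id": gs.set_id,
                "name": gs.name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": min(max(p, np.nextafter(0.0, 1.0)), 1.0),
                "fold_enrichment": (k / n) / (K / N),
                "overlap_genes": ",".join(overlap),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_id", "name", "overlap", "set_size", "query_size",
            "universe_size", "p_value", "fold_enrichment", "overlap_genes",
        ],
    )
    if len(result):
        result["fdr"] = bh_fdr(result["p_value"].to_numpy())
        result["significant"] = result["fdr"] < fdr_threshold
        result = result.sort_values(
            ["p_value", "set_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["fdr"] = []
        result["significant"] = []
    return result
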
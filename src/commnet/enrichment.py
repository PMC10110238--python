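"""Hypergeometric over-representation analysis against GMT gene sets.

The universe defaults to the measured genes (those surviving QC); a
genome-wide list can be supplied instead.  Enrichment is one-sided
(upper tail); p-values are BH-adjusted across the tested sets and flagged
significant at FDR <= 0.05.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom

from .datamodel import GeneSetCollection, ValidationError
from .differential import bh_fdr


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValidationError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(
    query_genes,
    collection: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each set of ``collection``.

    Sets with no overlap with the universe are excluded (not assigned a
    p-value); query genes outside the universe are dropped with a warning.
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped")
    query &= universe
    if not query:
        raise ValidationError("no query genes left after universe intersection")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        K = len(in_universe)
        k = len(query & in_universe)
        rows.append({
            "set_name": name, "k": k, "K": K, "n": n, "N": N,
            "p": hypergeom_upper_tail(k, K, n, N),
        })
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] <= fdr_threshold
    return out.sort_values(["fdr", "p", "set_name"]).reset_index(drop=True)
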
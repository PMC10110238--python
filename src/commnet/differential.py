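"""Rank-based differential tests and the three screening rules.

All tests are two-sided Wilcoxon rank-sum on log-normalized expression,
with Benjamini-Hochberg adjustment *within* each contrast (one cluster vs
rest, or one cell type's condition comparison).  Fold changes are computed
on back-transformed (expm1) normalized means with a small pseudocount, so
the log2FC thresholds refer to linear expression ratios.

Screens (thresholds inclusive at the boundary, see :class:`DEThresholds`):

* cluster markers — fold >= 1.28, detected in > 25% of the cluster's cells,
  FDR <= 0.05, upregulated only;
* cell-type-specific genes — one type vs all others, FDR <= 0.01 and
  log2FC >= 1 (at least twofold);
* condition DE — diabetic vs control within each type, FDR <= 0.05 and
  |log2FC| >= 0.36, both directions kept with a direction label.

A uni-DEG is a gene significant in exactly one cell type's condition
contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datamodel import ValidationError
from .qc_cluster import NormMatrix

PSEUDOCOUNT = 1e-9


@dataclass
class DEThresholds:
    """Screen cutoffs; every comparison is inclusive at the stated boundary
    except the marker detection fraction, which is strictly 'more than'."""

    marker_fold: float = 1.28
    marker_min_pct: float = 0.25
    marker_fdr: float = 0.05
    specific_fdr: float = 0.01
    specific_log2fc: float = 1.0
    de_fdr: float = 0.05
    de_log2fc: float = 0.36
    min_cells: int = 3


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    Exact p by enumeration of the null permutation distribution when the
    pooled sample has at most 20 observations and no ties; otherwise the
    normal approximation with midranks, tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    if np.ptp(pooled) == 0:
        return float(x.size * (pooled.size + 1) / 2), 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2)
    return w, float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if q.size and (q.min() < 0 or q.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def log2_fold_change(mean_in: float, mean_out: float, pseudocount: float = PSEUDOCOUNT) -> float:
    """log2 ratio of back-transformed means with a stabilizing pseudocount."""
    if mean_in < 0 or mean_out < 0:
        raise ValidationError("means must be non-negative")
    return float(np.log2((mean_in + pseudocount) / (mean_out + pseudocount)))


def _group_stats(x_in: np.ndarray, x_out: np.ndarray):
    """Per-gene back-transformed means, detection fractions and Wilcoxon p.

    Inputs are dense genes x cells blocks of log-normalized values.
    Vectorized across genes with the normal approximation (tie + continuity
    corrected); pooled-constant genes get p = 1.
    """
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    res = mannwhitneyu(x_in, x_out, alternative="two-sided",
                       method="asymptotic", axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    pooled_const = (x_in.max(axis=1) == x_in.min(axis=1)) & \
                   (x_out.max(axis=1) == x_out.min(axis=1)) & \
                   (x_in[:, 0] == x_out[:, 0])
    p[pooled_const] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    with np.errstate(divide="ignore"):
        lfc = np.log2((mean_in + PSEUDOCOUNT) / (mean_out + PSEUDOCOUNT))
    return mean_in, mean_out, pct_in, pct_out, p, lfc


def _one_vs_rest(norm: NormMatrix, groups: np.ndarray, min_cells: int) -> pd.DataFrame:
    dense = norm.dense()
    frames = []
    for g in pd.unique(groups):
        in_mask = groups == g
        if in_mask.sum() < min_cells or (~in_mask).sum() < min_cells:
            warnings.warn(f"group {g!r}: fewer than {min_cells} cells on one side; skipped")
            continue
        mi, mo, pi, po, p, lfc = _group_stats(dense[:, in_mask], dense[:, ~in_mask])
        frames.append(pd.DataFrame({
            "group": g, "gene": norm.gene_ids, "log2fc": lfc,
            "pct_in": pi, "pct_out": po, "mean_in": mi, "mean_out": mo,
            "p": p, "fdr": bh_fdr(p),
        }))
    if not frames:
        raise ValidationError("no group large enough to test")
    return pd.concat(frames, ignore_index=True)


def find_cluster_markers(norm: NormMatrix, labels, th: DEThresholds = None):
    """One-vs-rest marker screen per cluster.

    Returns (full table, filtered marker table); the filtered view keeps
    up-markers with fold >= marker_fold, pct_in > marker_min_pct and
    FDR <= marker_fdr, sorted by cluster then FDR.
    """
    th = th or DEThresholds()
    labels = np.asarray(labels)
    if len(pd.unique(labels)) < 2:
        raise ValidationError("marker screen needs at least two clusters")
    full = _one_vs_rest(norm, labels, th.min_cells).rename(columns={"group": "cluster_id"})
    keep = (
        (full["log2fc"] >= np.log2(th.marker_fold))
        & (full["pct_in"] > th.marker_min_pct)
        & (full["fdr"] <= th.marker_fdr)
    )
    filtered = full[keep].sort_values(["cluster_id", "fdr", "gene"]).reset_index(drop=True)
    return full, filtered


def find_specific_genes(norm: NormMatrix, cell_types, th: DEThresholds = None):
    """Cell-type-specific gene screen (one type vs all other cells).

    Returns (full table, filtered table).  The filtered table keeps records
    with FDR <= specific_fdr and log2FC >= specific_log2fc and carries a
    ``unique`` flag marking genes qualifying in exactly one type.
    """
    th = th or DEThresholds()
    cell_types = np.asarray(cell_types)
    full = _one_vs_rest(norm, cell_types, th.min_cells).rename(columns={"group": "cell_type"})
    keep = (full["fdr"] <= th.specific_fdr) & (full["log2fc"] >= th.specific_log2fc)
    filtered = full[keep].copy()
    counts = filtered["gene"].value_counts()
    filtered["unique"] = filtered["gene"].map(counts).eq(1)
    filtered = filtered.sort_values(["cell_type", "fdr", "gene"]).reset_index(drop=True)
    return full, filtered


def condition_de(
    norm: NormMatrix, cell_types, condition, th: DEThresholds = None
):
    """Per-type diabetic-vs-control screen.

    Returns (full table, significant table).  Significance is FDR <=
    de_fdr and |log2FC| >= de_log2fc; the ``direction`` column records
    up (diabetic-elevated) or down.
    """
    th = th or DEThresholds()
    cell_types = np.asarray(cell_types)
    condition = np.asarray(condition)
    dense = norm.dense()
    frames = []
    for t in pd.unique(cell_types):
        sel = cell_types == t
        dia = sel & (condition == "diabetic")
        ctl = sel & (condition == "control")
        if dia.sum() < th.min_cells or ctl.sum() < th.min_cells:
            warnings.warn(f"type {t!r}: fewer than {th.min_cells} cells in a condition; skipped")
            continue
        mi, mo, pi, po, p, lfc = _group_stats(dense[:, dia], dense[:, ctl])
        frames.append(pd.DataFrame({
            "cell_type": t, "gene": norm.gene_ids, "log2fc": lfc,
            "pct_diabetic": pi, "pct_control": po, "p": p, "fdr": bh_fdr(p),
        }))
    if not frames:
        raise ValidationError("no cell type has enough cells in both conditions")
    full = pd.concat(frames, ignore_index=True)
    full["direction"] = np.where(full["log2fc"] >= 0, "up", "down")
    sig = full[
        (full["fdr"] <= th.de_fdr) & (full["log2fc"].abs() >= th.de_log2fc)
    ].sort_values(["cell_type", "fdr", "gene"]).reset_index(drop=True)
    return full, sig


def de_counts_by_type(sig: pd.DataFrame) -> pd.DataFrame:
    """Up/down significant-gene counts per cell type (lollipop-plot tallies)."""
    out = (
        sig.groupby(["cell_type", "direction"], observed=True)["gene"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
    )
    out.columns.name = None
    return out.reset_index()


@dataclass
class UniDegResult:
    """Per-type unique DE genes with their share of the uni-DEG total."""

    per_type: dict          # cell_type -> set of genes
    total: int
    percentages: dict       # cell_type -> share of total, in percent

    def top_share(self, k: int = 5) -> float:
        """Summed percentage of the k types with the most uni-DEGs."""
        return float(sum(sorted(self.percentages.values(), reverse=True)[:k]))


def compute_unidegs(sig: pd.DataFrame) -> UniDegResult:
    """Genes significant in exactly one cell type's condition contrast."""
    types = list(pd.unique(sig["cell_type"]))
    gene_types = sig.groupby("gene")["cell_type"].nunique()
    uni_genes = set(gene_types[gene_types == 1].index)
    per_type = {
        t: set(sig.loc[(sig["cell_type"] == t) & sig["gene"].isin(uni_genes), "gene"])
        for t in types
    }
    total = sum(len(v) for v in per_type.values())
    pct = {
        t: (100.0 * len(v) / total if total else 0.0) for t, v in per_type.items()
    }
    return UniDegResult(per_type=per_type, total=total, percentages=pct)


def upregulated_unidegs(sig: pd.DataFrame, unidegs: UniDegResult, cell_type: str) -> set:
    """The focal type's uni-DEGs restricted to the up direction."""
    up = set(sig.loc[
        (sig["cell_type"] == cell_type) & (sig["direction"] == "up"), "gene"
    ])
    return unidegs.per_type.get(cell_type, set()) & up
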
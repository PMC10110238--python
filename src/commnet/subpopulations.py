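"""Focal-type subclustering and bootstrap-supported profile dendrograms.

The focal population (fibroblasts in the motivating study) is re-clustered
on its own highly variable genes, and subpopulation relatedness is assessed
by average-linkage hierarchical clustering of mean expression profiles on
correlation distance (1 - Pearson r), with branch support estimated by
resampling genes with replacement.  The support of a branch is the fraction
of bootstrap trees containing the same leaf bipartition (ordinary, single-
scale bootstrap proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .datamodel import CellAnnotation, ValidationError
from .qc_cluster import NormMatrix, cluster_cells, run_pca, select_hvg


def subcluster(
    norm: NormMatrix,
    ann: CellAnnotation,
    focal_type: str,
    resolution: float = 1.0,
    seed: int = 0,
    n_hvg: int = 500,
    n_pcs: int = 20,
    k: int = 20,
    min_cells: int = 50,
):
    """Re-cluster the focal type's cells; returns (labels Series, summary).

    Labels are size-ordered integers indexed by barcode; the summary frame
    counts cells per subcluster and condition.
    """
    mask = (ann.frame["cell_type"] == focal_type).to_numpy()
    if mask.sum() < min_cells:
        raise ValidationError(
            f"{focal_type!r} has {int(mask.sum())} cells; need >= {min_cells}"
        )
    sub = norm.subset_cells(mask)
    hvg = select_hvg(sub, min(n_hvg, sub.n_genes))
    emb = run_pca(sub, hvg, n_pcs)
    labels = cluster_cells(emb, resolution=resolution, seed=seed, k=min(k, sub.n_cells - 1))
    series = pd.Series(labels, index=sub.cell_ids, name="subcluster")
    summary = (
        pd.DataFrame({
            "subcluster": labels,
            "condition": ann.frame.loc[list(sub.cell_ids), "condition"].to_numpy(),
        })
        .value_counts()
        .unstack(fill_value=0)
        .sort_index()
        .reset_index()
    )
    return series, summary


def subpop_profiles(norm: NormMatrix, labels: pd.Series, genes=None) -> pd.DataFrame:
    """Mean log-normalized profile per subpopulation (subpops x genes)."""
    cells = list(labels.index)
    idx = {c: i for i, c in enumerate(norm.cell_ids)}
    cols = np.array([idx[c] for c in cells])
    dense = np.asarray(norm.values[:, cols].todense())
    frame = pd.DataFrame(dense.T, index=cells, columns=norm.gene_ids)
    if genes is not None:
        frame = frame[list(genes)]
    prof = frame.groupby(labels).mean()
    prof.index = [str(i) for i in prof.index]
    return prof


def profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between subpopulation mean profiles."""
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    sd = profiles.std(axis=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValidationError(f"constant profile for subcluster {flat.index[0]!r}")
    corr = np.corrcoef(profiles.to_numpy())
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


def _linkage(profiles: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return sch.average(squareform(dist, checks=False))


def _bipartitions(linkage: np.ndarray, n_leaves: int) -> set:
    """Non-trivial leaf bipartitions, each as the smaller-side frozenset."""
    members = {i: frozenset([i]) for i in range(n_leaves)}
    out = set()
    for step, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n_leaves + step] = merged
        if 1 < len(merged) < n_leaves:
            side = merged if len(merged) <= n_leaves - len(merged) else \
                frozenset(range(n_leaves)) - merged
            out.add(side)
    return out


@dataclass
class Dendrogram:
    """Average-linkage merge tree with bootstrap branch supports."""

    linkage: np.ndarray
    labels: list
    supports: dict            # frozenset of leaf indices -> support in [0, 1]
    n_boot: int
    linkage_method: str = "average"

    def support_for(self, leaf_names) -> float:
        """Support of the bipartition isolating the named leaves."""
        idx = frozenset(self.labels.index(l) for l in leaf_names)
        n = len(self.labels)
        side = idx if len(idx) <= n - len(idx) else frozenset(range(n)) - idx
        return self.supports.get(side, 0.0)

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            leaves = frozenset(node.pre_order(lambda n: n.id))
            n = len(self.labels)
            side = leaves if len(leaves) <= n - len(leaves) else \
                frozenset(range(n)) - leaves
            label = ""
            if 1 < len(leaves) < n:
                label = f"{self.supports.get(side, 0.0):.3f}"
            return f"({left},{right}){label}:{length:.6f}"

        root = walk(tree, tree.dist)
        return root + ";"


def hclust_bootstrap(
    profiles: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> Dendrogram:
    """Correlation-distance average-linkage tree with gene-bootstrap supports."""
    if n_boot < 100:
        raise ValidationError("n_boot < 100 gives unstable supports")
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    x = profiles.to_numpy(dtype=float)
    n_leaves, n_genes = x.shape
    base = _linkage(x)
    base_parts = _bipartitions(base, n_leaves)
    counts = {part: 0 for part in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, n_genes, size=n_genes)
        xb = x[:, cols]
        if np.any(xb.std(axis=1) == 0):
            continue
        parts = _bipartitions(_linkage(xb), n_leaves)
        for part in base_parts:
            if part in parts:
                counts[part] += 1
    supports = {part: c / n_boot for part, c in counts.items()}
    return Dendrogram(
        linkage=base, labels=list(profiles.index), supports=supports, n_boot=n_boot
    )
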
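"""Nucleus-level QC, normalization, HVG selection, PCA and graph clustering.

QC drops any nucleus with <500 or >4000 detected genes, >8000 UMIs, or a
mitochondrial count fraction above 10% (gene prefix ``mt-`` by default).
Normalization is counts-per-10,000 followed by log1p — the de facto
convention of the droplet toolchain.  Clustering is Leiden community
detection on a k-nearest-neighbour graph over the PCA embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datamodel import (
    UNASSIGNED,
    CellAnnotation,
    CountMatrix,
    ValidationError,
)


@dataclass
class QCThresholds:
    min_genes: int = 500
    max_genes: int = 4000
    max_umis: int = 8000
    max_mito_fraction: float = 0.10
    mito_gene_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValidationError("need 0 < min_genes < max_genes")
        if self.max_umis <= 0:
            raise ValidationError("max_umis must be positive")
        if not (0 < self.max_mito_fraction <= 1):
            raise ValidationError("max_mito_fraction must be in (0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_min_genes: int
    removed_max_genes: int
    removed_max_umis: int
    removed_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [
                    "input", "retained", "min_genes", "max_genes", "max_umis", "mito",
                ],
                "cells": [
                    self.n_input, self.n_retained, self.removed_min_genes,
                    self.removed_max_genes, self.removed_max_umis, self.removed_mito,
                ],
            }
        )


def qc_filter(counts: CountMatrix, ann: CellAnnotation, th: QCThresholds = None):
    """Apply the nucleus QC rules; returns (counts, annotation, report).

    A cell failing several criteria is removed once but counted under every
    criterion it trips.
    """
    th = th or QCThresholds()
    genes = counts.genes_per_cell()
    umis = counts.counts_per_cell()
    mito_mask = np.array(
        [str(g).startswith(th.mito_gene_prefix) for g in counts.gene_ids]
    )
    mito = np.asarray(counts.values[mito_mask, :].sum(axis=0)).ravel() if mito_mask.any() \
        else np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, mito / np.maximum(umis, 1), 1.0)

    too_few = genes < th.min_genes
    too_many = genes > th.max_genes
    too_deep = umis > th.max_umis
    too_mito = mito_frac > th.max_mito_fraction
    bad = too_few | too_many | too_deep | too_mito

    report = QCReport(
        n_input=counts.n_cells,
        n_retained=int((~bad).sum()),
        removed_min_genes=int(too_few.sum()),
        removed_max_genes=int(too_many.sum()),
        removed_max_umis=int(too_deep.sum()),
        removed_mito=int(too_mito.sum()),
    )
    if report.n_retained == 0:
        raise ValidationError(
            "no cells survive QC; review thresholds against this dataset"
        )
    kept = counts.subset_cells(~bad)
    return kept, ann.for_cells(kept.cell_ids), report


@dataclass
class NormMatrix:
    """Genes x cells log-normalized expression (CP-``scale_factor`` + log1p)."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask) -> "NormMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return NormMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx],
                          self.scale_factor)


def normalize_log(counts: CountMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """Depth-normalize each cell to ``scale_factor`` counts, then log1p."""
    totals = counts.counts_per_cell()
    if (totals == 0).any():
        raise ValidationError(
            f"{int((totals == 0).sum())} cell(s) with zero counts; run QC first"
        )
    scale = scale_factor / totals
    x = counts.values.astype(float).multiply(scale[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return NormMatrix(x, counts.gene_ids, counts.cell_ids, scale_factor)


def select_hvg(norm: NormMatrix, n_hvg: int) -> list:
    """Top ``n_hvg`` genes by binned normalized dispersion.

    Dispersion = var/mean of the back-transformed (expm1) normalized values,
    z-scored within 20 mean-abundance bins.  Deterministic; ties broken by
    gene symbol.  Genes with zero variance never outrank a variable gene.
    """
    if n_hvg > norm.n_genes:
        raise ValidationError(f"n_hvg={n_hvg} exceeds {norm.n_genes} genes")
    x = norm.values.copy()
    x.data = np.expm1(x.data)
    mean = np.asarray(x.mean(axis=1)).ravel()
    sq = x.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var *= norm.n_cells / max(norm.n_cells - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    order_mean = pd.Series(mean)
    bins = pd.cut(order_mean.rank(method="first"), bins=20, labels=False)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    z[var <= 0] = -np.inf  # constant genes last, always

    df = pd.DataFrame({"gene": norm.gene_ids, "z": z})
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n_hvg).tolist()


@dataclass
class Embedding:
    """Cells x components PCA coordinates with variance shares."""

    coords: np.ndarray
    variance_ratio: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_ratio) > 1e-12):
            raise ValidationError("variance shares must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def run_pca(norm: NormMatrix, genes, n_components: int) -> Embedding:
    """Centered, per-gene unit-scaled PCA over the selected genes.

    Component signs are fixed so each component's largest-magnitude gene
    loading is positive.
    """
    if norm.n_cells < 2:
        raise ValidationError("PCA needs at least two cells")
    gi = norm.gene_index()
    idx = np.array([gi[g] for g in genes], dtype=int)
    n_components = min(n_components, len(idx), norm.n_cells - 1)
    x = np.asarray(norm.values[idx, :].todense()).T  # cells x genes
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    flip = np.sign(pca.components_[np.arange(n_components),
                                   np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords *= flip[None, :]
    return Embedding(coords, pca.explained_variance_ratio_.copy(), norm.cell_ids)


def choose_n_pcs(emb: Embedding, frac: float = 0.05, floor: int = 10) -> int:
    """Elbow rule on the variance-share curve.

    The elbow is the smallest k after which the curve is flat: the first k
    such that the drop from share k+1 to share k+2 falls below ``frac``
    times the total drop across the curve.  Never returns less than
    ``floor`` components when that many exist.
    """
    s = np.asarray(emb.variance_ratio, dtype=float)
    m = len(s)
    if m < 3:
        return m
    total_drop = s[0] - s[-1]
    thresh = frac * total_drop
    elbow = m
    for k in range(1, m - 1):  # 1-based component index
        if s[k] - s[k + 1] < thresh:
            elbow = k
            break
    return min(m, max(elbow, min(floor, m)))


def cluster_cells(
    emb: Embedding,
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 20,
    n_components: int = None,
) -> np.ndarray:
    """Leiden modularity clustering on a kNN graph of the embedding.

    Returns integer labels relabeled by decreasing cluster size.
    """
    import igraph as ig
    import leidenalg

    coords = emb.coords if n_components is None else emb.coords[:, :n_components]
    n = coords.shape[0]
    if n <= k:
        raise ValidationError(f"{n} cells but k={k} neighbours; use a smaller k")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, ind = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in ind[i, 1:]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return np.array([remap[v] for v in labels], dtype=int)


def annotate_types(
    labels: np.ndarray,
    marker_map: dict,
    norm: NormMatrix,
    ann: CellAnnotation = None,
):
    """Assign each cluster the type whose canonical markers score highest.

    Marker genes are z-scored across cells; a cluster's score for a type is
    the mean z of that type's markers over the cluster's cells.  A cluster
    in which no marker of any type is expressed stays ``unassigned``.
    Returns (cell_type array, cluster->type map) or, if ``ann`` is given, an
    updated CellAnnotation.
    """
    if not marker_map:
        raise ValidationError("empty marker map")
    gi = norm.gene_index()
    dense_cache: dict = {}

    def gene_row(g):
        if g not in dense_cache:
            dense_cache[g] = np.asarray(norm.values[gi[g], :].todense()).ravel()
        return dense_cache[g]

    cluster_type: dict = {}
    for c in np.unique(labels):
        in_c = labels == c
        best, best_score = [], -np.inf
        any_expressed = False
        for t, genes in marker_map.items():
            present = [g for g in genes if g in gi]
            if not present:
                continue
            zs = []
            for g in present:
                row = gene_row(g)
                if row[in_c].sum() > 0:
                    any_expressed = True
                sd = row.std()
                zs.append((row[in_c].mean() - row.mean()) / sd if sd > 0 else 0.0)
            score = float(np.mean(zs))
            if score > best_score + 1e-12:
                best, best_score = [t], score
            elif abs(score - best_score) <= 1e-12:
                best.append(t)
        if not any_expressed or not best:
            cluster_type[int(c)] = UNASSIGNED
            continue
        if len(best) > 1:
            warnings.warn(
                f"cluster {c}: tie between {sorted(best)}; taking alphabetical first"
            )
        cluster_type[int(c)] = sorted(best)[0]

    cell_type = np.array([cluster_type[int(c)] for c in labels], dtype=object)
    if ann is not None:
        out = ann.with_column("cluster_id", labels)
        out = out.with_column("cell_type", cell_type)
        return out, cluster_type
    return cell_type, cluster_type
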
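"""Shared data model for the communication-analysis pipeline.

Gene identity throughout is the bare, case-sensitive symbol string; no
alias or ortholog mapping is attempted, so a mis-cased symbol simply fails
to join.  Count matrices are stored genes x cells in CSR sparse form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("control", "diabetic")
UNASSIGNED = "unassigned"


class CommnetError(Exception):
    """Base class for package errors."""


class FormatError(CommnetError):
    """A file does not conform to its declared external format."""


class ValidationError(CommnetError):
    """Parsed or constructed data violates a type invariant."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts.

    Invariants enforced on construction: entries are non-negative integers,
    gene and cell identifiers are unique and match the matrix dimensions.
    Duplicate gene symbols must be collapsed (summed) before construction;
    the readers in :mod:`commnet.io` do this.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene symbols (collapse before construction)")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entry")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with at least one count, per cell."""
        return np.diff(self.values.tocsc().indptr)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, genes) -> "CountMatrix":
        gi = self.gene_index()
        idx = np.array([gi[g] for g in genes], dtype=int)
        return CountMatrix(self.values[idx, :], self.gene_ids[idx], self.cell_ids)


@dataclass
class CellAnnotation:
    """Per-cell metadata: sample, condition and (once assigned) type/cluster.

    Backed by a DataFrame indexed by barcode with columns
    ``sample_id``, ``condition``, ``cell_type``, ``cluster_id``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if df.index.name != "cell_id":
            if "cell_id" in df.columns:
                df = df.set_index("cell_id")
            else:
                df.index.name = "cell_id"
        for col, default in (
            ("sample_id", "sample"),
            ("condition", CONDITIONS[0]),
            ("cell_type", UNASSIGNED),
            ("cluster_id", -1),
        ):
            if col not in df.columns:
                df[col] = default
        if df.index.duplicated().any():
            raise ValidationError("duplicate cell_id in annotation")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        self.frame = df

    @property
    def cell_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=object)

    def for_cells(self, cell_ids) -> "CellAnnotation":
        return CellAnnotation(self.frame.loc[list(cell_ids)].copy())

    def with_column(self, name: str, values) -> "CellAnnotation":
        df = self.frame.copy()
        df[name] = values
        return CellAnnotation(df)


@dataclass
class LigandReceptorTable:
    """Directed (ligand gene -> receptor gene) reference pairs."""

    pairs: list

    def __post_init__(self) -> None:
        seen, uniq = set(), []
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValidationError("empty gene symbol in ligand-receptor pair")
            key = (str(lig), str(rec))
            if key not in seen:
                seen.add(key)
                uniq.append(key)
        if not uniq:
            raise ValidationError("ligand-receptor table has no pairs")
        self.pairs = uniq

    @property
    def ligand_set(self) -> set:
        return {l for l, _ in self.pairs}

    @property
    def receptor_set(self) -> set:
        return {r for _, r in self.pairs}

    def ligands_of(self, receptor: str) -> list:
        return [l for l, r in self.pairs if r == receptor]


@dataclass
class EdgeList:
    """Undirected gene-gene edges with optional confidence scores in [0, 1].

    Self-loops are dropped (counted in ``n_self_loops``); duplicate edges are
    collapsed keeping the maximum score.
    """

    edges: dict = field(default_factory=dict)
    n_self_loops: int = 0

    @classmethod
    def from_pairs(cls, pairs) -> "EdgeList":
        edges: dict = {}
        loops = 0
        for item in pairs:
            a, b = item[0], item[1]
            score = item[2] if len(item) > 2 else None
            if a == b:
                loops += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in edges:
                old = edges[key]
                if score is not None and (old is None or score > old):
                    edges[key] = score
            else:
                edges[key] = score
        if loops:
            warnings.warn(f"dropped {loops} self-loop edge(s)")
        return cls(edges=edges, n_self_loops=loops)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_set(self) -> set:
        nodes: set = set()
        for a, b in self.edges:
            nodes.add(a)
            nodes.add(b)
        return nodes


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from GMT) with optional descriptions."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = set(genes)

    def __len__(self) -> int:
        return len(self.sets)
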
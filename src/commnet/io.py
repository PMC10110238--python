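"""Readers and writers for the external formats the pipeline touches.

Counts travel as Matrix Market coordinate files with one-per-line
``features.tsv`` / ``barcodes.tsv`` sidecars (the droplet-pipeline
convention); everything else is headered TSV/CSV, gene sets are GMT.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import (
    CellAnnotation,
    CountMatrix,
    EdgeList,
    FormatError,
    GeneSetCollection,
    LigandReceptorTable,
    ValidationError,
)


def _read_lines(path) -> list:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a genes x cells Matrix Market count matrix with sidecar files.

    Duplicate gene symbols are collapsed by summation, keeping the order of
    first occurrence.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - rewrap with file name
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    genes = _read_lines(features_path)
    cells = _read_lines(barcodes_path)
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{features_path}: {len(genes)} features for {mat.shape[0]} matrix rows"
        )
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(cells)} barcodes for {mat.shape[1]} matrix columns"
        )
    if mat.data.size and (mat.data.min() < 0 or not np.allclose(mat.data, np.round(mat.data))):
        raise ValidationError(f"{matrix_path}: negative or non-integer count entries")
    genes_arr = np.asarray(genes, dtype=object)
    if len(set(genes)) != len(genes):
        first = pd.unique(genes_arr)
        pos = {g: i for i, g in enumerate(first)}
        rows = np.array([pos[g] for g in genes])
        collapse = sp.csr_matrix(
            (np.ones(len(genes)), (rows, np.arange(len(genes)))),
            shape=(len(first), len(genes)),
        )
        mat = sp.csr_matrix(collapse @ mat)
        genes_arr = first
    return CountMatrix(mat, genes_arr, np.asarray(cells, dtype=object))


def write_counts_mtx(counts: CountMatrix, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), counts.values.tocoo(), field="integer")
    (out / "features.tsv").write_text("\n".join(map(str, counts.gene_ids)) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(map(str, counts.cell_ids)) + "\n")


def read_cell_metadata(path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'cell_id'")
    return CellAnnotation(df)


def write_cell_metadata(ann: CellAnnotation, path) -> None:
    ann.frame.reset_index().to_csv(path, sep="\t", index=False)


def read_lr_table(path) -> LigandReceptorTable:
    """Read a ligand-receptor pair table with header columns ligand/receptor."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "ligand" not in cols or "receptor" not in cols:
        raise FormatError(f"{path}: requires 'ligand' and 'receptor' columns")
    pairs = list(zip(df[cols["ligand"]].astype(str), df[cols["receptor"]].astype(str)))
    if not pairs:
        raise ValidationError(f"{path}: no ligand-receptor pairs parsed")
    return LigandReceptorTable(pairs)


def write_lr_table(lr: LigandReceptorTable, path) -> None:
    pd.DataFrame(lr.pairs, columns=["ligand", "receptor"]).to_csv(path, sep="\t", index=False)


def read_ppi_edges(path) -> EdgeList:
    """Read a tab-separated PPI edge list (gene_a, gene_b[, score])."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["gene_a", "gene_b"]:
                continue  # optional header
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected two gene columns")
            if len(parts) >= 3 and parts[2] != "":
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
                pairs.append((parts[0], parts[1], score))
            else:
                pairs.append((parts[0], parts[1]))
    if not pairs:
        warnings.warn(f"{path}: empty PPI edge list")
    return EdgeList.from_pairs(pairs)


def write_ppi_edges(edges: EdgeList, path) -> None:
    rows = [
        (a, b, "" if s is None else s) for (a, b), s in sorted(edges.edges.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path) -> GeneSetCollection:
    """Read GMT gene sets; later duplicate names get a numeric suffix."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                k = 2
                while f"{name}_{k}" in sets:
                    k += 1
                warnings.warn(f"{path}:{lineno}: duplicate set {name!r} stored as {name}_{k}")
                name = f"{name}_{k}"
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
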
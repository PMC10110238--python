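"""Ligand-receptor connection networks and the driver-gene screen.

A *connection* is one ligand-receptor pair whose ligand is expressed in a
sender population and whose receptor is expressed in a receiver population;
the sender x receiver matrix of such counts is built per condition and
differenced.  "Expressed" uses a detection-fraction rule (count > 0 in more
than ``min_fraction`` of the population's cells, default 20%); an
alternative "specific" mode defines a population's genes by the
cell-type-specific screen (FDR <= 0.01, log2FC >= 1).

The driver screen selects the focal type's specific receptors whose cognate
ligands are condition-upregulated in at least one sender population, and
merges them with the focal type's upregulated uni-DEGs; the merged set is
the input to PPI hub ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import LigandReceptorTable, ValidationError
from .differential import UniDegResult
from .qc_cluster import NormMatrix


def expressed_genes(
    norm: NormMatrix, cell_types, min_fraction: float = 0.20, cells_mask=None
) -> dict:
    """Per-type sets of genes detected in more than ``min_fraction`` of cells."""
    cell_types = np.asarray(cell_types)
    detected = norm.values.copy()
    detected.data = (detected.data > 0).astype(float)
    out: dict = {}
    for t in pd.unique(cell_types):
        sel = cell_types == t
        if cells_mask is not None:
            sel = sel & np.asarray(cells_mask)
        if not sel.any():
            out[t] = set()
            continue
        frac = np.asarray(detected[:, np.flatnonzero(sel)].mean(axis=1)).ravel()
        out[t] = set(norm.gene_ids[frac > min_fraction])
    return out


@dataclass
class ConnectionMatrix:
    """Sender x receiver counts of active ligand-receptor pairs."""

    counts: pd.DataFrame                 # senders (rows) x receivers (cols)
    contributing_pairs: dict             # (sender, receiver) -> [(ligand, receptor)]
    condition: str = ""

    @property
    def types(self) -> list:
        return list(self.counts.index)


def build_connection_matrix(
    expressed_sets: dict, lr: LigandReceptorTable, condition: str = ""
) -> ConnectionMatrix:
    """Count LR pairs with ligand expressed in sender, receptor in receiver.

    The autocrine diagonal (sender == receiver) is included.
    """
    if not lr.pairs:
        raise ValidationError("empty ligand-receptor table")
    types = sorted(expressed_sets)
    counts = pd.DataFrame(0, index=types, columns=types, dtype=int)
    pairs: dict = {(s, r): [] for s in types for r in types}
    for lig, rec in lr.pairs:
        senders = [t for t in types if lig in expressed_sets[t]]
        receivers = [t for t in types if rec in expressed_sets[t]]
        for s in senders:
            for r in receivers:
                counts.loc[s, r] += 1
                pairs[(s, r)].append((lig, rec))
    return ConnectionMatrix(counts=counts, contributing_pairs=pairs, condition=condition)


def total_connections(cm: ConnectionMatrix) -> pd.Series:
    """Connections made by each type, autocrine pairs counted once."""
    c = cm.counts
    return c.sum(axis=1) + c.sum(axis=0) - pd.Series(np.diag(c), index=c.index)


def compare_conditions(cm_control: ConnectionMatrix, cm_diabetic: ConnectionMatrix):
    """Diabetic minus control deltas; returns (delta matrix, delta totals, argmax type)."""
    if list(cm_control.counts.index) != list(cm_diabetic.counts.index):
        raise ValidationError("connection matrices cover different type universes")
    delta = cm_diabetic.counts - cm_control.counts
    delta_tot = total_connections(cm_diabetic) - total_connections(cm_control)
    return delta, delta_tot, delta_tot.idxmax()


def de_ligand_receptor_tally(sig_de: pd.DataFrame, lr: LigandReceptorTable) -> pd.DataFrame:
    """Per-type counts of up/down-regulated ligands and receptors.

    A gene that is both a ligand and a receptor contributes to both tallies.
    """
    lig, rec = lr.ligand_set, lr.receptor_set
    rows = []
    for t in pd.unique(sig_de["cell_type"]) if len(sig_de) else []:
        sub = sig_de[sig_de["cell_type"] == t]
        up = set(sub.loc[sub["direction"] == "up", "gene"])
        down = set(sub.loc[sub["direction"] == "down", "gene"])
        rows.append({
            "cell_type": t,
            "up_ligands": len(up & lig), "up_receptors": len(up & rec),
            "down_ligands": len(down & lig), "down_receptors": len(down & rec),
        })
    return pd.DataFrame(rows, columns=[
        "cell_type", "up_ligands", "up_receptors", "down_ligands", "down_receptors",
    ])


def cognate_ligand_screen(
    receptor: str, lr: LigandReceptorTable, sig_de: pd.DataFrame
) -> pd.DataFrame:
    """Condition-upregulated cognate ligands of a receptor, with evidence.

    One row per (sender type, ligand) where the ligand is paired to the
    receptor and passed the condition-DE filter upward in that type.
    """
    if receptor not in lr.receptor_set:
        raise ValidationError(f"receptor {receptor!r} absent from the LR reference")
    ligands = set(lr.ligands_of(receptor))
    hits = sig_de[
        sig_de["gene"].isin(ligands) & (sig_de["direction"] == "up")
    ]
    out = hits[["cell_type", "gene", "log2fc", "fdr"]].rename(
        columns={"cell_type": "sender_type", "gene": "ligand"}
    )
    return out.sort_values(["ligand", "sender_type"]).reset_index(drop=True)


@dataclass
class DriverGeneSet:
    """Output of the driver screen for one focal type."""

    focal_type: str
    receptors_with_up_ligands: list      # (receptor, [(sender, ligand, log2fc, fdr)])
    upregulated_unidegs: set
    merged_set: set = field(default_factory=set)

    def __post_init__(self) -> None:
        kept = {r for r, ev in self.receptors_with_up_ligands if ev}
        self.merged_set = set(self.upregulated_unidegs) | kept

    def evidence_frame(self) -> pd.DataFrame:
        rows = []
        for rec, evidence in self.receptors_with_up_ligands:
            for sender, lig, lfc, fdr in evidence:
                rows.append({"receptor": rec, "sender_type": sender,
                             "ligand": lig, "log2fc": lfc, "fdr": fdr})
        return pd.DataFrame(rows, columns=["receptor", "sender_type", "ligand",
                                           "log2fc", "fdr"])


def driver_screen(
    focal_type: str,
    specific: pd.DataFrame,
    sig_de: pd.DataFrame,
    unidegs: UniDegResult,
    lr: LigandReceptorTable,
    known_types=None,
) -> DriverGeneSet:
    """Focal-type receptor/uni-DEG merge used as the PPI hub input.

    Receptors = the focal type's specific genes that are receptors in the
    LR reference; only receptors with at least one condition-upregulated
    cognate ligand (in any sender type) are kept.  ``known_types`` (the
    annotation's type universe) guards against a mistyped focal type; when
    omitted, the filtered tables' own types are used, so a focal type with
    no hits anywhere is treated as empty rather than unknown.
    """
    if known_types is not None:
        if focal_type not in set(known_types):
            raise ValidationError(f"unknown focal type {focal_type!r}")
    else:
        seen = set(specific["cell_type"]) | set(unidegs.per_type)
        if seen and focal_type not in seen and focal_type not in set(sig_de["cell_type"]):
            raise ValidationError(f"focal type {focal_type!r} absent from upstream tables")
    focal_specific = set(
        specific.loc[specific["cell_type"] == focal_type, "gene"]
    )
    receptors = sorted(focal_specific & lr.receptor_set)
    with_evidence = []
    for rec in receptors:
        ev_frame = cognate_ligand_screen(rec, lr, sig_de)
        evidence = [
            (row.sender_type, row.ligand, float(row.log2fc), float(row.fdr))
            for row in ev_frame.itertuples()
        ]
        if evidence:
            with_evidence.append((rec, evidence))
    from .differential import upregulated_unidegs

    up_uni = upregulated_unidegs(sig_de, unidegs, focal_type)
    return DriverGeneSet(
        focal_type=focal_type,
        receptors_with_up_ligands=with_evidence,
        upregulated_unidegs=up_uni,
    )
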
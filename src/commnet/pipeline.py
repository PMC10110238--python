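"""End-to-end orchestration: simulate/load -> QC -> cluster -> annotate ->
differential screens -> communication networks -> driver screen -> PPI hubs
-> subpopulations -> ORA, with a JSON run report carrying content hashes,
seeds and thresholds for every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .communication import (
    build_connection_matrix,
    compare_conditions,
    de_ligand_receptor_tally,
    driver_screen,
    expressed_genes,
    total_connections,
)
from .datamodel import CommnetError, ValidationError
from .differential import (
    DEThresholds,
    compute_unidegs,
    condition_de,
    de_counts_by_type,
    find_cluster_markers,
    find_specific_genes,
    upregulated_unidegs,
)
from .enrichment import ora
from .network_hubs import induced_subgraph, rank_hubs
from .qc_cluster import (
    QCThresholds,
    annotate_types,
    choose_n_pcs,
    cluster_cells,
    normalize_log,
    run_pca,
    select_hvg,
)
from .subpopulations import (
    hclust_bootstrap,
    profile_correlation,
    subcluster,
    subpop_profiles,
)
from .synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_gene_sets,
    generate_lr_reference,
    generate_ppi,
)

STAGES = (
    "simulate", "qc", "cluster", "annotate", "differential",
    "connections", "drivers", "hubs", "subpop", "ora",
)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds, with the study's defaults."""

    # input: synthetic simulation by default, or explicit file paths
    synthetic: bool = True
    counts_dir: str = ""          # dir holding matrix.mtx/features.tsv/barcodes.tsv
    metadata_path: str = ""
    lr_path: str = ""
    ppi_path: str = ""
    gmt_path: str = ""
    marker_map: dict = field(default_factory=dict)   # type -> canonical markers
    # QC
    min_genes: int = 500
    max_genes: int = 4000
    max_umis: int = 8000
    max_mito: float = 0.10
    mito_prefix: str = "mt-"
    # clustering
    n_hvg: int = 2000
    n_pcs: int = 50
    resolution: float = 1.0
    knn: int = 20
    # screens
    marker_fold: float = 1.28
    marker_pct: float = 0.25
    marker_fdr: float = 0.05
    specific_fdr: float = 0.01
    specific_log2fc: float = 1.0
    de_fdr: float = 0.05
    de_log2fc: float = 0.36
    ora_fdr: float = 0.05
    # communication
    min_fraction: float = 0.20
    focal_type: str = "fibroblast"
    hub_k: int = 15
    # subpopulations
    subpop_resolution: float = 0.5
    n_boot: int = 1000
    # randomness
    seed: int = 0
    synthetic_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def de_thresholds(self) -> DEThresholds:
        return DEThresholds(
            marker_fold=self.marker_fold, marker_min_pct=self.marker_pct,
            marker_fdr=self.marker_fdr, specific_fdr=self.specific_fdr,
            specific_log2fc=self.specific_log2fc, de_fdr=self.de_fdr,
            de_log2fc=self.de_log2fc,
        )

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_genes=self.min_genes, max_genes=self.max_genes,
            max_umis=self.max_umis, max_mito_fraction=self.max_mito,
            mito_gene_prefix=self.mito_prefix,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Artifact writer that records a content hash for everything written."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.artifacts: dict = {}

    def write_tsv(self, name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, sep="\t", index=index)
        self.artifacts[name] = _sha256(path)

    def write_text(self, name: str, text: str) -> None:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        self.artifacts[name] = _sha256(path)


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> dict:
    """Execute all stages in dependency order; returns the run report.

    The report (also written as ``report.json``) lists every stage, the
    thresholds and seeds in force, per-stage counts and a SHA-256 hash of
    each artifact, so two runs with the same config are byte-comparable.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise CommnetError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(out)
    report: dict = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "counts": {},
        "seed": config.seed,
    }

    current = "simulate"

    def stage(name):
        nonlocal current
        current = name

    try:
        # ---- simulate / load --------------------------------------------
        truth = None
        if config.synthetic:
            syn = SyntheticConfig(seed=config.seed, **config.synthetic_overrides)
            counts, ann, truth = generate_dataset(syn)
            lr = generate_lr_reference(syn, truth)
            ppi = generate_ppi(syn, truth)
            gene_sets = generate_gene_sets(syn, truth)
            run.write_text("truth.json",
                           json.dumps(truth.to_jsonable(), sort_keys=True))
        else:
            d = Path(config.counts_dir)
            counts = cio.read_counts_mtx(
                d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
            )
            ann = cio.read_cell_metadata(config.metadata_path).for_cells(counts.cell_ids)
            lr = cio.read_lr_table(config.lr_path)
            ppi = cio.read_ppi_edges(config.ppi_path) if config.ppi_path else None
            gene_sets = cio.read_gmt(config.gmt_path) if config.gmt_path else None
        report["stages"].append("simulate")
        report["counts"]["input_cells"] = counts.n_cells
        report["counts"]["input_genes"] = counts.n_genes

        # ---- qc ----------------------------------------------------------
        stage("qc")
        from .qc_cluster import qc_filter

        counts, ann, qc_report = qc_filter(counts, ann, config.qc_thresholds())
        run.write_tsv("qc_report.tsv", qc_report.to_frame())
        report["stages"].append("qc")
        report["counts"]["qc_cells"] = counts.n_cells

        # ---- cluster ------------------------------------------------------
        stage("cluster")
        norm = normalize_log(counts)
        hvg = select_hvg(norm, min(config.n_hvg, norm.n_genes))
        emb = run_pca(norm, hvg, config.n_pcs)
        n_pcs = choose_n_pcs(emb)
        labels = cluster_cells(
            emb, resolution=config.resolution, seed=config.seed,
            k=config.knn, n_components=n_pcs,
        )
        run.write_tsv("clusters.tsv", pd.DataFrame({
            "cell_id": norm.cell_ids, "cluster_id": labels,
        }))
        report["stages"].append("cluster")
        report["counts"]["n_pcs"] = int(n_pcs)
        report["counts"]["n_clusters"] = int(labels.max()) + 1

        # ---- annotate -----------------------------------------------------
        stage("annotate")
        marker_map = dict(config.marker_map)
        if not marker_map and truth is not None:
            marker_map = {t: list(g[:3]) for t, g in truth.markers.items() if g}
        if marker_map:
            ann, cluster_type = annotate_types(labels, marker_map, norm, ann)
        else:
            ann = ann.with_column("cluster_id", labels)
            ann = ann.with_column("cell_type", [str(c) for c in labels])
            cluster_type = {int(c): str(c) for c in np.unique(labels)}
        cell_types = ann.frame["cell_type"].to_numpy()
        condition = ann.frame["condition"].to_numpy()
        cio.write_cell_metadata(ann, run.out_dir / "annotation.tsv")
        run.artifacts["annotation.tsv"] = _sha256(run.out_dir / "annotation.tsv")
        report["stages"].append("annotate")
        report["cluster_types"] = {str(k): v for k, v in cluster_type.items()}

        # ---- differential: markers, condition DE, uni-DEGs ---------------
        stage("differential")
        th = config.de_thresholds()
        markers_full, markers = find_cluster_markers(norm, labels, th)
        specific_full, specific = find_specific_genes(norm, cell_types, th)
        de_full, sig_de = condition_de(norm, cell_types, condition, th)
        unidegs = compute_unidegs(sig_de)
        run.write_tsv("markers.tsv", markers)
        run.write_tsv("markers_full.tsv", markers_full)
        run.write_tsv("specific.tsv", specific)
        run.write_tsv("de.tsv", sig_de)
        run.write_tsv("de_counts.tsv", de_counts_by_type(sig_de))
        run.write_tsv("unideg.tsv", pd.DataFrame(
            [(t, g) for t, gs in unidegs.per_type.items() for g in sorted(gs)],
            columns=["cell_type", "gene"],
        ))
        report["stages"].append("differential")
        report["counts"]["n_markers"] = int(len(markers))
        report["counts"]["n_unidegs"] = unidegs.total

        # ---- connections --------------------------------------------------
        stage("connections")
        matrices = {}
        for cond in ("control", "diabetic"):
            sets = expressed_genes(
                norm, cell_types, config.min_fraction,
                cells_mask=(condition == cond),
            )
            matrices[cond] = build_connection_matrix(sets, lr, cond)
            run.write_tsv(f"connections_{cond}.tsv", matrices[cond].counts, index=True)
        delta, delta_tot, top_delta_type = compare_conditions(
            matrices["control"], matrices["diabetic"]
        )
        run.write_tsv("connections_delta.tsv", delta, index=True)
        run.write_tsv("connection_totals.tsv", pd.DataFrame({
            "cell_type": delta.index,
            "control": total_connections(matrices["control"]),
            "diabetic": total_connections(matrices["diabetic"]),
            "delta": delta_tot,
        }))
        run.write_tsv("lr_tally.tsv", de_ligand_receptor_tally(sig_de, lr))
        report["stages"].append("connections")
        report["top_delta_type"] = str(top_delta_type)

        # ---- driver screen ------------------------------------------------
        stage("drivers")
        drivers = driver_screen(config.focal_type, specific, sig_de, unidegs, lr,
                                known_types=set(cell_types))
        run.write_tsv("drivers.tsv", drivers.evidence_frame())
        report["stages"].append("drivers")
        report["driver"] = {
            "focal_type": drivers.focal_type,
            "receptors": [r for r, ev in drivers.receptors_with_up_ligands],
            "evidence": {
                r: [{"sender_type": s, "ligand": l} for s, l, _, _ in ev]
                for r, ev in drivers.receptors_with_up_ligands
            },
            "merged_set_size": len(drivers.merged_set),
        }

        # ---- PPI hubs -----------------------------------------------------
        stage("hubs")
        if ppi is not None and drivers.merged_set:
            graph = induced_subgraph(ppi, drivers.merged_set)
            hubs, degree_table = rank_hubs(graph, config.hub_k)
            run.write_tsv("hubs.tsv", degree_table)
            report["hubs"] = hubs
        else:
            report["hubs"] = []
        report["stages"].append("hubs")

        # ---- subpopulations -----------------------------------------------
        stage("subpop")
        focal_cells = int((cell_types == config.focal_type).sum())
        if focal_cells >= 50:
            sublabels, summary = subcluster(
                norm, ann, config.focal_type,
                resolution=config.subpop_resolution, seed=config.seed,
            )
            sub_hvg = select_hvg(
                norm.subset_cells(ann.frame["cell_type"].to_numpy() == config.focal_type),
                min(500, norm.n_genes),
            )
            profiles = subpop_profiles(norm, sublabels, genes=sub_hvg)
            run.write_tsv("subpop/sublabels.tsv",
                          sublabels.rename_axis("cell_id").reset_index())
            run.write_tsv("subpop/summary.tsv", summary)
            if len(profiles) >= 2:
                corr = profile_correlation(profiles)
                run.write_tsv("subpop/correlation.tsv", corr, index=True)
                dend = hclust_bootstrap(profiles, n_boot=config.n_boot,
                                        seed=config.seed)
                run.write_text("dendrogram.nwk", dend.to_newick() + "\n")
                report["subpop_supports"] = {
                    ",".join(sorted(dend.labels[i] for i in part)): s
                    for part, s in dend.supports.items()
                }
            report["counts"]["n_subclusters"] = int(sublabels.max()) + 1
        else:
            warnings.warn(
                f"{config.focal_type!r} has {focal_cells} cells; subpopulation "
                "stage skipped"
            )
            report["counts"]["n_subclusters"] = 0
        report["stages"].append("subpop")

        # ---- ORA ----------------------------------------------------------
        stage("ora")
        if gene_sets is not None:
            query = upregulated_unidegs(sig_de, unidegs, config.focal_type)
            if query:
                universe = list(norm.gene_ids)
                ora_table = ora(query, gene_sets, universe, config.ora_fdr)
                run.write_tsv("ora.tsv", ora_table)
                report["counts"]["n_enriched_sets"] = int(ora_table["significant"].sum())
            else:
                report["counts"]["n_enriched_sets"] = 0
        report["stages"].append("ora")
    except Exception as exc:
        raise CommnetError(
            f"pipeline failed at stage {current!r} [stage_error:{current}]: {exc}"
        ) from exc

    report["artifacts"] = run.artifacts
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
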
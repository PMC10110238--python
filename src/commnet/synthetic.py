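"""Two-condition, multi-cell-type negative-binomial count simulator.

The generator emulates the structure of a droplet single-nucleus experiment
on control vs diabetic mouse hearts: several cell populations per condition,
gene-wise log-normal baseline means, NB counts with cell-wise log-normal
library-size factors, a mitochondrial gene block with a controlled fraction
of each cell's counts, and planted signal with known identity:

* per-type *marker* genes with a multiplicative fold elevation in their type
  (both conditions) — the target of the marker and specific-gene screens;
* per-type condition *DE* genes elevated only in diabetic cells of their
  type — by construction these are uni-DEGs of that type;
* one *driver* ligand-receptor pair: the receptor is a marker of the focal
  (fibroblast-like) type, the cognate ligand a condition-DE gene of a sender
  type, mirroring the Pdgf(s)-Pdgfra style of evidence the screen looks for;
* optionally, sub-signatures within the focal type, one of them strongly
  divergent, for subclustering and bootstrap-outgroup analyses.

Planted genes are drawn from the moderately expressed part of the baseline
mean distribution (means in [0.5, 3]) so that markers behave like real
markers: reliably detected in their own population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import (
    CellAnnotation,
    CountMatrix,
    EdgeList,
    LigandReceptorTable,
    ValidationError,
)

CELL_TYPE_NAMES = (
    "fibroblast",
    "endothelial",
    "macrophage",
    "cardiomyocyte",
    "pericyte",
    "adipocyte",
    "smooth_muscle",
    "endocardial",
    "epicardial",
    "schwann",
)

# canonical population markers (mouse heart); the first planted markers of
# each type are renamed to these so annotation-by-marker is exercised end to
# end on familiar symbols
CANONICAL_MARKERS = {
    "fibroblast": ("Pdgfra", "Pcdh9", "Bmper"),
    "endothelial": ("Pecam1", "Ccdc85a", "Btnl9"),
    "macrophage": ("Fcgr1", "F13a1", "Adgre1"),
    "cardiomyocyte": ("Ttn", "Mhrt", "Myh6"),
    "pericyte": ("Pdgfrb", "Vtn", "Trpc3"),
    "adipocyte": ("Adipoq", "Plin1", "Tshr"),
    "smooth_muscle": ("Acta2", "Myh11", "Cdh6"),
    "endocardial": ("Npr3", "Tmem108", "Plvap"),
    "epicardial": ("Msln", "Pcdh15", "Muc16"),
    "schwann": ("Plp1", "Gfra3"),
}

MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6",
    "mt-Atp8", "mt-Cytb", "mt-Nd3", "mt-Nd4", "mt-Nd5",
)

DRIVER_RECEPTOR = "Pdgfra"
DRIVER_LIGAND = "Pdgfc"


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults are the desk-scale study conditions.

    ``baseline_mean`` is the median of the log-normal gene-mean
    distribution (counts per cell at library-size factor 1);
    ``dispersion`` is the NB size parameter (smaller = noisier).
    """

    n_cell_types: int = 5
    cells_per_type_per_condition: int = 300
    n_genes: int = 2000
    baseline_mean: float = 0.8
    baseline_sigma: float = 1.0
    dispersion: float = 2.0
    n_markers_per_type: int = 20
    marker_fold: float = 4.0
    n_de_per_type: int = 10
    de_fold: float = 2.0
    library_size_cv: float = 0.3
    mito_fraction_range: tuple = (0.01, 0.08)
    n_samples_per_condition: int = 6
    # focal-type sub-structure (off by default; see subtype_scenario)
    n_subtypes: int = 0
    n_submarkers: int = 20
    sub_fold: float = 4.0
    outgroup_fold: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type_per_condition < 1:
            raise ValidationError("need at least one cell type and one cell per group")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_markers_per_type < 0 or self.n_de_per_type < 0:
            raise ValidationError("planted gene counts must be >= 0")
        for name in ("marker_fold", "de_fold", "sub_fold", "outgroup_fold"):
            if getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must exceed 1")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("mito_fraction_range must satisfy 0 <= lo <= hi <= 1")
        n_sub = self.n_subtypes * self.n_submarkers * 2 if self.n_subtypes else 0
        planted = (self.n_markers_per_type + self.n_de_per_type) * self.n_cell_types + n_sub
        if planted + len(MITO_GENES) > self.n_genes:
            raise ValidationError("planted gene demand exceeds n_genes")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValidationError("dispersion and baseline_mean must be positive")
        if self.library_size_cv < 0:
            raise ValidationError("library_size_cv must be >= 0")


def null_scenario(seed: int = 0) -> SyntheticConfig:
    """No planted markers or DE genes: every downstream call is a false positive."""
    return SyntheticConfig(n_markers_per_type=0, n_de_per_type=0, seed=seed)


def subtype_scenario(seed: int = 0) -> SyntheticConfig:
    """Focal type carries 3 sub-signatures, the last strongly divergent."""
    return SyntheticConfig(n_subtypes=3, seed=seed)


@dataclass
class GroundTruth:
    """Planted signal identities, for recovery testing."""

    cell_types: pd.Series            # planted type per cell_id
    markers: dict                    # type -> list of marker genes
    de_genes: dict                   # type -> list of diabetic-up genes
    driver: tuple                    # (focal_type, receptor, sender_type, ligand)
    config: SyntheticConfig
    library_size: pd.Series = None   # planted per-cell size factors
    subtypes: dict = field(default_factory=dict)
    # subtypes keys (when planted): "cell_type", "labels" (Series over the
    # focal cells), "markers" (sublabel -> genes), "outgroup" (sublabel)

    def all_planted_genes(self) -> set:
        genes: set = set()
        for gs in self.markers.values():
            genes.update(gs)
        for gs in self.de_genes.values():
            genes.update(gs)
        for gs in self.subtypes.get("markers", {}).values():
            genes.update(gs)
        return genes

    def to_jsonable(self) -> dict:
        return {
            "markers": {t: list(g) for t, g in self.markers.items()},
            "de_genes": {t: list(g) for t, g in self.de_genes.items()},
            "driver": list(self.driver),
            "cell_types": self.cell_types.to_dict(),
            "subtypes": {
                k: (v.to_dict() if isinstance(v, pd.Series) else
                    {s: list(g) for s, g in v.items()} if isinstance(v, dict) else v)
                for k, v in self.subtypes.items()
            },
        }


def _plan_truth(config: SyntheticConfig, rng: np.random.Generator):
    """Assign gene names and planted roles without sampling any counts.

    Returns (gene_ids, baseline_means, roles) where roles maps structured
    planted-gene indices; separated from count sampling so role-level
    properties can be checked cheaply over many seeds.
    """
    types = list(CELL_TYPE_NAMES[: config.n_cell_types])
    if config.n_cell_types > len(CELL_TYPE_NAMES):
        types += [f"type_{i}" for i in range(len(CELL_TYPE_NAMES), config.n_cell_types)]

    n = config.n_genes
    gene_ids = np.array([f"G{i:04d}" for i in range(n)], dtype=object)
    n_mito = min(len(MITO_GENES), max(1, n // 200))
    mito_idx = np.arange(n - n_mito, n)
    gene_ids[mito_idx] = list(MITO_GENES[:n_mito])

    means = config.baseline_mean * np.exp(
        config.baseline_sigma * rng.standard_normal(n)
    )

    # planted genes come from the moderately expressed pool
    eligible = np.flatnonzero((means >= 0.5) & (means <= 3.0))
    eligible = np.setdiff1d(eligible, mito_idx)
    need = (config.n_markers_per_type + config.n_de_per_type) * len(types)
    if config.n_subtypes:
        need += config.n_submarkers * (config.n_subtypes + 1)  # outgroup gets 2x
    if need > eligible.size:
        raise ValidationError(
            f"only {eligible.size} genes eligible for planting, need {need}; "
            "increase n_genes or widen the baseline distribution"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    pos = 0

    marker_idx, de_idx = {}, {}
    for t in types:
        marker_idx[t] = chosen[pos : pos + config.n_markers_per_type]
        pos += config.n_markers_per_type
    for t in types:
        de_idx[t] = chosen[pos : pos + config.n_de_per_type]
        pos += config.n_de_per_type

    sub_idx = {}
    if config.n_subtypes:
        for s in range(config.n_subtypes):
            k = config.n_submarkers * (2 if s == config.n_subtypes - 1 else 1)
            sub_idx[f"sub_{s}"] = chosen[pos : pos + k]
            pos += k

    # canonical naming: first markers of each type get field-standard symbols
    for t in types:
        for j, symbol in enumerate(CANONICAL_MARKERS.get(t, ())):
            if j < len(marker_idx[t]):
                gene_ids[marker_idx[t][j]] = symbol
    focal = types[0]
    sender = types[2] if len(types) > 2 else types[-1]
    driver = (focal, None, sender, None)
    if config.n_markers_per_type and config.n_de_per_type and len(types) >= 2:
        receptor_i = marker_idx[focal][0]
        if gene_ids[receptor_i] != DRIVER_RECEPTOR:
            gene_ids[receptor_i] = DRIVER_RECEPTOR
        # the driver ligand is the sender's best-expressed planted DE gene:
        # the motivating ligands are robustly expressed growth factors, and
        # the planted circuit is meant to be recoverable by construction
        ligand_i = de_idx[sender][int(np.argmax(means[de_idx[sender]]))]
        gene_ids[ligand_i] = DRIVER_LIGAND
        driver = (focal, DRIVER_RECEPTOR, sender, DRIVER_LIGAND)

    roles = {
        "types": types,
        "markers": marker_idx,
        "de": de_idx,
        "sub": sub_idx,
        "mito": mito_idx,
        "driver": driver,
    }
    return gene_ids, means, roles


def generate_dataset(config: SyntheticConfig):
    """Sample a (CountMatrix, CellAnnotation, GroundTruth) triple.

    Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids, means, roles = _plan_truth(config, rng)
    types = roles["types"]
    n_genes = config.n_genes
    n_per = config.cells_per_type_per_condition
    n_cells = len(types) * 2 * n_per

    cell_type = np.empty(n_cells, dtype=object)
    condition = np.empty(n_cells, dtype=object)
    i = 0
    for t in types:
        for cond in ("control", "diabetic"):
            cell_type[i : i + n_per] = t
            condition[i : i + n_per] = cond
            i += n_per
    cell_ids = np.array([f"CELL{j:05d}" for j in range(n_cells)], dtype=object)

    # mean matrix: baseline x marker/DE/subtype folds x library size
    mu = np.tile(means[:, None], (1, n_cells)).astype(float)
    for t in types:
        in_type = cell_type == t
        if len(roles["markers"][t]):
            mu[np.ix_(roles["markers"][t], np.flatnonzero(in_type))] *= config.marker_fold
        if len(roles["de"][t]):
            sel = in_type & (condition == "diabetic")
            mu[np.ix_(roles["de"][t], np.flatnonzero(sel))] *= config.de_fold

    sub_labels = None
    if config.n_subtypes:
        focal = types[0]
        focal_cells = np.flatnonzero(cell_type == focal)
        sub_labels = np.empty(n_cells, dtype=object)
        sub_labels[:] = ""
        # balanced assignment within each condition
        for cond in ("control", "diabetic"):
            cells = np.flatnonzero((cell_type == focal) & (condition == cond))
            assign = np.tile(np.arange(config.n_subtypes), len(cells) // config.n_subtypes + 1)
            sub_labels[cells] = [f"sub_{s}" for s in assign[: len(cells)]]
        outgroup = f"sub_{config.n_subtypes - 1}"
        for s, idx in roles["sub"].items():
            fold = config.outgroup_fold if s == outgroup else config.sub_fold
            cells = np.flatnonzero(sub_labels == s)
            mu[np.ix_(idx, cells)] *= fold
        del focal_cells

    # library size factors, log-normal with stated CV
    cv = config.library_size_cv
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        libsize = np.exp(rng.standard_normal(n_cells) * np.sqrt(sigma2) - sigma2 / 2)
    else:
        libsize = np.ones(n_cells)
    mu *= libsize[None, :]

    # mitochondrial block: configured fraction of each cell's expected counts
    mito_idx = roles["mito"]
    non_mito_total = mu.sum(axis=0) - mu[mito_idx, :].sum(axis=0)
    lo, hi = config.mito_fraction_range
    frac = rng.uniform(lo, hi, size=n_cells)
    with np.errstate(divide="ignore"):
        mito_total = non_mito_total * frac / np.maximum(1.0 - frac, 1e-12)
    mu[mito_idx, :] = np.maximum(mito_total[None, :] / len(mito_idx), 1e-12)

    r = config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids)

    sample_id = np.array([
        f"{cond}_{(j % config.n_samples_per_condition) + 1}"
        for j, cond in enumerate(condition)
    ], dtype=object)
    ann = CellAnnotation(pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": sample_id,
        "condition": condition,
    }))

    truth = GroundTruth(
        cell_types=pd.Series(cell_type, index=cell_ids),
        markers={t: [gene_ids[i] for i in roles["markers"][t]] for t in types},
        de_genes={t: [gene_ids[i] for i in roles["de"][t]] for t in types},
        driver=roles["driver"],
        config=config,
        library_size=pd.Series(libsize, index=cell_ids),
    )
    if sub_labels is not None:
        focal = types[0]
        focal_mask = cell_type == focal
        truth.subtypes = {
            "cell_type": focal,
            "labels": pd.Series(sub_labels[focal_mask], index=cell_ids[focal_mask]),
            "markers": {s: [gene_ids[i] for i in idx] for s, idx in roles["sub"].items()},
            "outgroup": f"sub_{config.n_subtypes - 1}",
        }
    return matrix, ann, truth


def generate_lr_reference(
    config: SyntheticConfig, truth: GroundTruth, n_decoys: int = 50
) -> LigandReceptorTable:
    """Ligand-receptor table containing the planted driver pair plus decoys.

    Decoy pairs are drawn among genes carrying no planted signal, so a decoy
    can never inherit evidence from a planted effect.
    """
    rng = np.random.default_rng(config.seed + 1)
    planted = truth.all_planted_genes()
    background = [
        g for g in _gene_universe(config, truth)
        if g not in planted and not g.startswith("mt-")
    ]
    if 2 * n_decoys > len(background):
        raise ValidationError(
            f"{n_decoys} decoy pairs need {2 * n_decoys} background genes, "
            f"have {len(background)}"
        )
    pairs = []
    _, receptor, _, ligand = truth.driver
    if receptor is not None:
        pairs.append((ligand, receptor))
    picked = rng.choice(len(background), size=2 * n_decoys, replace=False)
    for k in range(n_decoys):
        pairs.append((background[picked[2 * k]], background[picked[2 * k + 1]]))
    if not pairs:
        raise ValidationError("no pairs to emit: no driver planted and n_decoys=0")
    return LigandReceptorTable(pairs)


def generate_ppi(
    config: SyntheticConfig,
    truth: GroundTruth,
    hub_degree: int = 10,
    background_p: float = 0.01,
    n_background_genes: int = 200,
) -> EdgeList:
    """Random PPI in which the driver receptor is wired as a hub.

    The receptor gets ``hub_degree`` edges to the focal type's planted
    condition-DE genes (cycling through other types' DE genes if needed),
    plus Erdos-Renyi background edges at probability ``background_p`` over
    signal + background genes.
    """
    rng = np.random.default_rng(config.seed + 2)
    focal, receptor, _, _ = truth.driver
    signal = sorted(truth.all_planted_genes())
    universe = _gene_universe(config, truth)
    background = [g for g in universe if g not in set(signal) and not g.startswith("mt-")]
    extra = list(rng.choice(background, size=min(n_background_genes, len(background)),
                            replace=False))
    nodes = signal + extra

    pairs = []
    if receptor is not None and hub_degree:
        targets = [g for g in truth.de_genes.get(focal, []) if g != receptor]
        for t in truth.de_genes:
            if t != focal:
                targets += [g for g in truth.de_genes[t] if g != receptor]
        if hub_degree > len(targets):
            raise ValidationError(
                f"hub_degree {hub_degree} exceeds {len(targets)} available DE genes"
            )
        for g in targets[:hub_degree]:
            pairs.append((receptor, g))
    if background_p > 0:
        n = len(nodes)
        upper = rng.random((n, n)) < background_p
        for a in range(n):
            for b in range(a + 1, n):
                if upper[a, b]:
                    pairs.append((nodes[a], nodes[b]))
    return EdgeList.from_pairs(pairs)


def generate_gene_sets(
    config: SyntheticConfig, truth: GroundTruth, n_decoy_sets: int = 10, set_size: int = 40
):
    """GMT-style collection: one set per planted DE program plus decoy sets."""
    from .datamodel import GeneSetCollection

    rng = np.random.default_rng(config.seed + 3)
    universe = _gene_universe(config, truth)
    sets, desc = {}, {}
    for t, genes in truth.de_genes.items():
        if genes:
            pad = rng.choice(universe, size=max(0, set_size - len(genes)), replace=False)
            sets[f"{t}_response"] = set(genes) | set(pad)
            desc[f"{t}_response"] = f"planted diabetic response of {t}"
    for k in range(n_decoy_sets):
        sets[f"random_set_{k}"] = set(rng.choice(universe, size=set_size, replace=False))
        desc[f"random_set_{k}"] = "random decoy set"
    return GeneSetCollection(sets, desc)


def _gene_universe(config: SyntheticConfig, truth: GroundTruth) -> list:
    """Recreate the generated gene-name universe without resampling counts."""
    rng = np.random.default_rng(config.seed)
    gene_ids, _, _ = _plan_truth(config, rng)
    return list(gene_ids)
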
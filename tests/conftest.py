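"""Shared fixtures: expensive synthetic datasets are built once per session."""

import numpy as np
import pytest

from commnet import (
    SyntheticConfig,
    generate_dataset,
    normalize_log,
    qc_filter,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study-condition dataset: 5 types x 2 conditions x 300 cells."""
    counts, ann, truth = generate_dataset(SyntheticConfig(seed=1))
    return counts, ann, truth


@pytest.fixture(scope="session")
def qc_norm(default_dataset):
    """QC-filtered, normalized default dataset with planted type labels."""
    counts, ann, truth = default_dataset
    counts, ann, _ = qc_filter(counts, ann)
    norm = normalize_log(counts)
    types = truth.cell_types.loc[list(norm.cell_ids)].to_numpy()
    condition = ann.frame["condition"].to_numpy()
    return norm, ann, truth, types, condition


@pytest.fixture(scope="session")
def de_results(qc_norm):
    """Specific-gene, condition-DE and uni-DEG tables on planted labels."""
    from commnet import compute_unidegs, condition_de, find_specific_genes

    norm, ann, truth, types, condition = qc_norm
    _, specific = find_specific_genes(norm, types)
    _, sig = condition_de(norm, types, condition)
    unidegs = compute_unidegs(sig)
    return specific, sig, unidegs
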
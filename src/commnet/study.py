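"""Published group-level tallies from the motivating diabetic-heart study.

These are inputs (printed per-group figures), not results: the functions
below recompute the derived totals and shares from them at run time.
"""

from __future__ import annotations

import numpy as np

#: profiled nuclei per condition (6 mice each)
NUCLEI_PER_GROUP = {"control": 16490, "diabetic": 16095}

#: fibroblast nuclei per condition
FIBROBLASTS_PER_GROUP = {"control": 3428, "diabetic": 2988}

#: share of the uni-DEG total carried by each major cell type, in percent
UNIDEG_SHARE_PERCENT = {
    "cardiomyocyte": 32.8,
    "endothelial": 19.7,
    "fibroblast": 18.5,
    "macrophage": 17.7,
    "endocardial": 7.9,
}

#: condition-DE log2 fold-change cutoff
DE_LOG2FC_CUTOFF = 0.36


def total_cells(per_group: dict) -> int:
    """Pooled cell count across condition groups."""
    return int(sum(per_group.values()))


def top_share(shares: dict, k: int = 5) -> float:
    """Summed percentage of the k largest shares."""
    return float(sum(sorted(shares.values(), reverse=True)[:k]))


def linear_fold(log2fc: float) -> float:
    """Linear fold change implied by a log2 fold-change cutoff."""
    return float(np.exp2(log2fc))
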
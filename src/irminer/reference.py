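"""In-package reference tables for pipeline validation.

Two small literature-derived tables travel with the package: the set of
52 genes encoding previously described ITIM-bearing inhibitory
receptors (used to flag known receptors and benchmark recall), and the
per-cell-type counts of single-spanning receptors in each functional
category (the 215-gene single-spanner universe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Genes encoding previously described ITIM-bearing inhibitory receptors.
KNOWN_RECEPTOR_SYMBOLS: tuple[str, ...] = (
    "BTLA", "CLEC4A", "KIR3DL2", "NCR2", "SIGLEC11",
    "CD22", "FCGR2B", "KIR3DL3", "PDCD1", "SIRPA",
    "CD244", "FCRL2", "KLRC1", "PECAM1", "SIT1",
    "CD300A", "FCRL3", "KLRG1", "PILRA", "SLAMF6",
    "CD300LF", "FCRL4", "LAIR1", "PVR", "TIGIT",
    "CD33", "FCRL5", "LILRB1", "SIGLEC5", "TREML1",
    "CD5", "KIR2DL1", "LILRB2", "SIGLEC6", "VSIG4",
    "CD72", "KIR2DL2", "LILRB3", "SIGLEC7", "VSTM1",
    "CEACAM1", "KIR2DL3", "LILRB4", "SIGLEC8",
    "CLEC12A", "KIR2DL4", "LILRB5", "SIGLEC9",
    "CLEC12B", "KIR3DL1", "MPIG6B", "SIGLEC10",
)

#: Known receptors the sequence/topology pipeline fails to recall
#: (MPIG6B: the transmembrane helix of its ITIM-bearing isoforms is
#: mispredicted upstream, so the intracellular-motif filter drops it).
NOT_RECALLED_SYMBOLS: frozenset[str] = frozenset({"MPIG6B"})

#: Functional-category labels, in reporting order.
CATEGORIES: tuple[str, ...] = (
    "not_expressed",
    "negative_feedback",
    "threshold_negative_feedback",
    "threshold_disinhibition",
    "threshold",
)

# cell type -> counts per category, same order as CATEGORIES.
_CATEGORY_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "Neutrophils": (78, 6, 3, 4, 124),
    "Monocytes": (95, 26, 1, 21, 72),
    "NK cells": (104, 17, 2, 11, 81),
    "B cells": (104, 10, 0, 16, 85),
    "CD4 T cells": (116, 8, 2, 16, 73),
    "CD8 T cells": (109, 9, 4, 15, 78),
}


@dataclass(frozen=True)
class KnownReceptorReference:
    """The 52 described ITIM-bearing inhibitory-receptor genes."""

    gene_symbols: frozenset[str]
    flagged: frozenset[str]  # known receptors the pipeline does not recall

    def __post_init__(self) -> None:
        if len(self.gene_symbols) != 52:
            raise ValueError("known-receptor reference must hold 52 symbols")
        if not self.flagged <= self.gene_symbols:
            raise ValueError("flagged symbols must be known receptors")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.gene_symbols


@dataclass(frozen=True)
class CategoryCountReference:
    """Single-spanning receptor counts per functional category and cell type."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        totals = self.rows.sum(axis=1)
        if totals.nunique() != 1:
            raise ValueError("category rows must sum to a common universe size")

    @property
    def universe_size(self) -> int:
        """Size of the single-spanner universe (common row total)."""
        return int(self.rows.sum(axis=1).iloc[0])


def load_known_receptors() -> KnownReceptorReference:
    """Packaged reference of the 52 known inhibitory-receptor genes."""
    return KnownReceptorReference(
        gene_symbols=frozenset(KNOWN_RECEPTOR_SYMBOLS),
        flagged=NOT_RECALLED_SYMBOLS,
    )


def load_category_counts() -> CategoryCountReference:
    """Packaged per-cell-type functional-category counts (single spanners)."""
    rows = pd.DataFrame.from_dict(
        _CATEGORY_COUNTS, orient="index", columns=list(CATEGORIES)
    )
    rows.index.name = "cell_type"
    return CategoryCountReference(rows=rows)
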
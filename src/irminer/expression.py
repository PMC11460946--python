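"""Expression calls and functional-category classification.

Receptor genes are called expressed per cell type and state when their
mean log2 expression exceeds the median over all genes of the dataset
in that condition (strictly).  Comparing resting and activated states
then assigns each gene to one of four functional categories:

* ``negative_feedback`` -- absent at rest, induced by activation;
* ``threshold`` -- expressed at rest, |log2FC| <= 0.5 on activation;
* ``threshold_disinhibition`` -- expressed at rest, log2FC < -0.5
  (or lost entirely after activation);
* ``threshold_negative_feedback`` -- expressed at rest, log2FC > 0.5.

Genes expressed in neither state are ``not_expressed``.  For the
tumour T-cell stage, a gene counts as expressed in a subset when its
subcluster-weighted mean Z-score is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOG2FC_THRESHOLD = 0.5

SCALES = ("counts", "tpm", "log2")
STATES = ("resting", "activated")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with per-sample cell type and state."""

    values: pd.DataFrame  # genes x samples
    scale: str
    sample_meta: pd.DataFrame  # index: sample, columns: cell_type, state

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if not set(self.values.columns) <= set(self.sample_meta.index):
            raise ValueError("samples missing from sample_meta")
        missing = {"cell_type", "state"} - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta missing columns {sorted(missing)}")
        bad_state = set(self.sample_meta["state"]) - set(STATES)
        if bad_state:
            raise ValueError(f"unknown sample states {sorted(bad_state)}")
        if self.scale in ("counts", "tpm") and (self.values.values < 0).any():
            raise ValueError(f"negative values on {self.scale} scale")


@dataclass(frozen=True)
class ExpressionCall:
    """Per gene x cell type: expressed flags, log2FC, category."""

    gene: str
    cell_type: str
    expressed_resting: bool
    expressed_activated: bool
    log2fc: float
    category: str


@dataclass(frozen=True)
class TumourSubsetCall:
    gene: str
    subset: str
    weighted_mean_z: float

    @property
    def expressed(self) -> bool:
        return self.weighted_mean_z > 0


def log2_scale_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; the pseudocount keeps zeros at zero."""
    if matrix.scale != "tpm":
        raise ValueError("log2_scale_tpm expects a TPM-scale matrix")
    if (matrix.values.values < 0).any():
        raise ValueError("negative TPM values")
    return ExpressionMatrix(
        values=np.log2(matrix.values + 1.0),
        scale="log2",
        sample_meta=matrix.sample_meta,
    )


def median_of_ratios_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size-factor normalisation, then log2(x+1).

    Per-sample size factors are the median, over genes with an
    all-positive geometric mean, of the ratio count / geometric mean.
    Counts are divided by their sample's factor before the log
    transform.
    """
    if matrix.scale != "counts":
        raise ValueError("median_of_ratios_normalize expects counts")
    counts = matrix.values
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    with np.errstate(divide="ignore"):
        logc = np.log(counts.values.astype(float))
    usable = np.isfinite(logc).all(axis=1)
    if not usable.any():
        raise ValueError("no gene is positive in every sample")
    log_geo_means = logc[usable].mean(axis=1)
    log_ratios = logc[usable] - log_geo_means[:, None]
    size_factors = np.exp(np.median(log_ratios, axis=0))
    normalized = counts / size_factors
    return ExpressionMatrix(
        values=np.log2(normalized + 1.0),
        scale="log2",
        sample_meta=matrix.sample_meta,
    )


def condition_means(
    matrix: ExpressionMatrix, gene_set: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene mean over samples sharing (cell_type, state).

    Returns a genes x (cell_type, state) MultiIndex column frame;
    conditions with zero samples are simply absent.
    """
    if matrix.scale != "log2":
        raise ValueError("condition means are computed on log2 data")
    values = matrix.values if gene_set is None else matrix.values.loc[gene_set]
    meta = matrix.sample_meta.loc[values.columns]
    grouped = values.T.groupby(
        [meta["cell_type"], meta["state"]]
    ).mean().T
    grouped.columns.names = ["cell_type", "state"]
    return grouped


def call_expressed(
    mean_table: pd.DataFrame, all_gene_means: pd.DataFrame
) -> pd.DataFrame:
    """Expressed iff strictly above the per-condition median of all genes.

    ``all_gene_means`` must cover the dataset's full gene universe --
    the median is taken over every gene, not just candidates.
    """
    if not set(mean_table.index) <= set(all_gene_means.index):
        raise ValueError(
            "gene universe does not cover the candidate genes; pass the "
            "condition means of the full dataset"
        )
    medians = all_gene_means.median(axis=0)
    return mean_table.gt(medians, axis=1)


def assign_category(
    expressed_resting: bool,
    expressed_activated: bool,
    log2fc: float,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
) -> str:
    """Total, single-valued mapping onto the five category labels.

    The +/-0.5 boundaries belong to ``threshold`` (the up/down
    categories are strict); a gene expressed at rest but not after
    activation is ``threshold_disinhibition`` regardless of log2FC.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if not expressed_resting:
        return "negative_feedback" if expressed_activated else "not_expressed"
    if not expressed_activated:
        return "threshold_disinhibition"
    if log2fc < -log2fc_threshold:
        return "threshold_disinhibition"
    if log2fc > log2fc_threshold:
        return "threshold_negative_feedback"
    return "threshold"


def _per_sample_majority_calls(
    matrix: ExpressionMatrix, genes: list[str]
) -> pd.DataFrame:
    """Alternative call mode: expressed per sample, then per-condition majority."""
    per_sample = matrix.values.gt(matrix.values.median(axis=0), axis=1)
    meta = matrix.sample_meta.loc[per_sample.columns]
    frac = per_sample.T.groupby([meta["cell_type"], meta["state"]]).mean().T
    frac.columns.names = ["cell_type", "state"]
    return frac.loc[genes] > 0.5


def classify_expression(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    call_mode: str = "condition-mean",
) -> list[ExpressionCall]:
    """Full classification for every (gene, cell type) with both states.

    ``call_mode='condition-mean'`` compares per-condition mean
    expression against the per-condition median over all genes;
    ``'per-sample-majority'`` calls each sample separately and takes
    the majority within a condition.  log2FC is always
    mean(activated) - mean(resting) on the log2 scale.
    """
    if matrix.scale != "log2":
        raise ValueError("classification expects log2-scale data")
    all_means = condition_means(matrix)
    genes = list(matrix.values.index) if genes is None else genes
    present = [g for g in genes if g in matrix.values.index]
    means = all_means.loc[present]
    if call_mode == "condition-mean":
        expressed = call_expressed(means, all_means)
    elif call_mode == "per-sample-majority":
        expressed = _per_sample_majority_calls(matrix, present)
    else:
        raise ValueError(f"unknown call_mode {call_mode!r}")

    calls: list[ExpressionCall] = []
    cell_types = sorted({ct for ct, _ in means.columns})
    for gene in present:
        for ct in cell_types:
            if (ct, "resting") not in means.columns or (
                ct, "activated"
            ) not in means.columns:
                continue
            r = bool(expressed.loc[gene, (ct, "resting")])
            a = bool(expressed.loc[gene, (ct, "activated")])
            fc = float(
                means.loc[gene, (ct, "activated")]
                - means.loc[gene, (ct, "resting")]
            )
            calls.append(
                ExpressionCall(
                    gene=gene,
                    cell_type=ct,
                    expressed_resting=r,
                    expressed_activated=a,
                    log2fc=fc,
                    category=assign_category(r, a, fc, log2fc_threshold),
                )
            )
    return calls


def calls_to_frame(calls: list[ExpressionCall]) -> pd.DataFrame:
    """Long-format frame of expression calls."""
    return pd.DataFrame(
        [
            (c.gene, c.cell_type, c.expressed_resting, c.expressed_activated,
             c.log2fc, c.category)
            for c in calls
        ],
        columns=[
            "gene", "cell_type", "expressed_resting", "expressed_activated",
            "log2fc", "category",
        ],
    )


def subset_sharing_counts(
    calls: list[ExpressionCall],
) -> dict[frozenset[str], int]:
    """Exclusive (upset-style) sharing partition of expressed genes.

    A gene counts as expressed in a cell type when expressed in either
    state; each gene expressed anywhere contributes to exactly one
    cell-type combination.
    """
    per_gene: dict[str, set[str]] = {}
    for c in calls:
        if c.expressed_resting or c.expressed_activated:
            per_gene.setdefault(c.gene, set()).add(c.cell_type)
    counts: dict[frozenset[str], int] = {}
    for combo in map(frozenset, per_gene.values()):
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def tumour_subset_expression(
    zmatrix: pd.DataFrame,  # cells x genes
    cell_meta: pd.DataFrame,  # index: cell, columns: subset, subcluster
    subcluster_weights: dict[str, dict[str, float]],
    use_median_rule: bool = False,
) -> list[TumourSubsetCall]:
    """Weighted mean Z-score per (gene, T-cell subset) and expression call.

    The subset mean is the weighted average of subcluster mean
    Z-scores, with the supplied relative subcluster contributions
    (summing to 1 within each subset).  ``use_median_rule`` switches
    the expression call from "mean Z > 0" to "above the median of the
    subset means across subsets"; in that mode ``weighted_mean_z`` is
    reported relative to the per-gene median so the strictly-positive
    call reads off the alternative rule unchanged.
    """
    if not set(zmatrix.index) <= set(cell_meta.index):
        raise ValueError("cells missing from cell_meta")
    meta = cell_meta.loc[zmatrix.index]
    subset_means: dict[str, pd.Series] = {}
    for subset, weights in subcluster_weights.items():
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subset {subset!r}: weights sum to {total}, not 1")
        acc = None
        for subcluster, w in weights.items():
            mask = (meta["subset"] == subset) & (meta["subcluster"] == subcluster)
            if not mask.any():
                raise ValueError(
                    f"subset {subset!r}: subcluster {subcluster!r} has no cells"
                )
            mean_z = zmatrix.loc[mask.values].mean(axis=0)
            acc = w * mean_z if acc is None else acc + w * mean_z
        subset_means[subset] = acc

    table = pd.DataFrame(subset_means)  # genes x subsets
    cutoff = (
        table.median(axis=1)
        if use_median_rule
        else pd.Series(0.0, index=table.index)
    )
    return [
        TumourSubsetCall(
            gene=gene,
            subset=subset,
            weighted_mean_z=float(table.loc[gene, subset] - cutoff[gene]),
        )
        for gene in table.index
        for subset in table.columns
    ]
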
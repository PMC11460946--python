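"""End-to-end candidate discovery pipeline.

Stage order: length filter -> motif scan -> topology filter (membrane
protein with >= 1 fully intracellular motif) -> permutation filter
(chance likelihood <= 0.25 + epsilon) -> structure filter (>= 1 motif
with mean pLDDT below threshold) -> optional expression
classification.  Stage survivor sets are nested, per-stage counts are
logged, and the whole run is deterministic given the seed.

Gene-level aggregation keeps the best-scoring isoform: lowest
permutation likelihood, ties broken by lowest minimum motif pLDDT,
then lexicographic protein id.  A gene is a final candidate iff at
least one isoform passes every stage.  Proteins whose structure file
is missing are carried with status ``no-structure`` rather than
silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import expression as expr
from .io import CANDIDATE_COLUMNS, ProteinRecord, sort_candidate_table
from .motifs import DEFAULT_CONFIG, MotifConfig, scan_itam_embedded, scan_motifs
from .permutation import (
    DEFAULT_N_PERMUTATIONS,
    EPSILON_MAX,
    LIKELIHOOD_BASE,
    count_motifs_in_domains,
    permutation_likelihood,
    protein_rng,
)
from .reference import load_known_receptors
from .structure import PLDDT_THRESHOLD, read_plddt, structural_filter
from .topology import (
    NO_TM,
    annotate_topology,
    extract_intracellular_domains,
    filter_intracellular_motifs,
)

STAGES = (
    "input",
    "length",
    "motif",
    "topology",
    "permutation",
    "structure",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds, with the published defaults."""

    motif_config: MotifConfig = DEFAULT_CONFIG
    max_protein_length: int = 10_000
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    likelihood_base: float = LIKELIHOOD_BASE
    epsilon_max: float = EPSILON_MAX
    plddt_threshold: float = PLDDT_THRESHOLD
    log2fc_threshold: float = expr.LOG2FC_THRESHOLD
    seed: int = 0
    shuffle_mode: str = "per-domain"  # or "concatenated"
    call_mode: str = "condition-mean"

    def digest(self) -> str:
        def _coerce(v):
            if isinstance(v, (set, frozenset)):
                return sorted(v)
            return str(v)

        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=_coerce).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Gene-level candidate table plus per-protein detail and counts."""

    candidates: pd.DataFrame  # one row per gene, CANDIDATE_COLUMNS schema
    proteins: pd.DataFrame  # per-isoform detail
    stage_counts: pd.DataFrame  # stage x (proteins, genes)
    config: PipelineConfig = field(repr=False, default=None)
    expression_calls: pd.DataFrame | None = None

    def provenance(self) -> dict:
        return {
            "config_digest": self.config.digest() if self.config else None,
            "seed": self.config.seed if self.config else None,
            "stage_counts": {
                stage: {
                    "proteins": int(row["proteins"]),
                    "genes": int(row["genes"]),
                }
                for stage, row in self.stage_counts.iterrows()
            },
        }


def _evaluate_protein(
    record: ProteinRecord,
    topo_string: str | None,
    pdb_text: str | None,
    config: PipelineConfig,
) -> dict:
    """Run one isoform through every stage; returns a flat result row."""
    row = {
        "protein_id": record.protein_id,
        "gene_id": record.gene_id,
        "gene_symbol": record.gene_symbol or record.gene_id or record.protein_id,
        "protein_class": "",
        "motif_coords": "",
        "motif_classes": "",
        "n_intracellular_motifs": 0,
        "likelihood": np.nan,
        "epsilon": np.nan,
        "min_motif_plddt": np.nan,
        "passed_length": False,
        "passed_motif": False,
        "passed_topology": False,
        "passed_permutation": False,
        "passed_structure": False,
        "failure_stage": "",
        "status": "",
    }

    def reject(stage: str, status: str) -> dict:
        row["failure_stage"] = stage
        row["status"] = status
        return row

    if len(record) > config.max_protein_length:
        return reject("length", "rejected")
    row["passed_length"] = True

    hits = scan_motifs(
        record.sequence, config.motif_config, protein_id=record.protein_id
    )
    if not hits:
        return reject("motif", "rejected")
    hits = scan_itam_embedded(record.sequence, hits, config.motif_config)
    row["passed_motif"] = True

    if topo_string is None:
        return reject("topology", "no-topology")
    annotation = annotate_topology(
        record.protein_id, topo_string, record.sequence
    )
    row["protein_class"] = annotation.protein_class
    intracellular = filter_intracellular_motifs(hits, annotation)
    if annotation.protein_class == NO_TM or not intracellular:
        return reject("topology", "rejected")
    row["passed_topology"] = True
    row["motif_coords"] = ",".join(f"{h.start}-{h.end}" for h in intracellular)
    row["motif_classes"] = ",".join(
        h.motif_class + ("*" if h.itam_embedded else "")
        for h in intracellular
    )
    row["n_intracellular_motifs"] = len(intracellular)

    domains = [
        d.sequence
        for d in extract_intracellular_domains(annotation, record.sequence)
    ]
    if config.shuffle_mode == "concatenated":
        domains = ["".join(domains)]
    observed = count_motifs_in_domains(domains, config.motif_config)
    perm = permutation_likelihood(
        domains,
        observed,
        config.n_permutations,
        protein_rng(config.seed, record.protein_id),
        config=config.motif_config,
        protein_id=record.protein_id,
        threshold_base=config.likelihood_base,
        epsilon_max=config.epsilon_max,
        seed=config.seed,
    )
    row["likelihood"] = perm.likelihood
    row["epsilon"] = perm.epsilon
    if not perm.passed:
        return reject("permutation", "rejected")
    row["passed_permutation"] = True

    if pdb_text is None:
        # carried forward with an explicit status; counts as a survivor
        row["passed_structure"] = True
        row["status"] = "no-structure"
        return row
    confidences = read_plddt(pdb_text)
    result = structural_filter(
        intracellular, confidences, config.plddt_threshold
    )
    row["min_motif_plddt"] = min(
        mc.mean_plddt for mc in result.motif_confidences
    )
    if not result.passed:
        return reject("structure", "rejected")
    row["passed_structure"] = True
    row["status"] = "candidate"
    return row


def run_pipeline(
    config: PipelineConfig,
    proteome: list[ProteinRecord],
    topology: dict[str, str],
    structures: dict[str, str] | None = None,
    expression: expr.ExpressionMatrix | None = None,
) -> PipelineResult:
    """Run every isoform through all stages and aggregate per gene."""
    if not proteome:
        raise ValueError("empty proteome")
    structures = structures or {}
    known = load_known_receptors()

    rows = [
        _evaluate_protein(
            rec,
            topology.get(rec.protein_id),
            structures.get(rec.protein_id),
            config,
        )
        for rec in sorted(proteome, key=lambda r: r.protein_id)
    ]
    proteins = pd.DataFrame(rows)
    proteins["known_receptor"] = proteins["gene_symbol"].isin(
        known.gene_symbols
    )

    # gene-level aggregation: best isoform per gene
    def best_isoform(group: pd.DataFrame) -> pd.Series:
        ranked = group.sort_values(
            ["likelihood", "min_motif_plddt", "protein_id"],
            na_position="last",
            kind="stable",
        )
        survivors = ranked[ranked["failure_stage"] == ""]
        best = (survivors.iloc[0] if len(survivors) else ranked.iloc[0]).copy()
        if len(survivors) == 0:
            # report the furthest-progressing isoform's failure stage
            order = {s: i for i, s in enumerate(STAGES)}
            best["failure_stage"] = max(
                group["failure_stage"], key=lambda s: order.get(s, -1)
            )
        return best

    genes = pd.DataFrame(
        [best_isoform(g) for _, g in proteins.groupby("gene_symbol", sort=True)]
    ).reset_index(drop=True)
    candidates = sort_candidate_table(genes[list(CANDIDATE_COLUMNS)])

    stage_counts = _stage_counts(proteins)

    calls_frame = None
    if expression is not None:
        matrix = expression
        if matrix.scale == "tpm":
            matrix = expr.log2_scale_tpm(matrix)
        elif matrix.scale == "counts":
            matrix = expr.median_of_ratios_normalize(matrix)
        calls = expr.classify_expression(
            matrix,
            genes=list(candidates["gene_symbol"]),
            log2fc_threshold=config.log2fc_threshold,
            call_mode=config.call_mode,
        )
        calls_frame = expr.calls_to_frame(calls)

    return PipelineResult(
        candidates=candidates,
        proteins=proteins,
        stage_counts=stage_counts,
        config=config,
        expression_calls=calls_frame,
    )


def _stage_counts(proteins: pd.DataFrame) -> pd.DataFrame:
    flags = {
        "input": pd.Series(True, index=proteins.index),
        "length": proteins["passed_length"],
        "motif": proteins["passed_motif"],
        "topology": proteins["passed_topology"],
        "permutation": proteins["passed_permutation"],
        "structure": proteins["passed_structure"],
    }
    counts = {
        stage: {
            "proteins": int(mask.sum()),
            "genes": proteins.loc[mask, "gene_symbol"].nunique(),
        }
        for stage, mask in flags.items()
    }
    df = pd.DataFrame.from_dict(counts, orient="index").loc[list(STAGES)]
    df.index.name = "stage"
    return df


def stage_report(result: PipelineResult) -> pd.DataFrame:
    """Per-stage survivor counts (proteins and unique genes)."""
    counts = result.stage_counts
    if (counts["proteins"].diff().dropna() > 0).any():
        raise AssertionError("stage counts must be monotone non-increasing")
    return counts
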
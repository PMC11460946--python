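"""Seed-reproducible synthetic proteomes, structures, and expression data.

Every generator is a pure function of (parameters, seed) and records
its ground truth, so each pipeline stage can be tested end-to-end
without external downloads.  The generated data emulates the
statistical shape the pipeline assumes -- membrane topologies of all
protein classes, planted intracellular/extracellular motifs,
per-residue confidence profiles in AlphaFold's B-factor convention,
and expression matrices with genes planted in each functional
category -- not real protein evolution or geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from .expression import ExpressionMatrix
from .io import ProteinRecord
from .motifs import DEFAULT_CONFIG, MotifConfig, count_motifs, scan_motifs

#: Standard 20-residue alphabet used for background sampling.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Tyrosine-free background: windows can never complete the consensus,
#: so planted motif counts are exact and the chance likelihood of a
#: planted motif under shuffling stays uniformly low.
AA_NO_Y = AA20.replace("Y", "")

#: Residues that can neither occupy a constrained consensus slot nor be
#: the motif tyrosine; substituting one destroys a window without
#: creating another.
NEUTRAL_AA = "ADEGNPQ"

CANONICAL_MOTIF = "SDYSEL"  # S.Y..L -- a classic ITIM


@dataclass
class FixtureTruth:
    """Ground truth recorded by the generators."""

    # protein_id -> dict with keys: class, motif positions (intracellular /
    # extracellular 1-based starts), expected pipeline fate.
    proteins: dict[str, dict] = field(default_factory=dict)
    # gene -> cell_type -> planted category; and gene -> planted log2fc.
    categories: dict[str, dict[str, str]] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "proteins": self.proteins,
                "categories": self.categories,
                "log2fc": self.log2fc,
            },
            indent=2,
            sort_keys=True,
        )


def _background(rng: np.random.Generator, n: int, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def _strip_accidental_motifs(
    sequence: str,
    protected: list[int],
    rng: np.random.Generator,
    config: MotifConfig = DEFAULT_CONFIG,
) -> str:
    """Rejection step: re-draw the tyrosine of unplanned windows.

    ``protected`` lists 1-based starts of planted motifs.  Replacing an
    accidental window's tyrosine with a neutral residue can only
    destroy matches, so the loop terminates.
    """
    seq = list(sequence)
    protected_set = set(protected)
    # A planted window's tyrosine can never be another window's pos-3
    # tyrosine (that window would share the planted start), and a
    # neutral residue is legal at any wildcard slot of a planted
    # window, so the substitution below cannot break planted motifs.
    while True:
        accidental = [
            h
            for h in scan_motifs("".join(seq), config)
            if h.start not in protected_set
        ]
        if not accidental:
            return "".join(seq)
        for h in accidental:
            seq[h.tyrosine_pos - 1] = rng.choice(list(NEUTRAL_AA))


def _build_protein(
    rng: np.random.Generator,
    protein_class: str,
    n_out: int = 30,
    n_in: int = 40,
    tm_len: int = 21,
    plant_intracellular: bool = True,
    plant_extracellular: bool = False,
    alphabet: str = AA20,
) -> tuple[str, str, dict]:
    """One sequence + topology string with planted motifs; returns truth."""
    motif = CANONICAL_MOTIF

    def segment(n: int, plant: bool) -> tuple[str, int | None]:
        if plant:
            if n < len(motif) + 2:
                raise ValueError("segment too short to plant a motif")
            offset = int(rng.integers(1, n - len(motif)))  # keep off edges
            seq = (
                _background(rng, offset, alphabet)
                + motif
                + _background(rng, n - offset - len(motif), alphabet)
            )
            return seq, offset + 1
        return _background(rng, n, alphabet), None

    if protein_class == "type_I":
        out_seq, out_pos = segment(n_out, plant_extracellular)
        in_seq, in_pos = segment(n_in, plant_intracellular)
        seq = out_seq + _background(rng, tm_len, "AFGILV") + in_seq
        topo = "o" * n_out + "M" * tm_len + "i" * n_in
        in_start, out_start = n_out + tm_len, 0
    elif protein_class == "type_II":
        in_seq, in_pos = segment(n_in, plant_intracellular)
        out_seq, out_pos = segment(n_out, plant_extracellular)
        seq = in_seq + _background(rng, tm_len, "AFGILV") + out_seq
        topo = "i" * n_in + "M" * tm_len + "o" * n_out
        in_start, out_start = 0, n_in + tm_len
    elif protein_class == "multi_pass":
        in_seq, in_pos = segment(n_in, plant_intracellular)
        out_seq, out_pos = segment(n_out, plant_extracellular)
        tm = _background(rng, tm_len, "AFGILV")
        # second cytoplasmic segment is tyrosine-free background
        seq = in_seq + tm + out_seq + _background(rng, tm_len, "AFGILV") + _background(rng, n_in, AA_NO_Y)
        topo = "i" * n_in + "M" * tm_len + "o" * n_out + "M" * tm_len + "i" * n_in
        in_start, out_start = 0, n_in + tm_len
    elif protein_class == "no_tm":
        in_seq, in_pos = segment(n_in + n_out, plant_intracellular)
        out_pos = None
        seq = in_seq
        topo = "i" * (n_in + n_out)
        in_start, out_start = 0, 0
    else:
        raise ValueError(f"unknown protein class {protein_class!r}")

    truth = {
        "class": protein_class,
        "intracellular_motif_start": (
            in_start + in_pos if in_pos is not None else None
        ),
        "extracellular_motif_start": (
            out_start + out_pos if out_pos is not None else None
        ),
    }
    return seq, topo, truth


def make_synthetic_proteome(
    n_proteins: int,
    seed: int,
    class_mix: dict[str, float] | None = None,
    allow_background_motifs: bool = False,
) -> tuple[list[ProteinRecord], dict[str, str], FixtureTruth]:
    """Synthetic proteome with one planted intracellular motif per protein.

    ``class_mix`` gives sampling probabilities over protein classes
    (default: type I only).  Background residues are uniform over the
    20-residue alphabet; unless ``allow_background_motifs``, accidental
    consensus windows are re-drawn so planted counts are exact.
    """
    if class_mix is None:
        class_mix = {"type_I": 1.0}
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    classes = list(class_mix)
    probs = [class_mix[c] for c in classes]

    records, topologies, truth = [], {}, FixtureTruth()
    for k in range(n_proteins):
        pid = f"P{k + 1:04d}"
        cls = rng.choice(classes, p=probs)
        seq, topo, t = _build_protein(rng, str(cls))
        if not allow_background_motifs:
            protected = [
                p
                for p in (
                    t["intracellular_motif_start"],
                    t["extracellular_motif_start"],
                )
                if p is not None
            ]
            seq = _strip_accidental_motifs(seq, protected, rng)
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=seq,
                transcript_id=f"T{k + 1:04d}",
                gene_id=f"G{k + 1:04d}",
                gene_symbol=f"GENE{k + 1:02d}",
            )
        )
        topologies[pid] = topo
        truth.proteins[pid] = t
    return records, topologies, truth


_1TO3 = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}


def make_synthetic_structure(
    sequence: str, plddt_profile: list[float], seed: int = 0
) -> str:
    """Single-chain PDB text with the profile in the B-factor column.

    Every atom of residue i carries ``plddt_profile[i]`` at %6.2f
    precision, following the AlphaFold convention.  Backbone
    coordinates trace an extended (trivially self-avoiding) chain;
    geometry is irrelevant to confidence scoring.
    """
    if len(plddt_profile) != len(sequence):
        raise ValueError("profile length must equal sequence length")
    if any(not 0.0 <= v <= 100.0 for v in plddt_profile):
        raise ValueError("pLDDT values must lie in [0, 100]")
    lines = []
    serial = 1
    for i, (aa, plddt) in enumerate(zip(sequence, plddt_profile), start=1):
        resname = _1TO3.get(aa, "UNK")
        x0 = 3.8 * i
        for name, dx, dy, element in (
            ("N", -1.2, 0.8, "N"),
            ("CA", 0.0, 0.0, "C"),
            ("C", 1.2, 0.8, "C"),
            ("O", 1.4, 2.0, "O"),
        ):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} A{i:4d}    "
                f"{x0 + dx:8.3f}{dy:8.3f}{0.0:8.3f}{1.00:6.2f}{plddt:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_synthetic_expression(
    category_plan: dict[str, dict[str, tuple[str, float]]],
    n_samples: int = 4,
    noise_sd: float = 0.1,
    n_background: int = 400,
    seed: int = 0,
) -> tuple[ExpressionMatrix, FixtureTruth]:
    """Counts matrix with genes planted in known functional categories.

    ``category_plan`` maps gene -> cell_type -> (category, log2fc
    effect size); effect sizes for the up/down categories must clear
    the +/-0.5 boundary (|effect| >= 0.6).  Background genes draw
    log-normal baselines (log2 mean 5, sd 2) shared between states, so
    the per-condition median is well-defined near 5; planted genes sit
    at log2 9 (above median) or 1 (below), shifted on activation per
    plan.  Gaussian noise with ``noise_sd`` is added on the log2 scale
    and values are exported as rounded counts (2**x - 1).
    """
    rng = np.random.default_rng(seed)
    cell_types = sorted({ct for plan in category_plan.values() for ct in plan})
    if not cell_types:
        raise ValueError("empty category plan")
    for gene, plan in category_plan.items():
        for ct, (cat, eff) in plan.items():
            if cat in (
                "negative_feedback",
                "threshold_negative_feedback",
                "threshold_disinhibition",
            ) and abs(eff) < 0.6:
                raise ValueError(
                    f"{gene}/{ct}: effect {eff} too close to the 0.5 boundary"
                )

    samples, meta_rows = [], []
    for ct in cell_types:
        for state in ("resting", "activated"):
            for k in range(n_samples):
                samples.append(f"{ct}_{state}_{k + 1}")
                meta_rows.append((ct, state))
    meta = pd.DataFrame(
        meta_rows, index=samples, columns=["cell_type", "state"]
    )

    HI, LO = 9.0, 1.0  # log2 baselines well above/below the median (~5)
    genes = list(category_plan) + [f"BG{k:04d}" for k in range(n_background)]
    log2 = pd.DataFrame(0.0, index=genes, columns=samples)
    truth = FixtureTruth()

    bg_baselines = rng.normal(5.0, 2.0, size=n_background).clip(min=0.0)
    for sample, (ct, state) in zip(samples, meta_rows):
        col = np.empty(len(genes))
        for gi, gene in enumerate(category_plan):
            cat, eff = category_plan[gene].get(ct, ("not_expressed", 0.0))
            if cat == "not_expressed":
                mu = LO
            elif cat == "negative_feedback":
                mu = LO if state == "resting" else HI
            elif cat == "threshold":
                mu = HI
            elif cat == "threshold_negative_feedback":
                mu = HI if state == "resting" else HI + abs(eff)
            elif cat == "threshold_disinhibition":
                mu = HI if state == "resting" else HI - abs(eff)
            else:
                raise ValueError(f"unknown category {cat!r}")
            col[gi] = mu
        col[len(category_plan):] = bg_baselines
        log2[sample] = col + rng.normal(0.0, noise_sd, size=len(genes))

    for gene, plan in category_plan.items():
        truth.categories[gene] = {ct: cat for ct, (cat, _) in plan.items()}
        truth.log2fc[gene] = next(iter(plan.values()))[1]

    counts = np.round(np.exp2(log2.clip(lower=0.0)) - 1.0).astype(int)
    matrix = ExpressionMatrix(values=counts, scale="counts", sample_meta=meta)
    return matrix, truth


# ---------------------------------------------------------------------------
# End-to-end pipeline fixture: five true candidates plus one designed
# failure per stage.


def make_pipeline_fixture(
    seed: int,
) -> tuple[list[ProteinRecord], dict[str, str], dict[str, str], FixtureTruth]:
    """Ten-protein fixture exercising every pipeline stage.

    Proteins P0001-P0005 are true type I candidates (one intracellular
    motif, disordered tail).  P0006-P0010 each fail exactly one stage:
    oversized protein (length filter), no motif anywhere (motif scan),
    extracellular motif only (topology filter), composition-rich
    intracellular domain whose shuffles almost always contain a motif
    (permutation filter), and a fully ordered structure (pLDDT filter).

    Backgrounds are tyrosine-free, so planted motif counts are exact
    and true candidates keep a uniformly low chance likelihood for any
    seed.  Returns (records, topologies, pdb_texts, truth).
    """
    rng = np.random.default_rng(seed)
    n_out, tm_len, n_in = 30, 21, 40
    motif = CANONICAL_MOTIF

    def tail_with_motif(n: int) -> tuple[str, int]:
        offset = int(rng.integers(1, n - len(motif)))
        tail = (
            _background(rng, offset, AA_NO_Y)
            + motif
            + _background(rng, n - offset - len(motif), AA_NO_Y)
        )
        return tail, offset + 1

    records: list[ProteinRecord] = []
    topologies: dict[str, str] = {}
    pdbs: dict[str, str] = {}
    truth = FixtureTruth()

    def add(pid_num, gene_symbol, seq, topo, fate, profile=None, motif_start=None):
        pid = f"P{pid_num:04d}"
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=seq,
                transcript_id=f"T{pid_num:04d}",
                gene_id=f"G{pid_num:04d}",
                gene_symbol=gene_symbol,
            )
        )
        topologies[pid] = topo
        if profile is not None:
            pdbs[pid] = make_synthetic_structure(seq, profile)
        truth.proteins[pid] = {
            "class": "type_I",
            "fate": fate,
            "intracellular_motif_start": motif_start,
        }

    topo_I = "o" * n_out + "M" * tm_len + "i" * n_in
    ordered = [70.0] * n_out + [90.0] * tm_len  # ecto + TM profile prefix

    # -- five true candidates; the first carries a known-receptor symbol
    symbols = ["LAIR1", "GENE02", "GENE03", "GENE04", "GENE05"]
    for k, sym in enumerate(symbols, start=1):
        tail, pos = tail_with_motif(n_in)
        seq = _background(rng, n_out, AA_NO_Y) + _background(rng, tm_len, "AFGILV") + tail
        add(
            k, sym, seq, topo_I,
            fate="candidate",
            profile=ordered + [40.0] * n_in,
            motif_start=n_out + tm_len + pos,
        )

    # -- P0006: longer than the 10,000-residue topology limit
    tail, pos = tail_with_motif(n_in)
    huge_ecto = 10_001 - tm_len - n_in
    seq = _background(rng, huge_ecto, AA_NO_Y) + _background(rng, tm_len, "AFGILV") + tail
    add(
        6, "GENE06", seq, "o" * huge_ecto + "M" * tm_len + "i" * n_in,
        fate="fail_length", motif_start=huge_ecto + tm_len + pos,
    )

    # -- P0007: no motif anywhere (tyrosine-free sequence)
    seq = _background(rng, n_out + tm_len + n_in, AA_NO_Y)
    add(7, "GENE07", seq, topo_I, fate="fail_motif")

    # -- P0008: motif planted extracellularly only
    ecto_off = int(rng.integers(1, n_out - len(motif)))
    ecto = (
        _background(rng, ecto_off, AA_NO_Y)
        + motif
        + _background(rng, n_out - ecto_off - len(motif), AA_NO_Y)
    )
    seq = ecto + _background(rng, tm_len, "AFGILV") + _background(rng, n_in, AA_NO_Y)
    add(8, "GENE08", seq, topo_I, fate="fail_topology")

    # -- P0009: intracellular domain so rich in S/Y/L that almost every
    # shuffle contains a motif (observed count stays 1 by construction)
    rich_tail = motif + "S" * 10 + "Y" * 10 + "L" * 10
    assert count_motifs(rich_tail) == 1
    seq = _background(rng, n_out, AA_NO_Y) + _background(rng, tm_len, "AFGILV") + rich_tail
    add(
        9, "GENE09", seq, "o" * n_out + "M" * tm_len + "i" * len(rich_tail),
        fate="fail_permutation", motif_start=n_out + tm_len + 1,
    )

    # -- P0010: motif in a confidently folded region (all-95 profile)
    tail, pos = tail_with_motif(n_in)
    seq = _background(rng, n_out, AA_NO_Y) + _background(rng, tm_len, "AFGILV") + tail
    add(
        10, "GENE10", seq, topo_I,
        fate="fail_structure",
        profile=[95.0] * len(seq),
        motif_start=n_out + tm_len + pos,
    )

    return records, topologies, pdbs, truth


def write_fixture_directory(out_dir: str | Path, seed: int) -> Path:
    """Materialise the pipeline fixture as a self-contained directory."""
    from .io import write_protein_fasta, write_topology_file

    out = Path(out_dir)
    (out / "pdb").mkdir(parents=True, exist_ok=True)
    records, topologies, pdbs, truth = make_pipeline_fixture(seed)
    write_protein_fasta(records, out / "proteome.fasta")
    write_topology_file(topologies, out / "topology.tsv")
    meta = pd.DataFrame(
        [
            (r.protein_id, r.transcript_id, r.gene_id, r.gene_symbol)
            for r in records
        ],
        columns=["protein_id", "transcript_id", "gene_id", "gene_symbol"],
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    for pid, text in pdbs.items():
        (out / "pdb" / f"{pid}.pdb").write_text(text)

    plan = {
        f"GENE{k:02d}": {"Monocytes": (cat, eff)}
        for k, (cat, eff) in enumerate(
            [
                ("threshold", 0.0),
                ("negative_feedback", 1.0),
                ("threshold_disinhibition", 1.0),
                ("threshold_negative_feedback", 1.0),
                ("not_expressed", 0.0),
            ],
            start=1,
        )
    }
    matrix, expr_truth = make_synthetic_expression(plan, seed=seed)
    matrix.values.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    matrix.sample_meta.rename_axis("sample_id").to_csv(
        out / "sample_meta.tsv", sep="\t"
    )
    truth.categories = expr_truth.categories
    truth.log2fc = expr_truth.log2fc
    (out / "truth.json").write_text(truth.to_json())
    return out
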
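"""File I/O: protein FASTA, topology strings, and candidate tables.

FASTA parsing goes through Biopython; topology files are either a
two-column TSV (``id<TAB>per-residue string``) or TOPCONS-style blocks
(``>id`` header followed by the topology string).  The topology
alphabet is fixed to {i, o, M, S}: cytoplasmic, extracellular,
membrane, signal peptide.  Other dialects must be pre-mapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TOPOLOGY_ALPHABET = frozenset("ioMS")

#: Amino-acid alphabet accepted in input sequences (incl. ambiguity codes).
SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXU*")


@dataclass(frozen=True)
class ProteinRecord:
    """One translated isoform with its gene/transcript identifiers."""

    protein_id: str
    sequence: str
    transcript_id: str = ""
    gene_id: str = ""
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending header."""


def read_protein_fasta(
    path: str | Path, metadata: str | Path | None = None
) -> list[ProteinRecord]:
    """Read a protein FASTA, optionally joining a gene/transcript table.

    The FASTA header's first whitespace-delimited token is the protein
    identifier.  ``metadata`` is a TSV with columns ``protein_id``,
    ``transcript_id``, ``gene_id``, ``gene_symbol``; records absent
    from it keep empty annotation fields.  A trailing stop codon
    (``*``) is stripped from each sequence.
    """
    meta: dict[str, tuple[str, str, str]] = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
        required = {"protein_id", "transcript_id", "gene_id", "gene_symbol"}
        missing = required - set(mdf.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        for row in mdf.itertuples(index=False):
            meta[row.protein_id] = (
                row.transcript_id, row.gene_id, row.gene_symbol
            )

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaParseError(f"empty sequence for header '{entry.id}'")
        if entry.id in seen:
            raise FastaParseError(f"duplicate protein_id '{entry.id}'")
        seen.add(entry.id)
        tid, gid, sym = meta.get(entry.id, ("", "", ""))
        try:
            records.append(
                ProteinRecord(
                    protein_id=entry.id,
                    sequence=seq,
                    transcript_id=tid,
                    gene_id=gid,
                    gene_symbol=sym,
                )
            )
        except ValueError as exc:
            raise FastaParseError(str(exc)) from exc
    return records


def write_protein_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records as plain protein FASTA (id-only headers)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def _validate_topology(protein_id: str, states: str) -> None:
    for pos, ch in enumerate(states, start=1):
        if ch not in TOPOLOGY_ALPHABET:
            raise ValueError(
                f"{protein_id}: invalid topology character {ch!r} "
                f"at position {pos}"
            )


def read_topology_file(path: str | Path) -> dict[str, str]:
    """Read per-residue topology strings.

    Accepts a two-column TSV (``id<TAB>string``) or TOPCONS-style
    blocks (``>id`` line followed by one or more lines of topology
    characters).  Every string is validated against {i,o,M,S}.
    """
    text = Path(path).read_text()
    topo: dict[str, str] = {}
    if ">" in text:
        current: str | None = None
        chunks: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    topo[current] = "".join(chunks)
                current = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if current is not None:
            topo[current] = "".join(chunks)
    else:
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"expected 'id<TAB>topology', got {line!r}")
            topo[parts[0]] = parts[1]
    for pid, states in topo.items():
        _validate_topology(pid, states)
    return topo


def write_topology_file(topologies: dict[str, str], path: str | Path) -> None:
    """Write topology strings as a two-column TSV."""
    with open(path, "w") as fh:
        for pid, states in topologies.items():
            fh.write(f"{pid}\t{states}\n")


# ---------------------------------------------------------------------------
# Candidate table

#: Stable column order of the per-gene candidate TSV.
CANDIDATE_COLUMNS: tuple[str, ...] = (
    "gene_symbol",
    "gene_id",
    "protein_id",
    "protein_class",
    "motif_coords",
    "motif_classes",
    "n_intracellular_motifs",
    "likelihood",
    "epsilon",
    "min_motif_plddt",
    "passed_length",
    "passed_motif",
    "passed_topology",
    "passed_permutation",
    "passed_structure",
    "known_receptor",
    "failure_stage",
    "status",
)

_BOOL_COLUMNS = (
    "passed_length", "passed_motif", "passed_topology",
    "passed_permutation", "passed_structure", "known_receptor",
)
_FLOAT_COLUMNS = ("likelihood", "epsilon", "min_motif_plddt")
_INT_COLUMNS = ("n_intracellular_motifs",)


def empty_candidate_table() -> pd.DataFrame:
    """Header-only candidate table with the canonical dtypes."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CANDIDATE_COLUMNS})
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype(bool)
    for c in _FLOAT_COLUMNS:
        df[c] = df[c].astype(float)
    for c in _INT_COLUMNS:
        df[c] = df[c].astype(int)
    return df[list(CANDIDATE_COLUMNS)]


def sort_candidate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: gene_symbol, then protein_id."""
    return df.sort_values(
        ["gene_symbol", "protein_id"], kind="stable"
    ).reset_index(drop=True)


def write_candidate_table(candidates: pd.DataFrame, path: str | Path) -> None:
    """Write the candidate table as a TSV with stable column/row order."""
    missing = set(CANDIDATE_COLUMNS) - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    out = sort_candidate_table(candidates[list(CANDIDATE_COLUMNS)])
    out.to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read a candidate TSV back with canonical dtypes."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return empty_candidate_table()
    for c in _BOOL_COLUMNS:
        df[c] = df[c].map({"True": True, "False": False})
    for c in _FLOAT_COLUMNS:
        df[c] = np.where(df[c] == "", np.nan, df[c]).astype(float)
    for c in _INT_COLUMNS:
        df[c] = df[c].astype(int)
    return df[list(CANDIDATE_COLUMNS)]
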
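"""Membrane-topology annotation and intracellular-motif filtering.

A per-residue topology string over {i, o, M, S} (cytoplasmic,
extracellular, membrane, signal peptide) is turned into a protein-class
call plus the list of maximal transmembrane runs.  Candidate motifs
must lie entirely within an intracellular ('i') segment: an
inhibitory motif can only recruit cytoplasmic phosphatases if every one
of its six residues is on the cytoplasmic side of the membrane.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import ProteinRecord, TOPOLOGY_ALPHABET
from .motifs import MotifHit

NO_TM = "no_tm"
SINGLE_PASS_TYPE_I = "single_pass_type_I"
SINGLE_PASS_TYPE_II = "single_pass_type_II"
MULTI_PASS = "multi_pass"

PROTEIN_CLASSES = (NO_TM, SINGLE_PASS_TYPE_I, SINGLE_PASS_TYPE_II, MULTI_PASS)


@dataclass(frozen=True)
class TopologyAnnotation:
    """Per-residue topology plus derived membrane-protein class."""

    protein_id: str
    residue_states: str
    tm_segments: tuple[tuple[int, int], ...]
    protein_class: str

    def __len__(self) -> int:
        return len(self.residue_states)


@dataclass(frozen=True)
class IntracellularDomain:
    """One maximal cytoplasmic segment (1-based closed interval)."""

    protein_id: str
    domain_index: int
    start: int
    end: int
    sequence: str


def _maximal_runs(states: str, char: str) -> list[tuple[int, int]]:
    return [
        (m.start() + 1, m.end())
        for m in re.finditer(f"{char}+", states)
    ]


def annotate_topology(
    protein_id: str, residue_states: str, sequence: str
) -> TopologyAnnotation:
    """Classify the membrane-protein type from a topology string.

    Classes: no TM run -> ``no_tm``; >=2 runs -> ``multi_pass``; one
    run -> single-pass, type II when the N-terminal flank is
    cytoplasmic ('i'), type I otherwise (extracellular or
    signal-peptide N-terminus).  Signal-peptide residues count as the
    non-cytoplasmic side, never as intracellular.
    """
    if len(residue_states) != len(sequence):
        raise ValueError(
            f"{protein_id}: topology length {len(residue_states)} != "
            f"sequence length {len(sequence)}"
        )
    bad = set(residue_states) - TOPOLOGY_ALPHABET
    if bad:
        raise ValueError(f"{protein_id}: invalid topology states {sorted(bad)}")

    tm = _maximal_runs(residue_states, "M")
    if len(tm) == 0:
        cls = NO_TM
    elif len(tm) >= 2:
        cls = MULTI_PASS
    else:
        start, end = tm[0]
        if start == 1 and end == len(residue_states):
            raise ValueError(
                f"{protein_id}: all-membrane topology cannot be classified"
            )
        n_side = residue_states[start - 2] if start > 1 else None
        cls = SINGLE_PASS_TYPE_II if n_side == "i" else SINGLE_PASS_TYPE_I
    return TopologyAnnotation(
        protein_id=protein_id,
        residue_states=residue_states,
        tm_segments=tuple(tm),
        protein_class=cls,
    )


def extract_intracellular_domains(
    annotation: TopologyAnnotation, sequence: str
) -> list[IntracellularDomain]:
    """Maximal cytoplasmic segments, N-to-C; empty if no 'i' residues."""
    if len(annotation.residue_states) != len(sequence):
        raise ValueError("annotation/sequence length mismatch")
    return [
        IntracellularDomain(
            protein_id=annotation.protein_id,
            domain_index=k,
            start=start,
            end=end,
            sequence=sequence[start - 1 : end],
        )
        for k, (start, end) in enumerate(
            _maximal_runs(annotation.residue_states, "i")
        )
    ]


def filter_intracellular_motifs(
    hits: list[MotifHit], annotation: TopologyAnnotation
) -> list[MotifHit]:
    """Keep hits whose six residues are all cytoplasmic ('i')."""
    kept = []
    states = annotation.residue_states
    for h in hits:
        if h.end > len(states) or h.start < 1:
            raise ValueError(
                f"{annotation.protein_id}: hit {h.start}-{h.end} outside "
                f"annotation of length {len(states)}"
            )
        if all(states[p] == "i" for p in range(h.start - 1, h.end)):
            kept.append(h)
    return kept


def apply_length_filter(
    records: list[ProteinRecord], max_len: int = 10_000
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records at the topology-prediction length limit (inclusive)."""
    kept = [r for r in records if len(r) <= max_len]
    excluded = [r for r in records if len(r) > max_len]
    return kept, excluded
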
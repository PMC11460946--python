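"""Per-residue structure confidence (pLDDT) scoring of motifs.

Interaction motifs are typically found in intrinsically disordered
segments.  AlphaFold-style models store the per-residue confidence
score (pLDDT, 0-100) in the B-factor column, one value repeated on
every atom of a residue; low values mark likely disorder.  A motif is
scored as the arithmetic mean pLDDT of its six residues, and a protein
passes the structural filter when at least one motif scores below the
threshold (default 80) -- i.e. when some motif plausibly sits in an
accessible, disordered region.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

from Bio.PDB import PDBParser

from .motifs import MotifHit

#: Motifs with mean pLDDT at or above this are considered inaccessible.
PLDDT_THRESHOLD = 80.0

#: Mean pLDDT below this suggests intrinsic disorder.
DISORDER_PLDDT = 50.0


@dataclass(frozen=True)
class ResidueConfidence:
    residue_index: int  # 1-based
    plddt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(
                f"residue {self.residue_index}: pLDDT {self.plddt} "
                "outside [0, 100]"
            )


@dataclass(frozen=True)
class MotifConfidence:
    """Mean pLDDT over the six residues of one motif."""

    hit: MotifHit
    residue_plddts: tuple[float, ...]
    mean_plddt: float

    @property
    def disordered_flag(self) -> bool:
        return self.mean_plddt < DISORDER_PLDDT


@dataclass(frozen=True)
class StructureFilterResult:
    protein_id: str
    motif_confidences: tuple[MotifConfidence, ...]
    threshold: float
    passed: bool  # any motif below threshold


class PDBConfidenceError(ValueError):
    """Malformed or unsupported structure file."""


def read_plddt(pdb_text: str) -> list[ResidueConfidence]:
    """Extract per-residue pLDDT from a single-chain model PDB.

    The value is taken from the CA atom (falling back to the first atom
    of a residue with a warning when CA is absent); all atoms of a
    residue must agree to within 1e-3, and residue numbering must be
    gap-free, as in AlphaFold monomer output.  Multi-model or
    multi-chain files are rejected.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", io.StringIO(pdb_text))
    models = list(structure)
    if len(models) == 0:
        raise PDBConfidenceError("no ATOM records in structure")
    if len(models) > 1:
        raise PDBConfidenceError("multi-model files are not supported")
    chains = list(models[0])
    if len(chains) != 1:
        raise PDBConfidenceError(
            f"expected a single chain, found {len(chains)}"
        )
    residues = [r for r in chains[0] if r.id[0] == " "]
    if not residues:
        raise PDBConfidenceError("no standard residues in structure")

    out: list[ResidueConfidence] = []
    previous = None
    for res in residues:
        resseq = res.id[1]
        if previous is not None and resseq != previous + 1:
            raise PDBConfidenceError(
                f"residue numbering gap between {previous} and {resseq}"
            )
        previous = resseq
        atoms = list(res)
        bfactors = [a.get_bfactor() for a in atoms]
        if max(bfactors) - min(bfactors) > 1e-3:
            raise PDBConfidenceError(
                f"residue {resseq}: atom B-factors disagree "
                f"({min(bfactors)} vs {max(bfactors)})"
            )
        if "CA" in res:
            value = res["CA"].get_bfactor()
        else:
            warnings.warn(
                f"residue {resseq}: no CA atom, using first atom's B-factor",
                stacklevel=2,
            )
            value = bfactors[0]
        out.append(ResidueConfidence(residue_index=len(out) + 1, plddt=value))
    return out


def motif_confidence(
    hit: MotifHit, confidences: list[ResidueConfidence]
) -> MotifConfidence:
    """Mean pLDDT over the motif's six residues (inclusive interval)."""
    if hit.end > len(confidences):
        raise ValueError(
            f"{hit.protein_id}: motif end {hit.end} exceeds structure "
            f"length {len(confidences)} (isoform/structure mismatch?)"
        )
    values = tuple(
        confidences[i].plddt for i in range(hit.start - 1, hit.end)
    )
    return MotifConfidence(
        hit=hit, residue_plddts=values, mean_plddt=sum(values) / len(values)
    )


def structural_filter(
    hits: list[MotifHit],
    confidences: list[ResidueConfidence],
    threshold: float = PLDDT_THRESHOLD,
) -> StructureFilterResult:
    """Pass iff any motif's mean pLDDT is strictly below ``threshold``."""
    if not hits:
        raise ValueError("structural filter requires at least one motif")
    scored = tuple(motif_confidence(h, confidences) for h in hits)
    return StructureFilterResult(
        protein_id=hits[0].protein_id,
        motif_confidences=scored,
        threshold=threshold,
        passed=any(mc.mean_plddt < threshold for mc in scored),
    )
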
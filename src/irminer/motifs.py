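"""ITIM/ITSM short-linear-motif scanning.

Immunoreceptor tyrosine-based inhibitory motifs (ITIMs) follow the
six-residue consensus (V|L|I|S)xYxx(I|L|V); allowing threonine at the
first position, (V|L|I|S|T)xYxx(I|L|V), additionally captures switch
motifs (ITSMs).  A motif occurrence is any sequence window matching the
consensus; overlapping windows are all reported as distinct hits, and
the identical counter drives the permutation null so the statistic is
internally consistent.

Coordinates are 1-based closed intervals throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

#: Residues accepted at the first consensus position (ITSM extension includes T).
DEFAULT_POS1 = frozenset("VLIST")
#: Residues accepted at the sixth consensus position.
DEFAULT_POS6 = frozenset("ILV")


@dataclass(frozen=True)
class MotifConfig:
    """Consensus definition for the motif scanner.

    ``pos1_set`` / ``pos6_set`` are the constrained positions of the
    consensus; wildcard positions (2, 4, 5) accept any residue,
    including ambiguity codes X/U.  Constrained positions never match
    X/U, so ambiguous residues cannot create evidence at the positions
    that define the motif.  ``itam_linker_range`` is the allowed number
    of residues between the two Yxx(I|L) half-sites of an ITAM.
    """

    pos1_set: frozenset[str] = DEFAULT_POS1
    pos6_set: frozenset[str] = DEFAULT_POS6
    itam_linker_range: tuple[int, int] = (6, 12)

    def __post_init__(self) -> None:
        if not self.pos1_set >= frozenset("VLIS"):
            raise ValueError("pos1_set must contain at least {V,L,I,S}")
        lo, hi = self.itam_linker_range
        if lo > hi:
            raise ValueError("ITAM linker range is empty")

    def pattern(self) -> re.Pattern[str]:
        """Compiled lookahead pattern matching every (overlapping) window."""
        p1 = "".join(sorted(self.pos1_set))
        p6 = "".join(sorted(self.pos6_set))
        return re.compile(f"(?=[{p1}].Y..[{p6}])")


#: Scanner defaults: the extended ITIM/ITSM consensus.
DEFAULT_CONFIG = MotifConfig()

#: Restricted configuration matching only the classic ITIM consensus.
ITIM_ONLY_CONFIG = MotifConfig(pos1_set=frozenset("VLIS"))


@dataclass(frozen=True)
class MotifHit:
    """One six-residue ITIM/ITSM occurrence (1-based closed coordinates)."""

    protein_id: str
    start: int
    end: int
    tyrosine_pos: int
    subsequence: str
    motif_class: str  # "ITIM" or "ITSM"
    itam_embedded: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != 5:
            raise ValueError("motif window must span exactly 6 residues")
        if self.tyrosine_pos != self.start + 2:
            raise ValueError("tyrosine must sit at consensus position 3")


def scan_motifs(
    sequence: str,
    config: MotifConfig = DEFAULT_CONFIG,
    protein_id: str = "",
) -> list[MotifHit]:
    """Return every consensus window in ``sequence``, sorted by start.

    Overlapping hits are all reported.  A hit is labelled ITSM when the
    first consensus residue is threonine, ITIM otherwise; downstream
    stages treat the two classes identically.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    hits = []
    for m in config.pattern().finditer(sequence):
        p = m.start()  # 0-based
        window = sequence[p : p + 6]
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=p + 1,
                end=p + 6,
                tyrosine_pos=p + 3,
                subsequence=window,
                motif_class="ITSM" if window[0] == "T" else "ITIM",
            )
        )
    return hits


def count_motifs(sequence: str, config: MotifConfig = DEFAULT_CONFIG) -> int:
    """Number of consensus windows in ``sequence`` (overlaps counted)."""
    return len(config.pattern().findall(sequence))


def _itam_half_sites(sequence: str) -> list[int]:
    # 1-based tyrosine positions y with sequence[y+3] in {I,L}; ITAM
    # half-sites use the stricter Yxx(I|L) form (no valine).
    out = []
    for i, ch in enumerate(sequence):
        if ch == "Y" and i + 3 < len(sequence) and sequence[i + 3] in "IL":
            out.append(i + 1)
    return out


def scan_itam_embedded(
    sequence: str,
    hits: list[MotifHit],
    config: MotifConfig = DEFAULT_CONFIG,
) -> list[MotifHit]:
    """Flag hits whose tyrosine belongs to a spacing-valid ITAM.

    An ITAM is Yxx(I|L) x(6-12) Yxx(I|L): two half-sites with 6-12
    intervening residues between the end of the first half-site and the
    second tyrosine.  The flag is an annotation only — ITAM-embedded
    ITIMs are never filtered out, since such receptors may still signal
    either way.
    """
    halves = _itam_half_sites(sequence)
    lo, hi = config.itam_linker_range
    itam_tyrosines: set[int] = set()
    for a, y1 in enumerate(halves):
        for y2 in halves[a + 1 :]:
            linker = y2 - (y1 + 3) - 1
            if lo <= linker <= hi:
                itam_tyrosines.add(y1)
                itam_tyrosines.add(y2)
    return [
        replace(h, itam_embedded=h.tyrosine_pos in itam_tyrosines) for h in hits
    ]
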
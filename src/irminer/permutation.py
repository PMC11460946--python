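"""Composition-preserving permutation null for motif occurrence.

Large proteins, or proteins rich in tyrosines and hydrophobic residues,
contain ITIM/ITSM windows by chance alone.  The null model shuffles the
residues of each intracellular domain (Fisher-Yates, preserving
composition and domain lengths), recounts motifs with the identical
window counter used by the scanner, and reports the fraction of
shuffles with at least as many motifs as the original arrangement -- a
one-sided permutation p-value.  Candidates are kept when this
likelihood is at most 0.25 + epsilon, with epsilon drawn uniformly from
[0, 0.01) per protein to randomise borderline decisions reproducibly.

``exact_likelihood`` enumerates all residue orderings of a short domain
and serves as the independent oracle for the Monte-Carlo estimate.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .motifs import DEFAULT_CONFIG, MotifConfig, count_motifs

#: Default number of shuffles per protein.
DEFAULT_N_PERMUTATIONS = 10_000

#: Base inclusion threshold on the chance likelihood.
LIKELIHOOD_BASE = 0.25

#: Upper bound of the per-protein epsilon jitter added to the threshold.
EPSILON_MAX = 0.01


@dataclass(frozen=True)
class PermutationResult:
    """Monte-Carlo chance likelihood plus the epsilon-adjusted decision."""

    protein_id: str
    observed_count: int
    n_permutations: int
    n_geq: int
    likelihood: float
    epsilon: float
    threshold: float
    passed: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_geq <= self.n_permutations:
            raise ValueError("n_geq out of range")
        if self.passed != (self.likelihood <= self.threshold):
            raise ValueError("decision inconsistent with likelihood/threshold")


def protein_rng(seed: int, protein_id: str) -> np.random.Generator:
    """Per-protein child generator: reproducible and order-independent."""
    return np.random.default_rng([seed, zlib.crc32(protein_id.encode())])


def fisher_yates_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Uniformly random permutation of the residues of ``sequence``.

    Delegates to the generator's in-place shuffle, which implements the
    Fisher-Yates algorithm; the character multiset is preserved.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype="S1").copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def count_motifs_in_domains(
    domains: list[str], config: MotifConfig = DEFAULT_CONFIG
) -> int:
    """Total motif windows across domains; windows never span domains."""
    return sum(count_motifs(d, config) for d in domains if d)


def permutation_likelihood(
    domains: list[str],
    observed_count: int,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng: np.random.Generator | None = None,
    *,
    config: MotifConfig = DEFAULT_CONFIG,
    protein_id: str = "",
    epsilon: float | None = None,
    threshold_base: float = LIKELIHOOD_BASE,
    epsilon_max: float = EPSILON_MAX,
    seed: int | None = None,
    check_invariants: bool = False,
) -> PermutationResult:
    """Estimate the chance of >= ``observed_count`` motifs under shuffling.

    Each iteration independently shuffles every domain and recounts
    motifs with the scanner's window counter.  ``epsilon`` is drawn
    from [0, epsilon_max) with ``rng`` when not supplied.  With
    ``check_invariants`` every iteration asserts that shuffling
    preserved each domain's length and composition.
    """
    if not domains:
        raise ValueError("at least one intracellular domain required")
    if observed_count < 1:
        raise ValueError(
            "proteins enter the permutation test with >= 1 observed motif"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("provide rng or seed")
        rng = protein_rng(seed, protein_id)
    if epsilon is None:
        epsilon = float(rng.uniform(0.0, epsilon_max))
    if not 0.0 <= epsilon < epsilon_max + 1e-12:
        raise ValueError("epsilon outside [0, epsilon_max)")

    arrays = [
        np.frombuffer(d.encode("ascii"), dtype="S1").copy() for d in domains
    ]
    references = [np.sort(a.copy()) for a in arrays]
    n_geq = 0
    for _ in range(n_permutations):
        count = 0
        for arr, ref in zip(arrays, references):
            rng.shuffle(arr)
            if check_invariants:
                assert arr.size == ref.size
                assert np.array_equal(np.sort(arr), ref)
            count += count_motifs(arr.tobytes().decode("ascii"), config)
            if count >= observed_count:
                break
        if count >= observed_count:
            n_geq += 1

    likelihood = n_geq / n_permutations
    threshold = threshold_base + epsilon
    return PermutationResult(
        protein_id=protein_id,
        observed_count=observed_count,
        n_permutations=n_permutations,
        n_geq=n_geq,
        likelihood=likelihood,
        epsilon=epsilon,
        threshold=threshold,
        passed=likelihood <= threshold,
        seed=seed,
    )


def exact_likelihood(
    domain: str,
    config: MotifConfig = DEFAULT_CONFIG,
    observed: int | None = None,
    max_len: int = 9,
) -> Fraction:
    """Exact chance of >= ``observed`` motifs under position permutation.

    Enumerates all ``len!`` orderings of the residues (identical letters
    contribute their multiplicity, so the count is correctly weighted)
    and returns the exact probability as a fraction.  ``observed``
    defaults to the motif count of the domain as given, floored at 1,
    so a motif-free domain scores the probability of seeing any motif
    at all.  Feasible only for short domains.
    """
    n = len(domain)
    if n > max_len:
        raise ValueError(f"domain length {n} exceeds enumeration bound {max_len}")
    if n == 0:
        raise ValueError("empty domain")
    if observed is None:
        observed = max(1, count_motifs(domain, config))
    pattern = config.pattern()
    favourable = sum(
        1
        for perm in itertools.permutations(domain)
        if len(pattern.findall("".join(perm))) >= observed
    )
    return Fraction(favourable, math.factorial(n))


def apply_likelihood_filter(
    results: list[PermutationResult],
) -> tuple[list[PermutationResult], list[PermutationResult]]:
    """Partition results by the 0.25+epsilon inclusion decision."""
    kept = [r for r in results if r.passed]
    excluded = [r for r in results if not r.passed]
    return kept, excluded
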
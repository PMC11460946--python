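"""Permutation null: shuffling, counting, Monte-Carlo vs exact oracle."""

from fractions import Fraction

import numpy as np
import pytest

from irminer.motifs import count_motifs
from irminer.permutation import (
    PermutationResult,
    apply_likelihood_filter,
    count_motifs_in_domains,
    exact_likelihood,
    fisher_yates_shuffle,
    permutation_likelihood,
    protein_rng,
)

from conftest import random_protein


class TestFisherYatesShuffle:
    def test_homopolymer_fixed_point(self, rng):
        assert fisher_yates_shuffle("AAAA", rng) == "AAAA"

    def test_composition_preserved(self, rng):
        for _ in range(100):
            s = random_protein(rng, 30)
            assert sorted(fisher_yates_shuffle(s, rng)) == sorted(s)

    def test_two_letter_frequency_is_uniform(self, rng):
        # over 10,000 shuffles of "AB", "BA" appears ~half the time
        n_ba = sum(fisher_yates_shuffle("AB", rng) == "BA" for _ in range(10_000))
        assert abs(n_ba / 10_000 - 0.5) <= 0.015  # binomial 3-sigma


class TestCountMotifsInDomains:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            (["SDYSEL"], 1),
            (["SDYSEL", "TEYSTV"], 2),
            (["SDY", "SEL"], 0),  # no window spans the boundary
            ([], 0),
            (["", "SDYSEL"], 1),
        ],
    )
    def test_per_domain_sum(self, domains, expected):
        assert count_motifs_in_domains(domains) == expected


class TestExactLikelihood:
    def test_sayaal_is_one_in_120(self):
        assert exact_likelihood("SAYAAL") == Fraction(1, 120)

    def test_no_tyrosine_gives_zero(self):
        assert exact_likelihood("AAAAAA") == 0

    def test_all_tyrosine_gives_zero(self):
        # positions 1 and 6 can never satisfy the constrained sets
        assert exact_likelihood("YYYYYY") == 0

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError, match="enumeration bound"):
            exact_likelihood("SAYAALSAYA")  # length 10 > 9

    def test_matches_direct_enumeration_with_repeats(self):
        # independent cross-check: count favourable orderings by brute force
        import itertools, math

        domain = "SSYALA"
        favourable = sum(
            count_motifs("".join(p)) >= 1
            for p in itertools.permutations(domain)
        )
        assert exact_likelihood(domain) == Fraction(
            favourable, math.factorial(len(domain))
        )


class TestPermutationLikelihood:
    def test_sayaal_close_to_exact(self):
        exact = float(exact_likelihood("SAYAAL"))
        r = permutation_likelihood(
            ["SAYAAL"], 1, 10_000, np.random.default_rng(7)
        )
        se3 = 3 * np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(r.likelihood - exact) <= se3

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError, match=">= 1 observed"):
            permutation_likelihood(["AAAAAA"], 0, 100, np.random.default_rng(0))

    def test_empty_domain_list_rejected(self):
        with pytest.raises(ValueError, match="domain required"):
            permutation_likelihood([], 1, 100, np.random.default_rng(0))

    def test_same_seed_reproduces_result_exactly(self):
        a = permutation_likelihood(
            ["SAYAALKRED", "LDYARV"], 2, 500,
            protein_rng(42, "P1"), protein_id="P1", seed=42,
        )
        b = permutation_likelihood(
            ["SAYAALKRED", "LDYARV"], 2, 500,
            protein_rng(42, "P1"), protein_id="P1", seed=42,
        )
        assert a == b

    def test_identity_arrangement_floor(self, rng):
        # the original arrangement is always reachable, so the
        # likelihood can never be exactly zero
        for _ in range(10):
            domain = random_protein(rng, 8)
            if count_motifs(domain) == 0:
                domain = "SAYAAL" + domain[:2]
            r = permutation_likelihood(
                [domain], count_motifs(domain), 2000, rng
            )
            assert r.likelihood >= 0  # and typically >= 1/N
        dense = permutation_likelihood(["SDYSEL"] , 1, 5000, rng)
        assert dense.likelihood >= 1 / 5000

    def test_invariant_checking_mode(self, rng):
        r = permutation_likelihood(
            ["SAYAAL", "KRDESDYSEL"], 2, 200, rng, check_invariants=True
        )
        assert 0 <= r.likelihood <= 1

    def test_epsilon_recorded_and_bounded(self, rng):
        r = permutation_likelihood(["SAYAAL"], 1, 100, rng)
        assert 0.0 <= r.epsilon < 0.01
        assert r.threshold == 0.25 + r.epsilon


class TestLikelihoodFilter:
    def make(self, likelihood, epsilon):
        return PermutationResult(
            protein_id="P", observed_count=1, n_permutations=1000,
            n_geq=int(likelihood * 1000), likelihood=likelihood,
            epsilon=epsilon, threshold=0.25 + epsilon,
            passed=likelihood <= 0.25 + epsilon,
        )

    def test_low_likelihood_kept(self):
        kept, excluded = apply_likelihood_filter([self.make(0.04, 0.005)])
        assert len(kept) == 1 and not excluded

    def test_high_likelihood_excluded_for_any_epsilon(self):
        kept, excluded = apply_likelihood_filter([self.make(0.40, 0.0099)])
        assert not kept and len(excluded) == 1

    def test_borderline_decided_by_epsilon(self):
        kept, _ = apply_likelihood_filter([self.make(0.253, 0.005)])
        assert len(kept) == 1
        _, excluded = apply_likelihood_filter([self.make(0.253, 0.001)])
        assert len(excluded) == 1

    def test_inconsistent_decision_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PermutationResult(
                protein_id="P", observed_count=1, n_permutations=100,
                n_geq=4, likelihood=0.04, epsilon=0.0, threshold=0.25,
                passed=False,
            )


class TestProteinRng:
    def test_order_independent_streams(self):
        # the same protein gets the same stream regardless of other draws
        a = protein_rng(3, "P0001").uniform()
        _ = protein_rng(3, "P0002").uniform()
        b = protein_rng(3, "P0001").uniform()
        assert a == b

    def test_distinct_proteins_get_distinct_streams(self):
        assert protein_rng(3, "P0001").uniform() != protein_rng(3, "P0002").uniform()
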
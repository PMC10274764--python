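"""Likelihood models: worked examples, oracle equivalence, invariances."""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldchase.models import (
    FrequencyFunction,
    HomologDistributionPair,
    UninformativeSubsample,
    disomy_likelihood,
    matched_likelihood,
    unmatched_likelihood,
    window_llr,
)
from ldchase.panel import AncestryComposition

from .conftest import make_panel


def enumeration_oracle(a_reads, b_reads, f):
    """Independent brute force: sum over all homolog assignments of B-reads.

    matched: homolog 1 carries the A-alleles, so a B-read assigned to it
    joins the A conjunction; each of the 2^n assignments has weight
    (1/2)^n.  unmatched: the A conjunction stands alone.
    """
    n = len(b_reads)
    a_all = frozenset().union(*a_reads)
    p_matched = 0.0
    p_unmatched = 0.0
    for bits in range(2**n):
        side1 = [b_reads[i] for i in range(n) if bits >> i & 1]
        side2 = [b_reads[i] for i in range(n) if not bits >> i & 1]
        u1 = frozenset().union(*side1) if side1 else frozenset()
        u2 = frozenset().union(*side2) if side2 else frozenset()
        p_matched += f(a_all | u1) * f(u2)
        p_unmatched += f(a_all) * f(u1) * f(u2)
    return p_matched / 2**n, p_unmatched / 2**n


@pytest.fixture
def ld_pair(ld_panel, single_pop):
    return HomologDistributionPair.from_composition(ld_panel, single_pop)


class TestWorkedExamples:
    def test_matched_single_reads_recovers_half_joint_plus_product(self, ld_pair):
        # f(A)=f(B)=0.5, perfect LD so f(A,B)=0.5: 1/2*0.5 + 1/2*0.25
        a = [frozenset([(100, 1)])]
        b = [frozenset([(200, 1)])]
        assert matched_likelihood(a, b, ld_pair) == pytest.approx(0.375)

    def test_unmatched_single_reads_is_product(self, ld_pair):
        a = [frozenset([(100, 1)])]
        b = [frozenset([(200, 1)])]
        assert unmatched_likelihood(a, b, ld_pair) == pytest.approx(0.25)

    def test_llr_single_snp_perfect_ld(self, ld_pair):
        """The canonical worked value: gamma = ln(0.25/0.375) ~ -0.4055."""
        a = [frozenset([(100, 1)])]
        b = [frozenset([(200, 1)])]
        res = window_llr(a, b, ld_pair)
        assert res.gamma == pytest.approx(math.log(0.25 / 0.375))
        assert res.gamma == pytest.approx(-0.4055, abs=1e-4)

    def test_equilibrium_sites_give_zero_llr(self, equilibrium_panel, single_pop):
        """When the joint factorizes, both hypotheses coincide."""
        pair = HomologDistributionPair.from_composition(equilibrium_panel, single_pop)
        a = [frozenset([(100, 1)])]
        b = [frozenset([(200, 1)])]
        assert window_llr(a, b, pair).gamma == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_a_span_reduces_to_disomy(self, single_pop):
        panel = make_panel(np.array([[1, 1], [1, 0], [1, 1], [1, 0]]))
        pair = HomologDistributionPair.from_composition(panel, single_pop)
        a = [frozenset([(100, 1)])]  # fixed allele: F(A) = 1
        b = [frozenset([(200, 1)])]
        f = pair.d1
        assert unmatched_likelihood(a, b, pair) == pytest.approx(
            disomy_likelihood(b, f, f)
        )


class TestDisomyModel:
    def test_empty_reads_probability_one(self, ld_pair):
        assert disomy_likelihood([], ld_pair.d1, ld_pair.d2) == 1.0

    def test_single_read_marginalizes(self, ld_pair):
        b = frozenset([(100, 1)])
        f = ld_pair.d1
        assert disomy_likelihood([b], f, f) == pytest.approx(f(b))

    def test_two_reads_structure(self, equilibrium_panel, single_pop):
        f = FrequencyFunction(equilibrium_panel, single_pop)
        b1 = frozenset([(100, 1)])
        b2 = frozenset([(200, 1)])
        expected = 0.5 * f(b1 | b2) + 0.5 * f(b1) * f(b2)
        assert disomy_likelihood([b1, b2], f, f) == pytest.approx(expected)

    def test_read_cap_enforced(self, ld_pair):
        b = [frozenset([(100, 1)])] * 13
        with pytest.raises(ValueError, match="cap"):
            disomy_likelihood(b, ld_pair.d1, ld_pair.d2)


class TestOracleEquivalence:
    """Bitmask likelihoods equal exhaustive assignment enumeration."""

    @settings(deadline=None, max_examples=60)
    @given(
        seed=st.integers(0, 2**31 - 1),
        m=st.integers(1, 3),
        n=st.integers(1, 3),
    )
    def test_matches_enumeration_on_random_panels(self, seed, m, n):
        rng = np.random.default_rng(seed)
        panel = make_panel(rng.integers(0, 2, size=(8, 5)))
        comp = AncestryComposition.single("P1")
        pair = HomologDistributionPair.from_composition(panel, comp)

        def rand_read():
            k = int(rng.integers(1, 3))
            idx = rng.choice(5, size=k, replace=False)
            return frozenset(
                (int(panel.positions[i]), int(rng.integers(0, 2))) for i in idx
            )

        a = [rand_read() for _ in range(m)]
        b = [rand_read() for _ in range(n)]
        pm_o, pu_o = enumeration_oracle(a, b, pair.d1)
        assert matched_likelihood(a, b, pair) == pytest.approx(pm_o, rel=1e-12)
        assert unmatched_likelihood(a, b, pair) == pytest.approx(pu_o, rel=1e-12)

    def test_m2_n2_explicit(self, ld_panel, single_pop):
        pair = HomologDistributionPair.from_composition(ld_panel, single_pop)
        a = [frozenset([(100, 1)]), frozenset([(200, 1)])]
        b = [frozenset([(100, 1)]), frozenset([(200, 0)])]
        pm_o, pu_o = enumeration_oracle(a, b, pair.d1)
        assert matched_likelihood(a, b, pair) == pytest.approx(pm_o, rel=1e-12)
        assert unmatched_likelihood(a, b, pair) == pytest.approx(pu_o, rel=1e-12)


class TestExchangeability:
    def test_likelihood_invariant_under_read_permutation(self, single_pop):
        rng = np.random.default_rng(7)
        panel = make_panel(rng.integers(0, 2, size=(10, 4)))
        pair = HomologDistributionPair.from_composition(panel, single_pop)
        a = [frozenset([(100, 1)]), frozenset([(200, 0)])]
        b = [
            frozenset([(300, 1)]),
            frozenset([(400, 0)]),
            frozenset([(100, 0)]),
        ]
        base_m = matched_likelihood(a, b, pair)
        base_u = unmatched_likelihood(a, b, pair)
        for pa in permutations(a):
            for pb in permutations(b):
                assert matched_likelihood(list(pa), list(pb), pair) == pytest.approx(
                    base_m, rel=1e-12
                )
                assert unmatched_likelihood(list(pa), list(pb), pair) == pytest.approx(
                    base_u, rel=1e-12
                )


class TestAdmixture:
    def test_identical_parent_populations_collapse_to_non_admixed(
        self, two_pop_panel
    ):
        pair_recent = HomologDistributionPair.recent_admixture(
            two_pop_panel, "EUR", "EUR"
        )
        pair_plain = HomologDistributionPair.from_composition(
            two_pop_panel, AncestryComposition.single("EUR")
        )
        a = [frozenset([(100, 1)])]
        b = [frozenset([(100, 0)])]
        assert window_llr(a, b, pair_recent).gamma == pytest.approx(
            window_llr(a, b, pair_plain).gamma
        )

    def test_effective_frequency_substitution(self, two_pop_panel):
        comp = AncestryComposition.of({"EUR": 0.3, "EAS": 0.7})
        f = FrequencyFunction(two_pop_panel, comp)
        obs = frozenset([(100, 1)])
        expected = 0.3 * 0.75 + 0.7 * (1 / 6)
        assert f(obs) == pytest.approx(expected)


class TestZeroHandling:
    def test_absent_combination_floored_not_zero(self, single_pop):
        # alleles 1@100 and 1@200 both present but never together
        panel = make_panel(np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        f = FrequencyFunction(panel, single_pop)
        obs = frozenset([(100, 1), (200, 1)])
        assert f.raw(obs) == 0.0
        assert f(obs) == f.floor > 0.0

    def test_absent_allele_stays_zero(self, single_pop):
        panel = make_panel(np.array([[0], [0], [0], [0]]))
        f = FrequencyFunction(panel, single_pop)
        assert f(frozenset([(100, 1)])) == 0.0

    def test_all_absent_alleles_uninformative(self, single_pop):
        panel = make_panel(np.array([[0, 0]] * 4))
        pair = HomologDistributionPair.from_composition(panel, single_pop)
        a = [frozenset([(100, 1)])]
        b = [frozenset([(200, 1)])]
        with pytest.raises(UninformativeSubsample):
            window_llr(a, b, pair)

    def test_subset_frequencies_match_scalar_path(self, single_pop):
        rng = np.random.default_rng(13)
        panel = make_panel(rng.integers(0, 2, size=(9, 4)))
        f = FrequencyFunction(panel, single_pop)
        reads = [
            frozenset([(100, 1)]),
            frozenset([(200, 0), (300, 1)]),
            frozenset([(400, 1)]),
        ]
        infos = [f.read_info(r) for r in reads]
        vals = f.subset_frequencies(infos)
        for bits in range(8):
            union = frozenset().union(
                *(reads[i] for i in range(3) if bits >> i & 1)
            )
            assert vals[bits] == pytest.approx(f(union), rel=1e-12)
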
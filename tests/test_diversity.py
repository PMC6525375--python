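"""Diversity statistics against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitopop as mp
from conftest import random_sequences, table_from_counts


class TestSiteSummary:
    def test_identical_sequences(self):
        aln = mp.Alignment.from_records([("a", "ACGT"), ("b", "ACGT")])
        s = mp.site_summary(aln)
        assert (s.n_variable, s.n_parsimony_informative, s.n_singleton) == (0, 0, 0)

    def test_singleton_site_not_informative(self):
        # states A x1 and T x2: only one state reaches two carriers
        aln = mp.Alignment.from_records([("a", "AAA"), ("b", "AAT"), ("c", "AAT")])
        s = mp.site_summary(aln)
        assert s.n_variable == 1
        assert s.n_parsimony_informative == 0
        assert s.n_singleton == 1

    def test_informative_site(self):
        aln = mp.Alignment.from_records(
            [("a", "AAA"), ("b", "AAT"), ("c", "AAT"), ("d", "AAA")]
        )
        s = mp.site_summary(aln)
        assert s.n_parsimony_informative == 1

    def test_base_composition_sums_to_one(self, study_fixture):
        aln, *_ = study_fixture
        s = mp.site_summary(aln)
        assert abs(sum(s.base_composition.values()) - 1.0) < 1e-9

    def test_all_sites_excluded_errors(self):
        aln = mp.Alignment.from_records([("a", "N-"), ("b", "AC")])
        with pytest.raises(ValueError, match="deletion"):
            mp.site_summary(aln)


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3], 0.0),                 # monomorphic
            ([1, 1], 1.0),              # two distinct, n = 2
            ([2, 2], 4 * 0.5 / 3),      # direct formula: n(1-sum p^2)/(n-1)
        ],
    )
    def test_known_values(self, counts, expected):
        h, sd = mp.haplotype_diversity(counts)
        assert h == pytest.approx(expected, abs=1e-12)
        assert sd >= 0

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            mp.haplotype_diversity([1])

    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=8).filter(
            lambda c: sum(c) >= 2
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_zero_iff_monomorphic(self, counts):
        h, _ = mp.haplotype_diversity(counts)
        assert 0.0 <= h <= 1.0
        assert (h == 0.0) == (sum(1 for c in counts if c > 0) == 1)

    def test_invariant_under_collapse_expand(self, study_fixture):
        _aln, hier, table, _ = study_fixture
        h1, _ = mp.haplotype_diversity(table.group_counts())
        expanded = table.expand()
        recs = [(f"e{i}", s) for i, s in enumerate(expanded)]
        aln2 = mp.Alignment.from_records(recs)
        hier2 = mp.PopulationHierarchy({sid: ("x", "p", "s", "r") for sid, _ in recs})
        t2 = mp.collapse_haplotypes(aln2, hier2)
        h2, _ = mp.haplotype_diversity(t2.group_counts())
        assert h1 == h2


class TestNucleotideDiversity:
    def test_monomorphic_zero(self):
        t = table_from_counts(["ACGTACGT"], {"p": [5]})
        pi, _, K = mp.nucleotide_diversity(t)
        assert pi == 0.0 and K == 0.0

    def test_two_sequences_one_difference(self):
        rng = np.random.default_rng(1)
        seqs = random_sequences(rng, 2, 453, 1)
        t = table_from_counts(seqs, {"p": [1, 1]})
        pi, _, K = mp.nucleotide_diversity(t)
        assert K == pytest.approx(1.0)
        assert pi == pytest.approx(1 / 453)

    def test_matches_bruteforce_pairs(self):
        """pi equals the explicit average over all individual pairs."""
        rng = np.random.default_rng(5)
        seqs = random_sequences(rng, 4, 60, 3)
        counts = [6, 5, 4, 3]
        t = table_from_counts(seqs, {"p": [c for c in counts]})
        _, _, K = mp.nucleotide_diversity(t)
        individuals = []
        for s, c in zip(seqs, counts):
            individuals.extend([s] * c)
        diffs = [
            sum(a != b for a, b in zip(x, y))
            for x, y in itertools.combinations(individuals, 2)
        ]
        assert K == pytest.approx(np.mean(diffs), abs=1e-12)

    def test_pooling_identical_populations_invariant(self):
        rng = np.random.default_rng(9)
        seqs = random_sequences(rng, 3, 50, 2)
        single = table_from_counts(seqs, {"p1": [4, 2, 2]})
        double = table_from_counts(seqs, {"p1": [4, 2, 2], "p2": [4, 2, 2]})
        pi1, _, K1 = mp.nucleotide_diversity(single)
        pi2, _, K2 = mp.nucleotide_diversity(double)
        h1, _ = mp.haplotype_diversity(single.group_counts())
        h2, _ = mp.haplotype_diversity(double.group_counts())
        # unbiased (n-dependent) corrections shift estimates slightly with n
        assert pi1 == pytest.approx(pi2, rel=0.1)
        assert K1 == pytest.approx(K2, rel=0.1)
        assert h1 == pytest.approx(h2, abs=0.05)


class TestDiversityReport:
    def test_row_structure(self, study_fixture):
        _aln, hier, table, _ = study_fixture
        rows = mp.diversity_report(table, hier)
        levels = [r.level for r in rows]
        assert levels.count("population") == 15
        # Atlantic sub-region coincides with its region -> reported once
        assert levels.count("sub_region") == 2
        assert levels.count("region") == 2
        assert levels[-1] == "total"
        for r in rows:
            if r.defined:
                assert 0 <= r.h <= 1 and r.pi >= 0 and r.K >= 0
                assert r.Nh <= r.N

    def test_single_population_equals_total(self):
        rng = np.random.default_rng(3)
        seqs = random_sequences(rng, 3, 40, 2)
        t = table_from_counts(seqs, {"p1": [3, 2, 1]})
        hier = mp.PopulationHierarchy(
            {f"s{i}": ("x", "p1", "sr", "r") for i in range(6)}
        )
        rows = mp.diversity_report(t, hier)
        pop = [r for r in rows if r.level == "population"][0]
        tot = [r for r in rows if r.level == "total"][0]
        assert pop.h == tot.h and pop.K == tot.K

    def test_k_equals_pi_times_length(self, study_fixture):
        aln, hier, table, _ = study_fixture
        sites = aln.included_sites()
        rows = mp.diversity_report(table, hier, sites, len(sites))
        for r in rows:
            if r.defined:
                assert r.K == pytest.approx(r.pi * len(sites), rel=1e-9)
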
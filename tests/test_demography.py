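"""Neutrality statistics, mismatch distributions and expansion fits."""

import itertools
import math

import numpy as np
import pytest
from sympy.utilities.iterables import partitions

import mitopop as mp
from mitopop.demography import (
    SequenceGroup,
    _ewens_alleles_tail,
    expected_mismatch_demographic,
    expected_mismatch_spatial,
)
from conftest import random_sequences, table_from_counts


def _group(seqs: list[str]) -> SequenceGroup:
    return SequenceGroup.from_sequences(seqs)


class TestTajimasD:
    def test_no_polymorphism_undefined(self):
        assert mp.tajimas_d(_group(["ACGT", "ACGT"])) is None

    def test_hand_value_n4_one_singleton(self):
        # n=4, one singleton site: full a1..e2 hand evaluation gives -0.612
        seqs = ["AAAAA", "AAAAA", "AAAAA", "AAAAT"]
        d = mp.tajimas_d(_group(seqs))
        assert d == pytest.approx(-0.612, abs=1e-3)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_formula_oracle_small_n(self, trial):
        rng = np.random.default_rng(50 + trial)
        seqs = random_sequences(rng, int(rng.integers(4, 10)), 80, 2)
        g = _group(seqs)
        if g.S == 0:
            pytest.skip("monomorphic draw")
        n, S, K = g.n, g.S, g.K
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (K - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert mp.tajimas_d(g) == pytest.approx(expected, abs=1e-9)


class TestFusFs:
    def test_two_sequences_one_difference(self):
        # (theta)_2 = theta(theta+1); P(k=2) = theta^2/... = 0.5 at theta=1
        assert mp.fus_fs(2, 1.0, 2) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        assert mp.fus_fs(10, 0.0, 1) is None

    @pytest.mark.parametrize("n,theta", [(4, 0.8), (6, 1.5), (8, 2.0)])
    def test_stirling_tail_matches_partition_enumeration(self, n, theta):
        """Ewens tail via Stirling numbers vs brute-force sum over allele
        partitions weighted by the Ewens sampling formula."""
        rising = math.prod(theta + i for i in range(n))
        by_k = {}
        for part in partitions(n):
            k = sum(part.values())
            prob = (
                math.factorial(n)
                * theta**k
                / rising
                / math.prod(j**aj * math.factorial(aj) for j, aj in part.items())
            )
            by_k[k] = by_k.get(k, 0.0) + prob
        assert sum(by_k.values()) == pytest.approx(1.0)
        for k_obs in range(1, n + 1):
            brute = sum(v for k, v in by_k.items() if k >= k_obs)
            assert _ewens_alleles_tail(n, k_obs, theta) == pytest.approx(
                brute, abs=1e-12
            )


class TestR2:
    def test_two_sequences_one_difference(self):
        assert mp.r2_stat(_group(["AAAA", "AAAT"])) == pytest.approx(0.5)

    def test_monomorphic_undefined(self):
        assert mp.r2_stat(_group(["AAAA", "AAAA", "AAAA"])) is None


class TestMismatch:
    def test_identical_mass_at_zero(self):
        freq = mp.mismatch_observed(_group(["ACGT"] * 4))
        assert freq.tolist() == [1.0]

    def test_single_pair_one_difference(self):
        freq = mp.mismatch_observed(_group(["AAAA", "AAAT"]))
        assert freq.tolist() == [0.0, 1.0]

    def test_mean_equals_k(self, study_fixture):
        aln, _hier, table, _ = study_fixture
        g = SequenceGroup.from_table(table, None, aln.included_sites())
        freq = mp.mismatch_observed(g)
        assert freq.sum() == pytest.approx(1.0)
        assert float((np.arange(freq.size) * freq).sum()) == pytest.approx(g.K)

    def test_raggedness_hand_value(self):
        assert mp.raggedness([0.5, 0.5]) == pytest.approx(0.25)

    def test_smooth_flatter_than_spiky(self):
        smooth = np.full(10, 0.1)
        spiky = np.array([0.5, 0, 0.3, 0, 0.2, 0, 0, 0, 0, 0])
        assert mp.raggedness(smooth) < mp.raggedness(spiky)


class TestExpectedMismatch:
    def test_tau_zero_is_stationary_geometric(self):
        theta = 2.5
        f = expected_mismatch_demographic(15, 0.0, theta, 100.0)
        j = np.arange(15)
        geometric = theta**j / (theta + 1) ** (j + 1)
        assert np.allclose(f, geometric, atol=1e-12)

    def test_distributions_are_proper(self):
        for f in (
            expected_mismatch_demographic(200, 3.0, 0.4, 800.0),
            expected_mismatch_spatial(200, 3.0, 1.2, 4.0),
        ):
            assert (f >= 0).all()
            assert f.sum() == pytest.approx(1.0, abs=1e-6)

    def test_spatial_no_migration_is_single_population(self):
        # M=0: lineages never separate, ancestral deme same size: stationary
        theta = 1.5
        f = expected_mismatch_spatial(20, 2.0, theta, 0.0)
        j = np.arange(20)
        geometric = theta**j / (theta + 1) ** (j + 1)
        assert np.allclose(f, geometric, atol=1e-10)


class TestFitExpansion:
    def test_exact_curve_recovered(self):
        obs = expected_mismatch_demographic(25, 3.0, 0.5, 60.0)
        g = SequenceGroup(20, 5, float((np.arange(25) * obs).sum()), (0,) * 20, (1,) * 190)
        fit_obs = obs / obs.sum()
        from mitopop.demography import _fit_ssd

        tau, t0, t1, ssd = _fit_ssd(fit_obs, "demographic", None, np.random.default_rng(0))
        assert ssd < 1e-8
        assert tau == pytest.approx(3.0, abs=0.1)

    def test_fit_on_expansion_sample(self):
        scenario = mp.make_scenario(
            "postglacial_expansion",
            populations={"p": (60, "s", "r")},
            seed=5,
        )
        aln, hier, _ = mp.simulate_coalescent(scenario)
        table = mp.collapse_haplotypes(aln, hier)
        g = SequenceGroup.from_table(table, None, aln.included_sites())
        fit = mp.fit_expansion(g, "demographic", bootstrap=30, seed=2)
        assert fit.SSD >= 0
        assert fit.tau >= 0
        assert 0 < fit.P_SSD <= 1

    def test_requires_polymorphism(self):
        with pytest.raises(ValueError):
            mp.fit_expansion(_group(["AAAA", "AAAA"]), "demographic")


class TestNeutralitySignificance:
    def test_neutral_sample_p_moderate(self, small_panmictic):
        aln, _hier, table = small_panmictic
        g = SequenceGroup.from_table(table, None, aln.included_sites())
        res = mp.neutrality_tests(g, n_simulations=200, seed=3)
        # a neutral constant-size draw should not be extreme in either tail
        assert 0.005 < res.P_D < 0.995
        assert res.n == 25 and res.S == g.S

    def test_expansion_pushes_d_negative(self):
        negatives = 0
        for seed in range(6):
            scenario = mp.make_scenario(
                "postglacial_expansion", populations={"p": (50, "s", "r")}, seed=seed
            )
            aln, hier, _ = mp.simulate_coalescent(scenario)
            table = mp.collapse_haplotypes(aln, hier)
            g = SequenceGroup.from_table(table, None, aln.included_sites())
            d = mp.tajimas_d(g)
            if d is not None and d < 0:
                negatives += 1
        assert negatives >= 5
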
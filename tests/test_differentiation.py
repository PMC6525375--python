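"""Distances, AMOVA vs a brute-force oracle, FDR, GST/NST."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mitopop as mp
from conftest import random_sequences, table_from_counts


# ---------------------------------------------------------------------------
# Tajima-Nei distance
# ---------------------------------------------------------------------------


def _tajima_nei_oracle(sa: str, sb: str) -> float:
    """Straight transcription of the published formula, element by element."""
    L = len(sa)
    p = sum(a != b for a, b in zip(sa, sb)) / L
    if p == 0:
        return 0.0
    bases = "ACGT"
    g = {
        x: (sa.count(x) + sb.count(x)) / (2 * L) for x in bases
    }
    h = 0.0
    for i, j in itertools.combinations(range(4), 2):
        bi, bj = bases[i], bases[j]
        x_ij = sum(
            1 for a, b in zip(sa, sb) if {a, b} == {bi, bj}
        ) / L
        if g[bi] and g[bj]:
            h += x_ij**2 / (2 * g[bi] * g[bj])
    b_coef = 0.5 * (1 - sum(v**2 for v in g.values()) + p**2 / h)
    return -b_coef * math.log(1 - p / b_coef)


class TestTajimaNei:
    def test_identical_pair_zero(self):
        d = mp.tajima_nei_pair("ACGTACGT", "ACGTACGT")
        assert d == 0.0

    def test_jukes_cantor_limit(self):
        # near-equal base frequencies, one difference in 453 sites
        base = "ACGT" * 113 + "A"
        other = "T" + base[1:]
        p = 1 / 453
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert mp.tajima_nei_pair(base, other) == pytest.approx(jc, abs=1e-4)

    def test_matrix_matches_hand_oracle(self):
        rng = np.random.default_rng(17)
        seqs = random_sequences(rng, 3, 120, 4)
        dm = mp.tajima_nei_matrix(seqs)
        for i, j in itertools.combinations(range(3), 2):
            assert dm.d[i, j] == pytest.approx(
                _tajima_nei_oracle(seqs[i], seqs[j]), abs=1e-12
            )

    def test_saturation_names_pair(self):
        with pytest.raises(mp.differentiation.SaturationError, match="H1, H2"):
            mp.tajima_nei_matrix(["AAAA", "TTTT"])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _amova_oracle(pop_of_ind, hap_of_ind, d2):
    """Brute-force sums of squares over explicit individual pairs."""
    N = len(pop_of_ind)
    pops = sorted(set(pop_of_ind))
    def ssd(idx):
        tot = 0.0
        for a, b in itertools.combinations(idx, 2):
            tot += d2[hap_of_ind[a], hap_of_ind[b]]
        return tot / len(idx)
    ss_total = ssd(range(N))
    ss_wp = sum(ssd([i for i in range(N) if pop_of_ind[i] == p]) for p in pops)
    ss_ap = ss_total - ss_wp
    n_p = [sum(1 for q in pop_of_ind if q == p) for p in pops]
    P = len(pops)
    ms_wp = ss_wp / (N - P)
    ms_ap = ss_ap / (P - 1)
    n_c = (N - sum(c**2 for c in n_p) / N) / (P - 1)
    sw = ms_wp
    sa = (ms_ap - ms_wp) / n_c
    return sa / (sa + sw)


class TestAmova:
    def test_fixed_populations_phi_one(self):
        t = table_from_counts(
            ["AAAA", "TTTT"], {"p1": [5, 0], "p2": [0, 5]}
        )
        r = mp.amova(t, design="one_level", metric="frequency", permutations=99, seed=1)
        assert r.phi_st == pytest.approx(1.0)
        assert r.p_st is not None and r.p_st < 0.05

    def test_identical_frequencies_no_structure(self):
        t = table_from_counts(["AAAA", "AAAT"], {"p1": [3, 3], "p2": [3, 3]})
        r = mp.amova(t, design="one_level", metric="frequency", permutations=99, seed=1)
        assert r.phi_st <= 0
        assert r.p_st > 0.5

    @pytest.mark.parametrize("trial", range(5))
    def test_one_level_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_h = rng.integers(2, 5)
        n_pops = rng.integers(2, 4)
        counts = rng.integers(0, 5, size=(n_pops, n_h))
        counts[:, 0] += 2  # ensure every population has individuals
        seqs = ["".join(x) for x in itertools.product("ACGT", repeat=2)][:n_h]
        t = table_from_counts(
            seqs, {f"p{p}": counts[p].tolist() for p in range(n_pops)}
        )
        r = mp.amova(t, design="one_level", metric="frequency", permutations=0)
        pop_of_ind, hap_of_ind = [], []
        for p in range(n_pops):
            for h in range(n_h):
                pop_of_ind.extend([p] * counts[p, h])
                hap_of_ind.extend([h] * counts[p, h])
        d2 = 1.0 - np.eye(n_h)
        expected = _amova_oracle(pop_of_ind, np.array(hap_of_ind), d2)
        assert r.phi_st == pytest.approx(expected, abs=1e-10)

    def test_two_level_single_group_degenerates(self):
        rng = np.random.default_rng(12)
        seqs = random_sequences(rng, 3, 40, 2)
        t = table_from_counts(seqs, {"p1": [4, 1, 0], "p2": [1, 3, 1], "p3": [2, 2, 2]})
        one = mp.amova(t, design="one_level", metric="frequency", permutations=0)
        # two "groups" with identical composition ~ no among-group variance
        two = mp.amova(
            t, design="two_level", metric="frequency",
            grouping={"g1": ["p1", "p2"], "g2": ["p3"]}, permutations=0,
        )
        assert two.phi_st == pytest.approx(
            (two.sigma_among_pop + (two.sigma_among_group or 0)) / two.sigma_total
        )
        assert abs(one.phi_st) <= 1.0 and abs(two.phi_st) <= 1.5

    def test_permutation_pvalues_seed_stable(self):
        rng = np.random.default_rng(13)
        seqs = random_sequences(rng, 3, 40, 2)
        t = table_from_counts(seqs, {"p1": [4, 1, 0], "p2": [1, 3, 1]})
        a = mp.amova(t, design="one_level", metric="frequency", permutations=200, seed=3)
        b = mp.amova(t, design="one_level", metric="frequency", permutations=200, seed=3)
        c = mp.amova(t, design="one_level", metric="frequency", permutations=200, seed=4)
        assert a.p_st == b.p_st
        assert a.phi_st == c.phi_st  # point estimate independent of seed

    def test_requires_two_populations(self):
        t = table_from_counts(["AAAA", "AAAT"], {"p1": [3, 3]})
        with pytest.raises(ValueError):
            mp.amova(t, design="one_level", metric="frequency")


class TestByFdr:
    def test_single_test_is_alpha(self):
        assert mp.by_fdr(0.05, 1) == pytest.approx(0.05)

    def test_three_tests_hand_sum(self):
        assert mp.by_fdr(0.05, 3) == pytest.approx(0.05 / (11 / 6))

    def test_study_scale(self):
        # 105 pairwise comparisons at alpha 0.05
        assert math.floor(mp.by_fdr(0.05, 105) * 1e5) / 1e5 == 0.00954

    def test_decreases_with_m(self):
        vals = [mp.by_fdr(0.05, m) for m in (1, 10, 100, 1000)]
        assert vals == sorted(vals, reverse=True)


class TestPairwiseStructure:
    def test_shapes_and_mask(self):
        rng = np.random.default_rng(21)
        seqs = random_sequences(rng, 4, 60, 2)
        t = table_from_counts(
            seqs,
            {"p1": [4, 1, 0, 0], "p2": [1, 3, 1, 0], "p3": [0, 0, 3, 3]},
        )
        res = mp.pairwise_structure(t, permutations=99, seed=2)
        assert res.phi_st.shape == (3, 3)
        assert np.allclose(res.phi_st, res.phi_st.T)
        # mask only where raw P below critical value
        assert not (res.sig_phi & ~(res.p_phi < res.critical_value)).any()

    def test_identical_populations_nonpositive(self):
        rng = np.random.default_rng(23)
        seqs = random_sequences(rng, 2, 60, 2)
        t = table_from_counts(seqs, {"p1": [3, 3], "p2": [3, 3]})
        res = mp.pairwise_structure(t, permutations=49, seed=2)
        assert res.phi_st[0, 1] <= 0
        assert res.f_st[0, 1] <= 0


class TestGstNst:
    def test_equal_frequencies_gst_near_zero(self):
        rng = np.random.default_rng(31)
        seqs = random_sequences(rng, 3, 60, 2)
        t = table_from_counts(seqs, {"p1": [4, 3, 3], "p2": [4, 3, 3]})
        res = mp.gst_nst(t, permutations=0)
        assert abs(res.gst) < 0.1  # small negative bias of the unbiased estimator

    def test_fixed_populations_gst_one(self):
        rng = np.random.default_rng(32)
        seqs = random_sequences(rng, 2, 60, 2)
        t = table_from_counts(seqs, {"p1": [6, 0], "p2": [0, 6]})
        res = mp.gst_nst(t, permutations=0)
        assert res.gst == pytest.approx(1.0)

    def test_monomorphic_errors(self):
        t = table_from_counts(["ACGTACGT"], {"p1": [3], "p2": [3]})
        with pytest.raises(ValueError):
            mp.gst_nst(t, permutations=0)

    def test_identity_distance_reduces_nst_to_gst(self):
        rng = np.random.default_rng(33)
        seqs = random_sequences(rng, 3, 60, 2)
        t = table_from_counts(seqs, {"p1": [5, 2, 1], "p2": [1, 4, 2]})
        ident = mp.identity_matrix(t)
        res = mp.gst_nst(t, dist=ident, permutations=0)
        assert res.nst == pytest.approx(res.gst, abs=1e-12)
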
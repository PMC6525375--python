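"""Rarefaction subsampling, private-haplotype partitioning, and t-tests."""

import numpy as np
import pytest

import mitopop as mp
from conftest import random_sequences, table_from_counts


def _three_region_table(rng, n_haps=6, length=60):
    seqs = random_sequences(rng, n_haps, length, 2)
    counts = {
        "pA": [6, 4, 2, 0, 0, 0],
        "pB": [3, 3, 0, 4, 2, 0],
        "pC": [2, 0, 0, 0, 4, 6],
    }
    t = table_from_counts(seqs, counts)
    assign = {}
    k = 0
    for pop, sub in [("pA", "A"), ("pB", "B"), ("pC", "C")]:
        for _ in range(sum(counts[pop])):
            assign[f"s{k}"] = (pop, pop, sub, "all")
            k += 1
    return t, mp.PopulationHierarchy(assign)


class TestPrivatePartition:
    def test_shared_single_haplotype(self):
        sub = {"A": np.array([5, 0]), "B": np.array([5, 0])}
        assert mp.private_partition(sub) == {"A": 0, "B": 0}

    def test_disjoint_sets(self):
        sub = {"A": np.array([3, 2, 0, 0]), "B": np.array([0, 0, 4, 1])}
        assert mp.private_partition(sub) == {"A": 2, "B": 2}

    def test_constructed_overlap_pattern(self):
        # 6 haplotypes, hand-enumerated privacy: h0 everywhere, h1 in A+B,
        # h2 only A, h3 only B, h4 in B+C, h5 only C
        sub = {
            "A": np.array([2, 1, 3, 0, 0, 0]),
            "B": np.array([1, 2, 0, 2, 1, 0]),
            "C": np.array([4, 0, 0, 0, 1, 1]),
        }
        assert mp.private_partition(sub) == {"A": 1, "B": 1, "C": 1}


class TestRarefyRegions:
    def test_full_size_subsample_reproduces_totals(self):
        rng = np.random.default_rng(2)
        table, hier = _three_region_table(rng)
        sizes = {
            sub: int(table.group_counts(hier.populations_in_sub_region(sub)).sum())
            for sub in hier.sub_regions
        }
        n = min(sizes.values())
        # make all regions exactly size n by rarefying a table whose regions
        # are already equal: draw target equal to each region's size
        table_eq, hier_eq = _three_region_table(rng)
        res = mp.rarefy_regions(table_eq, hier_eq, target_n=n, replicates=3, seed=1)
        # the region whose size equals target must reproduce its full-sample
        # richness and diversity in every replicate
        for region in res.regions:
            full_counts = table_eq.group_counts(
                hier_eq.populations_in_sub_region(region)
            )
            if int(full_counts.sum()) != n:
                continue
            full_h, _ = mp.haplotype_diversity(full_counts)
            for rep in range(res.replicates):
                assert res.per_replicate[
                    rep, res.regions.index(region), 3
                ] == np.count_nonzero(full_counts)
                assert res.per_replicate[
                    rep, res.regions.index(region), 0
                ] == pytest.approx(full_h)

    def test_target_larger_than_region_errors(self):
        rng = np.random.default_rng(2)
        table, hier = _three_region_table(rng)
        with pytest.raises(ValueError, match="exceeds"):
            mp.rarefy_regions(table, hier, target_n=1000, replicates=2, seed=1)

    def test_matches_hypergeometric_expectation(self):
        """Monte-Carlo mean richness agrees with Hurlbert's closed form."""
        rng = np.random.default_rng(8)
        table, hier = _three_region_table(rng)
        res = mp.rarefy_regions(table, hier, target_n=8, replicates=400, seed=3)
        for region in res.regions:
            counts = table.group_counts(hier.populations_in_sub_region(region))
            expected = mp.expected_richness_hypergeometric(counts, 8)
            mc = res.replicate_vectors(region, "Hapr")
            se = mc.std(ddof=1) / np.sqrt(len(mc))
            assert mc.mean() == pytest.approx(expected, abs=max(4 * se, 0.05))

    def test_hypergeometric_formula_by_enumeration(self):
        """Closed form checked against exhaustive enumeration of subsets."""
        import itertools

        counts = [3, 2, 1]
        pool = [h for h, c in enumerate(counts) for _ in range(c)]
        n = 3
        rich = [len(set(c)) for c in itertools.combinations(range(len(pool)), n)]
        exact = np.mean([len({pool[i] for i in c})
                         for c in itertools.combinations(range(len(pool)), n)])
        assert mp.expected_richness_hypergeometric(counts, n) == pytest.approx(exact)

    def test_invariants(self):
        rng = np.random.default_rng(4)
        table, hier = _three_region_table(rng)
        res = mp.rarefy_regions(table, hier, target_n=8, replicates=20, seed=5)
        full_nh = {
            r: np.count_nonzero(
                table.group_counts(hier.populations_in_sub_region(r))
            )
            for r in res.regions
        }
        for rep in range(res.replicates):
            for ri, r in enumerate(res.regions):
                h, pi, K, hapr, np_, np_n, np_hapr = res.per_replicate[rep, ri]
                assert hapr <= full_nh[r]
                assert np_ <= hapr
                assert 0 <= np_n <= 1 and 0 <= np_hapr <= 1

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        table, hier = _three_region_table(rng)
        a = mp.rarefy_regions(table, hier, target_n=6, replicates=5, seed=9)
        b = mp.rarefy_regions(table, hier, target_n=6, replicates=5, seed=9)
        assert np.array_equal(a.per_replicate, b.per_replicate)


class TestCompareRegions:
    def test_identical_vectors_give_p_one(self):
        rng = np.random.default_rng(2)
        table, hier = _three_region_table(rng)
        res = mp.rarefy_regions(table, hier, target_n=8, replicates=4, seed=1)
        res_const = mp.RarefactionResult(
            res.regions, res.target_n, res.replicates,
            np.ones_like(res.per_replicate), res.seed,
        )
        df = mp.compare_regions(res_const)
        assert (df["t"] == 0).all()
        assert (df["P"] == 1).all()

    def test_pooled_variance_t_hand_value(self):
        """(1,2,3) vs (4,5,6): t = -3.674, P ~ 0.021 with df = 4."""
        from scipy import stats

        t, p = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)
        # and the package's comparison reports the same values
        pr = np.zeros((3, 2, len(mp.rarefaction.INDICES)))
        pr[:, 0, 0] = [1, 2, 3]
        pr[:, 1, 0] = [4, 5, 6]
        res = mp.RarefactionResult(("A", "B"), 5, 3, pr, 0)
        df = mp.compare_regions(res)
        row = df[(df["index"] == "h")].iloc[0]
        assert row["t"] == pytest.approx(-3.674, abs=1e-3)
        assert row["stars"] == "*"
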
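"""Rarefaction-based comparison of regional genetic diversification.

Regions of unequal sample size are compared by repeatedly drawing equal-size
subsamples (without replacement, independently per region), computing seven
diversity indices on each draw — haplotype diversity ``h``, nucleotide
diversity ``pi``, mean pairwise differences ``K``, haplotypic richness
``Hapr``, number of private haplotypes ``Np``, proportion of private
haplotypes ``Np/N`` and genetic endemism ``Np/Hapr`` — and contrasting the
replicate vectors between regions with unpaired t-tests.

Privacy is evaluated on the pooled replicate (all regions' subsamples of that
replicate together): a haplotype is private to a region when it appears in
that region's subsample and in no other region's subsample of the same draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import HaplotypeTable, PopulationHierarchy
from .diversity import haplotype_diversity, nucleotide_diversity

INDICES = ("h", "pi", "K", "Hapr", "Np", "Np_N", "Np_Hapr")


@dataclass(frozen=True)
class RarefactionResult:
    regions: tuple[str, ...]
    target_n: int
    replicates: int
    per_replicate: np.ndarray  # replicate x region x index
    seed: int | None

    @property
    def means(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_replicate.mean(axis=0), index=self.regions, columns=INDICES
        )

    def replicate_vectors(self, region: str, index: str) -> np.ndarray:
        return self.per_replicate[:, self.regions.index(region), INDICES.index(index)]


def _region_groups(
    table: HaplotypeTable, hier: PopulationHierarchy
) -> dict[str, list[str]]:
    """Default comparison units: sub-regions when nesting is two-level
    (so a region equal to its own sub-region still forms one unit)."""
    out: dict[str, list[str]] = {}
    for sub in hier.sub_regions:
        out[sub] = list(hier.populations_in_sub_region(sub))
    return out


def private_partition(subsamples: Mapping[str, np.ndarray]) -> dict[str, int]:
    """Count haplotypes private to each region within one pooled replicate.

    ``subsamples`` maps region -> per-haplotype count vector of that region's
    draw.  A haplotype is private to region ``r`` iff present in ``r`` and
    absent from every other region's subsample.
    """
    regions = list(subsamples)
    present = {r: np.asarray(c) > 0 for r, c in subsamples.items()}
    out = {}
    for r in regions:
        others = np.zeros_like(present[r])
        for o in regions:
            if o != r:
                others |= present[o]
        out[r] = int((present[r] & ~others).sum())
    return out


def rarefy_regions(
    table: HaplotypeTable,
    hier: PopulationHierarchy,
    target_n: int | None = None,
    replicates: int = 30,
    seed: int | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    sites: np.ndarray | None = None,
    seq_length: int | None = None,
) -> RarefactionResult:
    """Draw ``replicates`` equal-size subsamples per region and compute the
    seven diversity indices on each.

    ``target_n`` defaults to the smallest region size.  Subsampling RNG
    substreams are keyed by ``(seed, replicate, region)`` so results do not
    depend on evaluation order.
    """
    if groups is None:
        groups = _region_groups(table, hier)
    regions = list(groups)
    region_counts = {
        r: table.group_counts(list(groups[r])) for r in regions
    }
    sizes = {r: int(c.sum()) for r, c in region_counts.items()}
    if target_n is None:
        target_n = min(sizes.values())
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    for r, sz in sizes.items():
        if target_n > sz:
            raise ValueError(f"target_n={target_n} exceeds region {r!r} size {sz}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if seq_length is None:
        seq_length = (
            len(sites) if sites is not None
            else len(next(iter(table.haplotypes.values())))
        )
    n_haps = len(table.hap_ids)
    out = np.zeros((replicates, len(regions), len(INDICES)))
    base = seed if seed is not None else 0
    for rep in range(replicates):
        draws: dict[str, np.ndarray] = {}
        for ri, r in enumerate(regions):
            rng = np.random.default_rng(np.random.SeedSequence([base, 4, rep, ri]))
            pool = np.repeat(np.arange(n_haps), region_counts[r])
            chosen = rng.choice(pool, size=target_n, replace=False)
            draws[r] = np.bincount(chosen, minlength=n_haps)
        privates = private_partition(draws)
        for ri, r in enumerate(regions):
            c = draws[r]
            sub = HaplotypeTable(
                table.haplotypes,
                pd.DataFrame({"sub": c}, index=list(table.hap_ids)),
            )
            h, _ = haplotype_diversity(c[c > 0])
            pi, _, K = nucleotide_diversity(sub, None, sites, seq_length)
            hapr = int((c > 0).sum())
            np_r = privates[r]
            out[rep, ri] = [h, pi, K, hapr, np_r, np_r / target_n,
                            np_r / hapr if hapr else 0.0]
    return RarefactionResult(tuple(regions), target_n, replicates, out, seed)


def expected_richness_hypergeometric(counts: Sequence[int], n: int) -> float:
    """Hurlbert's closed-form rarefied richness
    ``E[Hapr] = sum_h (1 - C(N - c_h, n) / C(N, n))`` — the analytic check for
    the Monte-Carlo subsampling."""
    c = np.asarray(counts)
    c = c[c > 0]
    N = int(c.sum())
    if n > N:
        raise ValueError("subsample larger than sample")
    from scipy.special import gammaln

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for ch in c:
        if N - ch < n:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(N - ch, n) - log_comb(N, n))
    return float(total)


def compare_regions(
    result: RarefactionResult, welch: bool = False
) -> pd.DataFrame:
    """Unpaired t-tests between the replicate vectors of each region pair.

    Student's pooled-variance test by default (``welch=True`` switches to
    Welch's unequal-variance form).  Replicates from a single rarefaction are
    pseudo-replicates of one dataset, so these P-values describe the
    stability of the subsampling, not independent biological sampling.
    """
    if result.replicates < 2:
        raise ValueError("t-tests require >= 2 replicates")
    rows = []
    for idx in INDICES:
        for i, a in enumerate(result.regions):
            for b in result.regions[i + 1:]:
                va = result.replicate_vectors(a, idx)
                vb = result.replicate_vectors(b, idx)
                if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(va, vb, equal_var=not welch)
                rows.append(
                    {"index": idx, "region_a": a, "region_b": b,
                     "mean_a": va.mean(), "mean_b": vb.mean(),
                     "t": float(t), "P": float(p), "stars": _stars(float(p))}
                )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
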
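"""Genetic variability statistics: haplotype/nucleotide diversity, site summaries.

Implements the classical per-group indices for mtDNA haplotype data:

* ``h`` — Nei's unbiased haplotype (gene) diversity with its sampling standard
  deviation (Nei 1987, eq. 8.4/8.12),
* ``pi`` — per-site nucleotide diversity with Nei's stochastic variance
  (Nei 1987, eq. 10.5/10.7),
* ``K`` — mean number of pairwise nucleotide differences (uncorrected
  mismatch counts, no model correction),
* counts of variable / parsimony-informative / singleton sites and base
  composition.

Groups with a single sequence are reported as undefined; monomorphic groups
render as zeros, mirroring the usual table conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import Alignment, HaplotypeTable, PopulationHierarchy, mismatch_matrix


@dataclass(frozen=True)
class SiteSummary:
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    base_composition: dict[str, float]
    n_included_sites: int

    def __post_init__(self) -> None:
        assert self.n_variable == self.n_parsimony_informative + self.n_singleton


@dataclass(frozen=True)
class DiversityStats:
    """One row of a diversity report (population, sub-region, region or total)."""

    group: str
    level: str
    N: int
    Nh: int
    Nps: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    K: float
    defined: bool = True


def site_summary(aln: Alignment) -> SiteSummary:
    """Classify included sites as invariant, singleton or parsimony-informative.

    A site is variable when >= 2 states occur among the sequences; it is
    parsimony-informative when >= 2 states are each carried by >= 2 sequences,
    and a singleton (autapomorphic) site otherwise.
    """
    if aln.n < 2:
        raise ValueError("site summary requires >= 2 sequences")
    sites = aln.included_sites()
    if sites.size == 0:
        raise ValueError("all sites excluded by the complete-deletion rule")
    arr = aln.to_array()[:, sites]
    n_var = n_inf = n_sing = 0
    for col in arr.T:
        states, counts = np.unique(col, return_counts=True)
        if len(states) >= 2:
            n_var += 1
            if (counts >= 2).sum() >= 2:
                n_inf += 1
            else:
                n_sing += 1
    flat = arr.ravel()
    total = flat.size
    comp = {b: float((flat == b).sum()) / total for b in "ACGT"}
    return SiteSummary(n_var, n_inf, n_sing, comp, int(sites.size))


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation.

    ``h = n (1 - sum p_i^2) / (n - 1)`` with the sampling variance of Nei
    (1987, eq. 8.12).  Requires a total sample size of at least two.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(
    table: HaplotypeTable,
    populations: Sequence[str] | None = None,
    sites: np.ndarray | None = None,
    seq_length: int | None = None,
) -> tuple[float, float, float]:
    """Per-site nucleotide diversity ``pi``, its standard deviation, and ``K``.

    ``K`` is the mean raw mismatch count over all individual pairs (haplotypes
    weighted by their counts); ``pi = K / L`` where ``L`` is the analyzable
    (complete-deletion) length.  The standard deviation follows Nei's (1987,
    eq. 10.7) stochastic variance, which combines sampling and evolutionary
    variance as conventionally reported for mtDNA data.
    """
    counts = table.group_counts(populations)
    keep = counts > 0
    counts = counts[keep]
    seqs = [s for s, k in zip(table.sequences(), keep) if k]
    n = int(counts.sum())
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    if seq_length is None:
        seq_length = len(sites) if sites is not None else len(seqs[0])
    d = mismatch_matrix(seqs, sites)
    npairs = n * (n - 1) / 2.0
    cross = np.outer(counts, counts)
    total_diff = float((np.triu(cross * d, k=1)).sum()) + float(
        ((counts * (counts - 1) / 2.0) * np.diag(d)).sum()
    )
    K = total_diff / npairs
    pi = K / seq_length
    var = ((n + 1.0) / (3.0 * (n - 1.0))) * pi / seq_length + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0))), K


def _group_row(
    name: str,
    level: str,
    table: HaplotypeTable,
    populations: Sequence[str] | None,
    sites: np.ndarray | None,
    seq_length: int,
) -> DiversityStats:
    counts = table.group_counts(populations)
    keep = counts > 0
    n = int(counts.sum())
    nh = int(keep.sum())
    seqs = [s for s, k in zip(table.sequences(), keep) if k]
    if n < 2:
        return DiversityStats(name, level, n, nh, 0, 0.0, 0.0, 0.0, 0.0, 0.0, False)
    # sites variable within the group: any pair of present haplotypes differs there
    nps = _n_variable_sites(seqs, sites)
    h, h_sd = haplotype_diversity(counts[keep])
    pi, pi_sd, K = nucleotide_diversity(table, populations, sites, seq_length)
    return DiversityStats(name, level, n, nh, nps, h, h_sd, pi, pi_sd, K)


def _n_variable_sites(seqs: Sequence[str], sites: np.ndarray | None) -> int:
    arr = np.array([list(s) for s in seqs], dtype="U1")
    if sites is not None:
        arr = arr[:, sites]
    return int(sum(len(np.unique(col)) > 1 for col in arr.T))


def diversity_report(
    table: HaplotypeTable,
    hier: PopulationHierarchy,
    sites: np.ndarray | None = None,
    seq_length: int | None = None,
) -> list[DiversityStats]:
    """Diversity statistics for every population, sub-region, region and total.

    Sub-regions that coincide with a region (single-level nesting on that
    branch) are reported once, at the region level.
    """
    if seq_length is None:
        seq_length = len(sites) if sites is not None else len(next(iter(table.haplotypes.values())))
    rows: list[DiversityStats] = []
    for pop in table.populations:
        rows.append(_group_row(pop, "population", table, [pop], sites, seq_length))
    region_names = set(hier.regions)
    for sub in hier.sub_regions:
        if sub in region_names:
            continue
        pops = hier.populations_in_sub_region(sub)
        rows.append(_group_row(sub, "sub_region", table, pops, sites, seq_length))
    for reg in hier.regions:
        pops = hier.populations_in_region(reg)
        rows.append(_group_row(reg, "region", table, pops, sites, seq_length))
    rows.append(_group_row("Total", "total", table, None, sites, seq_length))
    return rows
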
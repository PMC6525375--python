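"""Population differentiation: distances, AMOVA, FDR correction, GST/NST.

The variance-partitioning machinery follows Excoffier, Smouse & Quattro
(1992): sums of squares are computed from squared inter-individual distances,
variance components from their expected mean squares, and Phi/F fixation
indices from component ratios, with significance from permutation schemes
that mirror the tested null (individuals among populations, individuals among
populations within groups, populations among groups).

Two distance metrics are supported: haplotype identity (``d = 1 - delta``,
yielding F-statistics) and molecular distances such as Tajima-Nei nucleotide
divergence (yielding Phi-statistics).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import HaplotypeTable, PopulationHierarchy, mismatch_matrix


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.d, dtype=float)
        if arr.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(arr) != 0):
            raise ValueError("nonzero diagonal in distance matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite distances")


class SaturationError(ValueError):
    """Raised when a pairwise divergence exceeds the model's valid range."""


def tajima_nei_pair(seq_a: str, seq_b: str, sites: np.ndarray | None = None) -> float:
    """Tajima & Nei (1984) corrected distance between two aligned sequences.

    ``d = -b ln(1 - p / b)`` with ``b = (1 - sum g_i^2 + p^2 / h) / 2`` and
    ``h = sum_{i<j} x_ij^2 / (2 g_i g_j)``, where ``g_i`` are base frequencies
    pooled over both sequences and ``x_ij`` the per-site frequencies of the
    unordered base pair ``(i, j)`` between them.  With equal base frequencies
    it collapses to the Jukes-Cantor correction.
    """
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b_arr = np.frombuffer(seq_b.encode(), dtype="S1")
    if sites is not None:
        a, b_arr = a[sites], b_arr[sites]
    L = a.size
    diff = a != b_arr
    p = float(diff.sum()) / L
    if p == 0.0:
        return 0.0
    bases = [b"A", b"C", b"G", b"T"]
    g = np.array([float((a == x).sum() + (b_arr == x).sum()) for x in bases]) / (2 * L)
    h = 0.0
    for i, j in itertools.combinations(range(4), 2):
        x_ij = float(((a == bases[i]) & (b_arr == bases[j])).sum()
                     + ((a == bases[j]) & (b_arr == bases[i])).sum()) / L
        if g[i] > 0 and g[j] > 0:
            h += x_ij**2 / (2.0 * g[i] * g[j])
    bcoef = 0.5 * (1.0 - float((g**2).sum()) + p**2 / h)
    arg = 1.0 - p / bcoef
    if arg <= 0:
        raise SaturationError(
            f"Tajima-Nei distance undefined (saturation) for a pair with p={p:.4f}"
        )
    return -bcoef * math.log(arg)


def tajima_nei_matrix(
    table_or_seqs: HaplotypeTable | Sequence[str],
    sites: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise Tajima-Nei distance matrix over haplotype sequences."""
    if isinstance(table_or_seqs, HaplotypeTable):
        labels = table_or_seqs.hap_ids
        seqs = table_or_seqs.sequences()
    else:
        seqs = tuple(table_or_seqs)
        labels = tuple(f"H{i + 1}" for i in range(len(seqs)))
    k = len(seqs)
    d = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        try:
            d[i, j] = d[j, i] = tajima_nei_pair(seqs[i], seqs[j], sites)
        except SaturationError as err:
            raise SaturationError(f"pair ({labels[i]}, {labels[j]}): {err}") from None
    return DistanceMatrix(labels, d)


def identity_matrix(table: HaplotypeTable) -> DistanceMatrix:
    """Haplotype-identity metric ``d(i, j) = 1 - delta_ij`` (F-statistics)."""
    k = len(table.hap_ids)
    return DistanceMatrix(table.hap_ids, 1.0 - np.eye(k))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmovaResult:
    design: str  # "one_level" | "two_level"
    metric: str  # "distance" | "frequency"
    sigma_within: float
    sigma_among_pop: float
    sigma_among_group: float | None
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_st: float | None
    p_sc: float | None
    p_ct: float | None
    permutations: int

    @property
    def sigma_total(self) -> float:
        return self.sigma_within + self.sigma_among_pop + (self.sigma_among_group or 0.0)


def _pair_ss(counts: np.ndarray, d2: np.ndarray) -> float:
    """sum over unordered individual pairs of squared distances, from hap counts."""
    return 0.5 * float(counts @ d2 @ counts)


def _one_level_components(pop_counts: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """(sigma_within, sigma_among) for populations x haplotypes counts."""
    n_p = pop_counts.sum(axis=1).astype(float)
    N = n_p.sum()
    P = len(n_p)
    total_counts = pop_counts.sum(axis=0)
    ss_total = _pair_ss(total_counts, d2) / N
    ss_wp = sum(_pair_ss(pop_counts[p], d2) / n_p[p] for p in range(P))
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap
    n_c = (N - (n_p**2).sum() / N) / (P - 1)
    sigma_w = ms_wp
    sigma_a = (ms_ap - ms_wp) / n_c
    return float(sigma_w), float(sigma_a)


def _two_level_components(
    pop_counts: np.ndarray, group_of_pop: np.ndarray, d2: np.ndarray
) -> tuple[float, float, float]:
    """(sigma_within, sigma_among_pop_within_group, sigma_among_group)."""
    n_p = pop_counts.sum(axis=1).astype(float)
    N = n_p.sum()
    P = len(n_p)
    groups = np.unique(group_of_pop)
    G = len(groups)
    ss_total = _pair_ss(pop_counts.sum(axis=0), d2) / N
    ss_wp = sum(_pair_ss(pop_counts[p], d2) / n_p[p] for p in range(P))
    ss_wg = 0.0
    N_g = {}
    for g in groups:
        sel = group_of_pop == g
        gc = pop_counts[sel].sum(axis=0)
        N_g[g] = n_p[sel].sum()
        ss_wg += _pair_ss(gc, d2) / N_g[g]
    ss_ap_wg = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    ms_wp = ss_wp / (N - P)
    ms_ap = ss_ap_wg / (P - G)
    ms_ag = ss_ag / (G - 1)
    sum_npg = {g: (n_p[group_of_pop == g] ** 2).sum() / N_g[g] for g in groups}
    n_coef = (N - sum(sum_npg.values())) / (P - G)
    n_prime = (sum(sum_npg.values()) - (n_p**2).sum() / N) / (G - 1)
    n_dprime = (N - sum(v**2 for v in N_g.values()) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_coef
    sigma_a = (ms_ag - sigma_c - n_prime * sigma_b) / n_dprime
    return float(sigma_c), float(sigma_b), float(sigma_a)


def _counts_from_individuals(
    hap_idx: np.ndarray, pop_idx: np.ndarray, n_pops: int, n_haps: int
) -> np.ndarray:
    out = np.zeros((n_pops, n_haps), dtype=float)
    np.add.at(out, (pop_idx, hap_idx), 1.0)
    return out


def amova(
    table: HaplotypeTable,
    hier: PopulationHierarchy | None = None,
    design: str = "one_level",
    grouping: Mapping[str, Sequence[str]] | None = None,
    metric: str = "frequency",
    dist: DistanceMatrix | None = None,
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance with permutation tests.

    ``grouping`` maps group names to population lists for the two-level
    design; by default populations are grouped by region from ``hier``.
    The supplied molecular distances enter the sums of squares as squared
    distances (the frequency metric is its own square).
    """
    if permutations < 0:
        raise ValueError("permutations must be >= 0")
    pops = list(table.populations)
    if len(pops) < 2:
        raise ValueError("AMOVA requires >= 2 populations")
    if metric == "frequency":
        dist = identity_matrix(table)
    elif dist is None:
        raise ValueError("distance metric requires a DistanceMatrix")
    d2 = np.asarray(dist.d, dtype=float)
    pop_counts = table.counts.to_numpy().T.astype(float)  # pops x haps

    # individual-level representation for permutation
    hap_idx = []
    pop_idx = []
    for p in range(len(pops)):
        for h in range(pop_counts.shape[1]):
            c = int(pop_counts[p, h])
            hap_idx.extend([h] * c)
            pop_idx.extend([p] * c)
    hap_idx = np.asarray(hap_idx)
    pop_idx = np.asarray(pop_idx)
    rng = np.random.default_rng(np.random.SeedSequence([seed if seed is not None else 0, 1]))

    if design == "one_level":
        sw, sa = _one_level_components(pop_counts, d2)
        tot = sw + sa
        phi_st = sa / tot if tot != 0 else 0.0
        p_st = None
        if permutations:
            ge = 0
            for _ in range(permutations):
                perm = rng.permutation(hap_idx)
                pc = _counts_from_individuals(perm, pop_idx, len(pops), d2.shape[0])
                swp, sap = _one_level_components(pc, d2)
                totp = swp + sap
                stat = sap / totp if totp != 0 else 0.0
                if stat >= phi_st:
                    ge += 1
            p_st = (ge + 1) / (permutations + 1)
        return AmovaResult(
            "one_level", metric, sw, sa, None, phi_st, None, None, p_st, None, None, permutations
        )

    if design != "two_level":
        raise ValueError(f"unknown design {design!r}")
    if grouping is None:
        if hier is None:
            raise ValueError("two-level AMOVA needs a grouping or a hierarchy")
        grouping = {r: hier.populations_in_region(r) for r in hier.regions}
    group_names = list(grouping)
    if len(group_names) < 2:
        raise ValueError("two-level AMOVA requires >= 2 groups")
    group_of_pop = np.empty(len(pops), dtype=int)
    for gi, g in enumerate(group_names):
        for p in grouping[g]:
            group_of_pop[pops.index(p)] = gi

    sc, sb, sa = _two_level_components(pop_counts, group_of_pop, d2)
    tot = sa + sb + sc
    phi_st = (sa + sb) / tot if tot != 0 else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) != 0 else 0.0
    phi_ct = sa / tot if tot != 0 else 0.0
    p_st = p_sc = p_ct = None
    if permutations:
        group_of_ind = group_of_pop[pop_idx]
        ge_st = ge_sc = ge_ct = 0
        for _ in range(permutations):
            # Phi_ST: individuals among populations across the whole design
            perm = rng.permutation(hap_idx)
            pc = _counts_from_individuals(perm, pop_idx, len(pops), d2.shape[0])
            c, b, a = _two_level_components(pc, group_of_pop, d2)
            t = a + b + c
            if (((a + b) / t) if t != 0 else 0.0) >= phi_st:
                ge_st += 1
            # Phi_SC: individuals among populations within their group
            perm2 = hap_idx.copy()
            for gi in range(len(group_names)):
                sel = np.flatnonzero(group_of_ind == gi)
                perm2[sel] = perm2[rng.permutation(sel)]
            pc2 = _counts_from_individuals(perm2, pop_idx, len(pops), d2.shape[0])
            c2, b2, _a2 = _two_level_components(pc2, group_of_pop, d2)
            if ((b2 / (b2 + c2)) if (b2 + c2) != 0 else 0.0) >= phi_sc:
                ge_sc += 1
            # Phi_CT: whole populations among groups
            gperm = rng.permutation(group_of_pop)
            c3, b3, a3 = _two_level_components(pop_counts, gperm, d2)
            t3 = a3 + b3 + c3
            if ((a3 / t3) if t3 != 0 else 0.0) >= phi_ct:
                ge_ct += 1
        p_st = (ge_st + 1) / (permutations + 1)
        p_sc = (ge_sc + 1) / (permutations + 1)
        p_ct = (ge_ct + 1) / (permutations + 1)
    return AmovaResult(
        "two_level", metric, sc, sb, sa, phi_st, phi_sc, phi_ct, p_st, p_sc, p_ct, permutations
    )


# ---------------------------------------------------------------------------
# pairwise structure + FDR
# ---------------------------------------------------------------------------


def by_fdr(alpha: float, m: int) -> float:
    """Benjamini-Yekutieli FDR critical value ``alpha / sum_{i=1}^m 1/i``,
    valid under arbitrary dependence among the m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / sum(1.0 / i for i in range(1, m + 1))


@dataclass(frozen=True)
class PairwiseDiffResult:
    populations: tuple[str, ...]
    phi_st: np.ndarray
    f_st: np.ndarray
    p_phi: np.ndarray
    p_f: np.ndarray
    critical_value: float
    sig_phi: np.ndarray
    sig_f: np.ndarray
    permutations: int
    low_n_pairs: tuple[tuple[str, str], ...] = ()


def pairwise_structure(
    table: HaplotypeTable,
    hier: PopulationHierarchy | None = None,
    dist: DistanceMatrix | None = None,
    permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PairwiseDiffResult:
    """Pairwise one-level AMOVA for every population pair, both metrics,
    with B-Y FDR correction of the permutation P-values."""
    pops = list(table.populations)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if dist is None:
        dist = tajima_nei_matrix(table)
    P = len(pops)
    phi = np.zeros((P, P))
    fst = np.zeros((P, P))
    p_phi = np.ones((P, P))
    p_f = np.ones((P, P))
    low_n = []
    m = P * (P - 1) // 2
    crit = by_fdr(alpha, m)
    for i, j in itertools.combinations(range(P), 2):
        pair = [pops[i], pops[j]]
        sub = table.restrict(pair)
        if min(sub.counts.sum(axis=0)) < 2:
            low_n.append((pops[i], pops[j]))
        sub_dist = _restrict_dist(dist, sub.hap_ids)
        res_d = amova(sub, design="one_level", metric="distance", dist=sub_dist,
                      permutations=permutations, seed=_pair_seed(seed, i, j, 0))
        res_f = amova(sub, design="one_level", metric="frequency",
                      permutations=permutations, seed=_pair_seed(seed, i, j, 1))
        phi[i, j] = phi[j, i] = res_d.phi_st
        fst[i, j] = fst[j, i] = res_f.phi_st
        p_phi[i, j] = p_phi[j, i] = res_d.p_st if res_d.p_st is not None else 1.0
        p_f[i, j] = p_f[j, i] = res_f.p_st if res_f.p_st is not None else 1.0
    off = ~np.eye(P, dtype=bool)
    sig_phi = (p_phi < crit) & off
    sig_f = (p_f < crit) & off
    return PairwiseDiffResult(
        tuple(pops), phi, fst, p_phi, p_f, crit, sig_phi, sig_f, permutations, tuple(low_n)
    )


def _pair_seed(seed: int | None, i: int, j: int, which: int) -> int:
    ss = np.random.SeedSequence([seed if seed is not None else 0, 2, i, j, which])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _restrict_dist(dist: DistanceMatrix, labels: Sequence[str]) -> DistanceMatrix:
    idx = [dist.labels.index(l) for l in labels]
    return DistanceMatrix(tuple(labels), dist.d[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# GST / NST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GstNstResult:
    gst: float
    nst: float
    P_nst_gt_gst: float | None
    permutations: int


def _pons_petit(freqs: np.ndarray, n_k: np.ndarray, d: np.ndarray) -> float:
    """Differentiation coefficient 1 - vS/vT with small-sample corrections.

    ``freqs`` is populations x haplotypes; with ``d = 1 - delta`` this is GST,
    with molecular distances it is NST (Pons & Petit 1996 framework with
    Nei & Chesser-style corrections; populations weighted equally).
    """
    K = freqs.shape[0]
    n_tilde = K / (1.0 / n_k).sum()  # harmonic mean sample size
    v_k = np.einsum("ki,ij,kj->k", freqs, d, freqs)
    v_s = n_tilde / (n_tilde - 1.0) * v_k.mean()
    pbar = freqs.mean(axis=0)
    v_t = float(pbar @ d @ pbar) + v_s / (n_tilde * K)
    if v_t == 0:
        raise ValueError("no diversity: differentiation undefined")
    return 1.0 - v_s / v_t


def gst_nst(
    table: HaplotypeTable,
    dist: DistanceMatrix | None = None,
    permutations: int = 1000,
    seed: int | None = None,
) -> GstNstResult:
    """GST (haplotype frequencies only) vs NST (frequencies + distances).

    ``NST > GST`` indicates phylogeographic structure: closely related
    haplotypes co-occur geographically.  Significance is assessed by permuting
    haplotype identities on the distance matrix, which preserves frequencies
    while breaking the genealogy-geography association.
    """
    counts = table.counts.to_numpy().T.astype(float)  # pops x haps
    n_k = counts.sum(axis=1)
    keep = n_k >= 2
    counts, n_k = counts[keep], n_k[keep]
    if counts.shape[0] < 2:
        raise ValueError("GST/NST require >= 2 populations with n >= 2")
    if counts.shape[1] < 2:
        raise ValueError("monomorphic data: GST/NST undefined")
    freqs = counts / n_k[:, None]
    ident = 1.0 - np.eye(counts.shape[1])
    gst = _pons_petit(freqs, n_k, ident)
    if dist is None:
        dist = tajima_nei_matrix(table)
    nst = _pons_petit(freqs, n_k, dist.d)
    p = None
    if permutations:
        rng = np.random.default_rng(np.random.SeedSequence([seed if seed is not None else 0, 3]))
        ge = 0
        k = counts.shape[1]
        for _ in range(permutations):
            perm = rng.permutation(k)
            nst_p = _pons_petit(freqs, n_k, dist.d[np.ix_(perm, perm)])
            if nst_p >= nst:
                ge += 1
        p = (ge + 1) / (permutations + 1)
    return GstNstResult(gst, nst, p, permutations)
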
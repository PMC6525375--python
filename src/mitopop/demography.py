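"""Demographic-history inference from mtDNA haplotype samples.

Three layers:

1. Neutrality statistics — Tajima's ``D``, Fu's ``Fs`` and the
   Ramos-Onsins & Rozas ``R2`` — whose significance is obtained from neutral
   coalescent simulations conditioned on the sample size and Watterson's
   theta estimated from the observed number of segregating sites.
2. The mismatch distribution (pairwise difference spectrum) and Harpending's
   raggedness index ``rg``.
3. Least-squares fits of the sudden demographic-expansion model
   (Rogers & Harpending) and of a spatial-expansion model (island demes
   colonised from a single ancestral deme), parameterised in mutational time
   units ``tau`` with goodness of fit measured by the sum of squared
   deviations (SSD) and tested by parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np
from scipy import optimize, special

from .data import HaplotypeTable, mismatch_matrix

THETA1_CAP = 1e5  # upper bound for the post-expansion theta, as customary


# ---------------------------------------------------------------------------
# sample summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceGroup:
    """Per-individual view of a set of aligned sequences.

    ``n`` individuals, ``S`` segregating sites, ``K`` mean pairwise
    differences, ``singletons[i]`` the number of singleton variants carried by
    individual ``i`` (folded spectrum, no outgroup), and the pooled pairwise
    mismatch counts needed for the mismatch distribution.
    """

    n: int
    S: int
    K: float
    singletons: tuple[int, ...]
    pair_diffs: tuple[int, ...]  # one entry per unordered individual pair

    @classmethod
    def from_sequences(
        cls, sequences: Sequence[str], sites: np.ndarray | None = None
    ) -> "SequenceGroup":
        if len(sequences) < 2:
            raise ValueError("need >= 2 sequences")
        arr = np.array([list(s) for s in sequences], dtype="U1")
        if sites is not None:
            arr = arr[:, sites]
        n = arr.shape[0]
        S = 0
        singles = np.zeros(n, dtype=int)
        candidate = np.flatnonzero((arr != arr[0:1]).any(axis=0))
        for ci in candidate:
            col = arr[:, ci]
            states, counts = np.unique(col, return_counts=True)
            if len(states) > 1:
                S += 1
                for st, c in zip(states, counts):
                    if c == 1:
                        singles[np.flatnonzero(col == st)[0]] += 1
        diffs = _pairwise_diffs(arr)
        K = float(np.mean(diffs)) if diffs.size else 0.0
        return cls(n, int(S), K, tuple(singles.tolist()), tuple(diffs.tolist()))

    @classmethod
    def from_table(
        cls,
        table: HaplotypeTable,
        populations: Sequence[str] | None = None,
        sites: np.ndarray | None = None,
    ) -> "SequenceGroup":
        return cls.from_sequences(table.expand(populations), sites)

    @property
    def n_haplotypes(self) -> int:
        # individuals with zero pairwise difference share a haplotype
        return _count_haplotypes(self.n, self.pair_diffs)


def _pairwise_diffs(arr: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise difference counts for a (n x sites) array,
    computed through the distinct rows so large samples stay cheap."""
    n = arr.shape[0]
    uniq, inverse = np.unique(arr, axis=0, return_inverse=True)
    k = uniq.shape[0]
    d = np.zeros((k, k), dtype=np.int64)
    for a in range(k):
        for b in range(a + 1, k):
            d[a, b] = d[b, a] = int((uniq[a] != uniq[b]).sum())
    iu, ju = np.triu_indices(n, k=1)
    return d[inverse[iu], inverse[ju]]


def _count_haplotypes(n: int, pair_diffs: Sequence[int]) -> int:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    it = iter(pair_diffs)
    for i in range(n):
        for j in range(i + 1, n):
            if next(it) == 0:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------


def tajimas_d(group: SequenceGroup) -> float | None:
    """Tajima's (1989) D; ``None`` when the group has no polymorphism."""
    n, S, K = group.n, group.S, group.K
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (K - S / a1) / math.sqrt(var)


def _ewens_alleles_tail(n: int, k_obs: int, theta: float) -> float:
    """P(number of alleles >= k_obs) under the Ewens sampling formula.

    Uses exact unsigned Stirling numbers of the first kind (arbitrary
    precision) with the rising factorial ``(theta)_n`` in log space.
    """
    # |s(n, k)| by the recursion |s(n+1, k)| = n |s(n, k)| + |s(n, k-1)|
    row = [0, 1]  # n = 1
    for m in range(1, n):
        new = [0] * (m + 2)
        for k in range(1, m + 2):
            prev_k = row[k] if k < len(row) else 0
            prev_km1 = row[k - 1] if (k - 1) < len(row) else 0
            new[k] = m * prev_k + prev_km1
        row = new
    log_rising = math.lgamma(theta + n) - math.lgamma(theta)
    total = 0.0
    for k in range(k_obs, n + 1):
        s = row[k] if k < len(row) else 0
        if s == 0:
            continue
        total += math.exp(math.log(s) + k * math.log(theta) - log_rising)
    return min(total, 1.0)


def fus_fs(n: int, K: float, k_obs: int) -> float | None:
    """Fu's (1997) Fs with ``theta = K`` (the pi-based estimate).

    ``S' = P(#alleles >= k_obs | theta)`` from the Ewens sampling formula;
    ``Fs = ln(S' / (1 - S'))``.  ``None`` when ``K == 0``.
    """
    if K <= 0:
        return None
    sp = _ewens_alleles_tail(n, k_obs, K)
    sp = min(max(sp, 1e-300), 1.0 - 1e-16)
    return math.log(sp / (1.0 - sp))


def r2_stat(group: SequenceGroup) -> float | None:
    """Ramos-Onsins & Rozas (2002) R2; ``None`` when there is no polymorphism."""
    if group.S == 0:
        return None
    u = np.asarray(group.singletons, dtype=float)
    return float(np.sqrt(((u - group.K / 2.0) ** 2).mean()) / group.S)


@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    K: float
    D: float | None
    Fs: float | None
    R2: float | None
    P_D: float | None = None
    P_Fs: float | None = None
    P_R2: float | None = None
    n_simulations: int = 0


def _fixed_s_null(n: int, S: int, anc_seed: int, rng: np.random.Generator) -> SequenceGroup:
    """One neutral null replicate conditioned on n and S (Hudson's fixed-S):
    a constant-size genealogy with exactly S mutations placed on branches
    proportionally to their lengths, each on its own site."""
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, random_seed=anc_seed
    )
    tree = ts.first()
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    lens = np.array([tree.branch_length(u) for u in nodes])
    picks = rng.choice(len(nodes), size=S, p=lens / lens.sum())
    G = np.zeros((S, n), dtype=np.int8)
    for m, ni in enumerate(picks):
        G[m, list(tree.samples(nodes[ni]))] = 1
    return _group_from_matrix(G)


def _group_from_matrix(G: np.ndarray) -> SequenceGroup:
    """Summarise a (sites x samples) genotype matrix (folded spectrum)."""
    n = G.shape[1]
    singles = np.zeros(n, dtype=int)
    for row in G:
        states, counts = np.unique(row, return_counts=True)
        if len(states) > 1:
            for st, c in zip(states, counts):
                if c == 1:
                    singles[np.flatnonzero(row == st)[0]] += 1
    diffs = _pairwise_diffs(G.T)
    return SequenceGroup(
        n, G.shape[0], float(np.mean(diffs)), tuple(singles.tolist()), tuple(diffs.tolist())
    )


def _sim_group(ts) -> SequenceGroup:
    G = ts.genotype_matrix()  # sites x samples
    n = ts.num_samples
    if G.shape[0] == 0:
        return SequenceGroup(n, 0, 0.0, tuple([0] * n), tuple([0] * (n * (n - 1) // 2)))
    singles = np.zeros(n, dtype=int)
    for row in G:
        states, counts = np.unique(row, return_counts=True)
        if len(states) > 1:
            for st, c in zip(states, counts):
                if c == 1:
                    singles[np.flatnonzero(row == st)[0]] += 1
    diffs = _pairwise_diffs(G.T)
    return SequenceGroup(
        n, G.shape[0], float(np.mean(diffs)), tuple(singles.tolist()), tuple(diffs.tolist())
    )


def neutrality_tests(
    group: SequenceGroup,
    n_simulations: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """Compute D, Fs, R2 with coalescent-simulation P-values.

    The null is the constant-size neutral coalescent conditioned on the
    sample size and the observed number of segregating sites (fixed-S
    mutation placement), which keeps the lower-tail test of D at its nominal
    level.  P-values are ``(b + 1)/(B + 1)`` fractions of simulated
    statistics <= observed, the direction in which population expansion
    pushes all three statistics.
    """
    D = tajimas_d(group)
    Fs = fus_fs(group.n, group.K, group.n_haplotypes)
    R2 = r2_stat(group)
    if group.S == 0 or n_simulations <= 0:
        return NeutralityResult(group.n, group.S, group.K, D, Fs, R2)
    base = seed if seed is not None else 0
    rng_seeds = np.random.SeedSequence([base, 5]).generate_state(n_simulations) % (2**31 - 1) + 1
    mut_rng = np.random.default_rng(np.random.SeedSequence([base, 5, 1]))
    d_le = fs_le = r2_le = 0
    d_tot = fs_tot = r2_tot = 0
    for s in rng_seeds:
        sim = _fixed_s_null(group.n, group.S, int(s), mut_rng)
        sd = tajimas_d(sim)
        if D is not None and sd is not None:
            d_tot += 1
            if sd <= D:
                d_le += 1
        sf = fus_fs(sim.n, sim.K, sim.n_haplotypes)
        if Fs is not None and sf is not None:
            fs_tot += 1
            if sf <= Fs:
                fs_le += 1
        sr = r2_stat(sim)
        if R2 is not None and sr is not None:
            r2_tot += 1
            if sr <= R2:
                r2_le += 1
    p_d = (d_le + 1) / (d_tot + 1) if (D is not None and d_tot) else None
    p_fs = (fs_le + 1) / (fs_tot + 1) if (Fs is not None and fs_tot) else None
    p_r2 = (r2_le + 1) / (r2_tot + 1) if (R2 is not None and r2_tot) else None
    return NeutralityResult(group.n, group.S, group.K, D, Fs, R2, p_d, p_fs, p_r2, n_simulations)


# ---------------------------------------------------------------------------
# mismatch distribution
# ---------------------------------------------------------------------------


def mismatch_observed(group: SequenceGroup) -> np.ndarray:
    """Normalised distribution of pairwise difference counts (classes 0..max)."""
    diffs = np.asarray(group.pair_diffs)
    freq = np.bincount(diffs) / diffs.size
    return freq


def raggedness(freq: Sequence[float]) -> float:
    """Harpending's raggedness index ``rg = sum (x_i - x_{i-1})^2``,
    summing from class 1 through one past the last class (``x_{d+1} = 0``)."""
    x = np.asarray(freq, dtype=float)
    if x.size == 0:
        raise ValueError("empty mismatch vector")
    padded = np.concatenate([x, [0.0]])
    return float(((padded[1:] - padded[:-1]) ** 2).sum())


def _stationary_mismatch(n_classes: int, theta: float) -> np.ndarray:
    """Geometric equilibrium spectrum ``theta^j / (theta+1)^{j+1}``."""
    j = np.arange(n_classes)
    return np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0))


def _poisson_pmf(n_classes: int, tau: float) -> np.ndarray:
    j = np.arange(n_classes)
    if tau <= 0:
        out = np.zeros(n_classes)
        out[0] = 1.0
        return out
    return np.exp(j * math.log(tau) - tau - special.gammaln(j + 1))


def expected_mismatch_demographic(
    n_classes: int, tau: float, theta0: float, theta1: float
) -> np.ndarray:
    """Expected mismatch distribution under a sudden demographic expansion.

    Pairwise coalescent with rate ``1/theta1`` (time in mutational units, so
    the expected number of differences given coalescence at ``t`` is ``t``)
    until ``tau``, then rate ``1/theta0`` in the pre-expansion population:

    ``F_j = P(coalesce < tau) part + e^{-tau/theta1} *
    sum_m Poisson(j - m; tau) F_m(theta0)``

    i.e. pairs surviving to the expansion carry their ancestral geometric
    differences plus ``Poisson(tau)`` new ones (Li's shifted form).  For
    ``tau = 0`` this reduces to the stationary geometric of ``theta0``.
    """
    j = np.arange(n_classes)
    tau = max(tau, 0.0)
    theta0 = max(theta0, 1e-12)
    theta1 = max(theta1, 1e-12)
    a1 = 1.0 + 1.0 / theta1
    recent = special.gammainc(j + 1, a1 * tau) * _stationary_mismatch(n_classes, theta1)
    pois = _poisson_pmf(n_classes, tau)
    anc = _stationary_mismatch(n_classes, theta0)
    surv = math.exp(-tau / theta1) if tau / theta1 < 700 else 0.0
    ancient = surv * np.convolve(pois, anc)[:n_classes]
    return recent + ancient


def expected_mismatch_spatial(
    n_classes: int, tau: float, theta: float, M: float
) -> np.ndarray:
    """Expected mismatch under a spatial (island) expansion.

    Two lineages sampled in one deme of size ``theta`` either coalesce there
    (rate ``1/theta``) or separate into distinct demes (rate ``2M/theta``,
    ``M`` the scaled migrant number); separated lineages cannot meet again
    among effectively infinite demes and coalesce only in the single ancestral
    deme (size ``theta``) entered at time ``tau``.
    """
    j = np.arange(n_classes)
    tau = max(tau, 0.0)
    theta = max(theta, 1e-12)
    M = max(M, 0.0)
    b = 1.0 + 2.0 * M
    a = 1.0 + b / theta
    # within-deme coalescence before tau: density (1/theta) e^{-b t / theta}
    geom_b = np.exp(j * math.log(theta) - (j + 1) * np.log(theta + b))
    recent = special.gammainc(j + 1, a * tau) * geom_b
    p_nc = 1.0 - (1.0 / b) * (1.0 - math.exp(-min(b * tau / theta, 700.0)))
    pois = _poisson_pmf(n_classes, tau)
    anc = _stationary_mismatch(n_classes, theta)
    ancient = p_nc * np.convolve(pois, anc)[:n_classes]
    return recent + ancient


@dataclass(frozen=True)
class MismatchFit:
    model: str  # "demographic" | "spatial"
    observed: tuple[float, ...]
    tau: float
    theta0: float
    theta1: float  # for the spatial model this slot holds M
    SSD: float
    rg: float
    P_SSD: float | None = None
    P_rg: float | None = None
    n_bootstrap: int = 0

    @property
    def expected(self) -> np.ndarray:
        if self.model == "demographic":
            return expected_mismatch_demographic(
                len(self.observed), self.tau, self.theta0, self.theta1
            )
        return expected_mismatch_spatial(
            len(self.observed), self.tau, self.theta0, self.theta1
        )


def _fit_ssd(
    observed: np.ndarray, model: str, init: Sequence[float] | None, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    n_classes = observed.size

    if model == "demographic":
        bounds = [(0.0, 100.0), (0.0, 50.0), (1e-3, THETA1_CAP)]

        def ssd(params):
            exp = expected_mismatch_demographic(n_classes, *params)
            return float(((observed - exp) ** 2).sum())
    elif model == "spatial":
        # M is capped where the island model is numerically panmictic, and
        # theta bounded away from zero, to cut the (theta -> 0, M -> inf)
        # ridge along which the expected spectrum is indistinguishable
        bounds = [(0.0, 100.0), (1e-2, 1e4), (0.0, 50.0)]

        def ssd(params):
            exp = expected_mismatch_spatial(n_classes, *params)
            return float(((observed - exp) ** 2).sum())
    else:
        raise ValueError(f"unknown expansion model {model!r}")

    mean_k = float((np.arange(n_classes) * observed).sum())
    if init is None:
        starts = [
            (max(mean_k, 0.1), 0.01, 1000.0)
            if model == "demographic"
            else (max(mean_k, 0.1), max(mean_k, 0.1), 1.0)
        ]
        for _ in range(3):
            starts.append(
                tuple(
                    lo + rng.random() * (min(hi, 10 * max(mean_k, 1.0)) - lo)
                    for lo, hi in bounds
                )
            )
    else:
        starts = [tuple(init)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            ssd, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000},
        )
        x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        val = ssd(x)
        if best is None or val < best[0]:
            best = (val, tuple(x))
    assert best is not None
    return (*best[1], best[0])


def _simulate_mismatch(
    n: int, model: str, tau: float, p2: float, p3: float, seed: int
) -> np.ndarray:
    """Parametric bootstrap draw of an observed mismatch distribution."""
    mu = 1e-3  # arbitrary per-locus rate; everything is scaled through it
    if model == "demographic":
        theta0, theta1 = max(p2, 0.01), max(p3, 0.01)
        N1 = theta1 / (2 * mu)
        N0 = theta0 / (2 * mu)
        t_gen = tau / (2 * mu)
        demog = msprime.Demography()
        demog.add_population(initial_size=N1)
        demog.add_population_parameters_change(time=t_gen, initial_size=N0)
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, demography=demog, random_seed=seed
        )
    else:
        theta, M = max(p2, 0.05), min(max(p3, 0.0), 50.0)
        n_demes = 30
        N = theta / (2 * mu)
        demog = msprime.Demography()
        for i in range(n_demes):
            demog.add_population(name=f"d{i}", initial_size=N)
        m_g = M / N
        for i in range(n_demes):
            for k in range(n_demes):
                if i != k:
                    demog.set_migration_rate(source=f"d{i}", dest=f"d{k}", rate=m_g / (n_demes - 1))
        t_gen = tau / (2 * mu)
        # collapse into a single ancestral deme of the same size
        demog.add_population(name="anc", initial_size=N)
        demog.add_population_split(time=t_gen, derived=[f"d{i}" for i in range(n_demes)], ancestral="anc")
        ts = msprime.sim_ancestry(
            samples={"d0": n}, ploidy=1, demography=demog, random_seed=seed
        )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=(seed ^ 0x2A6D1F) % (2**31 - 1) + 1, discrete_genome=False
    )
    G = ts.genotype_matrix()
    if G.shape[0] == 0:
        diffs = np.zeros(n * (n - 1) // 2, dtype=int)
    else:
        diffs = _pairwise_diffs(G.T)
    return np.bincount(diffs) / diffs.size


def fit_expansion(
    group: SequenceGroup,
    model: str = "demographic",
    bootstrap: int = 0,
    seed: int | None = None,
) -> MismatchFit:
    """Fit an expansion model to the observed mismatch distribution.

    Parameters are estimated by minimising the SSD between observed and
    expected spectra (derivative-free search with random restarts, post-
    expansion theta capped at 1e5).  ``P_SSD`` and ``P_rg`` come from a
    parametric bootstrap: samples of the same size are simulated under the
    fitted model, re-fitted, and the fraction of simulated SSD (raggedness)
    values >= observed is reported as ``(b+1)/(B+1)``; the model is
    conventionally accepted when ``P_SSD > 0.05``.
    """
    if group.S < 1:
        raise ValueError("expansion fit requires at least one segregating site")
    observed = mismatch_observed(group)
    rng = np.random.default_rng(np.random.SeedSequence([seed if seed is not None else 0, 6]))
    tau, p2, p3, ssd_obs = _fit_ssd(observed, model, None, rng)
    rg_obs = raggedness(observed)
    p_ssd = p_rg = None
    if bootstrap > 0:
        seeds = np.random.SeedSequence([seed if seed is not None else 0, 7]).generate_state(bootstrap) % (2**31 - 1) + 1
        ge_ssd = ge_rg = 0
        for s in seeds:
            sim_obs = _simulate_mismatch(group.n, model, tau, p2, p3, int(s))
            _, _, _, ssd_sim = _fit_ssd(sim_obs, model, (tau, p2, p3), rng)
            if ssd_sim >= ssd_obs:
                ge_ssd += 1
            if raggedness(sim_obs) >= rg_obs:
                ge_rg += 1
        p_ssd = (ge_ssd + 1) / (bootstrap + 1)
        p_rg = (ge_rg + 1) / (bootstrap + 1)
    return MismatchFit(
        model, tuple(observed.tolist()), tau, p2, p3, ssd_obs, rg_obs, p_ssd, p_rg, bootstrap
    )
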
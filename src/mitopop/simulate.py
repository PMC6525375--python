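"""Coalescent simulation of mtDNA haplotype datasets.

Generates alignments with the statistical structure the analysis modules
assume — a short mtDNA fragment sampled from populations nested in regions,
under constant-size, sudden-expansion or vicariance-with-secondary-contact
demographies — so that every pipeline stage can be exercised and calibrated
without external data.

Scaling conventions: ``theta`` is the per-locus scaled mutation rate
(``2 N u`` for a haploid maternally inherited locus), so the expected mean
pairwise difference of a constant-size sample is ``theta``; event times are
given in mutational time units ``tau`` (``tau = 2 u t`` generations), the
unit in which mismatch expansion times are reported.  Mutations are placed as
finite-sites Jukes-Cantor substitutions by default (so distance corrections
and network homoplasy are exercised); an infinite-sites mode maps each
mutation to its own column for closed-form checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import msprime
import numpy as np

from .data import (
    Alignment,
    PopulationHierarchy,
    collapse_haplotypes,
    write_fasta,
    write_haplotype_table,
)

_N_BASE = 100_000.0  # arbitrary deme size; all observables depend only on theta/tau


@dataclass(frozen=True)
class SimScenario:
    """Simulation scenario: sampling design + demography.

    ``populations`` maps population name -> ``(n, sub_region, region)``.
    ``demography`` is one of::

        {"kind": "constant"}
        {"kind": "sudden_expansion", "tau": float, "factor": float}
        {"kind": "vicariance", "split_tau": float, "contact_tau": float,
         "migration": float, "expansion_factor": float}

    For the vicariance scenario the two demes are keyed by region: the first
    region listed is deme 0, all others deme 1; after the (forward-time)
    split at ``split_tau``, migration at scaled rate ``migration`` resumes at
    ``contact_tau`` and both demes may expand by ``expansion_factor`` then.
    """

    populations: Mapping[str, tuple[int, str, str]]
    seq_len: int = 453
    theta: float = 1.5
    demography: Mapping = field(default_factory=lambda: {"kind": "constant"})
    infinite_sites: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        for key in ("tau", "split_tau", "contact_tau"):
            if key in self.demography and self.demography[key] < 0:
                raise ValueError(f"{key} must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(n for n, _, _ in self.populations.values())

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for _, _, reg in self.populations.values():
            if reg not in seen:
                seen.append(reg)
        return seen


@dataclass(frozen=True)
class SimulationTruth:
    scenario: SimScenario
    newick: str
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "seq_len": self.scenario.seq_len,
                "theta": self.scenario.theta,
                "demography": dict(self.scenario.demography),
                "seed": self.scenario.seed,
                **self.params,
            },
            indent=2,
        )


def _build_demography(scenario: SimScenario, mu_locus: float) -> tuple[msprime.Demography, dict]:
    """Translate theta/tau parameters into an msprime demography."""
    N = _N_BASE
    to_gen = 1.0 / (2.0 * mu_locus)  # mutational time unit -> generations
    kind = scenario.demography.get("kind", "constant")
    demog = msprime.Demography()
    if kind == "constant":
        demog.add_population(name="deme0", initial_size=N)
        samples = {"deme0": scenario.n_total}
    elif kind == "sudden_expansion":
        tau = scenario.demography["tau"]
        factor = scenario.demography.get("factor", 100.0)
        demog.add_population(name="deme0", initial_size=N)
        demog.add_population_parameters_change(
            time=tau * to_gen, initial_size=N / factor, population="deme0"
        )
        samples = {"deme0": scenario.n_total}
    elif kind == "vicariance":
        split = scenario.demography["split_tau"]
        contact = scenario.demography.get("contact_tau", 0.0)
        mig = scenario.demography.get("migration", 0.0)
        factor = scenario.demography.get("expansion_factor", 1.0)
        if contact > split:
            raise ValueError("secondary contact must postdate the split")
        regions = scenario.regions
        demog.add_population(name="deme0", initial_size=N)
        demog.add_population(name="deme1", initial_size=N)
        demog.add_population(name="anc", initial_size=N / factor)
        # backwards in time: migration on during [0, contact), off after
        if mig > 0:
            m_g = mig / N  # scaled M = N * m_g
            demog.set_migration_rate("deme0", "deme1", m_g)
            demog.set_migration_rate("deme1", "deme0", m_g)
            if contact > 0:
                demog.add_migration_rate_change(
                    time=contact * to_gen, rate=0.0, source="deme0", dest="deme1"
                )
                demog.add_migration_rate_change(
                    time=contact * to_gen, rate=0.0, source="deme1", dest="deme0"
                )
        if factor != 1.0:
            demog.add_population_parameters_change(
                time=contact * to_gen, initial_size=N / factor, population="deme0"
            )
            demog.add_population_parameters_change(
                time=contact * to_gen, initial_size=N / factor, population="deme1"
            )
        demog.add_population_split(
            time=split * to_gen, derived=["deme0", "deme1"], ancestral="anc"
        )
        samples = {}
        for pop, (n, _sub, reg) in scenario.populations.items():
            deme = "deme0" if reg == regions[0] else "deme1"
            samples[deme] = samples.get(deme, 0) + n
        demog.sort_events()
    else:
        raise ValueError(f"unknown demography kind {scenario.demography['kind']!r}")
    return demog, samples


def simulate_coalescent(
    scenario: SimScenario,
) -> tuple[Alignment, PopulationHierarchy, SimulationTruth]:
    """Sample a genealogy under the scenario and drop mutations on it.

    Deterministic given ``scenario.seed``.  Returns the alignment, the
    matching population hierarchy, and a truth record (realized genealogy in
    newick plus the generating parameters) sufficient to score recovery.
    """
    seed = scenario.seed if scenario.seed is not None else 1
    # independent streams for genealogy and mutations (a shared msprime seed
    # couples the two processes and biases mutation counts upward)
    anc_seed, mut_seed = (
        int(x % (2**31 - 1)) + 1
        for x in np.random.SeedSequence([seed, 0]).generate_state(2)
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    L = scenario.seq_len
    # theta = 2 N u  =>  scale the locus rate so that theta matches at N_BASE
    mu_locus = scenario.theta / (2.0 * _N_BASE)
    mu_site = mu_locus / L
    demog, samples = _build_demography(scenario, mu_locus if mu_locus > 0 else 1e-3)
    ts = msprime.sim_ancestry(
        samples=samples, ploidy=1, demography=demog, random_seed=anc_seed,
        sequence_length=L,
    )
    if scenario.theta > 0:
        if scenario.infinite_sites:
            mts = msprime.sim_mutations(
                ts, rate=mu_site, random_seed=mut_seed, discrete_genome=False
            )
        else:
            mts = msprime.sim_mutations(
                ts, rate=mu_site, random_seed=mut_seed,
                model=msprime.JC69(), discrete_genome=True,
            )
    else:
        mts = ts

    ancestral = rng.choice(list("ACGT"), size=L)
    seqs = np.tile(ancestral, (scenario.n_total, 1))
    if scenario.theta > 0:
        if scenario.infinite_sites:
            free_cols = rng.permutation(L)
            col_iter = iter(free_cols)
            for var in mts.variants():
                try:
                    col = next(col_iter)
                except StopIteration as exc:
                    raise ValueError(
                        "more mutations than sites in infinite-sites mode"
                    ) from exc
                alleles = _assign_bases(var.alleles, rng)
                seqs[:, col] = [alleles[g] for g in var.genotypes]
        else:
            for var in mts.variants():
                col = int(var.site.position)
                seqs[:, col] = [var.alleles[g] for g in var.genotypes]

    # sample -> population assignment follows the sampling design order
    assignments: dict[str, tuple[str, str, str, str]] = {}
    records: list[tuple[str, str]] = []
    idx = 0
    # msprime orders samples by population; group study populations per deme
    regions = scenario.regions
    pops_by_deme: dict[int, list[str]] = {0: [], 1: []}
    for pop, (n, _sub, reg) in scenario.populations.items():
        deme = 0 if (scenario.demography.get("kind") != "vicariance" or reg == regions[0]) else 1
        pops_by_deme[deme].append(pop)
    for deme in (0, 1):
        for pop in pops_by_deme[deme]:
            n, sub, reg = scenario.populations[pop]
            pop_token = pop.replace(" ", "_")
            for k in range(n):
                sid = f"{pop_token}_{k + 1}"
                records.append((sid, "".join(seqs[idx])))
                assignments[sid] = (pop, pop, sub, reg)
                idx += 1
    aln = Alignment.from_records(records)
    hier = PopulationHierarchy(assignments)
    newick = ts.first().as_newick()
    truth = SimulationTruth(scenario, newick, {"n_total": scenario.n_total})
    return aln, hier, truth


def _assign_bases(alleles: tuple, rng: np.random.Generator) -> list[str]:
    """Map abstract infinite-sites alleles (0/1 strings) onto nucleotides."""
    bases = list("ACGT")
    rng.shuffle(bases)
    return [bases[i % 4] for i in range(len(alleles))]


# ---------------------------------------------------------------------------
# presets and the study-shaped fixture
# ---------------------------------------------------------------------------

#: population layout of the study system: 15 populations nested in an East
#: Atlantic region and a two-basin Mediterranean, 155 samples in total.
STUDY_LAYOUT: dict[str, tuple[int, str, str]] = {
    "Azores": (18, "Atlantic Ocean", "Atlantic Ocean"),
    "Canary Islands": (17, "Atlantic Ocean", "Atlantic Ocean"),
    "Sesimbra": (7, "Atlantic Ocean", "Atlantic Ocean"),
    "Alboran Sea": (3, "western Mediterranean", "Mediterranean Sea"),
    "Alicante": (10, "western Mediterranean", "Mediterranean Sea"),
    "Valencia": (8, "western Mediterranean", "Mediterranean Sea"),
    "Tarragona": (11, "western Mediterranean", "Mediterranean Sea"),
    "Tyrrhenian Sea": (10, "western Mediterranean", "Mediterranean Sea"),
    "Northern Tunisia": (3, "western Mediterranean", "Mediterranean Sea"),
    "Eastern Tunisia": (12, "eastern Mediterranean", "Mediterranean Sea"),
    "Tripoli": (7, "eastern Mediterranean", "Mediterranean Sea"),
    "Istra": (16, "eastern Mediterranean", "Mediterranean Sea"),
    "Ionian Sea": (8, "eastern Mediterranean", "Mediterranean Sea"),
    "Aegean-Black seas": (11, "eastern Mediterranean", "Mediterranean Sea"),
    "Levantine Sea": (14, "eastern Mediterranean", "Mediterranean Sea"),
}


def make_scenario(preset: str, **overrides) -> SimScenario:
    """Named scenario presets.

    * ``panmixia`` — one constant-size deme, study sampling layout.
    * ``vicariance_admixture`` — two demes split in the late past, high
      migration resuming recently, post-contact expansion: yields two shallow
      haplogroups sharing common hubs, the study system's inferred history.
    * ``postglacial_expansion`` — single deme, 100-fold sudden expansion.
    """
    presets = {
        "panmixia": dict(
            populations=STUDY_LAYOUT, theta=1.5,
            demography={"kind": "constant"},
        ),
        "vicariance_admixture": dict(
            populations=STUDY_LAYOUT, theta=200.0,
            demography={
                "kind": "vicariance", "split_tau": 2.5, "contact_tau": 0.5,
                "migration": 1000.0, "expansion_factor": 2000.0,
            },
        ),
        "postglacial_expansion": dict(
            populations=STUDY_LAYOUT, theta=200.0,
            demography={"kind": "sudden_expansion", "tau": 1.0, "factor": 2000.0},
        ),
    }
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(presets)}")
    kwargs = presets[preset]
    kwargs.update(overrides)
    return SimScenario(**kwargs)


def generate_fixture_study(
    seed: int = 1, out_dir: str | Path | None = None
) -> tuple[Alignment, PopulationHierarchy, SimulationTruth]:
    """The canonical synthetic study-shaped dataset.

    155 samples, 15 populations, Atlantic/western-Mediterranean/eastern-
    Mediterranean nesting, 453 bp, vicariance-then-admixture history with
    post-contact expansion tuned so that nucleotide diversity is of order
    0.003.  When ``out_dir`` is given, writes FASTA, population map CSV,
    haplotype table CSV, the true genealogy (newick) and a JSON truth record.
    """
    scenario = make_scenario("vicariance_admixture", seed=seed)
    aln, hier, truth = simulate_coalescent(scenario)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(aln, out / "alignment.fasta")
        hier.to_frame().to_csv(out / "population_map.csv", index=False)
        table = collapse_haplotypes(aln, hier)
        write_haplotype_table(table, out / "haplotype_table.csv")
        (out / "true_tree.nwk").write_text(truth.newick + "\n")
        (out / "truth.json").write_text(truth.to_json() + "\n")
    return aln, hier, truth
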
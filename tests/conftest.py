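"""Shared fixtures: small constructed datasets and one simulated study-shaped
dataset (session-scoped so expensive stages run once)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mitopop as mp


def random_sequences(
    rng: np.random.Generator, n: int, length: int, n_mut: int
) -> list[str]:
    """A base sequence plus n-1 mutated copies (distinct random sites each)."""
    base = rng.choice(list("ACGT"), size=length)
    out = ["".join(base)]
    for _ in range(n - 1):
        seq = base.copy()
        sites = rng.choice(length, size=n_mut, replace=False)
        for s in sites:
            seq[s] = rng.choice([b for b in "ACGT" if b != seq[s]])
        out.append("".join(seq))
    return out


def table_from_counts(
    seqs: list[str], counts: dict[str, list[int]]
) -> mp.HaplotypeTable:
    haps = {f"H{i + 1}": s for i, s in enumerate(seqs)}
    return mp.HaplotypeTable(haps, pd.DataFrame(counts, index=list(haps)))


@pytest.fixture(scope="session")
def toy_alignment() -> mp.Alignment:
    rng = np.random.default_rng(42)
    base = "".join(rng.choice(list("ACGT"), size=80))
    variant = base[:5] + ("A" if base[5] != "A" else "G") + base[6:]
    recs = [(f"s{i}", base if i <= 4 else variant) for i in range(1, 7)]
    return mp.Alignment.from_records(recs)


@pytest.fixture(scope="session")
def toy_hierarchy(toy_alignment) -> mp.PopulationHierarchy:
    assign = {}
    for i, sid in enumerate(toy_alignment.sample_ids):
        pop = "p1" if i < 3 else "p2"
        assign[sid] = (pop, pop, "sub1", "reg1")
    return mp.PopulationHierarchy(assign)


@pytest.fixture(scope="session")
def study_fixture():
    """Study-shaped synthetic dataset: 155 samples, 15 pops, 453 bp."""
    aln, hier, truth = mp.generate_fixture_study(seed=7)
    table = mp.collapse_haplotypes(aln, hier)
    return aln, hier, table, truth


@pytest.fixture(scope="session")
def small_panmictic():
    """A small single-population sample for demography tests."""
    scenario = mp.make_scenario(
        "panmixia", populations={"pop": (25, "sub", "reg")}, theta=3.0, seed=11
    )
    aln, hier, _ = mp.simulate_coalescent(scenario)
    table = mp.collapse_haplotypes(aln, hier)
    return aln, hier, table
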
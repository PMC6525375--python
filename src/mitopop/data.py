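"""Core data containers: sequence alignment, population hierarchy, haplotype table.

The analysis operates on a multiple sequence alignment of equal-length mtDNA
fragments, a nested sample -> population -> sub-region -> region mapping, and
the haplotype table obtained by collapsing identical sequences.  All downstream
statistics (diversity, differentiation, demography, networks) consume these
three objects.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_CHARS = set("ACGTN-")
#: characters that exclude a site from statistical computations (complete deletion)
MISSING_CHARS = set("N-")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged lengths, duplicate ids...)."""


class HierarchyError(ValueError):
    """Raised for inconsistent population/region nesting."""


@dataclass(frozen=True)
class Alignment:
    """An equal-length DNA alignment.

    Parameters
    ----------
    records
        ``(sample_id, sequence)`` pairs in input order.  Sequences are strings
        over ``{A, C, G, T, N, -}``; case is normalised to upper on
        construction via :func:`read_fasta` / :meth:`from_records`.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if 0 in lengths:
            raise AlignmentError("alignment length must be > 0")
        ids = [sid for sid, _ in self.records]
        dup = [sid for sid, c in Counter(ids).items() if c > 1]
        if dup:
            raise AlignmentError(f"duplicate sample ids: {dup}")
        for sid, seq in self.records:
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in {sid}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple((sid, seq.upper()) for sid, seq in records))

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def included_sites(self) -> np.ndarray:
        """0-based indices of sites free of gaps/ambiguities in every sequence.

        Sites carrying ``-`` or ``N`` in any sequence are excluded from all
        pairwise and site-wise computations (complete deletion), so that every
        statistic refers to one fixed analyzable fragment.
        """
        arr = self.to_array()
        mask = ~np.isin(arr, list(MISSING_CHARS)).any(axis=0)
        return np.flatnonzero(mask)

    def to_array(self) -> np.ndarray:
        return np.array([list(seq) for _, seq in self.records], dtype="U1")


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are upper-cased; input order is preserved.  Ragged lengths or
    duplicated ids raise :class:`AlignmentError`.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class PopulationHierarchy:
    """Nested sample -> (site, population, sub_region, region) assignment.

    Every population belongs to exactly one sub-region and every sub-region to
    exactly one region; populations keep their input order, which fixes the
    column order of the haplotype table and all report rows.
    """

    assignments: Mapping[str, tuple[str, str, str, str]]
    populations: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.assignments:
            raise HierarchyError("empty population map")
        pop_seen: dict[str, str] = {}
        sub_seen: dict[str, str] = {}
        order: list[str] = []
        for sid, (site, pop, sub, reg) in self.assignments.items():
            if pop not in order:
                order.append(pop)
            if pop in pop_seen and pop_seen[pop] != sub:
                raise HierarchyError(
                    f"population {pop!r} assigned to sub-regions "
                    f"{pop_seen[pop]!r} and {sub!r}"
                )
            pop_seen[pop] = sub
            if sub in sub_seen and sub_seen[sub] != reg:
                raise HierarchyError(
                    f"sub-region {sub!r} assigned to regions "
                    f"{sub_seen[sub]!r} and {reg!r}"
                )
            sub_seen[sub] = reg
        if not self.populations:
            object.__setattr__(self, "populations", tuple(order))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationHierarchy":
        required = {"sample_id", "site", "population", "sub_region", "region"}
        missing = required - set(df.columns)
        if missing:
            raise HierarchyError(f"population map missing columns: {sorted(missing)}")
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        if dup:
            raise HierarchyError(f"duplicate sample ids in population map: {dup}")
        assignments = {
            row.sample_id: (row.site, row.population, row.sub_region, row.region)
            for row in df.itertuples()
        }
        return cls(assignments)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def population_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][1]

    @property
    def sub_regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, (_, _, sub, _) in self.assignments.items():
            if sub not in seen:
                seen.append(sub)
        return tuple(seen)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, (_, _, _, reg) in self.assignments.items():
            if reg not in seen:
                seen.append(reg)
        return tuple(seen)

    def populations_in_sub_region(self, sub: str) -> tuple[str, ...]:
        return tuple(
            p
            for p in self.populations
            if any(a[1] == p and a[2] == sub for a in self.assignments.values())
        )

    def populations_in_region(self, reg: str) -> tuple[str, ...]:
        return tuple(
            p
            for p in self.populations
            if any(a[1] == p and a[3] == reg for a in self.assignments.values())
        )

    def validate_against(self, aln: Alignment) -> None:
        aln_ids = set(aln.sample_ids)
        map_ids = set(self.assignments)
        missing = sorted(aln_ids - map_ids)
        if missing:
            raise HierarchyError(f"samples absent from population map: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "site": a[0], "population": a[1],
             "sub_region": a[2], "region": a[3]}
            for sid, a in self.assignments.items()
        ]
        return pd.DataFrame(rows)


def read_population_map(path: str | Path) -> PopulationHierarchy:
    """Read a CSV/TSV population map (columns: sample_id, site, population,
    sub_region, region) and validate the nesting invariants."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    return PopulationHierarchy.from_frame(df)


@dataclass(frozen=True)
class HaplotypeTable:
    """Haplotype sequences plus a haplotype x population count matrix.

    ``counts`` is a DataFrame indexed by haplotype id with one column per
    population.  Haplotype ids are assigned in descending order of total count
    (ties broken by first occurrence in the alignment), since published
    haplotype labels are not derivable from sequence data alone.
    """

    haplotypes: Mapping[str, str]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.haplotypes) != list(self.counts.index):
            raise ValueError("haplotype ids and count-matrix rows disagree")
        seqs = list(self.haplotypes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences are not mutually distinct")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative haplotype counts")
        if self.counts.to_numpy().sum() <= 0:
            raise ValueError("empty haplotype table")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def hap_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    def group_counts(self, populations: Sequence[str] | None = None) -> np.ndarray:
        """Per-haplotype counts pooled over ``populations`` (default: all)."""
        sub = self.counts if populations is None else self.counts[list(populations)]
        return sub.to_numpy().sum(axis=1).astype(int)

    def sequences(self) -> tuple[str, ...]:
        return tuple(self.haplotypes.values())

    def expand(self, populations: Sequence[str] | None = None) -> list[str]:
        """Repeat each haplotype sequence by its (pooled) count."""
        counts = self.group_counts(populations)
        out: list[str] = []
        for seq, c in zip(self.haplotypes.values(), counts):
            out.extend([seq] * int(c))
        return out

    def restrict(self, populations: Sequence[str]) -> "HaplotypeTable":
        sub = self.counts[list(populations)]
        keep = sub.to_numpy().sum(axis=1) > 0
        sub = sub.loc[keep]
        haps = {h: self.haplotypes[h] for h in sub.index}
        return HaplotypeTable(haps, sub)


def collapse_haplotypes(aln: Alignment, hier: PopulationHierarchy) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes and tabulate per population."""
    hier.validate_against(aln)
    totals: Counter[str] = Counter(seq for _, seq in aln.records)
    first_seen: dict[str, int] = {}
    for i, (_, seq) in enumerate(aln.records):
        first_seen.setdefault(seq, i)
    ordered = sorted(totals, key=lambda s: (-totals[s], first_seen[s]))
    hap_of_seq = {seq: f"H{i + 1}" for i, seq in enumerate(ordered)}
    pops = [p for p in hier.populations]
    mat = pd.DataFrame(
        0, index=[hap_of_seq[s] for s in ordered], columns=pops, dtype=int
    )
    for sid, seq in aln.records:
        mat.loc[hap_of_seq[seq], hier.population_of(sid)] += 1
    haplotypes = {hap_of_seq[s]: s for s in ordered}
    return HaplotypeTable(haplotypes, mat)


def read_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Read a haplotype count table (rows = haplotypes, columns = populations,
    optional ``sequence`` column)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index.name = None
    if "sequence" in df.columns:
        seqs = df["sequence"].astype(str).str.upper().to_dict()
        counts = df.drop(columns=["sequence"])
    else:
        # placeholder sequences: frequency-only analyses do not touch them
        seqs = {h: f"?{i}" for i, h in enumerate(df.index)}
        counts = df
    counts = counts.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return HaplotypeTable(seqs, counts)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "sequence", [table.haplotypes[h] for h in out.index])
    out.index.name = "haplotype"
    out.to_csv(path)


def pairwise_mismatches(seq_a: str, seq_b: str, sites: np.ndarray | None = None) -> int:
    """Number of differing sites between two aligned sequences.

    ``sites`` restricts the comparison to the complete-deletion site set; by
    default all sites are compared.
    """
    if sites is None:
        return sum(a != b for a, b in zip(seq_a, seq_b))
    a = np.frombuffer(seq_a.encode(), dtype="S1")[sites]
    b = np.frombuffer(seq_b.encode(), dtype="S1")[sites]
    return int((a != b).sum())


def mismatch_matrix(sequences: Sequence[str], sites: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of raw pairwise mismatch counts."""
    k = len(sequences)
    d = np.zeros((k, k), dtype=int)
    for i, j in itertools.combinations(range(k), 2):
        d[i, j] = d[j, i] = pairwise_mismatches(sequences[i], sequences[j], sites)
    return d
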
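"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are joined in order of increasing mutational distance (raw
mismatch counts, the TCS convention) up to a probabilistic connection limit:
the largest number of steps for which the probability that every observed
difference reflects a single substitution (no superimposed changes) still
exceeds the chosen confidence.  Multi-step joins insert inferred intermediate
haplotypes so that every edge represents exactly one mutational step.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import HaplotypeTable, mismatch_matrix


def parsimony_probability(n_diff: int, seq_len: int) -> float:
    """Probability that ``n_diff`` observed differences over ``seq_len`` sites
    arose without superimposed substitutions.

    Substitutions per site are modelled as Poisson with mean ``d``, the
    Jukes-Cantor-corrected divergence for ``p = n_diff / seq_len``.  Parsimony
    holds when each differing site experienced exactly one substitution and
    each identical site none (no hidden reversals/parallelisms):

    ``P = [P(1 sub | visible diff)]^j * [P(0 subs | no visible diff)]^(L-j)``
    """
    if n_diff == 0:
        return 1.0
    p = n_diff / seq_len
    if p >= 0.75:
        return 0.0
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    p_visible = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    p_same = 1.0 - p_visible
    p_one_given_diff = d * math.exp(-d) / p_visible
    p_zero_given_same = math.exp(-d) / p_same
    return p_one_given_diff**n_diff * p_zero_given_same ** (seq_len - n_diff)


def parsimony_limit(seq_len: int, confidence: float = 0.95) -> int:
    """Largest number of mutational steps with parsimony probability >= the
    confidence level; single-step connections are always allowed."""
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    j = 1
    while j < seq_len and parsimony_probability(j + 1, seq_len) >= confidence:
        j += 1
    return j


@dataclass
class ParsimonyNetwork:
    """Observed + inferred haplotypes connected by single-step edges."""

    graph: nx.Graph
    limit: int

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for n, d in self.graph.nodes(data=True):
            shape = "circle" if d["observed"] else "point"
            label = f"{n} ({d.get('count', 0)})" if d["observed"] else ""
            lines.append(f'  "{n}" [shape={shape}, label="{label}"];')
        for a, b in self.graph.edges():
            lines.append(f'  "{a}" -- "{b}";')
        lines.append("}")
        return "\n".join(lines)


def build_network(
    table: HaplotypeTable,
    limit: int | None = None,
    confidence: float = 0.95,
    sites: np.ndarray | None = None,
) -> ParsimonyNetwork:
    """Agglomerative statistical-parsimony network construction.

    Pairs are processed in increasing mutational distance; one-step pairs are
    always linked (exposing homoplasy loops), while multi-step joins are made
    only between disconnected components, inserting inferred intermediates.
    Ambiguous alternatives at the same distance are resolved deterministically:
    higher joint haplotype frequency first, then interiority (current degree),
    then haplotype id.  Components farther apart than the limit stay separate.
    """
    ids = list(table.hap_ids)
    seqs = list(table.sequences())
    counts = {h: int(c) for h, c in zip(ids, table.group_counts())}
    if limit is None:
        limit = parsimony_limit(len(seqs[0]) if sites is None else len(sites), confidence)
    d = mismatch_matrix(seqs, sites)
    g = nx.Graph(limit=limit)
    for h, s in zip(ids, seqs):
        g.add_node(h, observed=True, count=counts[h], sequence=s)
    if len(ids) == 1:
        return ParsimonyNetwork(g, limit)

    seq_of = dict(zip(ids, seqs))
    inferred_counter = itertools.count(1)

    def find(parents, x):
        while parents[x] != x:
            parents[x] = parents[parents[x]]
            x = parents[x]
        return x

    parents = {h: h for h in ids}
    for dist in range(1, limit + 1):
        pairs = [
            (i, j) for i, j in itertools.combinations(range(len(ids)), 2)
            if d[i, j] == dist
        ]
        pairs.sort(
            key=lambda ij: (
                -(counts[ids[ij[0]]] + counts[ids[ij[1]]]),
                -(g.degree(ids[ij[0]]) + g.degree(ids[ij[1]])),
                ids[ij[0]], ids[ij[1]],
            )
        )
        for i, j in pairs:
            a, b = ids[i], ids[j]
            if dist == 1:
                g.add_edge(a, b, steps=1)
                parents[find(parents, a)] = find(parents, b)
                continue
            if find(parents, a) == find(parents, b):
                continue
            # direction: mutate from the more frequent endpoint
            if (counts[b], b) > (counts[a], a):
                a, b = b, a
            sa, sb = seq_of[a], seq_of[b]
            positions = [k for k in _diff_positions(sa, sb, sites)]
            prev = a
            cur = list(sa)
            for step, pos in enumerate(positions[:-1], start=1):
                cur[pos] = sb[pos]
                mid = f"m{next(inferred_counter)}"
                g.add_node(mid, observed=False, count=0, sequence="".join(cur))
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, b, steps=1)
            parents[find(parents, a)] = find(parents, b)
    return ParsimonyNetwork(g, limit)


def _diff_positions(sa: str, sb: str, sites: np.ndarray | None) -> list[int]:
    rng = range(len(sa)) if sites is None else sites
    return [k for k in rng if sa[k] != sb[k]]


def root_weights(net: ParsimonyNetwork, component: set[str] | None = None) -> dict[str, float]:
    """Frequency-and-interiority ranking of candidate ancestral haplotypes.

    Coalescent theory predicts old (ancestral) haplotypes to be both common
    and interior in the network.  Each observed haplotype is weighted by
    ``count * (1 + degree)`` and weights are normalised to sum to one within
    the component, giving a root ranking in the spirit of outgroup weights.
    """
    g = net.graph
    if component is None:
        component = max(nx.connected_components(g), key=len)
    obs = [n for n in component if g.nodes[n]["observed"]]
    raw = {n: g.nodes[n]["count"] * (1 + g.degree(n)) for n in obs}
    total = sum(raw.values())
    if total == 0:
        return {n: 1.0 / len(obs) for n in obs}
    return {n: w / total for n, w in sorted(raw.items(), key=lambda kv: -kv[1])}
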
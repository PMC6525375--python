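"""Dispersal-vicariance (DIVA) ancestral-area reconstruction.

Given a rooted binary tree whose tips carry geographic ranges (non-empty
subsets of a small area set, e.g. A = Atlantic, B = Mediterranean, AB = both),
DIVA assigns ranges to internal nodes so as to minimise the number of
dispersal and extinction events, with vicariant and within-area speciation
free (Ronquist 1997 cost regime).  A Sankoff-style dynamic program over
candidate ranges yields the minimal cost, the exact number of cost-minimal
reconstructions, and the per-node frequency of each range among them
(uniform weight across co-optimal solutions, the S-DIVA convention);
frequencies can be averaged over a sample of trees matched by clade.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

Range = frozenset


@dataclass
class AreaTree:
    """A rooted binary tree with tip ranges."""

    tree: dendropy.Tree
    tip_areas: dict[str, Range]

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = tips - set(self.tip_areas)
        if missing:
            raise ValueError(f"tips without area assignment: {sorted(missing)}")
        for label, rng in self.tip_areas.items():
            if not rng:
                raise ValueError(f"tip {label!r} has an empty range")
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if len(node.child_nodes()) != 2:
                raise ValueError(
                    "tree must be binary and rooted (use resolve_polytomies=True)"
                )

    @property
    def areas(self) -> tuple[str, ...]:
        out = sorted(set().union(*self.tip_areas.values()))
        return tuple(out)

    def clade_tips(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())


def parse_newick(
    path_or_string: str | Path,
    tip_areas: Mapping[str, str | Sequence[str]],
    resolve_polytomies: bool = False,
) -> AreaTree:
    """Read a rooted newick tree and attach tip ranges.

    ``tip_areas`` maps tip labels to area strings (``"A"``, ``"B"``, ``"AB"``)
    or iterables of areas.  Polytomies raise unless ``resolve_polytomies``.
    """
    src = str(path_or_string)
    try:
        is_file = "(" not in src and Path(src).exists()
    except OSError:
        is_file = False
    if is_file:
        tree = dendropy.Tree.get(path=src, schema="newick")
    else:
        tree = dendropy.Tree.get(data=src, schema="newick")
    tree.is_rooted = True
    if resolve_polytomies:
        tree.resolve_polytomies()
    areas = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError("unlabeled tip in newick tree")
        label = leaf.taxon.label
        if label not in tip_areas:
            raise ValueError(f"no area assignment for tip {label!r}")
        val = tip_areas[label]
        areas[label] = Range(val) if not isinstance(val, Range) else val
    return AreaTree(tree, areas)


@dataclass
class DivaResult:
    """Optimal ancestral-range summary.

    ``node_ranges`` maps each internal node (keyed by its clade's tip set) to
    the frequency of each candidate range among cost-minimal reconstructions;
    ``node_events`` carries the vicariance frequency and the expected number
    of dispersals/extinctions charged at that node.
    """

    total_cost: int
    n_optimal: int
    node_ranges: dict[frozenset[str], dict[Range, float]]
    node_events: dict[frozenset[str], dict[str, float]] = field(default_factory=dict)

    def range_frequencies(self, clade: frozenset[str]) -> dict[str, float]:
        return {
            "".join(sorted(r)): f for r, f in self.node_ranges[clade].items()
        }

    @property
    def root_clade(self) -> frozenset[str]:
        return max(self.node_ranges, key=len)


def _candidate_ranges(areas: Sequence[str], max_areas: int) -> list[Range]:
    out = []
    for k in range(1, max_areas + 1):
        out.extend(Range(c) for c in itertools.combinations(areas, k))
    return out


def _allowed_splits(r: Range) -> list[tuple[Range, Range]]:
    """DIVA speciation modes: within-area duplication for single areas,
    vicariant bipartition for widespread ranges (both daughters non-empty)."""
    if len(r) == 1:
        return [(r, r)]
    items = sorted(r)
    splits = []
    for k in range(1, len(items)):
        for combo in itertools.combinations(items, k):
            s1 = Range(combo)
            s2 = r - s1
            splits.append((s1, s2))
    return splits


def _node_cost(r: Range, d1: Range, d2: Range) -> tuple[int, int, int]:
    """Min (cost, dispersals, extinctions) of producing daughter ranges
    ``d1, d2`` from parent range ``r`` across allowed speciation modes."""
    best = None
    for s1, s2 in _allowed_splits(r):
        disp = len(d1 - s1) + len(d2 - s2)
        ext = len(s1 - d1) + len(s2 - d2)
        cand = (disp + ext, disp, ext)
        if best is None or cand < best:
            best = cand
    return best


def diva_optimize(tree: AreaTree, max_areas: int = 2) -> DivaResult:
    """Exact DIVA optimisation with co-optimal counting and range marginals.

    An inside (post-order) pass computes, for each node and candidate range,
    the minimal subtree cost and the number of optimal sub-reconstructions;
    an outside (pre-order) pass completes exact per-node marginal frequencies
    and per-node expected event counts over all cost-minimal reconstructions.
    """
    if max_areas < 1:
        raise ValueError("max_areas must be >= 1")
    areas = tree.areas
    ranges = _candidate_ranges(areas, max_areas)
    INF = float("inf")

    down: dict[int, dict[Range, float]] = {}
    dcnt: dict[int, dict[Range, int]] = {}
    nodes = list(tree.tree.postorder_node_iter())
    for node in nodes:
        nid = id(node)
        if node.is_leaf():
            obs = tree.tip_areas[node.taxon.label]
            down[nid] = {r: (0.0 if r == obs else INF) for r in ranges}
            dcnt[nid] = {r: (1 if r == obs else 0) for r in ranges}
            continue
        c1, c2 = node.child_nodes()
        down[nid] = {}
        dcnt[nid] = {}
        for r in ranges:
            best, cnt = INF, 0
            for d1 in ranges:
                if down[id(c1)][d1] == INF:
                    continue
                for d2 in ranges:
                    if down[id(c2)][d2] == INF:
                        continue
                    cost = (
                        down[id(c1)][d1]
                        + down[id(c2)][d2]
                        + _node_cost(r, d1, d2)[0]
                    )
                    if cost < best:
                        best, cnt = cost, dcnt[id(c1)][d1] * dcnt[id(c2)][d2]
                    elif cost == best and best < INF:
                        cnt += dcnt[id(c1)][d1] * dcnt[id(c2)][d2]
            down[nid][r] = best
            dcnt[nid][r] = cnt

    root = tree.tree.seed_node
    total = min(down[id(root)].values())
    n_opt = sum(
        c for r, c in dcnt[id(root)].items() if down[id(root)][r] == total
    )

    # outside pass
    up: dict[int, dict[Range, float]] = {id(root): {r: 0.0 for r in ranges}}
    ucnt: dict[int, dict[Range, int]] = {id(root): {r: 1 for r in ranges}}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        c1, c2 = node.child_nodes()
        for child, sib in ((c1, c2), (c2, c1)):
            res_cost = {r: INF for r in ranges}
            res_cnt = {r: 0 for r in ranges}
            for r in ranges:
                if up[id(node)][r] == INF:
                    continue
                for ds in ranges:
                    if down[id(sib)][ds] == INF:
                        continue
                    for dc in ranges:
                        if child is c1:
                            cost_n = _node_cost(r, dc, ds)[0]
                        else:
                            cost_n = _node_cost(r, ds, dc)[0]
                        cost = up[id(node)][r] + down[id(sib)][ds] + cost_n
                        if cost < res_cost[dc]:
                            res_cost[dc] = cost
                            res_cnt[dc] = ucnt[id(node)][r] * dcnt[id(sib)][ds]
                        elif cost == res_cost[dc] and cost < INF:
                            res_cnt[dc] += ucnt[id(node)][r] * dcnt[id(sib)][ds]
            up[id(child)] = res_cost
            ucnt[id(child)] = res_cnt

    node_ranges: dict[frozenset[str], dict[Range, float]] = {}
    node_events: dict[frozenset[str], dict[str, float]] = {}
    for node in nodes:
        if node.is_leaf():
            continue
        nid = id(node)
        clade = tree.clade_tips(node)
        freqs: dict[Range, float] = {}
        for r in ranges:
            if down[nid][r] + up[nid][r] == total:
                freqs[r] = dcnt[nid][r] * ucnt[nid][r]
        z = sum(freqs.values())
        node_ranges[clade] = {r: v / z for r, v in freqs.items()}
        # expected events at this node over optimal reconstructions
        c1, c2 = node.child_nodes()
        disp = ext = vic = 0.0
        for r in ranges:
            if up[nid][r] == INF:
                continue
            for d1 in ranges:
                if down[id(c1)][d1] == INF:
                    continue
                for d2 in ranges:
                    if down[id(c2)][d2] == INF:
                        continue
                    cost_n, ndisp, next_ = _node_cost(r, d1, d2)
                    if up[nid][r] + down[id(c1)][d1] + down[id(c2)][d2] + cost_n == total:
                        mult = ucnt[nid][r] * dcnt[id(c1)][d1] * dcnt[id(c2)][d2]
                        disp += mult * ndisp
                        ext += mult * next_
                        if len(r) >= 2:
                            vic += mult
        node_events[clade] = {
            "vicariance": vic / n_opt,
            "dispersal": disp / n_opt,
            "extinction": ext / n_opt,
        }
    return DivaResult(int(total), int(n_opt), node_ranges, node_events)


def s_diva_summary(
    trees: Sequence[AreaTree],
    max_areas: int = 2,
    reference: AreaTree | None = None,
) -> DivaResult:
    """Average per-node range frequencies over a sample of trees.

    Nodes are matched across trees by their clade tip sets on a reference
    topology (first tree by default); trees lacking a clade contribute
    nothing to that node.  Costs/counts reported are the reference tree's.
    """
    if not trees:
        raise ValueError("no trees given")
    if reference is None:
        reference = trees[0]
    per_tree = [diva_optimize(t, max_areas) for t in trees]
    ref_res = diva_optimize(reference, max_areas)
    node_ranges: dict[frozenset[str], dict[Range, float]] = {}
    node_events: dict[frozenset[str], dict[str, float]] = {}
    for clade in ref_res.node_ranges:
        acc: dict[Range, float] = {}
        eacc: dict[str, float] = {"vicariance": 0.0, "dispersal": 0.0, "extinction": 0.0}
        n_contrib = 0
        for res in per_tree:
            if clade not in res.node_ranges:
                continue
            n_contrib += 1
            for r, f in res.node_ranges[clade].items():
                acc[r] = acc.get(r, 0.0) + f
            for k in eacc:
                eacc[k] += res.node_events[clade][k]
        if n_contrib:
            node_ranges[clade] = {r: f / n_contrib for r, f in acc.items()}
            node_events[clade] = {k: v / n_contrib for k, v in eacc.items()}
        else:
            node_ranges[clade] = ref_res.node_ranges[clade]
            node_events[clade] = ref_res.node_events[clade]
    return DivaResult(ref_res.total_cost, ref_res.n_optimal, node_ranges, node_events)
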
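"""Trie-pruned enumeration of induced motif matches.

The enumerator is ESU: nodes get integer labels (sorted-id order), each
node roots the enumeration of every connected k-node subgraph whose
smallest label it holds, and extension candidates are exclusive
neighbors with larger labels — so every connected k-set is produced
exactly once, in a well-defined discovery order.

Matching is *induced*: a node set matches a query motif iff its full
signed adjacency (including edge absences) is isomorphic to the motif.
During enumeration, each newly added node reveals 2i-1 adjacency
entries, which are fed to the path-tree; a dead end prunes every
extension of that partial subgraph, and a leaf reached at depth k
names the matched motif.  Because the tree holds the labels of *all*
isomorphs, the single ESU discovery order per node set suffices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .graph import SignedDigraph, induced_subgraph
from .motifs import Motif
from .pathtree import DEAD_END, PathTree, build_path_tree

__all__ = [
    "Match",
    "SearchStats",
    "enumerate_connected_subgraphs",
    "find_matches",
    "count_matches",
    "esu_partial_count",
]


@dataclass(frozen=True)
class Match:
    """One induced occurrence of a query motif in a network."""

    motif_id: str
    nodes: tuple[str, ...]  # in ESU discovery order
    matrix: tuple[tuple[int, ...], ...]  # induced signed adjacency, same order
    network: SignedDigraph = field(compare=False, hash=False)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def induced_edges(self) -> list[tuple[str, str, int]]:
        """Compressed-level edges among the matched nodes, sorted."""
        out = []
        for i, u in enumerate(self.nodes):
            for j, v in enumerate(self.nodes):
                s = self.matrix[i][j]
                if s != 0:
                    out.append((u, v, s))
        return sorted(out)


@dataclass
class SearchStats:
    """Instrumentation: partial subgraphs visited by the pruned search."""

    partials_visited: int = 0
    partials_pruned: int = 0
    matches: int = 0


def _esu(g: SignedDigraph, k: int, visitor) -> None:
    """Core ESU recursion; ``visitor`` controls pruning and receives sets.

    visitor(sub, w) -> (accept, state): called when node w is appended
    to partial subgraph ``sub`` (w excluded).  Returning accept=False
    prunes all extensions.  The visitor is re-entered with state pushed
    and popped around the recursion by the caller closure.
    """
    order = g.sorted_nodes()
    label = {n: i for i, n in enumerate(order)}

    def neighbors_gt(n: str, root_label: int) -> set[str]:
        return {u for u in g.neighbors(n) if label[u] > root_label}

    def extend(sub: list[str], ext: set[str], root_label: int,
               sub_neighborhood: set[str]) -> None:
        if len(sub) == k:
            return
        # deterministic candidate order
        for w in sorted(ext, key=lambda n: label[n]):
            keep = visitor(sub, w)
            if not keep:
                continue
            # exclusive neighborhood: new neighbors of w not adjacent to sub
            excl = {
                u for u in g.neighbors(w)
                if label[u] > root_label and u not in sub_neighborhood and u != w
            }
            new_ext = {u for u in ext if label[u] > label[w]} | excl
            sub.append(w)
            extend(sub, new_ext, root_label, sub_neighborhood | {w} | g.neighbors(w))
            sub.pop()
            visitor_pop()

    visitor_pop = getattr(visitor, "pop", lambda: None)

    for v in order:
        root_label = label[v]
        if not visitor([], v):  # visitor pushes state only on acceptance
            continue
        ext = neighbors_gt(v, root_label)
        extend([v], ext, root_label, {v} | g.neighbors(v))
        visitor_pop()


def enumerate_connected_subgraphs(g: SignedDigraph, k: int) -> Iterator[tuple[str, ...]]:
    """Yield every weakly connected k-node set exactly once.

    Sets are yielded as tuples in ESU discovery order; connectivity is
    judged on the underlying undirected graph (self-loops do not create
    adjacency).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    results: list[tuple[str, ...]] = []
    stack: list[str] = []

    def visitor(sub: list[str], w: str) -> bool:
        stack.append(w)
        if len(sub) + 1 == k:
            results.append(tuple(sub) + (w,))
        return True

    visitor.pop = stack.pop  # type: ignore[attr-defined]
    _esu(g, k, visitor)
    yield from results


def esu_partial_count(g: SignedDigraph, k: int) -> int:
    """Number of partial subgraphs an unpruned ESU enumeration visits."""
    count = 0

    def visitor(sub: list[str], w: str) -> bool:
        nonlocal count
        count += 1
        return True

    _esu(g, k, visitor)
    return count


def find_matches(g: SignedDigraph, tree: PathTree,
                 stats: SearchStats | None = None) -> list[Match]:
    """All induced matches of the tree's motifs in ``g``.

    Each ESU extension feeds the new node's 2i-1 induced-adjacency
    entries (self-loop sign, row against earlier nodes, column against
    earlier nodes) to the trie; a missing child prunes the branch, and a
    leaf at depth k emits one :class:`Match` per motif id stored there.
    """
    k = tree.k
    matches: list[Match] = []
    positions = [tree.root]

    def visitor(sub: list[str], w: str) -> bool:
        if stats is not None:
            stats.partials_visited += 1
        frag = [g.sign(w, w)]
        frag.extend(g.sign(w, u) for u in sub)   # row (i, 1..i-1)
        frag.extend(g.sign(u, w) for u in sub)   # column (1..i-1, i)
        nxt = tree.step(positions[-1], tuple(frag))
        if nxt is DEAD_END:
            if stats is not None:
                stats.partials_pruned += 1
            return False  # nothing pushed; caller does not pop
        positions.append(nxt)
        if nxt.depth == k and nxt.motif_ids:
            order = tuple(sub) + (w,)
            mat = tuple(tuple(int(x) for x in row)
                        for row in induced_subgraph(g, list(order)))
            for mid in sorted(nxt.motif_ids):
                matches.append(Match(mid, order, mat, g))
                if stats is not None:
                    stats.matches += 1
        return True

    visitor.pop = positions.pop  # type: ignore[attr-defined]
    _esu(g, k, visitor)
    return matches


def count_matches(g: SignedDigraph, motifs: Sequence[Motif]) -> dict[str, int]:
    """Per-motif induced-occurrence counts (one per matched node set)."""
    counts: Counter[str] = Counter({m.id: 0 for m in motifs})
    by_size: dict[int, list[Motif]] = {}
    for m in motifs:
        by_size.setdefault(m.size, []).append(m)
    for k, group in sorted(by_size.items()):
        tree = build_path_tree(group, k)
        for match in find_matches(g, tree):
            counts[match.motif_id] += 1
    return dict(counts)
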
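"""Recovering full-size motif instances from compressed matches.

A match found on the compressed network stands for a family of circuits
in the original network: each compressed edge (a, b, sigma) abbreviates
one or more original paths a -> ... -> b whose internal nodes were all
eliminated by compression and whose sign product equals sigma.  The
recovery is a depth-first search with exactly those two constraints.
Instances are then assembled by choosing one recovered path per
compressed edge, requiring the chosen paths' internal nodes to be
pairwise disjoint (a realizable circuit cannot route two motif edges
through the same eliminated molecule), and enforcing any minimum-size
flag the motif carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx

from .compress import CompressedNetwork, sign_product
from .graph import SignedDigraph
from .motifs import Motif
from .search import Match

__all__ = [
    "EdgePath",
    "MotifInstance",
    "expand_edge",
    "instantiate",
    "structural_properties",
]

#: default cap on recovered path length (edges); DFS over eliminated
#: nodes is exponential in the worst case and needs a bound
DEFAULT_MAX_LEN = 8


@dataclass(frozen=True)
class EdgePath:
    """One original-network path realizing a compressed edge."""

    nodes: tuple[str, ...]  # n0..nL; n0 == nL only when expanding a self-loop
    sign: int

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    @property
    def internal(self) -> frozenset[str]:
        return frozenset(self.nodes[1:-1])

    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes, self.nodes[1:]))

    def __str__(self) -> str:
        return ">".join(self.nodes)


@dataclass(frozen=True)
class MotifInstance:
    """A concrete full-size regulatory motif in the original network."""

    motif_id: str
    match_nodes: tuple[str, ...]  # compressed-level member nodes
    paths: tuple[tuple[tuple[str, str, int], EdgePath], ...]  # (compressed edge, path)

    @property
    def size(self) -> int:
        """Number of distinct original-network molecules involved."""
        members: set[str] = set(self.match_nodes)
        for _, p in self.paths:
            members.update(p.nodes)
        return len(members)

    @property
    def member_nodes(self) -> frozenset[str]:
        members: set[str] = set(self.match_nodes)
        for _, p in self.paths:
            members.update(p.nodes)
        return frozenset(members)

    def edge_multiset(self) -> tuple[tuple[str, str], ...]:
        """Deduplication key: the sorted multiset of traversed edges."""
        out: list[tuple[str, str]] = []
        for _, p in self.paths:
            out.extend(p.edges())
        return tuple(sorted(out))


def expand_edge(original: SignedDigraph, a: str, b: str, sigma: int,
                eliminated: frozenset[str] | set[str],
                max_len: int = DEFAULT_MAX_LEN) -> list[EdgePath]:
    """All original paths a -> ... -> b realizing a compressed edge.

    Constraints: internal nodes all belong to ``eliminated``; the sign
    product of traversed edges equals ``sigma``; paths are simple
    (``a == b`` allowed only as the two endpoints of a self-loop
    expansion); at most ``max_len`` edges.  The direct edge (a, b,
    sigma), when present in the original, qualifies as a length-1 path.
    Results are sorted lexicographically by node sequence.
    """
    for n in (a, b):
        if not original.has_node(n):
            raise KeyError(f"unknown node: {n!r}")
    if sigma not in (1, -1):
        raise ValueError(f"sigma must be +1 or -1, got {sigma!r}")

    allowed = set(eliminated) | {a, b}
    sub = nx.DiGraph(
        (u, v, {"sign": s}) for (u, v, s) in original.edges
        if u in allowed and v in allowed
    )
    paths: list[EdgePath] = []

    def collect(seq: list[str]) -> None:
        signs = [sub.edges[u, v]["sign"] for u, v in zip(seq, seq[1:])]
        if sign_product(signs) == sigma:
            paths.append(EdgePath(tuple(seq), sigma))

    if a != b:
        if sub.has_node(a) and sub.has_node(b):
            for seq in nx.all_simple_paths(sub, a, b, cutoff=max_len):
                # internal nodes must be eliminated; endpoints are exempt
                if all(n in eliminated for n in seq[1:-1]):
                    collect(seq)
    else:
        # self-loop: direct loop edge plus cycles through eliminated nodes
        if sub.has_edge(a, a):
            collect([a, a])
        if sub.has_node(a):
            for s in sorted(sub.successors(a)):
                if s == a or s not in eliminated:
                    continue
                for seq in nx.all_simple_paths(sub, s, a, cutoff=max_len - 1):
                    if all(n in eliminated for n in seq[:-1]):
                        collect([a] + list(seq))

    paths.sort(key=lambda p: p.nodes)
    return paths


def instantiate(match: Match, expansions: dict[tuple[str, str, int], list[EdgePath]],
                motif: Motif | None = None,
                allow_shared_internals: bool = False) -> list[MotifInstance]:
    """Assemble instances by choosing one recovered path per edge.

    ``expansions`` maps every compressed edge of the match to its
    recovered paths.  Selections whose paths share internal nodes (with
    each other or with the matched nodes) are discarded unless
    ``allow_shared_internals``; instances below a flagged motif's
    minimum size are discarded; duplicates (same traversed edge
    multiset) collapse to one.  An edge with no recovered path yields
    zero instances for the whole match.
    """
    edges = match.induced_edges()
    missing = [e for e in edges if e not in expansions]
    if missing:
        raise KeyError(f"no expansion list for compressed edge(s): {missing}")
    if any(not expansions[e] for e in edges):
        return []

    min_size = motif.min_size if motif is not None else None
    match_nodes = set(match.nodes)
    out: list[MotifInstance] = []
    seen: set[tuple[tuple[str, str], ...]] = set()
    for choice in product(*(expansions[e] for e in edges)):
        if not allow_shared_internals:
            used: set[str] = set()
            ok = True
            for p in choice:
                internal = p.internal
                if internal & match_nodes or internal & used:
                    ok = False
                    break
                used |= internal
            if not ok:
                continue
        inst = MotifInstance(
            motif_id=match.motif_id,
            match_nodes=match.nodes,
            paths=tuple(zip(edges, choice)),
        )
        if min_size is not None and inst.size < min_size:
            continue
        key = inst.edge_multiset()
        if key in seen:
            continue
        seen.add(key)
        out.append(inst)
    return out


def structural_properties(inst: MotifInstance) -> dict:
    """Per-edge sign/length and total size of one motif instance."""
    return {
        "motif_id": inst.motif_id,
        "members": sorted(inst.member_nodes),
        "edges": [
            {
                "from": e[0],
                "to": e[1],
                "path": str(p),
                "sign": p.sign,
                "length": p.length,
            }
            for e, p in inst.paths
        ],
        "size": inst.size,
    }


def expand_match(match: Match, comp: CompressedNetwork, motif: Motif | None = None,
                 max_len: int = DEFAULT_MAX_LEN,
                 allow_shared_internals: bool = False) -> list[MotifInstance]:
    """Convenience: expand every compressed edge of a match and instantiate."""
    expansions = {
        (a, b, s): expand_edge(comp.original, a, b, s, comp.eliminated, max_len)
        for (a, b, s) in match.induced_edges()
    }
    return instantiate(match, expansions, motif, allow_shared_internals)
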
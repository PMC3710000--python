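"""Synthetic networks, random query motifs, and the brute-force oracle.

The generator emulates the size regime of curated signaling pathway
collections: sparse digraphs (edge/node ratio around 1.3-2.3) with a
minority of inhibitory edges (about 18% in large integrated pathway
maps, the default here).  The oracle defines induced-match semantics in
the most transparent way possible — enumerate every k-subset of nodes
and every bijection onto the motif — and deliberately shares no code
with the trie-pruned search it is used to validate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np

from .graph import SignedDigraph, induced_subgraph
from .motifs import Motif

__all__ = [
    "GeneratorSpec",
    "random_network",
    "random_query_motifs",
    "OracleIndex",
    "oracle_matches",
]

#: inhibitory-edge fraction typical of integrated human pathway maps
DEFAULT_NEGATIVE_FRACTION = 0.18


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic signed network."""

    n: int
    m: int
    negative_fraction: float = DEFAULT_NEGATIVE_FRACTION
    allow_self_loops: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        cap = self.n * (self.n - 1) + (self.n if self.allow_self_loops else 0)
        if not 0 <= self.m <= cap:
            raise ValueError(f"m={self.m} infeasible for n={self.n} "
                             f"(max {cap} ordered pairs)")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must be in [0, 1]")


def _node_name(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def random_network(spec: GeneratorSpec) -> SignedDigraph:
    """Uniformly sample ``m`` distinct ordered pairs as signed edges.

    Fixed-m sampling (not per-edge probability) so tests control
    density exactly; each edge is inhibitory independently with
    probability ``negative_fraction``.  Identical specs give identical
    graphs.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(spec.n - 1)))
    names = [_node_name(i, width) for i in range(spec.n)]
    pairs = [(i, j) for i in range(spec.n) for j in range(spec.n)
             if i != j or spec.allow_self_loops]
    chosen = rng.choice(len(pairs), size=spec.m, replace=False)
    signs = np.where(rng.random(spec.m) < spec.negative_fraction, -1, 1)
    g = SignedDigraph(nodes=names)
    for idx, s in zip(chosen, signs):
        i, j = pairs[idx]
        g.add_edge(names[i], names[j], int(s))
    return g


def _connected_k_sets(g: SignedDigraph, k: int):
    """Brute force: all k-subsets weakly connected in g (small n only)."""
    nodes = g.sorted_nodes()
    for subset in combinations(nodes, k):
        if _is_weakly_connected(g, subset):
            yield subset


def _is_weakly_connected(g: SignedDigraph, subset) -> bool:
    members = set(subset)
    seen = {subset[0]}
    frontier = [subset[0]]
    while frontier:
        u = frontier.pop()
        for v in g.neighbors(u) & members - seen:
            seen.add(v)
            frontier.append(v)
    return len(seen) == len(members)


def random_query_motifs(g: SignedDigraph, k: int, count: int, seed: int = 0) -> list[Motif]:
    """Sample pairwise non-isomorphic connected induced k-subgraphs of g.

    Mirrors the query-generation protocol of motif-search benchmarking:
    random connected induced subgraphs of the network itself,
    deduplicated up to isomorphism.  When fewer than ``count``
    non-isomorphic k-subgraphs exist among the sampled sets, all found
    are returned.
    """
    from .isomorphism import canonical_form  # local: keeps oracle layering clear

    if k > 6:
        raise ValueError("query motif size is limited to 6")
    rng = np.random.default_rng(seed)
    nodes = g.sorted_nodes()
    found: dict[tuple, Motif] = {}
    budget = max(200, 50 * count)
    for _ in range(budget):
        if len(found) >= count:
            break
        # randomized BFS growth of a connected set
        start = nodes[rng.integers(len(nodes))]
        members = [start]
        while len(members) < k:
            frontier = sorted(set().union(*(g.neighbors(u) for u in members)) -
                              set(members))
            if not frontier:
                break
            members.append(frontier[rng.integers(len(frontier))])
        if len(members) != k:
            continue
        sub = SignedDigraph(
            edges=[(u, v, s) for (u, v, s) in g.edges
                   if u in members and v in members],
            nodes=members,
        )
        form = canonical_form(sub)
        if form not in found:
            mid = f"query_{k}_{len(found):02d}"
            found[form] = Motif(mid, "custom", sub,
                                source_note="sampled induced subgraph")
    return list(found.values())


class OracleIndex:
    """Subset-times-permutation match oracle for one (network, k).

    Enumerates every k-subset of nodes once, storing each induced
    signed adjacency grouped by a permutation-invariant key (sorted
    per-node degree/sign profiles), then answers motif queries by
    exhaustive bijection testing within the matching group.  The
    semantics are exactly "some bijection maps the induced subgraph
    onto the motif, signs included"; no search/path-tree code is used.
    """

    #: guard against runaway C(n, k) * k! work
    MAX_NODES = {3: 60, 4: 50, 5: 40}

    def __init__(self, g: SignedDigraph, k: int):
        limit = self.MAX_NODES.get(k, 30)
        if len(g) > limit:
            raise ValueError(
                f"oracle limited to {limit} nodes for k={k} "
                f"(C(n,k)*k! enumeration); got {len(g)}"
            )
        self.g = g
        self.k = k
        nodes = g.sorted_nodes()
        dense = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
        pos = {n: i for i, n in enumerate(nodes)}
        for u, v, s in g.edges:
            dense[pos[u], pos[v]] = s
        subs = np.array(list(combinations(range(len(nodes)), k)), dtype=np.intp)
        # all induced submatrices in one gather: shape (C(n,k), k, k)
        mats = dense[subs[:, :, None], subs[:, None, :]]
        codes = np.sort(self._profile_codes(mats), axis=1)
        order = np.lexsort(codes.T[::-1])
        uniq, starts = np.unique(codes[order], axis=0, return_index=True)
        bounds = np.append(starts, len(order))
        self._nodes = nodes
        self._subs = subs
        self._mats = mats
        self._groups: dict[tuple, np.ndarray] = {
            tuple(code): order[lo:hi]
            for code, lo, hi in zip(uniq.tolist(), bounds[:-1], bounds[1:])
        }

    @staticmethod
    def _profile_codes(mats: np.ndarray) -> np.ndarray:
        """Per-node degree/sign profiles packed into one int per node.

        The profile (self-loop sign, out+/-, in+/- edge counts) is
        permutation-covariant, so its sorted multiset is a cheap
        isomorphism invariant used to group candidate subsets.
        """
        diag = mats[..., np.arange(mats.shape[-1]), np.arange(mats.shape[-1])]
        return (
            (diag.astype(np.int64) + 1) * 10**8
            + (mats > 0).sum(axis=-1, dtype=np.int64) * 10**6
            + (mats < 0).sum(axis=-1, dtype=np.int64) * 10**4
            + (mats > 0).sum(axis=-2, dtype=np.int64) * 10**2
            + (mats < 0).sum(axis=-2, dtype=np.int64)
        )

    @classmethod
    def _invariant(cls, mat: np.ndarray) -> tuple:
        """Sorted profile multiset of one signed adjacency matrix."""
        return tuple(np.sort(cls._profile_codes(mat[None, ...]), axis=1)[0].tolist())

    def matches(self, motif: Motif) -> set[frozenset[str]]:
        if motif.size != self.k:
            raise ValueError(f"motif size {motif.size} != index size {self.k}")
        target = induced_subgraph(motif.graph, motif.graph.sorted_nodes())
        key = self._invariant(target)
        out: set[frozenset[str]] = set()
        perms = [np.array(p) for p in permutations(range(self.k))]
        for row in self._groups.get(key, np.empty(0, dtype=np.intp)):
            mat = self._mats[row]
            for p in perms:
                if np.array_equal(mat[np.ix_(p, p)], target):
                    out.add(frozenset(self._nodes[i] for i in self._subs[row]))
                    break
        return out


def oracle_matches(g: SignedDigraph, motif: Motif) -> set[frozenset[str]]:
    """Every node set whose induced signed subgraph is isomorphic to the motif.

    Convenience wrapper building a fresh :class:`OracleIndex`; batch
    callers querying many motifs of one size against one network should
    build the index once.
    """
    return OracleIndex(g, motif.size).matches(motif)
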
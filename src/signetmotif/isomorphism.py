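"""Canonical labels and isomorphism for small signed digraphs.

A k-node signed adjacency matrix is linearised into a *canonical label*
of length k²: for each node i (1-based) append the diagonal entry
(i,i), then the row entries (i,1)..(i,i-1), then the column entries
(1,i)..(i-1,i).  Node i thus contributes exactly 2i-1 entries — the new
matrix cells revealed when the i-th node joins a growing subgraph,
which is what makes this ordering suitable for incremental trie lookup
during search.

Isomorphism here is *signed*: a bijection must map edges onto edges of
equal sign.  Canonical forms are obtained by exhaustive permutation,
which is exact and fast for motif sizes up to :data:`MAX_MOTIF_SIZE`.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np

from .graph import SignedDigraph, induced_subgraph

__all__ = [
    "MAX_MOTIF_SIZE",
    "entry_order",
    "label_of",
    "matrix_of",
    "all_isomorph_labels",
    "canonical_form",
    "are_isomorphic",
    "automorphism_count",
]

#: largest motif size for which exhaustive (k!) canonicalisation is used
MAX_MOTIF_SIZE = 6

#: sort key making the canonical form the lexicographically smallest
#: label under the order 0 < +1 < -1 (sparse graphs sort early)
_ENTRY_RANK = {0: 0, 1: 1, -1: 2}


@lru_cache(maxsize=None)
def entry_order(k: int) -> tuple[tuple[int, int], ...]:
    """The fixed (row, column) read-off order for a k×k matrix, 1-based.

    For k=3: (1,1),(2,2),(2,1),(1,2),(3,3),(3,1),(3,2),(1,3),(2,3).
    Node i contributes the slice of length 2i-1 starting at (i-1)².
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    order: list[tuple[int, int]] = []
    for i in range(1, k + 1):
        order.append((i, i))
        order.extend((i, j) for j in range(1, i))
        order.extend((j, i) for j in range(1, i))
    return tuple(order)


def label_of(matrix) -> tuple[int, ...]:
    """Read a square {0,+1,-1} adjacency matrix off in entry order."""
    m = np.asarray(matrix, dtype=int)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {m.shape}")
    if not np.isin(m, (-1, 0, 1)).all():
        raise ValueError("matrix entries must be in {0, +1, -1}")
    k = m.shape[0]
    return tuple(int(m[r - 1, c - 1]) for r, c in entry_order(k))


def matrix_of(label: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`label_of`: rebuild the k×k matrix from a label."""
    k = int(round(len(label) ** 0.5))
    if k * k != len(label):
        raise ValueError(f"label length {len(label)} is not a perfect square")
    m = np.zeros((k, k), dtype=int)
    for entry, (r, c) in zip(label, entry_order(k)):
        m[r - 1, c - 1] = entry
    return m


def label_sort_key(label: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(_ENTRY_RANK[e] for e in label)


def _check_size(g: SignedDigraph) -> list[str]:
    nodes = g.sorted_nodes()
    if len(nodes) > MAX_MOTIF_SIZE:
        raise ValueError(
            f"graph has {len(nodes)} nodes; exhaustive canonicalisation is "
            f"limited to {MAX_MOTIF_SIZE} (k! isomorph generation)"
        )
    return nodes


def all_isomorph_labels(m: SignedDigraph) -> frozenset[tuple[int, ...]]:
    """Labels of the adjacency matrix under all k! node orderings.

    The result has exactly k!/|Aut(m)| distinct members.  Two graphs
    are isomorphic iff their label sets coincide (equivalently,
    intersect).
    """
    nodes = _check_size(m)
    base = induced_subgraph(m, nodes)
    k = len(nodes)
    labels = set()
    for perm in permutations(range(k)):
        idx = np.array(perm)
        labels.add(label_of(base[np.ix_(idx, idx)]))
    return frozenset(labels)


def canonical_form(m: SignedDigraph) -> tuple[int, ...]:
    """The lexicographically smallest isomorph label (order 0 < +1 < -1)."""
    return min(all_isomorph_labels(m), key=label_sort_key)


def automorphism_count(m: SignedDigraph) -> int:
    """|Aut(m)| — the number of sign-preserving self-isomorphisms."""
    import math

    k = len(m)
    return math.factorial(k) // len(all_isomorph_labels(m))


def are_isomorphic(a: SignedDigraph, b: SignedDigraph) -> bool:
    """True iff a node bijection maps a's signed edges exactly onto b's."""
    if len(a) != len(b) or a.n_edges != b.n_edges:
        return False
    _check_size(a)
    _check_size(b)
    return canonical_form(a) == canonical_form(b)
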
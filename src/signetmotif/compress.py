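"""Network compression by node-based reduction.

Linear regulatory cascades carry the same net effect as a single signed
interaction: the sign of a path is the product of its edge signs.  The
reduction repeatedly eliminates intermediate nodes, replacing each
(predecessor, eliminated, successor) wedge with a bypass edge whose sign
is the product of the two traversed signs, until a fixpoint is reached.
The reduced network preserves the sign-dynamics of the original in the
sense that every reduced edge is realized by at least one original path
through eliminated nodes with the same net sign (the expansion step
recovers those paths).

Eliminability of a node v (all must hold):

* v is not protected and has no self-loop;
* in_degree(v) >= 1 and out_degree(v) >= 1 (true intermediates only);
* in_degree(v) == 1 or out_degree(v) == 1 (linear-cascade gate, keeps
  bypass growth bounded; can be disabled);
* no bypass edge (p, s) would conflict in sign with an existing edge or
  with another bypass created by the same elimination.

Collapsing a 2-cycle through an eliminated node creates a self-loop on
the survivor; this is deliberate, since compressed motif forms include
self-regulation, and expansion restores the true loop length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Sequence

from .graph import SignedDigraph, SignConflictError

__all__ = ["CompressedNetwork", "compress", "sign_product"]


def sign_product(signs: Sequence[int]) -> int:
    """Net regulatory effect of a cascade: the product of its edge signs."""
    if len(signs) == 0:
        raise ValueError("sign_product of an empty cascade is undefined")
    if any(s not in (1, -1) for s in signs):
        raise ValueError("signs must be +1 or -1")
    return prod(signs)


@dataclass
class CompressedNetwork:
    """A reduced network plus the bookkeeping needed to expand it back."""

    reduced: SignedDigraph
    eliminated: frozenset[str]
    original: SignedDigraph
    protected: frozenset[str] = field(default_factory=frozenset)

    def summary(self) -> dict:
        return {
            "nodes_before": len(self.original),
            "nodes_after": len(self.reduced),
            "edges_before": self.original.n_edges,
            "edges_after": self.reduced.n_edges,
            "eliminated": sorted(self.eliminated),
        }


def _eliminable(g: SignedDigraph, v: str, protected: frozenset[str],
                linear_gate: bool, allow_self_loops: bool) -> list[tuple[str, str, int]] | None:
    """Bypass edges created by eliminating v, or None if v is not eliminable."""
    if v in protected or g.has_edge(v, v):
        return None
    preds = [p for p in g.predecessors(v) if p != v]
    succs = [s for s in g.successors(v) if s != v]
    ind, outd = len(preds), len(succs)
    if ind < 1 or outd < 1:
        return None
    if linear_gate and not (ind == 1 or outd == 1):
        return None
    bypass: dict[tuple[str, str], int] = {}
    for p in preds:
        for s in succs:
            sigma = sign_product([g.sign(p, v), g.sign(v, s)])
            if p == s and not allow_self_loops:
                return None
            existing = g.sign(p, s)
            if existing != 0 and existing != sigma:
                return None  # would conflict with an edge already present
            if (p, s) in bypass and bypass[(p, s)] != sigma:
                return None  # two wedges through v disagree in sign
            bypass[(p, s)] = sigma
    return [(p, s, sigma) for (p, s), sigma in sorted(bypass.items())]


def compress(g: SignedDigraph, protected: Sequence[str] | frozenset[str] = (),
             linear_gate: bool = True, allow_self_loops: bool = True) -> CompressedNetwork:
    """Reduce ``g`` to a fixpoint of node elimination.

    Parameters
    ----------
    g
        Validated network (no conflicting parallel edges; guaranteed by
        :class:`~signetmotif.graph.SignedDigraph` construction).
    protected
        Node ids never eliminated (e.g. the source/target of a
        path-constrained analysis).
    linear_gate
        Require in-degree == 1 or out-degree == 1 for elimination
        (default).  Disabling allows hub elimination with |P|·|S|
        bypass edges.
    allow_self_loops
        Permit bypass self-loops when a 2-cycle collapses (default).

    Nodes are scanned in sorted-id order, repeatedly, until a full pass
    eliminates nothing; the scan order is deterministic, so identical
    inputs give identical reductions.
    """
    protected = frozenset(protected)
    unknown = protected - g.nodes
    if unknown:
        raise KeyError(f"protected nodes not in network: {sorted(unknown)}")
    work = g.copy()
    eliminated: set[str] = set()
    changed = True
    while changed:
        changed = False
        for v in work.sorted_nodes():
            bypass = _eliminable(work, v, protected, linear_gate, allow_self_loops)
            if bypass is None:
                continue
            work.remove_node(v)
            for p, s, sigma in bypass:
                work.add_edge(p, s, sigma)
            eliminated.add(v)
            changed = True
    return CompressedNetwork(
        reduced=work,
        eliminated=frozenset(eliminated),
        original=g,
        protected=protected,
    )
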
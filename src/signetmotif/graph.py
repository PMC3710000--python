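"""Signed directed graphs: data model, validation and edge-list I/O.

A signaling network is modelled as a directed graph whose edges carry a
sign, +1 for activation and -1 for inhibition.  The universal on-disk
representation is a 3-column whitespace-separated edge list::

    regulator   relation   target

where ``relation`` is ``+`` or ``-`` (the Unicode minus sign is also
accepted on input).  Node identifiers are arbitrary non-whitespace
strings and are compared case-sensitively.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "SignedDigraph",
    "DegreeProfile",
    "ParseError",
    "SignConflictError",
    "read_network",
    "write_network",
    "induced_subgraph",
]

#: relation tokens accepted on input, normalised to an integer sign
_RELATION_TOKENS = {"+": 1, "-": -1, "−": -1}
_SIGN_TOKENS = {1: "+", -1: "-"}


class ParseError(ValueError):
    """Raised when an edge-list line cannot be interpreted."""


class SignConflictError(ValueError):
    """Raised when an ordered node pair carries both signs."""


class SignedDigraph:
    """A directed graph with signed edges and optional node role marks.

    At most one edge per ordered ``(source, target)`` pair; self-loops
    are allowed and carry a sign like any other edge.  Backed by a
    :class:`networkx.DiGraph` with a ``sign`` attribute per edge.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, int]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        self._g = nx.DiGraph()
        for n in nodes:
            self.add_node(n)
        for u, v, s in edges:
            self.add_edge(u, v, s)

    # -- construction -------------------------------------------------

    def add_node(self, n: str) -> None:
        if not isinstance(n, str) or not n or any(c.isspace() for c in n):
            raise ValueError(f"node id must be a non-empty string without whitespace: {n!r}")
        self._g.add_node(n)

    def add_edge(self, u: str, v: str, sign: int) -> None:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        if self._g.has_edge(u, v) and self._g.edges[u, v]["sign"] != sign:
            raise SignConflictError(f"conflicting signs for edge ({u!r}, {v!r})")
        self.add_node(u)
        self.add_node(v)
        self._g.add_edge(u, v, sign=sign)

    def remove_node(self, n: str) -> None:
        self._g.remove_node(n)

    def copy(self) -> "SignedDigraph":
        out = SignedDigraph()
        out._g = self._g.copy()
        return out

    @classmethod
    def from_nx(cls, g: nx.DiGraph) -> "SignedDigraph":
        out = cls()
        out._g = nx.DiGraph()
        out._g.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            out._g.add_edge(u, v, sign=d["sign"])
        return out

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str, int]]:
        return frozenset((u, v, d["sign"]) for u, v, d in self._g.edges(data=True))

    def sorted_nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def sorted_edges(self) -> list[tuple[str, str, int]]:
        return sorted(self.edges)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, n: str) -> bool:
        return self._g.has_node(n)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def sign(self, u: str, v: str) -> int:
        """Sign of edge u->v, or 0 if absent."""
        if self._g.has_edge(u, v):
            return self._g.edges[u, v]["sign"]
        return 0

    def successors(self, n: str) -> list[str]:
        return sorted(self._g.successors(n))

    def predecessors(self, n: str) -> list[str]:
        return sorted(self._g.predecessors(n))

    def neighbors(self, n: str) -> set[str]:
        """Undirected neighborhood (union of in- and out-neighbors), self excluded."""
        out = set(self._g.successors(n)) | set(self._g.predecessors(n))
        out.discard(n)
        return out

    def in_degree(self, n: str) -> int:
        return self._g.in_degree(n)

    def out_degree(self, n: str) -> int:
        return self._g.out_degree(n)

    def degree_profile(self, n: str) -> "DegreeProfile":
        return DegreeProfile(
            node=n,
            in_degree=self._g.in_degree(n),
            out_degree=self._g.out_degree(n),
            degree=self._g.in_degree(n) + self._g.out_degree(n),
        )

    def node_marks(self) -> Mapping[str, str]:
        """Per-node role labels.

        A node with only inward edges is marked ``input`` and one with
        only outward edges ``output`` — this follows the originating
        tool's wording, which is inverted relative to the usual
        signaling convention (where sources are "inputs"); see the
        methods note.  Nodes with both, or with neither, are
        ``internal``.  Self-loops count toward both directions.
        """
        marks: dict[str, str] = {}
        for n in self._g.nodes:
            ind, outd = self._g.in_degree(n), self._g.out_degree(n)
            if ind > 0 and outd == 0:
                marks[n] = "input"
            elif outd > 0 and ind == 0:
                marks[n] = "output"
            else:
                marks[n] = "internal"
        return marks

    def to_nx(self) -> nx.DiGraph:
        """A copy as a plain networkx DiGraph with 'sign' edge attributes."""
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"SignedDigraph(|V|={len(self)}, |E|={self.n_edges})"


@dataclass(frozen=True)
class DegreeProfile:
    node: str
    in_degree: int
    out_degree: int
    degree: int


def read_network(stream, on_conflict: str = "drop_conflicts") -> SignedDigraph:
    """Parse a 3-column signed edge list into a validated graph.

    Parameters
    ----------
    stream
        Text stream, string, or iterable of lines.  Lines starting with
        ``#`` and blank lines are ignored.
    on_conflict
        ``"drop_conflicts"`` (default) removes *all* edges of any
        ordered pair observed with both signs, mirroring the exclusion
        of inconsistent activation/inhibition annotations when pathway
        sources are integrated.  ``"reject"`` raises
        :class:`SignConflictError` instead.

    Raises
    ------
    ParseError
        On a malformed line (wrong column count, unknown relation
        token), naming the line number; also on entirely empty input.
    """
    if on_conflict not in ("drop_conflicts", "reject"):
        raise ValueError(f"unknown conflict policy: {on_conflict!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    seen: dict[tuple[str, str], int] = {}
    conflicted: set[tuple[str, str]] = set()
    n_lines = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        src, rel, tgt = fields[0], fields[1], fields[2]
        if rel not in _RELATION_TOKENS:
            raise ParseError(f"line {lineno}: unknown relation symbol {rel!r}")
        sign = _RELATION_TOKENS[rel]
        key = (src, tgt)
        if key in seen and seen[key] != sign:
            if on_conflict == "reject":
                raise SignConflictError(
                    f"line {lineno}: edge ({src}, {tgt}) carries both signs"
                )
            conflicted.add(key)
        else:
            seen[key] = sign

    if n_lines == 0:
        raise ParseError("empty input: no edge lines found")

    g = SignedDigraph()
    for (src, tgt), sign in seen.items():
        if (src, tgt) in conflicted:
            # integration rule: an inconsistent interaction is excluded
            # entirely, but its endpoints stay in the network
            g.add_node(src)
            g.add_node(tgt)
        else:
            g.add_edge(src, tgt, sign)
    return g


def write_network(g: SignedDigraph, stream, warn=None) -> None:
    """Emit ``g`` as a 3-column edge list (ASCII signs, tab-separated).

    The format cannot express isolated nodes; they are omitted with a
    warning callback (default: silently dropped, see docs).  Guarantees
    ``read_network(write_network(g)) == g`` for graphs without isolated
    nodes.
    """
    covered: set[str] = set()
    for u, v, s in g.sorted_edges():
        stream.write(f"{u}\t{_SIGN_TOKENS[s]}\t{v}\n")
        covered.update((u, v))
    isolated = g.nodes - covered
    if isolated and warn is not None:
        warn(f"omitting {len(isolated)} isolated node(s): {sorted(isolated)}")


def induced_subgraph(g: SignedDigraph, node_list: list[str]) -> np.ndarray:
    """Signed adjacency matrix of the subgraph induced by ``node_list``.

    ``M[i, j]`` is the sign of the edge ``node_list[i] -> node_list[j]``
    or 0 if absent; the diagonal holds self-loop signs.  Row/column
    order follows ``node_list``, so permuting the list permutes the
    matrix symmetrically.
    """
    if len(set(node_list)) != len(node_list):
        raise ValueError("node_list contains duplicates")
    for n in node_list:
        if not g.has_node(n):
            raise KeyError(f"unknown node: {n!r}")
    k = len(node_list)
    m = np.zeros((k, k), dtype=int)
    for i, u in enumerate(node_list):
        for j, v in enumerate(node_list):
            m[i, j] = g.sign(u, v)
    return m
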
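"""Path-tree: a trie over canonical-label fragments of motif isomorphs.

All k! labelled variants of every same-size query motif are generated
and their canonical labels split into per-node fragments: the i-th node
of a growing subgraph reveals exactly 2i-1 new adjacency entries (its
self-loop, its row against earlier nodes, its column against earlier
nodes).  The trie keys children by those fragments, so a subgraph
enumerator can test in one dictionary lookup whether a partially
discovered subgraph can still extend to *any* isomorph of *any* query
motif — a dead end prunes the whole branch, and reaching depth k at a
leaf names the matched motif(s).

Since non-isomorphic graphs have disjoint isomorph-label sets, leaves of
a tree built from a non-isomorphic library carry exactly one motif id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .isomorphism import MAX_MOTIF_SIZE, all_isomorph_labels, label_sort_key
from .motifs import Motif

__all__ = ["PathTree", "PathTreeNode", "DEAD_END", "build_path_tree"]

#: sentinel returned by :meth:`PathTree.step` when no isomorph remains
DEAD_END = None


@dataclass
class PathTreeNode:
    depth: int  # number of nodes already placed (root = 0)
    children: dict[tuple[int, ...], "PathTreeNode"] = field(default_factory=dict)
    motif_ids: frozenset[str] = frozenset()  # non-empty at leaves only

    @property
    def is_leaf(self) -> bool:
        return bool(self.motif_ids)


@dataclass
class PathTree:
    k: int
    root: PathTreeNode

    def step(self, position: PathTreeNode, new_entries: tuple[int, ...]):
        """Descend one level; ``DEAD_END`` if no isomorph starts this way.

        ``new_entries`` must be the 2i-1 adjacency entries contributed
        by the i-th node, i = position.depth + 1.
        """
        expected = 2 * (position.depth + 1) - 1
        if len(new_entries) != expected:
            raise ValueError(
                f"expected {expected} entries at depth {position.depth + 1}, "
                f"got {len(new_entries)}"
            )
        return position.children.get(tuple(new_entries), DEAD_END)

    # -- introspection ------------------------------------------------

    def leaves(self) -> list[PathTreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.depth == self.k:
                out.append(node)
            else:
                stack.extend(node.children.values())
        return out

    def labels(self) -> dict[tuple[int, ...], frozenset[str]]:
        """All root-to-leaf label sequences, concatenated, with motif ids."""
        out: dict[tuple[int, ...], frozenset[str]] = {}

        def walk(node: PathTreeNode, prefix: tuple[int, ...]):
            if node.depth == self.k:
                out[prefix] = node.motif_ids
                return
            for frag, child in node.children.items():
                walk(child, prefix + frag)

        walk(self.root, ())
        return out

    def n_nodes(self) -> int:
        count, stack = 0, [self.root]
        while stack:
            node = stack.pop()
            count += 1
            stack.extend(node.children.values())
        return count

    def to_dict(self) -> dict:
        """JSON-serialisable nested view, for debugging dumps."""

        def conv(node: PathTreeNode) -> dict:
            d: dict = {"depth": node.depth}
            if node.motif_ids:
                d["motifs"] = sorted(node.motif_ids)
            if node.children:
                d["children"] = {
                    ",".join(map(str, frag)): conv(child)
                    for frag, child in sorted(node.children.items(),
                                              key=lambda kv: label_sort_key(kv[0]))
                }
            return d

        return {"k": self.k, "root": conv(self.root)}


def _fragments(label: tuple[int, ...], k: int) -> list[tuple[int, ...]]:
    """Split a k²-length label into the k per-node fragments (lengths 2i-1)."""
    frags, pos = [], 0
    for i in range(1, k + 1):
        width = 2 * i - 1
        frags.append(label[pos:pos + width])
        pos += width
    return frags


def build_path_tree(motifs: Sequence[Motif], k: int) -> PathTree:
    """Build the trie for all ``k``-node motifs in ``motifs``.

    All motifs must have exactly k nodes; one tree is built per motif
    size and the search runs once per size.
    """
    if not 1 <= k <= MAX_MOTIF_SIZE:
        raise ValueError(f"motif size must be in 1..{MAX_MOTIF_SIZE}, got {k}")
    if not motifs:
        raise ValueError("cannot build a path-tree from an empty motif list")
    wrong = [m.id for m in motifs if m.size != k]
    if wrong:
        raise ValueError(f"motifs not of size {k}: {wrong}")

    root = PathTreeNode(depth=0)
    for motif in motifs:
        for label in sorted(all_isomorph_labels(motif.graph), key=label_sort_key):
            node = root
            for frag in _fragments(label, k):
                child = node.children.get(frag)
                if child is None:
                    child = PathTreeNode(depth=node.depth + 1)
                    node.children[frag] = child
                node = child
            node.motif_ids = node.motif_ids | {motif.id}
    return PathTree(k=k, root=root)
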
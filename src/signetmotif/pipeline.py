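"""End-to-end regulatory motif analysis.

Whole-network analysis runs the four stages in order: compress the
network, search the reduced network for induced occurrences of the
compressed query motifs (one path-tree per motif size), recover the
original paths behind each compressed edge, and assemble annotated
full-size instances.  Path-constrained analysis additionally restricts
reporting to instances lying on the shortest path(s) between a chosen
source and target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .compress import CompressedNetwork, compress
from .expand import DEFAULT_MAX_LEN, MotifInstance, expand_match, structural_properties
from .graph import SignedDigraph
from .motifs import Motif
from .pathtree import build_path_tree
from .search import Match, SearchStats, find_matches

__all__ = ["AnalysisOptions", "AnalysisReport", "analyze", "analyze_path", "shortest_paths"]

logger = logging.getLogger("signetmotif")


@dataclass(frozen=True)
class AnalysisOptions:
    compression: bool = True
    max_path_len: int = DEFAULT_MAX_LEN
    allow_shared_internals: bool = False
    linear_gate: bool = True
    #: path-constrained mode: motif nodes must lie on the union of all
    #: shortest paths ("union") or on a single shortest path ("single")
    path_scope: str = "union"
    protected: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "compression": self.compression,
            "max_path_len": self.max_path_len,
            "allow_shared_internals": self.allow_shared_internals,
            "linear_gate": self.linear_gate,
            "path_scope": self.path_scope,
            "protected": list(self.protected),
        }


@dataclass
class AnalysisReport:
    counts: dict[str, int]
    instances: list[MotifInstance]
    matches: list[Match]
    compression: CompressedNetwork
    options: AnalysisOptions
    stats: SearchStats = field(default_factory=SearchStats)
    notice: str = ""

    def instance_table(self) -> pd.DataFrame:
        rows = []
        for inst in self.instances:
            props = structural_properties(inst)
            rows.append({
                "motif_id": props["motif_id"],
                "members": ";".join(props["members"]),
                "paths": ";".join(e["path"] for e in props["edges"]),
                "signs": ";".join("+" if e["sign"] > 0 else "-" for e in props["edges"]),
                "lengths": ";".join(str(e["length"]) for e in props["edges"]),
                "size": props["size"],
            })
        return pd.DataFrame(
            rows, columns=["motif_id", "members", "paths", "signs", "lengths", "size"]
        )

    def summary(self) -> dict:
        return {
            "counts": dict(sorted(self.counts.items())),
            "total_instances": len(self.instances),
            "total_matches": len(self.matches),
            "compression": self.compression.summary(),
            "search": {
                "partials_visited": self.stats.partials_visited,
                "partials_pruned": self.stats.partials_pruned,
            },
            "options": self.options.to_dict(),
            "notice": self.notice,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _motif_index(motifs: Sequence[Motif]) -> dict[str, Motif]:
    index: dict[str, Motif] = {}
    for m in motifs:
        if m.id in index:
            raise ValueError(f"duplicate motif id: {m.id!r}")
        index[m.id] = m
    return index


def analyze(network: SignedDigraph, motifs: Sequence[Motif],
            options: AnalysisOptions | None = None) -> AnalysisReport:
    """Whole-network regulatory motif identification.

    With compression disabled, the search runs on the original network
    and every reported instance is a raw match whose edges are all
    direct (length 1).
    """
    if not motifs:
        raise ValueError("motif list is empty")
    options = options or AnalysisOptions()
    index = _motif_index(motifs)

    if options.compression:
        comp = compress(network, protected=options.protected,
                        linear_gate=options.linear_gate)
    else:
        comp = CompressedNetwork(
            reduced=network, eliminated=frozenset(), original=network,
            protected=frozenset(options.protected),
        )
    logger.info("compression: %d -> %d nodes (%d eliminated)",
                len(comp.original), len(comp.reduced), len(comp.eliminated))

    by_size: dict[int, list[Motif]] = {}
    for m in motifs:
        by_size.setdefault(m.size, []).append(m)

    stats = SearchStats()
    matches: list[Match] = []
    for k, group in sorted(by_size.items()):
        tree = build_path_tree(group, k)
        matches.extend(find_matches(comp.reduced, tree, stats))
    logger.info("search: %d compressed matches (%d partials, %d pruned)",
                len(matches), stats.partials_visited, stats.partials_pruned)

    instances: list[MotifInstance] = []
    for match in matches:
        instances.extend(expand_match(
            match, comp, index[match.motif_id],
            max_len=options.max_path_len,
            allow_shared_internals=options.allow_shared_internals,
        ))
    # global deduplication: two matches can expand to the same circuit
    unique: dict[tuple, MotifInstance] = {}
    for inst in instances:
        unique.setdefault((inst.motif_id, inst.edge_multiset()), inst)
    instances = sorted(unique.values(),
                       key=lambda i: (i.motif_id, i.edge_multiset()))
    logger.info("expansion: %d instances", len(instances))

    counts = {m.id: 0 for m in motifs}
    for inst in instances:
        counts[inst.motif_id] += 1
    return AnalysisReport(counts, instances, matches, comp, options, stats)


def shortest_paths(network: SignedDigraph, source: str, target: str) -> list[list[str]]:
    """All directed minimum-edge-count paths from source to target.

    Returns ``[[source]]`` when source == target and ``[]`` when the
    target is unreachable.
    """
    for n in (source, target):
        if not network.has_node(n):
            raise KeyError(f"unknown node: {n!r}")
    g = network.to_nx()
    if source == target:
        return [[source]]
    try:
        return sorted(nx.all_shortest_paths(g, source, target))
    except nx.NetworkXNoPath:
        return []


def analyze_path(network: SignedDigraph, motifs: Sequence[Motif],
                 source: str, target: str,
                 options: AnalysisOptions | None = None) -> AnalysisReport:
    """Motif analysis restricted to the source -> target shortest path(s).

    The source and target are protected from elimination so the
    compressed matches can be located relative to them.  An instance is
    retained when its compressed-match node set lies within the node
    union of all shortest paths (``path_scope="union"``) or within a
    single shortest path (``path_scope="single"``).
    """
    options = options or AnalysisOptions()
    options = AnalysisOptions(**{**options.to_dict(),
                                 "protected": tuple(sorted({*options.protected,
                                                            source, target}))})
    paths = shortest_paths(network, source, target)
    if not paths:
        comp = compress(network, protected=options.protected,
                        linear_gate=options.linear_gate) if options.compression else \
            CompressedNetwork(network, frozenset(), network, frozenset(options.protected))
        return AnalysisReport(
            counts={m.id: 0 for m in motifs}, instances=[], matches=[],
            compression=comp, options=options,
            notice=f"target {target!r} unreachable from {source!r}",
        )

    report = analyze(network, motifs, options)
    if options.path_scope == "union":
        on_path = set().union(*paths)
        keep = [i for i in report.instances if set(i.match_nodes) <= on_path]
    elif options.path_scope == "single":
        path_sets = [set(p) for p in paths]
        keep = [i for i in report.instances
                if any(set(i.match_nodes) <= s for s in path_sets)]
    else:
        raise ValueError(f"unknown path_scope: {options.path_scope!r}")

    counts = {m.id: 0 for m in motifs}
    for inst in keep:
        counts[inst.motif_id] += 1
    return AnalysisReport(counts, keep, report.matches, report.compression,
                          options, report.stats)
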
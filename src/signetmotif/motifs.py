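"""Built-in regulatory motif library and isomorphism-aware registration.

The built-ins are the *compressed* forms of regulatory circuits whose
dynamic behaviour (oscillation, adaptation, bistability) has been
established by mathematical modelling: 1- and 2-node feedback loops
whose cascades have been collapsed, and 3-node adaptation circuits.
They ship as plain edge-list files plus a manifest so the set can be
extended or corrected without code changes; the library is validated to
be pairwise non-isomorphic on load.

Motifs flagged with a minimum size (``min_size=3``) only count as
realized instances when the expanded circuit spans at least that many
distinct molecules — e.g. a compressed negative self-loop stands for a
longer negative feedback cycle, and delayed negative feedback needs at
least three components to oscillate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .graph import SignedDigraph, read_network
from .isomorphism import MAX_MOTIF_SIZE, are_isomorphic, canonical_form

__all__ = ["Motif", "REGULATORY_CLASSES", "builtin_motifs", "add_motif", "load_motif_file"]

REGULATORY_CLASSES = ("oscillation", "adaptation", "bistable_switch", "custom")

#: aliases accepted wherever a class name is taken
_CLASS_ALIASES = {"bistable": "bistable_switch", "bistable-switch": "bistable_switch"}


@dataclass(frozen=True)
class Motif:
    """A small signed digraph with a regulatory-class annotation."""

    id: str
    regulatory_class: str
    graph: SignedDigraph
    min_size: int | None = None
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.regulatory_class not in REGULATORY_CLASSES:
            raise ValueError(f"unknown regulatory class: {self.regulatory_class!r}")
        if len(self.graph) > MAX_MOTIF_SIZE:
            raise ValueError(
                f"motif {self.id!r} has {len(self.graph)} nodes; "
                f"limit is {MAX_MOTIF_SIZE}"
            )

    @property
    def size(self) -> int:
        return len(self.graph)

    def canonical_form(self):
        return canonical_form(self.graph)


def _normalize_class(name: str) -> str:
    name = _CLASS_ALIASES.get(name, name)
    if name not in REGULATORY_CLASSES:
        raise ValueError(
            f"unknown regulatory class {name!r}; expected one of {REGULATORY_CLASSES}"
        )
    return name


def load_motif_file(path_or_stream, motif_id: str, regulatory_class: str = "custom",
                    min_size: int | None = None, source_note: str = "") -> Motif:
    """Read one motif from a 3-column edge list."""
    if hasattr(path_or_stream, "read"):
        g = read_network(path_or_stream, on_conflict="reject")
    else:
        with open(path_or_stream, encoding="utf-8") as fh:
            g = read_network(fh, on_conflict="reject")
    return Motif(motif_id, _normalize_class(regulatory_class), g, min_size, source_note)


def _load_builtins() -> list[Motif]:
    pkg = resources.files("signetmotif.data.motifs")
    manifest = json.loads(pkg.joinpath("manifest.json").read_text(encoding="utf-8"))
    motifs = []
    for entry in manifest["motifs"]:
        g = read_network(pkg.joinpath(entry["file"]).read_text(encoding="utf-8"),
                         on_conflict="reject")
        motifs.append(Motif(
            id=entry["id"],
            regulatory_class=entry["class"],
            graph=g,
            min_size=entry.get("min_size"),
            source_note=entry.get("note", ""),
        ))
    # library invariant: no two members isomorphic
    forms = [m.canonical_form() for m in motifs]
    for i in range(len(motifs)):
        for j in range(i + 1, len(motifs)):
            if motifs[i].size == motifs[j].size and forms[i] == forms[j]:
                raise ValueError(
                    f"built-in library contains isomorphic motifs: "
                    f"{motifs[i].id!r} and {motifs[j].id!r}"
                )
    return motifs


def builtin_motifs(class_filter: str | None = None) -> list[Motif]:
    """The built-in compressed motif set, optionally filtered by class.

    Guaranteed members include the negative-feedback 2-loop
    (oscillation), buffered-negative-feedback and incoherent-feedforward
    3-node circuits (adaptation), and the mutual-activation loop,
    mutual-inhibition loop and positive self-loop (bistable switch).
    """
    motifs = _load_builtins()
    if class_filter is None:
        return motifs
    cls = _normalize_class(class_filter)
    return [m for m in motifs if m.regulatory_class == cls]


def add_motif(lib: list[Motif], m: Motif) -> tuple[list[Motif], str | None]:
    """Append ``m`` unless isomorphic to an existing member.

    Returns the (possibly unchanged) library and the id of the
    isomorphic duplicate when rejection occurred, else ``None`` —
    mirroring the save-time isomorphism check of interactive motif
    designers.
    """
    for existing in lib:
        if existing.size == m.size and are_isomorphic(existing.graph, m.graph):
            return lib, existing.id
    return lib + [m], None
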
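# signetmotif

Regulatory motif detection in signed directed signaling networks.

Signaling networks are digraphs whose edges carry a sign: `+` for
activation, `-` for inhibition. Circuits with characteristic dynamics —
**oscillation** (delayed negative feedback), **adaptation** (buffered
negative feedback, incoherent feedforward) and **bistable switching**
(positive and double-negative feedback) — recur in such networks, but
their realizations are hidden inside cascades of intermediate
molecules: a chain `A → X → Y ⊣ B` has the same net regulatory effect
as a single inhibiting edge `A ⊣ B`, since the sign of a path is the
product of its edge signs. `signetmotif` finds these circuits in three
stages:

1. **Compression.** Intermediate nodes are iteratively eliminated,
   each replaced by bypass edges with sign
   σ(p,v)·σ(v,s), until a fixpoint — collapsing every linear cascade
   into a single signed interaction while preserving sign-dynamics.
2. **Search.** The compressed network is scanned for *induced*
   occurrences of compressed motif forms (1–3-node signed digraphs).
   The enumerator is ESU, which visits every weakly connected k-node
   set exactly once; candidate extension is pruned by a **path-tree**,
   a trie over the canonical labels of *all* isomorphs of all query
   motifs. A k×k signed adjacency matrix is linearised in the fixed
   order (1,1), (2,2), (2,1), (1,2), (3,3), (3,1), (3,2), (1,3), (2,3), …
   so the i-th discovered node contributes exactly the 2i−1 entries it
   reveals, and feasibility of a partial subgraph is one dictionary
   lookup. Reaching a leaf at depth k names the matched motif.
3. **Expansion.** Each compressed edge of a match is expanded back
   into the original-network paths that realize it (depth-first search
   constrained to eliminated internal nodes and matching sign
   product), and full-size motif instances are assembled by choosing
   one path per edge, with per-edge sign/length and total size
   annotations.

The built-in motif library ships the compressed non-isomorphic forms
of oscillation, adaptation and bistable-switch circuits established in
the mathematical-modelling literature; user motifs in the same
edge-list format can be added (isomorphism-checked) or searched alone.

## Worked example

A synthetic apoptosis-like cascade (`apoptosis_like.tsv`, 8 nodes / 11
edges): an executioner caspase hub (`CASP3s`) sits in three positive
feedback loops — via `CASP6s`/`CASP8s`, via `CASP9s`, and a
double-negative loop with the inhibitor `IAP`:

```text
SIG	+	CASP8s
CASP8s	+	CASP3s
CASP3s	+	CASP6s
CASP6s	+	CASP8s
CASP3s	+	CASP9s
CASP9s	+	CASP3s
IAP	-	CASP3s
CASP3s	-	IAP
SIG	+	BID
BID	+	CASP9s
CASP9s	+	CASP7s
```

```sh
signetmotif analyze --network apoptosis_like.tsv --motif-class bistable --out apop
```

prints

```text
bist_coupled_activation	2
bist_mutual_activation	0
bist_mutual_inhibition	0
bist_positive_selfloop	2
bist_toggle_selfactivation	0
total instances: 4
```

and writes `apop.instances.tsv`:

```text
motif_id	members	paths	signs	lengths	size
bist_coupled_activation	CASP3s;CASP6s;CASP8s;CASP9s	CASP3s>CASP6s>CASP8s>CASP3s;CASP3s>CASP9s;CASP9s>CASP3s	+;+;+	3;1;1	4
bist_coupled_activation	CASP3s;CASP9s;IAP	CASP3s>IAP>CASP3s;CASP3s>CASP9s;CASP9s>CASP3s	+;+;+	2;1;1	3
bist_positive_selfloop	CASP3s;CASP6s;CASP8s	CASP3s>CASP6s>CASP8s>CASP3s	+	3	3
bist_positive_selfloop	CASP3s;IAP	CASP3s>IAP>CASP3s	+	2	2
```

Reading the first row: compression collapsed the three-caspase loop
and the IAP loop onto a `CASP3s` self-activation, the search matched
the *coupled positive feedback* compressed form on
`{CASP3s, CASP9s}`, and expansion recovered the concrete circuit —
the self-loop realized by the length-3 path
`CASP3s>CASP6s>CASP8s>CASP3s` plus the direct mutual activation with
`CASP9s`, a 4-molecule bistable switch. All four instances are
positive feedback circuits containing the hub `CASP3s`, i.e. the
analysis pinpoints caspase-3 as the bistability-carrying node. The
four instances fall into two compressed bistable-switch types and
differ in size (2–4) even within one type.

Other entry points: `signetmotif analyze-path --source ... --target ...`
restricts reporting to instances on the shortest path(s) between two
nodes; `signetmotif compress` runs the reduction standalone;
`signetmotif motifs` lists the built-in library; `signetmotif gen`
emits synthetic fixture networks. The same functionality is available
as a library (`signetmotif.analyze`, `signetmotif.compress`, …).

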
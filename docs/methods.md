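# Methods

## Model

A signaling network is a signed digraph G = (V, E), E ⊆ V×V with
σ: E → {+1, −1} (activation/inhibition); at most one edge per ordered
pair, self-loops allowed. The net regulatory effect of a path is the
product of its edge signs. A *regulatory motif* is a small signed
digraph whose topology is sufficient (under suitable kinetics) for a
dynamic behaviour — oscillation, adaptation, or bistable switching.
Because cascades carry the same net effect as single edges, motifs are
represented in *compressed form* (1–3 nodes) and matched against a
compressed network; matches are then re-expanded into concrete
full-size circuits.

Two signed digraphs are isomorphic iff a node bijection maps edges
onto edges with equal direction *and sign*. Matching is **induced**: a
node set matches a query iff its full induced signed adjacency —
including edge absences — is isomorphic to the query. This is the
semantics ESU enumeration naturally produces; it differs from the
monomorphism default of general-purpose subgraph matchers, which would
also accept supergraphs of the pattern.

## Canonical labels and the path-tree

A k×k signed adjacency matrix is linearised by reading, for each node
i = 1..k: the diagonal entry (i,i), then row entries (i,1)..(i,i−1),
then column entries (1,i)..(i−1,i) — 2i−1 entries per node, k² total.
For k = 3 the order is (1,1), (2,2), (2,1), (1,2), (3,3), (3,1),
(3,2), (1,3), (2,3). The slice contributed by node i consists exactly
of the adjacency entries revealed when the i-th node joins a growing
subgraph, which is what makes the linearisation suitable for
incremental feasibility checks.

All k! labelled variants of each query motif are generated by
exhaustive permutation (yielding k!/|Aut| distinct labels) and loaded
into a trie keyed by the per-node fragments. Exhaustive
canonicalisation replaces a general canonical-labelling backend; it is
exact, dependency-free, and cheap at motif scale, which is why motif
size is capped at 6 (beyond 5 the k! generation dominates in any
case). The canonical form of a graph is its lexicographically smallest
label under the entry order 0 < +1 < −1 (any fixed total order works;
this one sorts sparse graphs early). Non-isomorphic graphs have
disjoint label sets, so trie leaves built from a non-isomorphic
library carry exactly one motif id; one trie is built per motif size
and the search runs once per size. Tries are rebuilt on demand —
construction costs k!·|motifs| label generations, microseconds at
motif scale — so no on-disk trie library is kept.

## Search

ESU enumeration: nodes receive integer labels in sorted-id order
(deterministic output); each node roots the enumeration of all
connected k-sets in which it is the smallest label, and extension
candidates are *exclusive* neighbors (not adjacent to the current
subgraph) with labels above the root's. Every weakly connected k-set
is visited exactly once, in a well-defined discovery order.
Connectivity is judged on the underlying undirected graph; self-loops
do not create adjacency but do appear on induced-matrix diagonals.

When node i is appended, its 2i−1 new induced-adjacency entries are
fed to the trie. A missing child prunes every extension of that
partial subgraph — sound because the first i² label entries of a k-set
depend only on the first i discovered nodes, so any completable
partial has its prefix in the trie. A leaf at depth k emits one match
per motif at that leaf. Instrumented counters (partials visited /
pruned) let tests assert that pruning never exceeds the unpruned
visit count.

On a fully connected N-node network the number of explored nodes is
bounded by Σ_k C(N,k)·k comparisons of 2k−1 entries each, i.e. time
O(N·2^N) in the worst case; on sparse signaling-like networks almost
all partials are pruned and observed scaling is near-linear in N (the
acceptance script measures a log-log slope ≈ 1.1 over 100–800 nodes).

## Compression

Node-based reduction to a fixpoint. A node v is eliminable iff all of:
v unprotected; no self-loop; in-degree ≥ 1 and out-degree ≥ 1; the
*linear-cascade gate* in-degree == 1 or out-degree == 1; and every
bypass edge (p, s, σ(p,v)·σ(v,s)) is sign-consistent with existing
edges and with the other bypasses of the same elimination. Elimination
removes v and adds the bypasses (deduplicated); nodes are scanned in
sorted-id order repeatedly until a pass eliminates nothing.

Design choices, each switchable:

* **Linear gate (default on).** Bounds bypass growth (≤ max(|P|,|S|)
  new edges) and captures exactly linear-cascade reduction — the
  behaviour that motivates compression. Disabling allows hub
  elimination with |P|·|S| bypasses.
* **Self-loop creation (default on).** Collapsing a 2-cycle through an
  eliminated node leaves a signed self-loop on the survivor; compressed
  motif forms include self-regulation, and expansion restores the true
  loop length.
* **Conflict handling.** A sign conflict aborts that node's
  elimination entirely (node retained); dropping either edge would
  destroy dynamics information.

Elimination order can select among equivalent reductions; the
sorted-order scan makes one deterministic choice, and correctness is
stated as soundness (every reduced edge realized by ≥ 1 original path
of equal sign through eliminated nodes, verified exhaustively in
tests) rather than as uniqueness of the reduction. The eliminability
rule here is a reconstruction of linear-cascade reduction from the
behaviour the method requires; it is idempotent and sound by
construction and test.

## Expansion and instances

A compressed edge (a, b, σ) is expanded by DFS into all simple paths
a → … → b with internal nodes ⊆ eliminated and sign product σ; the
direct edge qualifies as a length-1 path, and self-loop expansion
permits a = b with ≥ 1 internal eliminated node (recovering collapsed
feedback cycles). Paths are capped at **max_len = 8 edges** by default
— unbounded DFS over eliminated regions can blow up combinatorially,
and recovered regulatory cascades beyond ~8 steps are rarely
interpretable; configurable.

Instances are the Cartesian selection of one path per compressed
edge, filtered by:

* **Internal-node disjointness (default on).** Paths of one instance
  may not share internal nodes with each other or with the matched
  nodes — overlapping paths would not constitute a realizable circuit
  of the motif's topology. Switch: `allow_shared_internals`.
* **Minimum size.** Motifs flagged with min_size (the built-in pure
  negative-feedback forms, see below) drop instances spanning fewer
  distinct molecules.
* **Deduplication** by the sorted multiset of traversed edges, within
  a match and across matches, so identical circuits report once.
  Instance-level counting (every admissible path combination, not one
  representative per match) is used throughout.

## Built-in motif library

The compressed forms ship as edge-list data files plus a manifest, so
the set can be extended or corrected without code changes; pairwise
non-isomorphism is validated at load. The library is a curated core
set from the modelling literature: oscillation — negative 2-loop,
negative self-loop, amplified negative feedback, substrate depletion;
adaptation — buffered negative feedback and incoherent feedforward,
each in two sign placements; bistable switch — mutual activation,
mutual inhibition, positive self-loop, coupled positive feedback,
toggle with self-activation. Only the pure negative-feedback
oscillation forms carry the min_size = 3 flag: delayed negative
feedback requires at least three components to oscillate, whereas
positive feedback (mutual activation, autocatalysis) is bistable at
size 1–2, so flagging the positive self-loop would wrongly discard
2-node loops recovered from compression.

Node role marks follow the originating convention for signed edge
lists: a node with only inward edges is labelled "input", only outward
"output". This is inverted relative to the common signaling usage
(sources as inputs); both labels are exposed verbatim and downstream
code treats them as descriptive only.

## Path-constrained analysis

All minimum-edge-count directed source→target paths are computed
(networkx all-shortest-paths; the contract is *all* shortest paths,
which single-predecessor all-pairs reconstruction cannot deliver).
Source and target are protected from elimination. Whether an instance
"lies on the path" is genuinely ambiguous; both readings are exposed:
`path_scope="union"` (default) keeps instances whose compressed-match
nodes lie in the union of all shortest paths, `"single"` requires
containment in one shortest path. Unreachable pairs yield an empty
report with a notice, exit code 0.

## Synthetic data and what tests show

The generator samples m distinct ordered pairs uniformly (fixed m, so
tests control density exactly), signs negative independently with
probability 0.18 by default — the inhibitory fraction of large
integrated human pathway maps — and 0.2–0.3 in correctness tests to
exercise sign handling harder. Sizes follow the regime of curated
pathway collections: tens of nodes for oracle comparisons (the
subset×permutation oracle costs C(n,k)·k!), hundreds for scaling runs,
~1240/3144 for the compression-reduction figure. Random uniform
digraphs lack the hubs, degree correlations and modularity of real
signaling networks, so passing tests certify algorithmic correctness
(exact agreement with brute-force semantics, soundness, scaling), not
biological recall on real pathway data; the expansion combinatorics
on heavily compressed real hubs may also be richer than on uniform
graphs.

The oracle is structurally independent of the search: it enumerates
subsets and permutations over dense numpy adjacency, grouped by a
sorted per-node degree/sign profile for speed, and imports nothing
from the search or trie modules.

## Numerical and degenerate-input choices

Determinism everywhere: sorted node scans, sorted ESU candidate
order, lexicographic path order, sorted report keys — identical
inputs give byte-identical reports. Edge-list parsing accepts ASCII
`-` and Unicode `−`, emits ASCII; conflicting (both-sign) pairs are
dropped entirely by default (mirroring database-integration practice
of excluding inconsistent interactions) or rejected under the strict
policy; the 3-column format cannot express isolated nodes, so the
writer omits them with a warning hook. Empty motif lists, empty
graphs, k = 1 queries, and zero-match runs are all defined (empty
results, exit 0).

## Known limitations

* Motif size ≤ 6 (exhaustive canonicalisation); practically ≤ 5.
* Compression is not guaranteed to shrink search time: it can densify
  neighbourhoods (bypass fan-out), a trade-off inherent to reduction.
* No statistical significance testing against randomized networks;
  the tool matches user-chosen queries, it does not z-score them.
* No dynamical simulation: regulatory classes are taken from the
  modelling literature, and a topological match does not guarantee the
  behaviour under arbitrary kinetics.
* max_len truncates path recovery in deeply compressed regions.
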
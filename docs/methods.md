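# Methods

## Graph model

A structure is a simple undirected graph: no loops, no multi-edges,
unweighted.  Vertex indices are 0-based; molfile 1-based atom numbers are
converted at the parse boundary.  Explicit hydrogens present in a molfile
are kept as vertices — they are degree 1, acyclic by construction, and
removed from all further work by the biconnected preprocessing, so results
are unaffected and no silent structure editing takes place.  Bond orders
and element symbols are carried as labels only.  Edge indices follow input
order and are the coordinates of the GF(2) edge bit vectors (`EdgeBitSet`,
arbitrary-precision integers) in which all linear algebra is done.
Disconnected inputs are supported everywhere; every algorithm operates per
connected/biconnected component.

## Cycle membership (`ring_search`)

One iterative (stack-based, not recursive — molecular chains can exceed
default recursion depths) depth-first search finds the biconnected
components.  Single-edge components are bridges and acyclic; the rest are
ring systems.  A component with |E| = |V| has circuit rank 1 and is exactly
one elementary cycle ("simple": isolated or spiro ring); |E| > |V| marks a
fused or bridged system ("non-simple").  Membership is stored in bit sets
over the vertex and edge index spaces.  Simple components short-circuit
every downstream algorithm; walks for them start at the component's
minimum vertex index and proceed toward the smaller-indexed neighbour, a
deterministic orientation applied to all reported cycles.

## Initial cycle families (`short_cycles`)

The relevant-cycle machinery follows Vismara's compact construction.
Vertices are ranked by (degree ascending, index ascending); for each root
`r` a BFS runs in the subgraph induced by ranks ≤ rank(r), recording
distances, the full shortest-path DAG, path counts and S-sets (the set of
vertices on *any* shortest path, kept as bit masks).  Families are:

* odd `<r, y, z>`: edge y–z with d(y) = d(z), weight 2·d(y) + 1;
* even `<r, q, y, z>`: predecessors y, z of an apex q, weight 2·d(q);

both requiring S(r,y) ∩ S(r,z) = {r}.  Under that condition every pairing
of a shortest r–y path with a shortest r–z path is an elementary cycle, so
the family has exactly `paths(y) × paths(z)` members — countable without
generating walks — and each cycle of the graph belongs to exactly one
family (rooted at its rank-maximal vertex).

Because every cycle inside a non-simple biconnected component passes
through at least one vertex of degree > 2 (otherwise the component would
be that cycle alone), and such vertices are rank-maximal under the
degree-ascending order, roots of degree ≤ 2 can never produce a family
there.  The restricted mode therefore issues searches only from degree > 2
vertices; an instrumented counter (`InitialCycles.search_count`) exposes
how many were run (naphthalene: 2, anthracene: 4, versus one per vertex
unrestricted).  The whole-graph entry points do not restrict, which keeps
them valid for arbitrary graphs and provides an independent route for the
preprocessing-equivalence tests.

## Derived cycle sets

* **Relevance.**  A family is relevant iff its prototype is not a GF(2)
  sum of strictly shorter cycles, tested by Gaussian elimination against
  the span of all smaller-weight prototypes (which equals the span of all
  shorter cycles).  Same-weight prototypes are never tested against each
  other — interchangeable same-weight cycles are all relevant (barrelene's
  three hexagons being the canonical example).
* **MCB.**  Greedy over prototypes in non-decreasing weight with two
  shortcuts: a candidate whose edge set is not covered by the union of
  basis edges is independent without elimination, and the scan stops once
  the basis size reaches the circuit rank.  Ties are broken by the fixed
  family sort (weight, root, y, z, q), making the reported basis
  deterministic even where the MCB itself is not unique.
* **Essential cycles.**  Only single-member relevant families can be
  essential (a multi-member family's cycles are interchangeable across
  bases).  Such a prototype is essential iff it is independent of the span
  of every *other* relevant prototype of weight ≤ its own.  This decides
  the intersection of all MCBs entirely on prototypes, keeping the
  computation polynomial regardless of the relevant-cycle count.
* **Enumeration guard.**  `count_relevant` sums the family member products;
  enumeration (`relevant_cycles`, and the sets derived from it) refuses to
  materialise more than 1,000,000 cycles by default (configurable) —
  pathological inputs with millions of relevant cycles exist and the count
  is known before any walk is built.
* **Vertex-short / edge-short (LSSR).**  Every shortest cycle through a
  vertex or edge is relevant (a decomposition into strictly shorter cycles
  would contain a shorter cycle through that vertex/edge), so these sets
  are obtained by selecting per-vertex/per-edge minimum-weight cycles, with
  ties kept, from the enumerated relevant set.  No basis check is applied.
* **Triplet cycles.**  For each length-2 path u–v–w of the cyclic
  subgraph, the cycle formed by the two edges plus a lexicographically
  smallest shortest u–w path avoiding v; triples whose endpoints are
  disconnected without v contribute nothing.  The unique flag deduplicates
  by edge set.  This captures envelope rings (naphthalene's 10-cycle)
  while never producing a fused system's full perimeter when a shorter
  closure exists (anthracene's 14-cycle is absent).

## All elementary cycles (`all_cycles`)

Path-graph reduction.  The removal order is predetermined — degree
ascending, index ascending, fixed before reduction and never revised —
which allows directed indexing: each path edge is stored only at whichever
endpoint is removed first, so edges are deleted in bulk exactly once.
Interiors are vertex bit masks; two paths meeting at the reduced vertex
join iff their vertex sets share only that vertex (bit intersection plus
endpoint checks), and a join whose far endpoints coincide emits a cycle.
Cycles are deduplicated by edge set and reported in canonical orientation.

Feasibility is a degree threshold on the evolving path graph, checked
after each join: if any vertex's path-edge degree exceeds `max_degree`
(default 684, the value that covers ~99.99% of fused ring systems in large
compound collections; values up to 5000 were the tested range) the run
aborts with a deterministic error naming the vertex.  Unlike a timeout the
outcome is a property of the input, not of the machine or its load.

## Facade and CLI

`cycles(g, method)` applies the preprocessing (biconnected split, simple
short-circuit, degree>2 search restriction), dispatches per component,
maps indices back and merges — and is contractually equal to the direct
whole-graph computation for every method, which the test suite asserts on
every fixture.  `cycles_or_fallback` absorbs feasibility errors by
substituting an always-feasible set (recording `fallback_used`), the
pattern downstream consumers such as aromaticity perception need.  The CLI
emits line-delimited, key-sorted JSON (byte-stable for fixed input and
flags); data on stdout, diagnostics on stderr; exit 1 for parse errors,
2 for feasibility errors without a fallback.

## Fixtures, oracles and what the tests show

All fixtures are generated programmatically: classical small ring systems
(barrelene, naphthalene, anthracene, azulene, cubane, biphenyl,
propan-2-ylbenzene, cyclohexane, spiro[4.5]decane) plus a C60 fullerene
built as the truncated icosahedron from icosahedron coordinates.  Random
test graphs are seeded spanning trees with a bounded number of extra
chords (circuit rank ≤ 5 and ≤ 12 vertices), which matches the sparse,
small-ring character of drug-like molecules; property tests run the
production algorithms against deliberately naive oracles (DFS cycle
enumeration anchored at minimum vertices; all minimum bases by exhaustive
weight-stratified subset search) that share no code with them.  Those
sizes keep the exhaustive oracles exact; they do not exercise
macrocycles, very high-rank cages beyond C60, or the >5000-degree regime
of the feasibility threshold, so conclusions about such structures rest on
the algorithms' invariants rather than on direct test evidence.

## Numerical and degenerate-input choices

* Empty and acyclic graphs return empty cycle sets and rank-0 bases
  everywhere; no special casing is required by callers.
* All tie-breaks (vertex ranking, family sort, path reconstruction,
  removal order, walk orientation) are by ascending index, so every
  reported object is reproducible across runs and platforms.
* GF(2) elimination keeps rows keyed by pivot bit; candidate reduction is
  O(rank) big-integer XORs, adequate for molecule-scale edge counts.
* The degree threshold is checked after each join (the bookkeeping point
  is not externally specified); anyone comparing feasibility sets against
  other implementations should expect boundary cases to differ.

## Known limitations

* V3000 molfiles, kekulisation, valence checking and aromaticity are out
  of scope; SMILES input requires RDKit and is the only chemistry
  dependency, kept behind a narrow optional interface.
* Weighted MCBs and the original Kirchhoff-fundamental "SSSR" definition
  are not provided (the latter is computationally intractable and of
  historical interest only).
* `relevant_cycles` is exponential in the worst case by nature; the guard
  makes this an explicit, catchable condition rather than a hang.
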
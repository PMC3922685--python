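# ringkit

Ring perception for chemical structures: fast, deterministic computation of
the cycle sets a cheminformatics toolkit needs — which atoms and bonds are
in a ring, a minimum cycle basis, the uniquely defined relevant and
essential cycles, every elementary cycle, and the auxiliary vertex-short,
edge-short (LSSR) and triplet sets.

A molecule is modelled as a simple undirected graph *G = (V, E)* (atoms are
vertices, bonds unweighted edges; element symbols and bond orders are
carried but never consulted).  A chemical ring is an elementary cycle: a
closed walk with no repeated vertex, every vertex of degree 2 within the
cycle.  The key quantities:

- **Circuit rank** `|E| − |V| + |ConnComp(G)|` — the number of independent
  rings, and the size of every minimum cycle basis.
- **Minimum cycle basis (MCB)** — a minimum-total-weight set of cycles
  whose GF(2) (XOR over edge sets) combinations generate every cycle.
  Generally non-unique; historically conflated with "SSSR".
- **Relevant cycles** — the union of *all* MCBs: unique, but potentially
  exponential in number.  **Essential cycles** — the intersection of all
  MCBs: unique, always polynomial, possibly empty.
- **All elementary cycles** — enumerated directly by path-graph reduction,
  with feasibility decided by a machine-independent *degree threshold*
  (default 684) on the evolving path graph instead of a wall-clock timeout,
  so the same input always succeeds or fails identically.

Cycle membership and ring-system partitioning come from a single
depth-first search for biconnected components: a component with
|E| = |V| *is* one ring (isolated/spiro) and short-circuits every
algorithm; only fused/bridged systems (|E| > |V|) do real work, and
shortest-path searches inside them are needed only from atoms of degree
greater than 2.

## Worked example

Barrelene (bicyclo[2.2.2]octa-2,5,7-triene): two bridgehead carbons joined
by three two-carbon bridges — 8 atoms, 9 bonds, circuit rank 2.

```python
>>> import ringkit as rk
>>> g = rk.build_graph(8, [(0, 2), (2, 3), (3, 1), (0, 4), (4, 5), (5, 1),
...                        (0, 6), (6, 7), (7, 1)])
>>> rk.circuit_rank(g)
2
>>> [c.weight for c in rk.minimum_cycle_basis(g).cycles]
[6, 6]
>>> len(rk.relevant_cycles(g).cycles)
3
>>> len(rk.essential_cycles(g).cycles)
0
```

Barrelene is "two rings" by nomenclature (rank 2) but its three hexagons
are perfectly symmetric: each pair forms an MCB, so all three are relevant
and — counter-intuitively — none is essential.

The same from the shell, reading an SDF:

```sh
$ ringkit --set relevant --in tests/data/barrelene.sdf
{"circuit_rank": 2, "cycles": [{"atoms": [0, 2, 3, 1, 5, 4, 0], "size": 6},
 {"atoms": [0, 2, 3, 1, 7, 6, 0], "size": 6},
 {"atoms": [0, 4, 5, 1, 7, 6, 0], "size": 6}],
 "cyclic_atoms": [0, 1, 2, 3, 4, 5, 6, 7],
 "cyclic_bonds": [0, 1, 2, 3, 4, 5, 6, 7, 8],
 "id": "barrelene", "n_atoms": 8, "n_bonds": 9, "set": "relevant"}
```

(one JSON object per record; shown wrapped).  `--set` accepts `mcb`,
`relevant`, `essential`, `all`, `vertex-short`, `edge-short`, `triplet`;
`--fallback mcb` substitutes a feasible set when `all`/`relevant` trip
their guards; `--count-only` reports relevant-cycle counts without
generating a single walk.

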
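# bicomm — community detection in bipartite networks

Many networked systems are *bipartite* (two-mode): genes tied to samples,
people to committees, artists to teams, hosts to parasites.  Edges run only
between the two node sets, so one-mode community detection cannot be applied
directly, and the common workarounds each lose something.  `bicomm` is a
toolkit for researchers who need the community structure of **both** modes
of a bipartite network, built around two strategies:

* **Dual-projection** — project the binary biadjacency matrix *B* into both
  weighted one-mode networks, *BBᵀ* (shared-neighbor counts among mode-1
  nodes) and *BᵀB*, detect communities in each projection separately, and
  then match the two solutions across modes so as to maximize Barber's
  bipartite modularity

  *Q_B = (1/m) Σ_{ij} (B_ij − k_i d_j / m) δ(g_i, g_j)*,

  where *m* is the edge count, *k_i*, *d_j* the mode-1/mode-2 degrees and
  δ fires when node *i* (mode 1) and node *j* (mode 2) carry the same joint
  community label.

* **Combined** (baseline) — embed *B* in the block off-diagonal meta-matrix
  `[[0, B], [Bᵀ, 0]]` and detect communities of both modes simultaneously
  with a one-mode algorithm.

Detection in both pipelines uses the walktrap algorithm (random walks of 4
steps, weighted; the reference igraph implementation behind a pluggable
interface), cutting the agglomerative dendrogram at maximum Newman
modularity.  The combined approach is known to break down when the two
modes contain *different numbers* of communities, because community
computations for one mode are entangled with the other; the dual-projection
approach avoids that coupling.  The package ships planted-partition
bipartite generators and an NMI-based Monte-Carlo harness to quantify
exactly this effect.

## Worked example

```sh
python examples/detect_communities.py
```

builds a 6-artist × 4-team affiliation network with two planted groups and
one cross-cutting tie, and prints:

```
dual-projection:
  artist communities: [0, 0, 0, 1, 1, 1]
  team communities:   [0, 0, 1, 1]
  Barber Q_B = 0.413  (joint communities: 2)
combined:
  artist communities: [0, 0, 0, 1, 1, 1]
  team communities:   [0, 0, 1, 1]
  Barber Q_B = 0.413  (joint communities: 2)
```

Both pipelines recover the two planted groups; each joint community pairs
one artist community with one team community, and Q_B ≈ 0.41 says the
matched solution concentrates far more ties within communities than the
degree-preserving chance baseline (Q_B = 0).

The other examples generate a benchmark graph
(`examples/generate_benchmark.py`) and run a 50-replicate method comparison
(`examples/compare_methods.py`), which prints

```
unequal_3_2 dual: NMI = 0.825 +/- 0.095 (50 reps)
unequal_3_2 combined: NMI = 0.637 +/- 0.093 (50 reps)
dual-projection advantage: +0.188 mean NMI
```

— with three communities in mode 1 and two in mode 2, the dual-projection
approach recovers the planted structure substantially better than the
combined baseline.

A thin CLI mirrors the library (`bicomm generate`, `bicomm detect`,
`bicomm simulate`); run `bicomm --help`.

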
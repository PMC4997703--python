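# encentra

Ensemble centrality ranking of essential proteins from protein–protein
interaction (PPI) networks and gene expression data.

## The problem

Knocking out an essential gene kills the organism, so ranking proteins by
predicted essentiality guides target selection and minimal-genome studies.
The classic computational shortcut is the centrality–lethality rule: in a
PPI network *G(V, E)*, highly central proteins are more often essential.
In practice plain centrality measures have low accuracy, partly because
interactomes are noisy, and partly because not every interaction
contributes equally to essentiality — interactions between two proteins
that are strongly **co-expressed** matter more.

`encentra` implements an ensemble framework that exploits this. For each
edge *(u, v)* the Pearson correlation coefficient (PCC) of the two
proteins' expression profiles is the edge's co-expression weight. The
pipeline then:

1. **Data partition** — generate *m* networks from the original one by
   deleting, at each threshold *thr₁ < … < thrₘ*, the edges whose weight
   falls below it. Two strategies: *absolute* (keep |PCC| ≥ thr, default
   thresholds 0, 0.1, …, 0.8, 0.9, 0.91, …, 0.95, *m* = 15) and *uniform*
   (signed PCC ≥ thr, default −0.7, −0.6, …, 0.8, 0.9, 0.91, 0.92,
   *m* = 19). Nodes are never removed.
2. **Grading** — score every protein on every member network with one
   base centrality measure: degree (DC), betweenness (BC), closeness
   (CC), eigenvector (EC) or subgraph (SC) centrality. Per network,
   zero-degree proteins are set to 0 and scores are divided by their
   maximum, so *s(j, i) ∈ [0, 1]*.
3. **Integrating** — weighted voting:
   *fs(j) = Σᵢ s(j, i) · wᵢ* with a non-decreasing weight vector. The
   default is *dominant weighting* w4 = (1, 2, 3, 5, 8, …, 987): each
   weight is the sum of its two predecessors, so the sparse
   high-co-expression networks dominate while the original network
   (weight 1) is never discarded.
4. **Ranking** — sort by *fs* descending; ties break deterministically
   by identifier (a seeded random mode exists).

The package also provides the evaluation battery (top-*n* essential
counts, pairwise/joint top-*n* overlaps, union-of-top-*n* score
correlation, low-degree analysis), the two single-network baselines
(centrality on the |PCC| ≥ 0.75 filtered network; DC/EC/SC on the
PCC-weighted network), and a seeded synthetic benchmark generator with
planted co-expressed essential cliques and decoy hubs.

## Worked example

```python
from encentra import (SyntheticSpec, generate, run_ensemble, rank,
                      degree_centrality, essential_in_top)

net, expr, essential = generate(SyntheticSpec(seed=1))   # 300 proteins
ensemble = run_ensemble(net, expr, measure="DC", strategy="absolute")
plain = rank(degree_centrality(net))
print(essential_in_top(ensemble, essential, 60))  # -> 60
print(essential_in_top(plain, essential, 60))     # -> 0
```

The benchmark plants 60 essential proteins in 12 co-expressed cliques
and 20 high-degree "decoy hubs" whose neighbours are not co-expressed.
Plain degree centrality ranks the decoys first and finds 0 of the 60
essentials in its top 60; the ensemble (EnDC-a, dominant weighting)
finds all 60, because only the clique edges survive the high
co-expression thresholds that carry the large voting weights. The
scripts in `examples/` walk through this comparison, the co-expression
weight analysis behind the thresholds, and the voting-weight/baseline
comparisons, printing the numbers above.

Real data are read from generic text formats: a two-column edge list
(`read_network`), a TSV expression matrix (`read_expression`, proteins
without expression are zero-filled by `attach_missing`) and a
one-id-per-line essential list (`read_essential_set`). A thin CLI mirrors
the workflow: `encentra run`, `encentra synth`, `encentra evaluate`.

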
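# Methods

## Model and assumptions

The framework treats essential-protein prediction as an ensemble of one
base learner (a centrality measure) applied to a family of views of the
interactome. The two assumptions are: (a) essential proteins tend to be
co-expressed with some of their interaction partners, and (b)
interactions between two highly co-expressed proteins contribute more to
their endpoints' essentiality than other interactions. Under these
assumptions, filtering the network at increasing co-expression
thresholds concentrates signal: in the high-threshold members, most
surviving edges join co-expressed (disproportionately essential)
proteins, so centrality computed there is a sharper essentiality signal
than centrality on the full, noisy network. Weighted voting combines the
views without throwing the original network away.

Nothing in the method estimates parameters from labels: the essential
reference list is used only for evaluation.

## Pipeline details and conventions

**Co-expression weights.** The sample Pearson correlation of the two
endpoint expression profiles (≥ 2 samples required). Proteins without
expression data get constant-zero profiles, whose correlations are
defined as 0 — "no co-expression evidence" — so their edges survive only
at thresholds ≤ 0. Node strength is the *signed* sum of incident edge
weights; an `abs`-strength variant was considered and rejected because
the PCC-weighted network is defined with raw PCC values (strong negative
co-expression is rare in the data this emulates, so the choice is mostly
cosmetic, but it is exposed nowhere to keep the surface small).

**Thresholding.** Retention is `weight >= thr` (uniform) or
`|weight| >= thr` (absolute); deletion happens only strictly below the
threshold. This makes the threshold-0 member of the absolute schedule
identical to the original network — the anchor the weight-1 vote relies
on — and makes member edge sets nested by construction. Nodes are kept
(degree may drop to 0), which keeps the score matrix rectangular across
members. Default schedules: absolute 0, 0.1, …, 0.8, 0.9, 0.91, …, 0.95
(m = 15); uniform −0.7, …, 0.8, 0.9, 0.91, 0.92 (m = 19). Both are
user-overridable; the right ladder is organism- and dataset-dependent.

**Centrality conventions.** DC is the raw degree. BC is the unnormalized
unordered-pair betweenness; only the induced ranking matters and
per-member max-normalization removes scale anyway. CC uses
Wasserman–Faust component scaling so small-component nodes are not
inflated; isolated nodes score 0. EC is the Perron eigenvector of the
connected component with the largest spectral radius (symmetric
eigendecomposition, unit Euclidean norm, zeros outside the component);
a tie between components is broken toward the component containing the
lexicographically smallest node. SC is the diagonal of exp(A) via
eigendecomposition, Σⱼ φⱼ(v)² e^{λⱼ}. All measures are exact and
deterministic — no sampled betweenness, no iterative tolerance.

**Zero-degree mask, then normalization.** In each member network, any
protein of degree 0 is scored 0 for *all* measures before the column is
divided by its maximum. Without the mask, SC would give every
disconnected protein a floor of exp(0) = 1, which after weighting would
swamp the vote in sparse members. All-zero columns (edgeless members)
are left as zeros rather than 0/0.

**Voting weights.** Four named 15-element vectors: w1 all ones; w2 =
1…15 (gradual advance); w3 = eight 1s then 8…13, 15 (prior-guided
advance: flat through the low thresholds where measures barely change);
w4 = 1, 2, 3, 5, 8, …, 987 (dominant weighting, each weight the sum of
its two predecessors). The uniform-strategy default keeps weight 1 on
the eight negative thresholds and then follows the same ramp. Weights
must be positive; a decreasing step only warns, because plateaus are
legitimate but decreases contradict assumption (b). Final scores are
linear in the weights, so rankings are invariant under positive
rescaling.

**Ranking.** Descending by final score; exact ties break by ascending
identifier. That determinism is a deliberate departure from leaving tied
(typically zero-score) proteins in arbitrary order: reruns and tests
must reproduce. A seeded random tie-break mode preserves the
"ties are arbitrary" semantics when wanted. Evaluation functions warn
when a tie spans the top-*n* boundary, since membership is then decided
by the tie rule.

**Baselines.** PCC-threshold: the base measure on the single
|PCC| ≥ 0.75 network (0.75 is where essential/nonessential weight
distributions visibly separate), zero-degree masked. PCC-weighted:
DC = node strength, EC/SC on the signed weighted adjacency; BC and CC
are refused because shortest-path measures need positive weights.

**Low-degree analysis.** Degrees and node strengths always refer to the
original network, never a filtered member: the point of the report is to
contrast ensemble picks with the original network's hubs.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes,
not any particular interactome. Defaults: 300 proteins, 36 expression
samples, 12 planted essential modules of 5 proteins (cliques), 20
nonessential decoy hubs wired to 25 random non-module partners each, and
an Erdős–Rényi background of mean degree 4 over the non-module proteins.
Module members share a latent standard-normal profile plus Gaussian
noise with s.d. σ = √(1/ρ − 1) so the expected within-module PCC is
ρ = 0.9; all other proteins have i.i.d. standard-normal expression. One
PCG64 stream per call, consumed topology-first, makes output
bit-identical under a fixed seed.

Cliques (rather than merely dense subgraphs) make the planted structure
unambiguous; decoy hubs exist specifically to decouple degree from
essentiality, the failure mode the ensemble corrects. What the benchmark
does **not** capture: scale-free degree distributions, overlapping
complexes, essential proteins with *low* co-expression (present in real
data and the main cause of the method's accuracy decay at large *n*),
correlated noise across samples, and false-negative edges. On these
fixtures the class separation is far cleaner than in real interactomes —
the KS distance between essential and nonessential weight distributions
is ≈ 1, and the ensemble can recover every planted essential — so
passing tests demonstrate the machinery's correctness and the intended
qualitative behaviour (ensemble ≫ base, low-degree recovery, higher
inter-method agreement), not field accuracy.

## Problem sizes and numerics

Tests and the acceptance script run the full pipeline on 300-protein
benchmarks (10 seeds) and verify centrality implementations against
brute-force oracles on 200 random graphs of ≤ 7 nodes; the whole suite
completes in seconds. Dense eigendecomposition is used for EC/SC, which
is exact and comfortable to a few thousand nodes; yeast-scale networks
(~6 000 proteins) fit, but very large interactomes would want a sparse
eigensolver. Correlations are computed by centring and normalising each
expression row once, making each edge weight a single dot product,
clamped to [−1, 1]. The EC component tie tolerance is 1e−12 on the
spectral radius. Ranking round-trips through TSV use the shortest
exact float representation.

## Known limitations

* Identifier harmonisation between interaction and expression data is
  assumed done; no ORF/gene/UniProt mapping is attempted.
* The absolute-strategy default schedule and w4 encode a specific
  prior (dense sampling of the 0.9–0.95 tail); other organisms or
  expression compendia may need a different ladder, which is why both
  are plain arguments.
* KS p-values are not computed, only the statistic; significance
  testing belongs to a reporting layer with multiple-testing context.
* Boosting-style sequential reweighting and combining *different*
  centrality measures into one vote are out of scope: each ensemble uses
  one base measure.
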
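# Methods

This note documents the models and procedures implemented in `adrnet`, the
defaults chosen where the design was open, and what the synthetic benchmark
does and does not demonstrate.

## Interactome handling

The interactome is read as an undirected edge list (2-column TSV or SIF;
relations in SIF are ignored).  Accessions are opaque, case-sensitive
strings — no identifier mapping is attempted.  Self-loops are dropped with
a warning, duplicate undirected edges merged, and by default the graph is
restricted to its largest connected component, because diffusion scores,
diffusion-state distances and panel distances are undefined or degenerate
across components.  Degree centrality is normalized by `n−1` and
betweenness is the endpoint-excluding Brandes variant normalized by
`(n−1)(n−2)/2`, so graphs of different sizes are comparable; the clustering
coefficient of a degree-<2 node is defined as 0.

## Diffusion score

Seed-based scoring uses random walk with restart: the fixed point of
`s = α·W·s + (1−α)·e` with `W` the column-normalized adjacency and `e`
uniform over seeds.  This is a standard, well-defined member of the
message-passing/diffusion family used for gene–disease prioritization; the
restart parameter defaults to `α = 0.5` and is config-exposed, as is the
convergence tolerance (1e−6 on the max per-node change, 1000 iteration
cap; non-convergence is flagged, not fatal).  On a graph with no isolated
node the scores sum to 1, which the tests assert.  Seeds missing from the
graph are dropped with a warning — failing the whole run because one
accession is unmapped would be worse in practice — and an error is raised
only when no seed maps.

## Module partitions and the %-of-clusters features

Two partitions capture the "ADR module" idea:

* **DSD + spectral.**  `He(u)` is the vector of expected visit counts of a
  simple random walk from `u` over steps 0..t (t = 5 by default; the finite
  walk rather than the convergent infinite form keeps the computation a
  handful of dense matrix products and is config-exposed).  `DSD(u,v)` is
  the L1 distance between the two profiles.  Spectral clustering is applied
  to the affinity `exp(−d/σ)` with σ the median off-diagonal distance.  The
  number of clusters defaults to `round(n/15)`; published pipelines built
  on this metric add a merging step with densely connected bipartite
  subgraphs, which is deliberately not reproduced — the per-protein feature
  only needs a DSD-based partition.
* **Louvain** greedy modularity maximization (resolution 1.0), with module
  ids made deterministic by sorting communities by their smallest member.

The per-protein feature is `100 · |modules occupied by seeds ∪ {v}| /
|seeds ∪ {v}|`.  The literature describing these features reports only the
direction (ADR-associated proteins occupy fewer modules) without a
per-protein formula; this operationalization is the package's own choice
and reproduces that direction on the synthetic benchmark (planted members
score lower than matched background, one-sided rank test).

## Enrichment and function conservation index

GO terms carried by the top 100 diffusion-ranked proteins (count
config-exposed) are tested against the whole graph as background with a
one-sided Fisher exact test, corrected by Benjamini–Hochberg at α = 0.05.
The conservation index compares the protein's indicator vector over the
enriched universe *E* with the all-ones vector: `1 − Hamming/|E| =
|GO(v) ∩ E|/|E|`.  The denominator is |E| — not the whole GO vocabulary —
because the index is anchored so that full overlap yields exactly 1.  An
empty *E* yields index 0 with a warning.  Annotations are used as given; no
propagation to GO ancestors is performed.

## Safety-panel distance

Hop distances from the protein to every reachable panel member (self
included at 0) are summarized by their first quartile, computed with linear
interpolation between order statistics (the common "type 7" convention,
pinned for bit-stability).  If no panel member is reachable the node count
of the graph is returned as a sentinel — an impossible hop count that
preserves the "far = large" ordering.

## Dataset construction

ADRs with fewer than 10 associated proteins are dropped (config-exposed;
chosen as a round default for "well-characterized"), and a system-organ-class
(SOC) qualifies for SOC-level modeling when it retains at least 5 ADRs; SOC
pseudo-ADRs pool the deduplicated union of member proteins.  DIAMOnD
expansion scores each candidate by the hypergeometric tail probability of
its connectivity to the current module, `P(X ≥ ks)` with `X ~
Hypergeom(N, s0, k)`; the added node minimizes p with ties broken by lower
degree, then accession.  Because floating-point tails can misorder
mathematically tied candidates, the near-minimal set is re-ranked with
exact rational arithmetic before the tie-break applies.  The DIAMOnD
*score* is defined as `1 − p`, giving the 0–1 "higher is closer" scale the
0.6/0.7/0.8/0.9 threshold menu implies.  Positives are seeds plus
above-threshold expansion; negatives are a seeded uniform sample from the
remaining below-threshold nodes of the whole graph (`round(ratio ×
positives)` of them, ratio menu 1:1/1:1.5/1:3/1:5).  The full threshold ×
ratio grid is enumerated as configured; no particular grid size is
hardcoded.

## Classifiers

Features are standardized to zero mean and unit variance with
training-fold statistics only (SVM and the network need comparable
scales).  Grid search under stratified 5-fold CV selects hyperparameters by
mean ROC AUC; the winner is refit on all rows.  Defaults: SVM — RBF kernel,
C ∈ {0.1, 1, 10, 100}, γ ∈ {1e−3 … 1}, posteriors via sigmoid calibration
fitted on training folds; RF — 500 trees, max_features ∈ {2, 3, 8}, depth
∈ {3, 5, 10, none}; NN — SGD-trained feed-forward net with ReLU hidden
layers and a logistic output, learning rate ∈ {1e−3, 1e−2, 1e−1}, epochs ∈
{50, 200}, one or two hidden layers of 8 or 16 units.  A reduced grid
(`SMALL_GRIDS`) with the same families but fewer points is used by the
benchmark protocol.  All randomness is keyed to one seed, making CV reports
bit-reproducible.

Metrics (ACC/PREC/REC/MCC/NPV/PPV, ROC AUC, AUPRC) come from the confusion
matrix and the positive-class probability; zero-denominator ratios are
reported as 0 with a warning flag rather than NaN.

## Voting

The consensus score uses the posterior of the *predicted* class (hence
pᵢ ≥ 0.5); `c = Σ pᵢ·classᵢ` lies in [−3, 3].  A score of exactly 0 maps
to the negative class — no liability flag without positive evidence.  The
red flag returns the minority class of a 2–1 split and the unanimous class
otherwise (the rule is only defined by a dissenting opinion; unanimity has
no dissenter to promote).

## Synthetic benchmark

The generator emulates the structural assumptions, not any real dataset:

* Barabási–Albert preferential attachment (n = 1000, m = 3) for the
  heavy-tailed interactome; the convention (growth from m unconnected
  nodes) is pinned so the edge count `m(n−m)` is testable.
* A 30-node connected module grown by seeded BFS, densified by adding each
  missing internal edge with probability 0.3 — enough local cohesion to be
  detectable without making the module a clique.  Half the module (rounded
  up) is the known seed set; the rest are held-out positives.
* Five "module" GO terms annotate planted nodes with probability 0.8 and
  background nodes at 0.1 (0.8 gives reliable but imperfect enrichment);
  45 further terms are background noise.
* A 48-member panel sampled with weight `2^(−d)` in the hop distance *d*
  to the module, so planted proteins sit measurably closer to it.

The benchmark protocol (`adrnet.evaluation`) trains on a stratified 70%
split (reduced grids, threshold 0.9, ratio 1:1) and evaluates on the held
30%, averaging over five seeds; directional checks compare 30 planted
members against degree-matched background nodes with one-sided
Mann–Whitney tests.  Problem sizes were chosen so a full five-seed study
completes in about two minutes on a single CPU.

What passing shows: the features carry the intended directional signal and
the learning/voting machinery recovers a planted module far above chance.
What it does not show: performance on real interactomes, whose degree
correlations, annotation biases, and literature-driven seed ascertainment
the generator does not model; nor calibration of posteriors on real ADR
label noise.

## Known limitations

* The diffusion scorer is one member of the family used in practice;
  ensemble message-passing variants are not reproduced.
* DSD matrices are dense (O(n²) memory), practical to ~10⁴ nodes.
* Louvain partitions depend on the seed; determinism is per-seed, not
  canonical.
* SOC-level models inherit whatever PT→SOC mapping the association table
  provides; no MedDRA hierarchy is consulted.
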
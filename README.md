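# adrnet

Network-based prediction of adverse-drug-reaction (ADR) liability for
protein targets.

Unexpected ADRs are a major cause of late-stage attrition in drug discovery.
Rather than asking which reactions a *drug* may cause, `adrnet` takes a
**target-centric** view: given a protein, how likely is its modulation to
elicit a specific adverse reaction?  The premise is guilt-by-association on
the interactome — proteins associated with the same ADR tend to sit close
together in the protein–protein interaction network, forming ADR modules.

## Method

For each protein *v* in an undirected interactome *G* and each ADR with a
curated seed set *S* of associated proteins, eight network features are
computed:

1. **Diffusion score** — the stationary value of a random walk with restart,
   the fixed point of `s = α·W·s + (1−α)·e`, where `W` is the
   column-normalized adjacency of *G*, `e` the uniform restart distribution
   on *S*, and `α = 0.5`.
2. **Degree centrality** — `deg(v) / (n−1)`.
3. **Betweenness centrality** — normalized Brandes betweenness.
4. **Clustering coefficient** — `triangles(v) / (deg(v)·(deg(v)−1)/2)`.
5. **% of clusters (DSD)** — partition *G* by spectral clustering of the
   diffusion-state-distance matrix (L1 distance between expected
   random-walk visit profiles); the feature is
   `100·|modules(S ∪ {v})| / |S ∪ {v}|`: low when *v* co-clusters with the
   seeds.
6. **% of clusters (Louvain)** — same statistic on a Louvain modularity
   partition.
7. **Function conservation index** — GO terms enriched among the
   top-diffusing proteins (one-sided Fisher exact test, Benjamini–Hochberg
   at 0.05) form a universe *E*; the index is `|GO(v) ∩ E| / |E|`, with 1
   meaning *v* carries every enriched function.
8. **Safety-panel distance** — the first quartile of hop distances from *v*
   to a panel of "very important targets" used in preclinical safety
   pharmacology.

Because curated positives per ADR are few, the positive class is augmented
by DIAMOnD-style module expansion: candidates are iteratively ranked by the
hypergeometric significance of their connectivity to the growing module,
and those with score `1 − p` above a threshold (0.6–0.9 menu) join the
positives.  Negatives are sampled from the rest of the network at
configurable imbalance ratios (1:1 to 1:5).  An RBF-kernel SVM, a random
forest, and a feed-forward neural network (SGD, ReLU hidden layers,
logistic output) are each tuned by grid search under stratified 5-fold
cross-validation, and their outputs are combined per protein by three
voting rules:

- **jury vote** — majority class;
- **consensus** — `c = Σᵢ pᵢ·classᵢ` over the three classifiers, with `pᵢ`
  the posterior of the predicted class; positive iff `c > 0`;
- **red flag** — the dissenting class on a 2–1 split.

## Worked example

The package ships a synthetic-data generator that emulates the study
conditions: a 1000-node preferential-attachment interactome, a planted and
locally densified 30-protein ADR module (half of it the known seed set,
half held out), GO terms enriched on the module, and a 48-member safety
panel placed preferentially near it.

```python
from adrnet.evaluation import run_fixture_study

result, fixture, ctx = run_fixture_study(seed=1)
print(f"dataset rows: {result.n_rows}")
for kind in ("SVM", "RF", "NN"):
    rep = result.test_metrics[kind]
    print(f"{kind:9s} cv_auc={result.cv_mean_roc_auc[kind]:.3f} "
          f"test acc={rep.acc:.3f} mcc={rep.mcc:.3f}")
for rule in ("jury", "consensus", "red_flag"):
    rep = result.test_metrics[rule]
    print(f"{rule:9s} test acc={rep.acc:.3f} mcc={rep.mcc:.3f}")
```

prints

```
dataset rows: 284
SVM       cv_auc=0.847 test acc=0.744 mcc=0.493
RF        cv_auc=0.868 test acc=0.756 mcc=0.515
NN        cv_auc=0.847 test acc=0.721 mcc=0.444
jury      test acc=0.733 mcc=0.468
consensus test acc=0.733 mcc=0.468
red_flag  test acc=0.756 mcc=0.515
```

The 284 rows are the DIAMOnD-augmented positives (seeds plus expansion at
threshold 0.9) and an equal number of sampled negatives; `cv_auc` is the
mean 5-fold cross-validated ROC AUC inside the 70% training split, and the
remaining columns are scored on the held-out 30%.  The random forest
separates module members from background well (AUC ≈ 0.87), and the voting
rules track the best single classifier.

The same pipeline is available from the shell:

```bash
adrnet simulate -o fixture/ --seed 5
adrnet train -c run.yaml -o models/ --seed 5
adrnet predict -m models/ -c run.yaml -p proteins.txt \
    -a "synthetic module toxicity" -o report.tsv
```

where `run.yaml` points at the network, association, annotation and panel
files.  The prediction report contains, per (protein, ADR), the class and
posterior of each classifier plus the jury, consensus and red-flag
outcomes; proteins absent from the network are flagged `NOT_IN_NETWORK`.

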
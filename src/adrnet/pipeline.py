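"""End-to-end orchestration: features for every node, labeled datasets,
training of the three classifier families, and voted predictions.

This module is the programmatic counterpart of the command-line interface;
the acceptance script and the CLI both drive the pipeline through it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clustering, features, graphio, learn, propagation, voting
from .dataset import (
    DiamondRanking,
    LabeledDataset,
    TrainingConfig,
    build_training_sets,
    diamond_expand,
)
from .features import (
    FEATURE_NAMES,
    EnrichedTermSet,
    FeatureVector,
    GOAnnotationMap,
    VITPanel,
)
from .graphio import InteractomeGraph
from .propagation import SeedSet

logger = logging.getLogger(__name__)


@dataclass
class FeatureContext:
    """Shared per-ADR intermediates from which any node's vector follows."""

    graph: InteractomeGraph
    seeds: SeedSet
    scores: propagation.DiffusionScores
    topology: graphio.TopologyProfile
    k1: clustering.ModulePartition
    louvain: clustering.ModulePartition
    enriched: EnrichedTermSet
    annotations: GOAnnotationMap
    panel: VITPanel
    panel_q1: dict[str, float]


def build_feature_context(
    g: InteractomeGraph,
    seeds: SeedSet,
    annotations: GOAnnotationMap,
    panel: VITPanel,
    *,
    alpha: float = 0.5,
    enrichment_top_n: int = 100,
    enrichment_alpha: float = 0.05,
    walk_length: int = 5,
    n_spectral_clusters: int | None = None,
    louvain_resolution: float = 1.0,
    rng_seed: int = 0,
) -> FeatureContext:
    """Run every global computation once for one ADR seed set.

    ``n_spectral_clusters`` defaults to ``round(n / 15)`` (at least 2).
    """
    seeds = seeds.restrict_to(g)
    panel = panel.restrict_to(g)
    scores = propagation.propagate(g, seeds, alpha=alpha)
    topology = graphio.topology_profile(g)

    dsd = clustering.dsd_matrix(g, walk_length=walk_length)
    if n_spectral_clusters is None:
        n_spectral_clusters = max(2, round(g.n_nodes / 15))
    k1 = clustering.spectral_partition(dsd, n_spectral_clusters, rng_seed=rng_seed)
    louvain = clustering.louvain_partition(
        g, resolution=louvain_resolution, rng_seed=rng_seed
    )

    top = propagation.top_ranked(scores, min(enrichment_top_n, g.n_nodes))
    enriched = features.fisher_enrichment(
        annotations, study=set(top), background=g.nodes, alpha=enrichment_alpha
    )
    panel_q1 = features.panel_q1_distances(g, panel)
    return FeatureContext(
        graph=g,
        seeds=seeds,
        scores=scores,
        topology=topology,
        k1=k1,
        louvain=louvain,
        enriched=enriched,
        annotations=annotations,
        panel=panel,
        panel_q1=panel_q1,
    )


def feature_vector(ctx: FeatureContext, protein: str) -> FeatureVector:
    """One node's 8-feature vector from precomputed context."""
    if protein not in ctx.graph:
        raise KeyError(f"{protein!r} not in graph")
    return FeatureVector(
        guild_score=ctx.scores.scores[protein],
        degree_centrality=ctx.topology.degree_centrality[protein],
        betweenness=ctx.topology.betweenness[protein],
        clustering_coefficient=ctx.topology.clustering_coefficient[protein],
        pct_clusters_k1=clustering.cluster_fraction_feature(
            ctx.k1, ctx.seeds, protein
        ),
        pct_clusters_ln=clustering.cluster_fraction_feature(
            ctx.louvain, ctx.seeds, protein
        ),
        function_index=features.function_conservation_index(
            ctx.annotations.terms_of(protein), ctx.enriched
        ),
        vit_q1_distance=ctx.panel_q1[protein],
    )


def feature_table(ctx: FeatureContext) -> dict[str, FeatureVector]:
    """Feature vectors for every node of the graph."""
    return {n: feature_vector(ctx, n) for n in sorted(ctx.graph.nodes)}


@dataclass
class AdrModels:
    """The three trained classifier bundles for one ADR plus its dataset."""

    adr_label: str
    dataset: LabeledDataset
    ranking: DiamondRanking
    bundles: dict[str, learn.TrainedModelBundle]

    def predict(self, fv: FeatureVector) -> voting.VotingResult:
        preds = [
            learn.predict_with_model(self.bundles[k], fv)
            for k in learn.CLASSIFIER_KINDS
        ]
        return voting.vote(preds)


def train_adr_models(
    ctx: FeatureContext,
    config: TrainingConfig,
    grids: dict[str, dict[str, list]] | None = None,
    max_diamond_steps: int = 200,
) -> AdrModels:
    """DIAMOnD-augmented dataset plus SVM/RF/NN bundles for one ADR."""
    ranking = diamond_expand(ctx.graph, ctx.seeds, max_steps=max_diamond_steps)
    table = feature_table(ctx)
    ds = build_training_sets(ctx.graph, ctx.seeds, ranking, table, config)
    bundles = {
        kind: learn.train_model(
            ds,
            kind,
            grid=(grids or learn.DEFAULT_GRIDS)[kind],
            rng_seed=config.rng_seed,
        )
        for kind in learn.CLASSIFIER_KINDS
    }
    return AdrModels(
        adr_label=ctx.seeds.adr_label, dataset=ds, ranking=ranking, bundles=bundles
    )
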
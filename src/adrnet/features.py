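"""GO enrichment, function conservation index, safety-panel distance, and
assembly of the 8-dimensional per-protein feature vector.

Feature order (fixed):

1. ``guild_score`` — seed-based diffusion score
2. ``degree_centrality``
3. ``betweenness``
4. ``clustering_coefficient``
5. ``pct_clusters_k1`` — % of modules occupied by seeds+protein, DSD partition
6. ``pct_clusters_ln`` — same, Louvain partition
7. ``function_index`` — overlap between the protein's GO terms and the terms
   enriched among top-diffusion proteins (1 = full overlap)
8. ``vit_q1_distance`` — first quartile of hop distances to the safety panel
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .clustering import ModulePartition, cluster_fraction_feature
from .graphio import InteractomeGraph, TopologyProfile, bfs_distances
from .propagation import DiffusionScores, SeedSet

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

FEATURE_NAMES = (
    "guild_score",
    "degree_centrality",
    "betweenness",
    "clustering_coefficient",
    "pct_clusters_k1",
    "pct_clusters_ln",
    "function_index",
    "vit_q1_distance",
)


@dataclass
class GOAnnotationMap:
    """Mapping accession -> set of GO term ids (used as given, no ancestor
    propagation)."""

    annotations: dict[str, set[str]]

    def __post_init__(self) -> None:
        for terms in self.annotations.values():
            for t in terms:
                if not GO_ID_RE.match(t):
                    raise ValueError(f"malformed GO id {t!r}")

    def terms_of(self, accession: str) -> set[str]:
        return self.annotations.get(accession, set())


@dataclass
class EnrichedTermSet:
    """Significantly enriched GO terms, sorted by ascending raw p."""

    terms: list[tuple[str, float, float]]  # (go_id, p_value, adjusted_p)
    alpha: float

    @property
    def term_ids(self) -> set[str]:
        return {t for t, _, _ in self.terms}


@dataclass
class VITPanel:
    """Safety-pharmacology panel ("very important targets")."""

    accessions: set[str]
    label: str = "VIT"

    def restrict_to(self, g: InteractomeGraph) -> "VITPanel":
        present = self.accessions & g.nodes
        missing = self.accessions - present
        if missing:
            logger.warning(
                "%s: %d panel member(s) absent from graph, dropped",
                self.label,
                len(missing),
            )
        if not present:
            raise ValueError(f"{self.label}: no panel member maps into the graph")
        return VITPanel(present, self.label)


@dataclass(frozen=True)
class FeatureVector:
    guild_score: float
    degree_centrality: float
    betweenness: float
    clustering_coefficient: float
    pct_clusters_k1: float
    pct_clusters_ln: float
    function_index: float
    vit_q1_distance: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def fisher_enrichment(
    ann: GOAnnotationMap,
    study: set[str],
    background: set[str],
    alpha: float = 0.05,
) -> EnrichedTermSet:
    """One-sided Fisher enrichment of GO terms in ``study`` vs ``background``.

    Every term carried by at least one study protein is tested with a 2x2
    one-sided (greater) Fisher exact test; Benjamini–Hochberg adjustment is
    applied across the tested terms and terms with adjusted p <= alpha are
    retained, sorted by ascending raw p.
    """
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study must be a subset of background")

    term_study: dict[str, int] = {}
    term_bg: dict[str, int] = {}
    for acc in background:
        for t in ann.terms_of(acc):
            term_bg[t] = term_bg.get(t, 0) + 1
            if acc in study:
                term_study[t] = term_study.get(t, 0) + 1

    tested = sorted(term_study)
    if not tested:
        logger.warning("no GO term annotates any study protein")
        return EnrichedTermSet(terms=[], alpha=alpha)

    n_study, n_bg = len(study), len(background)
    pvals = []
    for t in tested:
        a = term_study[t]
        b = n_study - a
        c = term_bg[t] - a
        d = n_bg - n_study - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        pvals.append(float(p))

    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    kept = [
        (t, p, float(q))
        for t, p, q in zip(tested, pvals, adj)
        if q <= alpha
    ]
    kept.sort(key=lambda row: (row[1], row[0]))
    return EnrichedTermSet(terms=kept, alpha=alpha)


def function_conservation_index(
    protein_terms: set[str], enriched: EnrichedTermSet
) -> float:
    """Normalized overlap with the enriched-term universe E.

    Over E, the protein's presence/absence indicator is compared with the
    all-ones vector: ``1 - hamming/|E| = |protein_terms & E| / |E|``.  A value
    of 1 means the protein carries every enriched function; an empty E yields
    0 with a warning.
    """
    e = enriched.term_ids
    if not e:
        logger.warning("empty enriched-term set: function index defaults to 0")
        return 0.0
    return len(protein_terms & e) / len(e)


def vit_q1_distance(
    g: InteractomeGraph, protein: str, panel: VITPanel
) -> float:
    """First quartile of hop distances from ``protein`` to the panel.

    Panel members unreachable from the protein are ignored; if none is
    reachable the node count of the graph is returned as a "farther than
    anything" sentinel.  The quartile uses linear interpolation between order
    statistics.
    """
    if protein not in g:
        raise KeyError(f"{protein!r} not in graph")
    dist = bfs_distances(g, protein)
    reachable = sorted(dist[m] for m in panel.accessions if m in dist)
    if not reachable:
        logger.warning("no panel member reachable from %s; sentinel used", protein)
        return float(g.n_nodes)
    return float(np.percentile(reachable, 25))


def panel_q1_distances(
    g: InteractomeGraph, panel: VITPanel
) -> dict[str, float]:
    """Vectorized ``vit_q1_distance`` for every node, via one BFS per panel
    member instead of one per protein."""
    per_node: dict[str, list[int]] = {n: [] for n in g.nodes}
    for member in sorted(panel.accessions):
        for node, d in bfs_distances(g, member).items():
            per_node[node].append(d)
    sentinel = float(g.n_nodes)
    return {
        n: (float(np.percentile(sorted(ds), 25)) if ds else sentinel)
        for n, ds in per_node.items()
    }


def assemble_features(
    g: InteractomeGraph,
    protein: str,
    scores: DiffusionScores,
    k1: ModulePartition,
    ln: ModulePartition,
    seeds: SeedSet,
    ann: GOAnnotationMap,
    enriched: EnrichedTermSet,
    panel: VITPanel,
    topology: TopologyProfile | None = None,
) -> FeatureVector:
    """Populate the 8 feature fields for one protein (deterministic)."""
    if protein not in g:
        raise KeyError(f"{protein!r} not in graph")
    for name, mapping in (
        ("diffusion scores", scores.scores),
        ("K1 partition", k1.assignment),
        ("Louvain partition", ln.assignment),
    ):
        if protein not in mapping:
            raise KeyError(f"{protein!r} absent from {name}")
    if topology is None:
        from .graphio import topology_profile

        topology = topology_profile(g)
    return FeatureVector(
        guild_score=scores.scores[protein],
        degree_centrality=topology.degree_centrality[protein],
        betweenness=topology.betweenness[protein],
        clustering_coefficient=topology.clustering_coefficient[protein],
        pct_clusters_k1=cluster_fraction_feature(k1, seeds, protein),
        pct_clusters_ln=cluster_fraction_feature(ln, seeds, protein),
        function_index=function_conservation_index(ann.terms_of(protein), enriched),
        vit_q1_distance=vit_q1_distance(g, protein, panel),
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_annotations_tsv(source: IO[str] | str) -> GOAnnotationMap:
    """Plain 2-column TSV: accession <tab> GO id (one pair per row)."""
    close = isinstance(source, str)
    fh = open(source, "rt") if close else source
    annotations: dict[str, set[str]] = {}
    try:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() in ("accession", "protein"):
                continue
            acc, go_id = parts[0], parts[1]
            annotations.setdefault(acc, set()).add(go_id)
    finally:
        if close:
            fh.close()
    return GOAnnotationMap(annotations)


def read_gaf(source: IO[str] | str) -> GOAnnotationMap:
    """Minimal GAF 2.x reader: column 2 (DB object id) and column 5 (GO id);
    rows whose qualifier (column 4) contains NOT are skipped."""
    close = isinstance(source, str)
    fh = open(source, "rt") if close else source
    annotations: dict[str, set[str]] = {}
    try:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            if "NOT" in cols[3].split("|"):
                continue
            annotations.setdefault(cols[1], set()).add(cols[4])
    finally:
        if close:
            fh.close()
    return GOAnnotationMap(annotations)


def read_panel(source: IO[str] | str, label: str = "VIT") -> VITPanel:
    """Plain-text accession list, one per line."""
    close = isinstance(source, str)
    fh = open(source, "rt") if close else source
    try:
        accs = {
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        }
    finally:
        if close:
            fh.close()
    if not accs:
        raise ValueError("panel file contains no accessions")
    return VITPanel(accessions=accs, label=label)


def export_feature_table(
    table: Mapping[str, FeatureVector], path: str
) -> None:
    """Write a feature matrix as TSV with the fixed 8-column header."""
    with open(path, "wt") as fh:
        fh.write("accession\t" + "\t".join(FEATURE_NAMES) + "\n")
        for acc in sorted(table):
            vals = "\t".join(f"{v:.10g}" for v in table[acc].as_array())
            fh.write(f"{acc}\t{vals}\n")
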
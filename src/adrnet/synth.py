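"""Synthetic fixtures: scale-free interactome, planted ADR module, GO
annotations and safety panel — everything the pipeline needs, generated
deterministically from a seed.

The generator emulates the structural assumptions of the predictor rather
than any particular real dataset:

* a preferential-attachment (Barabási–Albert) graph stands in for the
  heavy-tailed interactome;
* ADR-associated proteins occupy a connected, locally densified subgraph
  (an "ADR module"); half of them act as the known seed set, the other half
  are held-out positives;
* a few GO terms are strongly over-represented inside the module, giving the
  enrichment and function-index features signal;
* the safety panel is sampled with probability decaying in hop distance from
  the module, so planted proteins sit closer to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .dataset import ADRAssociationTable
from .features import GOAnnotationMap, VITPanel
from .graphio import InteractomeGraph
from .propagation import SeedSet

SYNTH_ADR = "synthetic module toxicity"
SYNTH_SOC = "synthetic organ class"


@dataclass(frozen=True)
class SynthConfig:
    n_nodes: int = 1000
    attachment_m: int = 3
    module_size: int = 30
    densify_prob: float = 0.3
    n_go_terms: int = 50
    module_term_count: int = 5
    module_annotation_rate: float = 0.8
    background_annotation_rate: float = 0.1
    panel_size: int = 48
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be smaller than n_nodes")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.module_term_count > self.n_go_terms:
            raise ValueError("module_term_count exceeds n_go_terms")


@dataclass
class SyntheticFixture:
    graph: InteractomeGraph
    associations: ADRAssociationTable
    annotations: GOAnnotationMap
    panel: VITPanel
    truth: dict[str, str]  # accession -> "planted" | "background"
    seeds: SeedSet
    held_out_positives: set[str]


def _accession(i: int) -> str:
    return f"P{i:05d}"


def generate_interactome(n: int, m: int, rng_seed: int) -> InteractomeGraph:
    """Preferential-attachment graph with accession-style node names.

    Convention pinned for testability: growth starts from ``m`` unconnected
    nodes and each of the remaining ``n - m`` arrivals attaches ``m`` edges,
    so the edge count is exactly ``m * (n - m)``.
    """
    if not n > m >= 1:
        raise ValueError("require n > m >= 1")
    g = nx.barabasi_albert_graph(n, m, seed=rng_seed)
    g = nx.relabel_nodes(g, {i: _accession(i) for i in g.nodes})
    return InteractomeGraph(graph=g, label=f"synthetic-ba-n{n}-m{m}")


def plant_adr_module(
    g: InteractomeGraph,
    module_size: int,
    densify_prob: float,
    rng_seed: int,
) -> tuple[SeedSet, set[str]]:
    """Select a connected subgraph, densify it, and split it into a seed set
    and held-out positives.

    The module is grown by breadth-first search from a random anchor; each
    absent internal edge is then added with probability ``densify_prob``.
    ``ceil(module_size / 2)`` members (seeded choice) become the ADR seed
    set; the rest are held-out planted positives.  The graph is modified in
    place (densification edges are real interactions downstream).
    """
    if module_size > g.n_nodes:
        raise ValueError("graph too small for requested module")
    rng = np.random.default_rng(rng_seed)
    order = sorted(g.nodes)
    anchor = order[int(rng.integers(len(order)))]

    planted: list[str] = []
    seen = {anchor}
    queue = [anchor]
    while queue and len(planted) < module_size:
        node = queue.pop(0)
        planted.append(node)
        for nb in sorted(g.graph.neighbors(node)):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    if len(planted) < module_size:
        raise ValueError("BFS exhausted the component before module_size")

    for i, u in enumerate(planted):
        for v in planted[i + 1 :]:
            if not g.graph.has_edge(u, v) and rng.random() < densify_prob:
                g.graph.add_edge(u, v)

    n_seeds = math.ceil(module_size / 2)
    seed_members = set(
        rng.choice(sorted(planted), size=n_seeds, replace=False).tolist()
    )
    seeds = SeedSet(adr_label=SYNTH_ADR, accessions=seed_members)
    return seeds, set(planted)


def generate_annotations_and_panel(
    g: InteractomeGraph, planted: set[str], cfg: SynthConfig
) -> tuple[GOAnnotationMap, VITPanel]:
    """Enriched GO annotations on the module plus a nearby safety panel.

    The first ``module_term_count`` GO terms annotate planted nodes with
    probability ``module_annotation_rate`` and background nodes at
    ``background_annotation_rate``; the remaining terms annotate every node
    at the background rate.  Panel members are drawn without replacement with
    weight ``2^(-d)``, ``d`` being the hop distance to the planted module.
    """
    if not planted <= g.nodes:
        raise ValueError("planted set must be a subset of graph nodes")
    rng = np.random.default_rng(cfg.rng_seed + 1)
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    module_terms = terms[: cfg.module_term_count]
    order = sorted(g.nodes)

    annotations: dict[str, set[str]] = {n: set() for n in order}
    for t in module_terms:
        for n in order:
            rate = (
                cfg.module_annotation_rate
                if n in planted
                else cfg.background_annotation_rate
            )
            if rng.random() < rate:
                annotations[n].add(t)
    for t in terms[cfg.module_term_count :]:
        for n in order:
            if rng.random() < cfg.background_annotation_rate:
                annotations[n].add(t)

    # multi-source BFS distance to the module
    dist = {n: math.inf for n in order}
    frontier = sorted(planted)
    for n in frontier:
        dist[n] = 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.graph.neighbors(u):
                if dist[v] == math.inf:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = sorted(nxt)
    weights = np.array(
        [2.0 ** (-dist[n]) if dist[n] != math.inf else 0.0 for n in order]
    )
    if np.count_nonzero(weights) < cfg.panel_size:
        raise ValueError("not enough reachable nodes for the requested panel")
    weights = weights / weights.sum()
    members = rng.choice(order, size=cfg.panel_size, replace=False, p=weights)
    panel = VITPanel(accessions=set(members.tolist()), label="synthetic-VIT")
    return GOAnnotationMap({n: s for n, s in annotations.items() if s}), panel


def generate_fixture(cfg: SynthConfig) -> SyntheticFixture:
    """Compose graph, module, annotations, panel and truth labels."""
    g = generate_interactome(cfg.n_nodes, cfg.attachment_m, cfg.rng_seed)
    seeds, planted = plant_adr_module(
        g, cfg.module_size, cfg.densify_prob, cfg.rng_seed
    )
    annotations, panel = generate_annotations_and_panel(g, planted, cfg)

    import pandas as pd

    records = pd.DataFrame(
        {
            "adr_label": SYNTH_ADR,
            "soc_label": SYNTH_SOC,
            "accession": sorted(seeds.accessions),
        }
    )
    truth = {
        n: ("planted" if n in planted else "background") for n in sorted(g.nodes)
    }
    return SyntheticFixture(
        graph=g,
        associations=ADRAssociationTable(records=records),
        annotations=annotations,
        panel=panel,
        truth=truth,
        seeds=seeds,
        held_out_positives=planted - seeds.accessions,
    )


def degree_matched_background(
    fixture: SyntheticFixture, n: int, rng_seed: int
) -> list[str]:
    """Background nodes whose degrees track the planted nodes' degrees.

    For each of ``n`` planted nodes (cycled if needed) the unused background
    node with the closest degree is taken — a matched negative control group
    for directional feature comparisons.
    """
    g = fixture.graph.graph
    planted = sorted(p for p, lab in fixture.truth.items() if lab == "planted")
    background = sorted(p for p, lab in fixture.truth.items() if lab == "background")
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(background)
    available = background.copy()
    chosen: list[str] = []
    for i in range(n):
        target_deg = g.degree(planted[i % len(planted)])
        best = min(available, key=lambda b: (abs(g.degree(b) - target_deg), b))
        chosen.append(best)
        available.remove(best)
    return chosen


def write_fixture(fixture: SyntheticFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the same formats the pipeline reads.

    Returns the mapping of file roles to paths: network (edge TSV),
    associations (TSV), annotations (2-column TSV), panel (accession list),
    truth (TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "associations": outdir / "associations.tsv",
        "annotations": outdir / "annotations.tsv",
        "panel": outdir / "panel.txt",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["network"], "wt") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in fixture.graph.graph.edges):
            fh.write(f"{u}\t{v}\n")
    fixture.associations.records.to_csv(paths["associations"], sep="\t", index=False)
    with open(paths["annotations"], "wt") as fh:
        for acc in sorted(fixture.annotations.annotations):
            for t in sorted(fixture.annotations.annotations[acc]):
                fh.write(f"{acc}\t{t}\n")
    with open(paths["panel"], "wt") as fh:
        for acc in sorted(fixture.panel.accessions):
            fh.write(acc + "\n")
    with open(paths["truth"], "wt") as fh:
        fh.write("accession\tstatus\n")
        for acc, status in fixture.truth.items():
            fh.write(f"{acc}\t{status}\n")
    return paths
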
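"""Labeled training-set construction for per-ADR and per-SOC models.

Curated protein–ADR associations are typically few per ADR, so the positive
class is augmented by DIAMOnD-style disease-module expansion: neighbors of
the current module are ranked by the hypergeometric significance of their
connectivity to it and admitted while their score (1 - p) clears a threshold.
Negatives are drawn at random from the rest of the network below the same
threshold, at a configurable class-imbalance ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .features import FeatureVector
from .graphio import InteractomeGraph
from .propagation import SeedSet

logger = logging.getLogger(__name__)

DIAMOND_THRESHOLDS = (0.6, 0.7, 0.8, 0.9)
NEG_RATIOS = (1.0, 1.5, 3.0, 5.0)


@dataclass
class ADRAssociationTable:
    """Protein–ADR association records with their MedDRA SOC grouping.

    Backed by a DataFrame with columns ``adr_label``, ``soc_label``,
    ``accession``; (adr_label, accession) pairs are unique.
    """

    records: pd.DataFrame
    soc_eligible: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        required = ["adr_label", "soc_label", "accession"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"association table missing columns: {missing}")
        dup = self.records.duplicated(subset=["adr_label", "accession"])
        if dup.any():
            raise ValueError("duplicate (adr_label, accession) pairs")
        if (self.records[required] == "").any().any():
            raise ValueError("empty labels or accessions in association table")

    @property
    def adr_labels(self) -> list[str]:
        return sorted(self.records["adr_label"].unique())

    def proteins_of(self, adr_label: str) -> set[str]:
        mask = self.records["adr_label"] == adr_label
        return set(self.records.loc[mask, "accession"])

    def seed_set(self, adr_label: str) -> SeedSet:
        prots = self.proteins_of(adr_label)
        if not prots:
            raise KeyError(f"no associations for ADR {adr_label!r}")
        return SeedSet(adr_label=adr_label, accessions=prots)


@dataclass
class DiamondRanking:
    """Ordered DIAMOnD expansion steps: (accession, step, p_hyper, score)."""

    steps: list[tuple[str, int, float, float]]

    def scores(self) -> dict[str, float]:
        return {acc: score for acc, _, _, score in self.steps}


@dataclass(frozen=True)
class TrainingConfig:
    diamond_threshold: float = 0.9
    neg_ratio: float = 1.0
    rng_seed: int = 0
    allow_free_values: bool = False

    def __post_init__(self) -> None:
        if self.allow_free_values:
            return
        if self.diamond_threshold not in DIAMOND_THRESHOLDS:
            raise ValueError(
                f"diamond_threshold must be one of {DIAMOND_THRESHOLDS} "
                "(or set allow_free_values)"
            )
        if self.neg_ratio not in NEG_RATIOS:
            raise ValueError(
                f"neg_ratio must be one of {NEG_RATIOS} (or set allow_free_values)"
            )


@dataclass
class LabeledDataset:
    """Feature rows with ±1 labels for one ADR under one TrainingConfig."""

    rows: list[tuple[str, FeatureVector, int]]
    config: TrainingConfig
    adr_label: str

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        x = np.vstack([fv.as_array() for _, fv, _ in self.rows])
        y = np.array([label for _, _, label in self.rows], dtype=int)
        accs = [acc for acc, _, _ in self.rows]
        return x, y, accs

    def to_frame(self) -> pd.DataFrame:
        from .features import FEATURE_NAMES

        x, y, accs = self.to_arrays()
        df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
        df.insert(0, "accession", accs)
        df["label"] = y
        return df


def read_associations_tsv(source: IO[str] | str) -> ADRAssociationTable:
    """TSV with required header: adr_label, soc_label, accession."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"adr_label", "soc_label", "accession"}
    if not required <= set(df.columns):
        raise ValueError(
            f"association TSV must have header columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return ADRAssociationTable(records=df[["adr_label", "soc_label", "accession"]])


def filter_associations(
    t: ADRAssociationTable,
    min_proteins_per_adr: int = 10,
    min_adrs_per_soc: int = 5,
) -> ADRAssociationTable:
    """Drop under-characterized ADRs; flag SOCs eligible for SOC-level models.

    ADRs with fewer than ``min_proteins_per_adr`` associated proteins are
    removed.  SOCs that retain fewer than ``min_adrs_per_soc`` ADRs remain in
    the table (their ADRs are still modeled individually) but are excluded
    from SOC-level modeling via ``soc_eligible``.
    """
    df = t.records
    counts = df.groupby("adr_label")["accession"].nunique()
    keep_adrs = set(counts[counts >= min_proteins_per_adr].index)
    dropped = set(counts.index) - keep_adrs
    out = df[df["adr_label"].isin(keep_adrs)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"no ADR retains >= {min_proteins_per_adr} proteins after filtering"
        )
    soc_counts = out.groupby("soc_label")["adr_label"].nunique()
    eligible = set(soc_counts[soc_counts >= min_adrs_per_soc].index)
    logger.info(
        "association filter: kept %d/%d ADRs (dropped %d); %d/%d SOCs eligible",
        len(keep_adrs),
        len(counts),
        len(dropped),
        len(eligible),
        len(soc_counts),
    )
    return ADRAssociationTable(records=out, soc_eligible=eligible)


def merge_to_soc(t: ADRAssociationTable) -> ADRAssociationTable:
    """One pseudo-ADR per eligible SOC, pooling member-ADR proteins."""
    df = t.records
    socs = t.soc_eligible if t.soc_eligible else set(df["soc_label"].unique())
    rows = []
    for soc in sorted(socs):
        prots = sorted(set(df.loc[df["soc_label"] == soc, "accession"]))
        rows.extend(
            {"adr_label": soc, "soc_label": soc, "accession": p} for p in prots
        )
    merged = pd.DataFrame(rows, columns=["adr_label", "soc_label", "accession"])
    return ADRAssociationTable(records=merged, soc_eligible=set(socs))


def _exact_hypergeom_tail(ks: int, n_total: int, s0: int, k: int):
    """P(X >= ks) as an exact fraction (numerator, denominator pair)."""
    from fractions import Fraction
    from math import comb

    num = sum(comb(s0, x) * comb(n_total - s0, k - x) for x in range(ks, min(s0, k) + 1))
    return Fraction(num, comb(n_total, k))


def diamond_expand(
    g: InteractomeGraph, seeds: SeedSet, max_steps: int = 200
) -> DiamondRanking:
    """Iterative DIAMOnD expansion of the seed module.

    At each step, every node with >= 1 link to the current module (size s0)
    is scored by the hypergeometric tail ``P(X >= ks)`` with
    ``X ~ Hypergeom(N=node count, successes=s0, draws=candidate degree)``;
    the lowest-p node joins the module (ties: lower degree, then lexicographic
    accession).  Each step records ``score = 1 - p``.
    """
    seeds = seeds.restrict_to(g)
    graph = g.graph
    n_total = g.n_nodes
    module = set(seeds.accessions)
    degree = dict(graph.degree())
    # links from each outside node into the module
    ks: dict[str, int] = {}
    for s in module:
        for nb in graph.neighbors(s):
            if nb not in module:
                ks[nb] = ks.get(nb, 0) + 1

    steps: list[tuple[str, int, float, float]] = []
    for step in range(1, max_steps + 1):
        if not ks:
            logger.warning(
                "DIAMOnD ranking truncated at step %d: no connected candidate",
                step,
            )
            break
        s0 = len(module)
        pvals = {
            cand: float(hypergeom.sf(k_in - 1, n_total, s0, degree[cand]))
            for cand, k_in in ks.items()
        }
        p_min = min(pvals.values())
        # float rounding can misorder mathematically tied tails, so the
        # near-minimal set is re-ranked with exact rational arithmetic
        near = [c for c, p in pvals.items() if p <= p_min * (1 + 1e-9) + 1e-300]
        exact = {
            c: _exact_hypergeom_tail(ks[c], n_total, s0, degree[c]) for c in near
        }
        chosen = min(near, key=lambda c: (exact[c], degree[c], c))
        p = pvals[chosen]
        steps.append((chosen, step, p, 1.0 - p))
        module.add(chosen)
        del ks[chosen]
        for nb in graph.neighbors(chosen):
            if nb not in module:
                ks[nb] = ks.get(nb, 0) + 1
    return DiamondRanking(steps=steps)


def build_training_sets(
    g: InteractomeGraph,
    seeds: SeedSet,
    ranking: DiamondRanking,
    features: Mapping[str, FeatureVector] | Callable[[str], FeatureVector],
    config: TrainingConfig,
) -> LabeledDataset:
    """Assemble a ±1 labeled dataset for one ADR.

    Positives are the seeds plus every ranked node whose DIAMOnD score
    reaches ``config.diamond_threshold``; negatives are a seeded uniform
    sample of the remaining nodes whose score falls below it (unranked nodes
    score 0), ``round(neg_ratio * positives)`` of them.
    """
    seeds = seeds.restrict_to(g)
    scores = ranking.scores()
    positives = set(seeds.accessions) | {
        acc for acc, sc in scores.items() if sc >= config.diamond_threshold
    }
    pool = sorted(
        acc
        for acc in g.nodes
        if acc not in positives
        and scores.get(acc, 0.0) < config.diamond_threshold
    )
    n_neg = round(config.neg_ratio * len(positives))
    if len(pool) < n_neg:
        raise ValueError(
            f"negative pool too small: need {n_neg}, have {len(pool)} "
            f"(deficit {n_neg - len(pool)})"
        )
    rng = np.random.default_rng(config.rng_seed)
    negatives = sorted(rng.choice(pool, size=n_neg, replace=False).tolist())

    get = features.__getitem__ if isinstance(features, Mapping) else features
    rows = [(acc, get(acc), +1) for acc in sorted(positives)]
    rows += [(acc, get(acc), -1) for acc in negatives]
    return LabeledDataset(rows=rows, config=config, adr_label=seeds.adr_label)


def config_grid(
    thresholds: Iterable[float] = DIAMOND_THRESHOLDS,
    ratios: Iterable[float] = NEG_RATIOS,
    rng_seed: int = 0,
) -> list[TrainingConfig]:
    """Enumerate the threshold x ratio training-config grid."""
    return [
        TrainingConfig(diamond_threshold=t, neg_ratio=r, rng_seed=rng_seed)
        for t in thresholds
        for r in ratios
    ]


def export_dataset(ds: LabeledDataset, path: str) -> None:
    ds.to_frame().to_csv(path, sep="\t", index=False)
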
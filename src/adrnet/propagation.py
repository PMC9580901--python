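"""Seed-based network diffusion ("guilt-by-association" scoring).

Each adverse-drug-reaction (ADR) has a curated set of associated proteins,
the *seeds*.  A random walk with restart on the interactome spreads mass from
the seeds to the rest of the network; the stationary score of a node measures
how quickly the seeds' signal reaches it and is the first entry of the
per-protein feature vector.

The fixed point solved is ``s = alpha * W @ s + (1 - alpha) * e`` with ``W``
the column-normalized adjacency matrix and ``e`` the restart distribution,
uniform over the seeds.  On a graph with no isolated node the scores sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graphio import InteractomeGraph

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Proteins associated with one ADR (or SOC pseudo-ADR)."""

    adr_label: str
    accessions: set[str]

    def restrict_to(self, g: InteractomeGraph) -> "SeedSet":
        """Drop seeds absent from the graph; error if none remain."""
        present = self.accessions & g.nodes
        missing = self.accessions - present
        if missing:
            logger.warning(
                "%s: %d seed(s) absent from graph, dropped: %s",
                self.adr_label,
                len(missing),
                sorted(missing)[:5],
            )
        if not present:
            raise ValueError(
                f"{self.adr_label}: no seed maps into the graph"
            )
        return SeedSet(self.adr_label, present)


@dataclass
class DiffusionScores:
    scores: dict[str, float]
    alpha: float
    iterations_run: int
    converged: bool


def _column_normalized_adjacency(g: InteractomeGraph, order: list[str]) -> sp.csr_matrix:
    a = nx_adjacency(g, order)
    deg = np.asarray(a.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
    return (a @ sp.diags(inv)).tocsr()


def nx_adjacency(g: InteractomeGraph, order: list[str]) -> sp.csr_matrix:
    import networkx as nx

    return nx.to_scipy_sparse_array(g.graph, nodelist=order, format="csr", dtype=float)


def propagate(
    g: InteractomeGraph,
    seeds: SeedSet,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> DiffusionScores:
    """Random walk with restart from the seed set.

    Parameters
    ----------
    alpha
        Walk-continuation probability in (0, 1); ``1 - alpha`` is the restart
        probability.  ``alpha -> 0`` recovers the restart vector itself.
    tol
        Iteration stops when the max absolute per-node change drops below it.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    seeds = seeds.restrict_to(g)

    order = sorted(g.nodes)
    index = {n: i for i, n in enumerate(order)}
    w = _column_normalized_adjacency(g, order)

    e = np.zeros(len(order))
    for acc in seeds.accessions:
        e[index[acc]] = 1.0 / len(seeds.accessions)

    s = e.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        s_next = alpha * (w @ s) + (1.0 - alpha) * e
        if np.max(np.abs(s_next - s)) < tol:
            s = s_next
            converged = True
            break
        s = s_next
    if not converged:
        logger.warning(
            "propagation did not converge in %d iterations (tol=%g)", max_iter, tol
        )
    return DiffusionScores(
        scores={n: float(s[i]) for i, n in enumerate(order)},
        alpha=alpha,
        iterations_run=iterations,
        converged=converged,
    )


def top_ranked(scores: DiffusionScores, k: int) -> list[str]:
    """The ``k`` highest-scoring accessions, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [acc for acc, _ in ranked[:k]]


def export_scores(scores: DiffusionScores, path: str) -> None:
    """Write scores as a 2-column TSV (accession, score), descending."""
    ranked = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "wt") as fh:
        for acc, val in ranked:
            fh.write(f"{acc}\t{val:.10g}\n")
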
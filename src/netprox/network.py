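"""Confidence-thresholded protein interaction network and its statistics.

The disease network is the induced subgraph of a STRING-style scored
interaction table on the disease signature plus the drug-target nodes, with
edges kept only at combined score >= 0.9 (the threshold is inclusive:
"minimum" reads as attainable). Isolated members of the query set are
retained as degree-0 nodes, so the node count is exactly the set arithmetic
|signature union targets|.

Enrichment of the observed edge count over chance uses a degree-product
(Chung-Lu) null: with universe degrees k and universe edge count m, the
expected number of connections among the selected nodes is

    E = sum over unordered pairs {i, j} of min(1, k_i * k_j / (2 m))

and the upper-tail p-value treats the observed count as Poisson with mean E,
evaluated through the regularized incomplete gamma function so that
p-values far below 1e-16 remain meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

#: Default drug classes and their single target proteins (gene symbols):
#: ACE inhibitors -> ACE, angiotensin receptor blockers -> AGTR1,
#: beta-blockers -> ADRB1, mineralocorticoid receptor antagonists -> NR3C2.
DEFAULT_TARGETS: dict[str, set[str]] = {
    "ACEi": {"ACE"},
    "ARB": {"AGTR1"},
    "beta_blocker": {"ADRB1"},
    "MRA": {"NR3C2"},
}


@dataclass
class InteractionNetwork:
    """The thresholded disease network plus the universe it was cut from."""

    graph: nx.Graph               # nodes = signature union targets
    universe: nx.Graph = field(repr=False)  # every thresholded interaction

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def load_interactions(path: str | Path, min_score: float = 0.9) -> pd.DataFrame:
    """Parse a scored interaction table and apply the confidence threshold.

    Accepts whitespace- or tab-delimited files with at least three columns
    (protein1, protein2, combined_score); a header row is auto-detected.
    Scores in the STRING 0-1000 integer dialect are divided by 1000. Rows
    with score >= min_score are retained; self-interactions are dropped and
    symmetric duplicates collapse to the maximum score.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                score = float(fields[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: unparseable score {fields[2]!r}"
                ) from None
            rows.append((fields[0], fields[1], score))
    if not rows:
        raise ValueError(f"{path}: no interaction rows")

    scores = np.array([r[2] for r in rows])
    if scores.max() > 1.0:  # 0-1000 integer dialect
        if scores.max() > 1000 or scores.min() < 0:
            raise ValueError(f"{path}: scores outside both the [0,1] and 0-1000 dialects")
        scores = scores / 1000.0
    elif scores.min() < 0:
        raise ValueError(f"{path}: negative interaction scores")

    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for (p1, p2, _), s in zip(rows, scores):
        if p1 == p2:
            n_self += 1
            continue
        key = (p1, p2) if p1 < p2 else (p2, p1)
        if s > best.get(key, -1.0):
            best[key] = s
    if n_self:
        logger.info("dropped %d self-interactions", n_self)

    kept = sorted((k, v) for k, v in best.items() if v >= min_score)
    return pd.DataFrame(
        {
            "protein1": [k[0] for k, _ in kept],
            "protein2": [k[1] for k, _ in kept],
            "combined_score": [v for _, v in kept],
        }
    )


def build_network(
    table: pd.DataFrame,
    disease: set[str],
    targets: dict[str, set[str]] | None = None,
) -> InteractionNetwork:
    """Induce the disease network on signature + drug-target nodes.

    The node set is the union of the disease signature and every target id;
    members without any retained interaction stay as isolated nodes (and
    absent targets are logged), so n_nodes = |disease union targets| always.
    The universe keeps every thresholded interaction for the null models.
    """
    if not disease:
        raise ValueError("disease signature set is empty")
    target_ids: set[str] = set()
    for ids in (targets or {}).values():
        target_ids |= set(ids)
    nodes = set(map(str, disease)) | set(map(str, target_ids))

    universe = nx.Graph()
    for p1, p2, s in table.itertuples(index=False):
        universe.add_edge(str(p1), str(p2), score=float(s))
    universe.add_nodes_from(nodes)

    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    for u, v, data in universe.edges(data=True):
        if u in nodes and v in nodes:
            graph.add_edge(u, v, **data)

    absent = sorted(t for t in target_ids if universe.degree(t) == 0)
    if absent:
        logger.info("targets absent from the interaction universe kept isolated: %s",
                    absent)
    return InteractionNetwork(graph=graph, universe=universe)


def expected_random_edges(net: InteractionNetwork) -> float:
    """Degree-product expectation of the edge count among the selected nodes.

    E = sum over unordered node pairs of min(1, k_i k_j / (2m)), with degrees
    and edge count m taken from the universe.
    """
    m = net.universe.number_of_edges()
    if net.universe.number_of_nodes() == 0:
        raise ValueError("empty universe")
    nodes = sorted(net.graph.nodes)
    k = np.array([net.universe.degree(v) for v in nodes], dtype=float)
    if m == 0:
        return 0.0
    probs = np.minimum(1.0, np.outer(k, k) / (2.0 * m))
    return float((probs.sum() - np.diag(probs).sum()) / 2.0)


def enrichment_pvalue(observed: int, expected: float) -> float:
    """Upper-tail Poisson probability P(X >= observed | lambda = expected).

    Evaluated as the regularized lower incomplete gamma function
    gammainc(observed, expected), which stays accurate deep in the tail
    (p-values of 1e-280 and below are representable). Returns a value in
    (0, 1]; results that underflow double precision are floored at the
    smallest positive float.
    """
    if observed < 0:
        raise ValueError("observed edge count must be >= 0")
    if expected <= 0:
        raise ValueError("expected edge count must be > 0")
    if observed == 0:
        return 1.0
    p = float(special.gammainc(observed, expected))
    return max(p, np.nextafter(0.0, 1.0))


def network_stats(net: InteractionNetwork) -> dict:
    """Descriptive + enrichment statistics of the disease network."""
    expected = expected_random_edges(net)
    stats = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "expected_edges": expected,
    }
    stats["enrichment_p"] = (
        enrichment_pvalue(net.n_edges, expected) if expected > 0 else 1.0
    )
    return stats


def shortest_paths(
    net: InteractionNetwork | nx.Graph, sources: set[str] | list[str]
) -> dict[str, dict[str, int]]:
    """Unweighted BFS hop counts from each source to every reachable node.

    Unreachable nodes are simply absent from a source's inner map — callers
    must treat missing entries as unreachable, never as a large distance.
    """
    graph = net.graph if isinstance(net, InteractionNetwork) else net
    out: dict[str, dict[str, int]] = {}
    for s in sources:
        if s not in graph:
            raise ValueError(f"unknown source node {s!r}")
        out[s] = dict(nx.single_source_shortest_path_length(graph, s))
    return out
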
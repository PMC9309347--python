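"""Cross-species set translation by reciprocal best hits (RBH).

A gene set from species A is translated to species B by accepting a pair
(a, b) only when b is a's unique top-scoring hit in the A->B table and a is
b's unique top-scoring hit in the B->A table; the result is one-to-one by
construction. Queries whose best score is tied between subjects are dropped
rather than resolved arbitrarily, so the output is invariant to row order.
A separate one-to-one gene-to-protein mapping step then carries the
translated set into the protein interaction namespace.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def _clean_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the hit-table invariants: finite scores, best score per pair."""
    if not {"query", "subject", "score"}.issubset(table.columns):
        table = table.copy()
        table.columns = ["query", "subject", "score", *table.columns[3:]]
    if table["score"].isna().any() or not pd.api.types.is_numeric_dtype(table["score"]):
        raise ValueError("hit-table scores must be finite numbers")
    n0 = len(table)
    table = (
        table.groupby(["query", "subject"], as_index=False)["score"].max()
    )
    if len(table) < n0:
        logger.info("collapsed %d duplicate (query, subject) hits", n0 - len(table))
    return table


def best_hits(table: pd.DataFrame) -> dict[str, str]:
    """Top-scoring subject per query; tied queries are omitted (and logged)."""
    if len(table) == 0:
        raise ValueError("hit table is empty")
    table = _clean_hits(table)
    out: dict[str, str] = {}
    for query, grp in table.groupby("query"):
        top = grp["score"].max()
        winners = grp.loc[grp["score"] == top, "subject"]
        if len(winners) > 1:
            logger.info("query %s dropped: best score tied among %d subjects",
                        query, len(winners))
            continue
        out[str(query)] = str(winners.iloc[0])
    return out


def reciprocal_best_hits(ab: pd.DataFrame, ba: pd.DataFrame) -> list[tuple[str, str]]:
    """Ortholog pairs (a, b) that are mutual best hits in both directions.

    One-to-one by construction: a appears at most once as a query in ab, and
    reciprocity forbids two queries sharing a subject. An empty reverse table
    yields an empty map.
    """
    if len(ba) == 0:
        return []
    fwd = best_hits(ab)
    rev = best_hits(ba)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    return sorted(pairs)


def map_set(
    genes: set[str] | list[str],
    gene2protein: pd.DataFrame,
    orthologs: list[tuple[str, str]] | None = None,
) -> set[str]:
    """Translate a gene set into a deduplicated protein set, strictly 1:1.

    Genes are first carried across species by the ortholog map (if given),
    then into proteins by the two-column mapping table. Genes with zero or
    multiple protein images, and proteins hit by more than one gene, are
    dropped and logged — the mapping is enforced one-to-one on both sides.
    """
    genes = set(map(str, genes))
    if orthologs is not None:
        ortho = dict(orthologs)
        lost = genes - set(ortho)
        if lost:
            logger.info("%d genes without an ortholog dropped", len(lost))
        genes = {ortho[g] for g in genes & set(ortho)}

    g2p = gene2protein.copy()
    g2p.columns = ["gene", "protein", *g2p.columns[2:]]
    g2p = g2p[g2p["gene"].isin(genes)].drop_duplicates(["gene", "protein"])

    multi_image = g2p["gene"].value_counts()
    bad_genes = set(multi_image[multi_image > 1].index)
    if bad_genes:
        logger.info("%d genes with multiple protein images dropped", len(bad_genes))
    g2p = g2p[~g2p["gene"].isin(bad_genes)]

    multi_source = g2p["protein"].value_counts()
    bad_prots = set(multi_source[multi_source > 1].index)
    if bad_prots:
        logger.info("%d proteins hit by multiple genes dropped", len(bad_prots))
    g2p = g2p[~g2p["protein"].isin(bad_prots)]

    unmapped = genes - set(g2p["gene"])
    if unmapped:
        logger.info("%d genes without a protein entry dropped", len(unmapped))
    return set(g2p["protein"].astype(str))
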
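"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study's data layers: a two-group log-intensity
expression matrix with planted differentially expressed genes and gene-wise
variance heterogeneity drawn from the scaled inverse-chi-square prior; paired
cross-species similarity ("hit") tables with planted one-to-one orthologs and
lower-scoring decoys; a modular scored interactome (stochastic block model)
with a STRING-like confidence channel; and a disease signature seeded inside
one module with drug-target nodes placed at controlled graph distances.

Every generator is deterministic given its seed, and each returns the planted
truth alongside the data so downstream stages can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io

#: Drug-class labels attached to the first four synthetic targets, mirroring
#: the neurohormonal-antagonism classes (ACE inhibitor, angiotensin-receptor
#: blocker, beta-blocker, mineralocorticoid-receptor antagonist).
DRUG_CLASSES = ("ACEi", "ARB", "beta_blocker", "MRA")


class InfeasibleDistanceError(ValueError):
    """Requested target placement distance cannot be realised on this graph."""


@dataclass
class SyntheticExpressionTruth:
    matrix: pd.DataFrame          # genes x samples, log2 intensities
    groups: pd.Series             # sample id -> group label
    de_genes: set[str]            # planted differential genes
    effect_size: float            # log2 shift added to group B for planted genes
    d0_true: float                # prior degrees of freedom of the variance model
    s0sq_true: float              # prior variance of the variance model
    gene_variances: pd.Series = field(repr=False, default=None)


@dataclass
class SyntheticInteractomeTruth:
    interactions: pd.DataFrame    # protein1, protein2, combined_score
    block_of: dict[str, int]      # node -> planted block label
    p_in: float
    p_out: float
    n_blocks: int

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.block_of)
        g.add_edges_from(
            zip(self.interactions["protein1"], self.interactions["protein2"])
        )
        return g


def gen_expression(
    n_genes: int,
    n_per_group: int,
    frac_de: float,
    effect_size: float,
    d0_true: float = 4.0,
    s0sq_true: float = 0.05,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    group_labels: tuple[str, str] = ("sham", "mi"),
) -> SyntheticExpressionTruth:
    """Simulate a two-group log2 expression matrix with planted DE genes.

    Gene-wise true variances are drawn as ``s0sq_true * d0_true / chi2(d0_true)``
    — the scaled inverse-chi-square model the moderated-t estimator assumes —
    so the empirical-Bayes hyperparameters are recoverable ground truth.
    Exactly ``round(frac_de * n_genes)`` genes carry a mean shift of
    ``effect_size`` in the second group before noise is added.
    """
    if n_genes < 10:
        raise ValueError(f"n_genes must be >= 10, got {n_genes}")
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError(f"frac_de must be in [0, 1], got {frac_de}")
    if d0_true <= 0 or s0sq_true <= 0:
        raise ValueError("d0_true and s0sq_true must be positive")

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:06d}" for i in range(n_genes)]
    la, lb = group_labels
    samples = [f"{la}_{j + 1:02d}" for j in range(n_per_group)] + [
        f"{lb}_{j + 1:02d}" for j in range(n_per_group)
    ]
    groups = pd.Series([la] * n_per_group + [lb] * n_per_group, index=samples)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    variances = s0sq_true * d0_true / rng.chisquare(d0_true, size=n_genes)

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    mean = np.tile(baseline[:, None], (1, 2 * n_per_group))
    mean[de_idx, n_per_group:] += effect_size

    noise = rng.standard_normal((n_genes, 2 * n_per_group)) * np.sqrt(variances)[:, None]
    matrix = pd.DataFrame(mean + noise, index=genes, columns=samples)

    return SyntheticExpressionTruth(
        matrix=matrix,
        groups=groups,
        de_genes={genes[i] for i in de_idx},
        effect_size=effect_size,
        d0_true=d0_true,
        s0sq_true=s0sq_true,
        gene_variances=pd.Series(variances, index=genes),
    )


def gen_hit_tables(
    n_orthologs: int,
    n_decoys: int,
    seed: int = 0,
    id_prefixes: tuple[str, str] = ("GA", "GB"),
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Simulate reciprocal similarity tables with planted one-to-one orthologs.

    Each planted pair is the unique mutual top hit in both directions (scores
    in [90, 100]); decoy rows pair random queries and subjects at strictly
    lower scores (in [10, 80]). Returns (A->B table, B->A table, truth pairs).
    """
    if n_orthologs < 1:
        raise ValueError(f"n_orthologs must be >= 1, got {n_orthologs}")
    if n_decoys < 0:
        raise ValueError(f"n_decoys must be >= 0, got {n_decoys}")

    rng = np.random.default_rng(seed)
    pa, pb = id_prefixes
    a_ids = [f"{pa}{i + 1:05d}" for i in range(n_orthologs)]
    b_ids = [f"{pb}{i + 1:05d}" for i in range(n_orthologs)]
    truth = list(zip(a_ids, b_ids))

    ab_rows = [(a, b, rng.uniform(90.0, 100.0)) for a, b in truth]
    ba_rows = [(b, a, rng.uniform(90.0, 100.0)) for a, b in truth]
    for _ in range(n_decoys):
        qa = a_ids[rng.integers(n_orthologs)]
        sb = b_ids[rng.integers(n_orthologs)]
        ab_rows.append((qa, sb, rng.uniform(10.0, 80.0)))
        qb = b_ids[rng.integers(n_orthologs)]
        sa = a_ids[rng.integers(n_orthologs)]
        ba_rows.append((qb, sa, rng.uniform(10.0, 80.0)))

    ab = pd.DataFrame(ab_rows, columns=["query", "subject", "score"])
    ba = pd.DataFrame(ba_rows, columns=["query", "subject", "score"])
    return ab, ba, truth


def gen_interactome(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
    noisy_scores: bool = False,
) -> SyntheticInteractomeTruth:
    """Simulate a modular scored interactome as a stochastic block model.

    Edges form independently with probability ``p_in`` within a block and
    ``p_out`` between blocks. Confidence scores for present edges are uniform
    on [0.9, 1.0] by default so the standard 0.9 cut keeps them; with
    ``noisy_scores=True`` they are uniform on [0, 1] to exercise the score
    filter. The graph is simple and undirected.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be positive")
    if not (0.0 <= p_out <= p_in <= 1.0) or (p_out == p_in and p_in > 0):
        raise ValueError(
            f"need 0 <= p_out < p_in <= 1 (or both zero), got p_in={p_in}, p_out={p_out}"
        )

    rng = np.random.default_rng(seed)
    sizes = [block_size] * n_blocks
    probs = np.full((n_blocks, n_blocks), p_out)
    np.fill_diagonal(probs, p_in)
    g = nx.stochastic_block_model(sizes, probs.tolist(), seed=int(seed))

    names = {i: f"P{i + 1:06d}" for i in g.nodes}
    block_of = {names[i]: i // block_size for i in g.nodes}

    lo, hi = (0.0, 1.0) if noisy_scores else (0.9, 1.0)
    edges = sorted(tuple(sorted((names[u], names[v]))) for u, v in g.edges)
    scores = rng.uniform(lo, hi, size=len(edges))
    table = pd.DataFrame(
        {
            "protein1": [e[0] for e in edges],
            "protein2": [e[1] for e in edges],
            "combined_score": scores,
        }
    )
    return SyntheticInteractomeTruth(
        interactions=table, block_of=block_of, p_in=p_in, p_out=p_out, n_blocks=n_blocks
    )


def gen_signature_and_targets(
    truth: SyntheticInteractomeTruth,
    sig_size: int,
    n_targets: int = 4,
    target_distance: int = 1,
    seed: int = 0,
) -> tuple[set[str], dict[str, set[str]]]:
    """Plant a disease signature inside one block and place drug targets.

    The signature is drawn from a single block; each target node is chosen so
    its shortest-path distance to the signature equals ``target_distance``
    (0 places the target inside the signature). Raises
    :class:`InfeasibleDistanceError` when the graph offers too few nodes at
    the requested distance rather than placing targets silently elsewhere.
    """
    if sig_size < 1:
        raise ValueError("sig_size must be positive")
    if n_targets < 1:
        raise ValueError("n_targets must be positive")
    if target_distance < 0:
        raise ValueError("target_distance must be >= 0")

    rng = np.random.default_rng(seed)
    blocks: dict[int, list[str]] = {}
    for node, b in truth.block_of.items():
        blocks.setdefault(b, []).append(node)
    eligible = sorted(b for b, members in blocks.items() if len(members) >= sig_size)
    if not eligible:
        raise ValueError(f"no block has >= {sig_size} nodes")
    block = eligible[rng.integers(len(eligible))]
    members = sorted(blocks[block])
    signature = set(rng.choice(members, size=sig_size, replace=False))

    g = truth.graph()
    dist = nx.multi_source_dijkstra_path_length(g, signature, weight=None)
    if target_distance == 0:
        candidates = sorted(signature)
    else:
        candidates = sorted(n for n, d in dist.items() if d == target_distance)
    if len(candidates) < n_targets:
        raise InfeasibleDistanceError(
            f"only {len(candidates)} nodes at distance {target_distance} "
            f"from the signature; {n_targets} targets requested"
        )
    chosen = rng.choice(candidates, size=n_targets, replace=False)
    labels = list(DRUG_CLASSES) + [f"drug_{i + 1:02d}" for i in range(4, n_targets)]
    targets = {labels[i]: {str(chosen[i])} for i in range(n_targets)}
    return signature, targets


def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 2000,
    n_per_group: int = 4,
    effect_size: float = 1.0,
    d0_true: float = 4.0,
    s0sq_true: float = 0.05,
    n_blocks: int = 10,
    block_size: int = 25,
    p_in: float = 0.25,
    p_out: float = 0.01,
    sig_size: int = 20,
    n_targets: int = 4,
    target_distance: int = 1,
) -> dict:
    """Write one coherent synthetic study to ``outdir`` and return its truth.

    The layers are linked end to end: the planted differential genes are the
    species-A orthologs of species-B genes that map one-to-one onto the
    proteins of the planted disease signature, so running the full pipeline on
    these files should recover the signature block and rank the planted
    targets as proximal.

    Files written: expression.tsv, samples.tsv, hits_ab.tsv, hits_ba.tsv,
    gene2protein.tsv, interactions.tsv, signature.gmt, targets.gmt and a
    truth.json sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731 - per-layer seeds

    net = gen_interactome(n_blocks, block_size, p_in, p_out, seed=sub())
    signature, targets = gen_signature_and_targets(
        net, sig_size=sig_size, n_targets=n_targets,
        target_distance=target_distance, seed=sub(),
    )

    frac_de = sig_size / n_genes
    expr = gen_expression(
        n_genes, n_per_group, frac_de, effect_size,
        d0_true=d0_true, s0sq_true=s0sq_true, seed=sub(),
    )

    # Orthologs for every expression gene; species-B partners carry the
    # one-to-one protein mapping. Planted DE genes map to signature proteins,
    # a random slice of null genes maps to the remaining interactome nodes.
    ab, ba, pairs = gen_hit_tables(n_genes, n_decoys=n_genes, seed=sub())
    a_of_gene = dict(zip(sorted(expr.matrix.index), [a for a, _ in pairs]))
    b_of_a = dict(pairs)

    de_sorted = sorted(expr.de_genes)
    other_genes = sorted(set(expr.matrix.index) - expr.de_genes)
    other_proteins = sorted(set(net.block_of) - signature)
    n_extra = min(len(other_genes), len(other_proteins))
    extra_genes = list(rng.choice(other_genes, size=n_extra, replace=False))

    mapping_rows = [
        (b_of_a[a_of_gene[g]], p) for g, p in zip(de_sorted, sorted(signature))
    ] + [
        (b_of_a[a_of_gene[g]], p) for g, p in zip(extra_genes, other_proteins)
    ]
    gene2protein = pd.DataFrame(mapping_rows, columns=["gene", "protein"]).sort_values(
        "gene", ignore_index=True
    )

    # Expression rows are renamed to their species-A hit-table ids so the
    # orthology stage operates on one namespace.
    matrix = expr.matrix.rename(index=a_of_gene)

    io.write_expression(matrix, outdir / "expression.tsv")
    io.write_sample_sheet(expr.groups, outdir / "samples.tsv")
    io.write_hit_table(ab, outdir / "hits_ab.tsv")
    io.write_hit_table(ba, outdir / "hits_ba.tsv")
    io.write_mapping(gene2protein, outdir / "gene2protein.tsv")
    net.interactions.to_csv(
        outdir / "interactions.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT
    )
    io.write_gmt({"disease_signature": signature}, outdir / "signature.gmt")
    io.write_gmt(targets, outdir / "targets.gmt")

    truth = {
        "seed": seed,
        "signature": sorted(signature),
        "targets": {k: sorted(v) for k, v in targets.items()},
        "de_genes_a_ids": sorted(a_of_gene[g] for g in expr.de_genes),
        "block_of": net.block_of,
        "d0_true": d0_true,
        "s0sq_true": s0sq_true,
        "effect_size": effect_size,
        "target_distance": target_distance,
    }
    io.write_json(truth, outdir / "truth.json")
    return truth
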
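"""End-to-end orchestration: expression -> signature -> network -> drugs.

Stages run in order differential expression -> orthology -> network ->
proximity -> clustering. Any prefix is skippable by supplying its output as
an input: a curated protein signature file bypasses the expression and
orthology stages entirely, which is how a literature-curated disease
characterization (like the 222-protein post-MI set) enters the pipeline.

One global seed is split deterministically into per-stage seeds, every seed
is recorded in the run report, and all outputs are plain text (TSV/JSON), so
identical config + seed reproduce byte-identical results.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cluster import cluster_network
from .diffexpr import FilterParams, run_diffexpr
from .network import (
    DEFAULT_TARGETS,
    build_network,
    load_interactions,
    network_stats,
)
from .orthology import map_set, reciprocal_best_hits
from .proximity import degree_matched_null, mechanism_overlap, rank_all_proteins

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serialized verbatim into the outdir."""

    # inputs (signature mode needs only interactions [+ signature, targets];
    # expression mode needs the first five)
    expression: str | None = None
    samples: str | None = None
    hits_ab: str | None = None
    hits_ba: str | None = None
    gene2protein: str | None = None
    interactions: str | None = None
    signature: str | None = None
    targets: str | None = None
    # stage parameters
    normalize: bool = True
    p_adj_max: float = 0.01
    lfc_min: float = 0.25
    min_score: float = 0.9
    metric: str = "closest"
    n_perm: int = 1000
    radius: int = 1
    k_min: int = 2
    k_max: int = 20
    dim: int = 12
    n_restarts: int = 20
    seed: int = 0
    outdir: str = "netprox_out"
    rank_proteins: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every detectable problem; an empty list means runnable."""
    problems: list[str] = []
    if config.interactions is None:
        problems.append("interactions path is required")
    if config.signature is None:
        needed = ["expression", "samples", "hits_ab", "hits_ba", "gene2protein"]
        for name in needed:
            if getattr(config, name) is None:
                problems.append(
                    f"{name} path is required when no curated signature is given"
                )
    for name in ("expression", "samples", "hits_ab", "hits_ba", "gene2protein",
                 "interactions", "signature", "targets"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name} path does not exist: {p}")
    if not 0.0 < config.min_score <= 1.0:
        problems.append(f"min_score must be in (0, 1], got {config.min_score}")
    if config.p_adj_max <= 0 or config.lfc_min <= 0:
        problems.append("filter thresholds must be positive")
    if config.n_perm < 100:
        problems.append(f"n_perm must be >= 100, got {config.n_perm}")
    if config.metric not in ("closest", "average"):
        problems.append(f"metric must be 'closest' or 'average', got {config.metric!r}")
    if config.radius < 0:
        problems.append("radius must be >= 0")
    if config.k_max - config.k_min + 1 < 4:
        problems.append("clustering K range must span >= 4 values")
    if config.dim < 2:
        problems.append("embedding dim must be >= 2")
    return problems


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4, dtype=np.uint64)
    names = ("diffexpr", "proximity", "ranking", "clustering")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write every artifact under ``config.outdir``.

    Returns the run report (also written as report.json). Raises on the
    first failing stage with the stage name in the message; an
    ``incomplete.marker`` file flags partially written output directories.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "incomplete.marker"
    marker.write_text("run in progress\n")
    config.to_yaml(outdir / "config.yaml")
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "software_version": _version(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": {},
    }

    try:
        signature = _signature_stage(config, outdir, report)
        targets = (
            {k: set(v) for k, v in io.read_gmt(config.targets).items()}
            if config.targets
            else {k: set(v) for k, v in DEFAULT_TARGETS.items()}
        )
        report["counts"]["drug_classes"] = len(targets)

        net, stats = _network_stage(config, signature, targets, outdir, report)
        _proximity_stage(config, net, signature, targets, seeds, outdir, report)
        _clustering_stage(config, net, seeds, outdir, report)
    except Exception as exc:  # annotate the failing stage, keep the marker
        report["error"] = str(exc)
        io.write_json(report, outdir / "report.json")
        raise

    io.write_json(report, outdir / "report.json")
    marker.unlink()
    return report


def _version() -> str:
    from . import __version__

    return __version__


def _signature_stage(config: PipelineConfig, outdir: Path, report: dict) -> set[str]:
    if config.signature:
        signature = io.read_id_set(config.signature)
        report["counts"]["signature_proteins"] = len(signature)
        report["signature_source"] = "curated"
        return signature

    try:
        matrix = io.read_expression(config.expression)
        groups = io.read_sample_sheet(config.samples)
        params = FilterParams(p_adj_max=config.p_adj_max, lfc_min=config.lfc_min)
        results, genes, prior = run_diffexpr(
            matrix, groups, params=params, normalize=config.normalize
        )
    except Exception as exc:
        raise RuntimeError(f"stage diffexpr failed ({config.expression}): {exc}") from exc
    out = results.rename(
        columns={
            "logfc": "logFC", "t_mod": "t", "p_raw": "P.Value", "p_adj": "adj.P.Val"
        }
    )[["gene", "logFC", "t", "P.Value", "adj.P.Val", "passes"]]
    out.to_csv(outdir / "de_results.tsv", sep="\t", index=False,
               float_format=io.FLOAT_FMT)
    report["counts"]["genes_in"] = len(results)
    report["counts"]["genes_passing_filter"] = len(genes)
    report["prior"] = {"d0": prior.d0, "s0sq": prior.s0sq}

    try:
        ab = io.read_hit_table(config.hits_ab)
        ba = io.read_hit_table(config.hits_ba)
        orthologs = reciprocal_best_hits(ab, ba)
        g2p = io.read_mapping(config.gene2protein)
        signature = map_set(genes, g2p, orthologs)
    except Exception as exc:
        raise RuntimeError(f"stage orthology failed ({config.hits_ab}): {exc}") from exc
    pd.DataFrame(orthologs, columns=["id_a", "id_b"]).to_csv(
        outdir / "orthologs.tsv", sep="\t", index=False
    )
    io.write_id_set(signature, outdir / "signature_derived.txt")
    report["counts"]["ortholog_pairs"] = len(orthologs)
    report["counts"]["signature_proteins"] = len(signature)
    report["signature_source"] = "derived"
    if not signature:
        raise RuntimeError("stage orthology failed: derived signature is empty")
    return signature


def _network_stage(config, signature, targets, outdir: Path, report: dict):
    try:
        table = load_interactions(config.interactions, min_score=config.min_score)
        net = build_network(table, signature, targets)
        stats = network_stats(net)
    except Exception as exc:
        raise RuntimeError(f"stage network failed ({config.interactions}): {exc}") from exc
    edges = pd.DataFrame(
        sorted((min(u, v), max(u, v), d["score"]) for u, v, d in
               net.graph.edges(data=True)),
        columns=["protein1", "protein2", "combined_score"],
    )
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False,
                 float_format=io.FLOAT_FMT)
    io.write_json(stats, outdir / "network_stats.json")
    report["counts"]["n_nodes"] = stats["n_nodes"]
    report["counts"]["n_edges"] = stats["n_edges"]
    report["network_stats"] = stats
    return net, stats


def _proximity_stage(config, net, signature, targets, seeds, outdir: Path, report: dict):
    from .network import InteractionNetwork

    # Proximity and the ranked association list are scored over the whole
    # thresholded interactome (the universe): every protein is tested against
    # the signature, not only members of the induced disease network.
    uni = InteractionNetwork(graph=net.universe, universe=net.universe)
    try:
        rows = []
        for drug in sorted(targets):
            res = degree_matched_null(
                uni, targets[drug], signature, n_perm=config.n_perm,
                seed=seeds["proximity"], metric=config.metric,
            )
            rows.append((drug, res.entity, res.d_obs, res.null_mean,
                         res.null_sd, res.z, res.p_emp))
        drug_df = pd.DataFrame(
            rows, columns=["drug", "targets", "d_obs", "null_mean",
                           "null_sd", "z", "p_emp"]
        )
        drug_df.to_csv(outdir / "drug_proximity.tsv", sep="\t", index=False,
                       float_format=io.FLOAT_FMT)

        if config.rank_proteins:
            ranked = rank_all_proteins(
                uni, signature, n_perm=config.n_perm, seed=seeds["ranking"]
            )
            ranked.to_csv(outdir / "ranked_proteins.tsv", sep="\t", index=False,
                          float_format=io.FLOAT_FMT)
            report["counts"]["ranked_proteins"] = len(ranked)

        overlaps = {}
        drugs = sorted(targets)
        for i, da in enumerate(drugs):
            for db in drugs[i + 1:]:
                overlaps[f"{da}|{db}"] = mechanism_overlap(
                    net, targets[da], targets[db], radius=config.radius
                )
        io.write_json(overlaps, outdir / "mechanism_overlap.json")
    except Exception as exc:
        raise RuntimeError(f"stage proximity failed: {exc}") from exc
    report["drug_proximity"] = drug_df.to_dict(orient="records")
    report["mechanism_overlap"] = {
        k: {"jaccard": v["jaccard"], "n_shared": len(v["shared_nodes"])}
        for k, v in overlaps.items()
    }


def _clustering_stage(config, net, seeds, outdir: Path, report: dict):
    # the embedding dimension and K range cannot exceed the network size
    n = net.graph.number_of_nodes()
    dim = min(config.dim, n - 2)
    k_max = min(config.k_max, n - 1)
    if dim < 2 or k_max - config.k_min + 1 < 4:
        logger.warning("network too small to cluster (n=%d)", n)
        report["clustering"] = {"skipped": f"network too small (n={n})"}
        return
    try:
        model = cluster_network(
            net, k_min=config.k_min, k_max=k_max, dim=dim,
            n_restarts=config.n_restarts, seed=seeds["clustering"],
        )
    except Exception as exc:
        raise RuntimeError(f"stage clustering failed: {exc}") from exc
    model.assignment().rename_axis("node").reset_index().to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(model.inertia_curve_.items()), columns=["k", "inertia"]
    ).to_csv(outdir / "inertia_curve.tsv", sep="\t", index=False,
             float_format=io.FLOAT_FMT)
    report["clustering"] = {
        "k_selected": model.k_selected_,
        "embedding_dim": dim,
        "n_clustered_nodes": len(model.nodes_),
    }
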
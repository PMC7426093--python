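"""End-to-end orchestration of the decomposition pipeline.

Stage order mirrors the analysis the package implements: per-sample cell
calling and ambient ("soup") correction, merging, a first broad clustering
round on the clean counts, pooled size factors using the broad populations,
the size-factor band filter, gene fractions, a second clustering round,
marker statistics and (optionally) the ligand-receptor network.  Every
stage is a pure function of its inputs, parameters and seed; a manifest
with parameter and output checksums makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ambient, cluster, lr_network, markers, normalize
from .datatypes import ClusterProfile, ClusterResult, CountMatrix, SoupModel
from .io import read_lr_pairs, read_mtx_triplet

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for a full pipeline run.

    ``samples`` maps sample name to a Matrix-Market triplet directory (the
    raw droplet matrix including empty droplets).  ``empty_ranges`` maps
    sample name to the inclusive [lo, hi] total-UMI window defining its
    empty droplets.
    """

    samples: dict[str, str]
    empty_ranges: dict[str, tuple[int, int]]
    min_cell_umis: int = 350
    max_cell_umis: int = 15_000
    broad_k: int = 6
    broad_merge: dict[int, str] = field(default_factory=dict)
    min_gene_mean: float = 1.0  # detection floor for clustering inputs
    top_expr_fraction: float = 0.2
    round1_gene_fraction: float = 0.2
    round1_variance_threshold: float = 0.85
    round2_gene_fraction: float = 0.15
    round2_variance_threshold: float = 0.95
    final_k: int = 21
    perplexity: float = 30.0
    lr_pairs_file: str | None = None
    k_ligand: int = 13
    k_receptor: int = 14
    lr_alpha: float = 0.01
    run_markers: bool = True
    seed: int = 0
    outdir: str | None = None

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "empty_ranges" in d:
            d["empty_ranges"] = {k: tuple(v) for k, v in d["empty_ranges"].items()}
        if "broad_merge" in d:
            d["broad_merge"] = {int(k): str(v) for k, v in d["broad_merge"].items()}
        return PipelineConfig(**d)


@dataclass
class PipelineResult:
    merged: CountMatrix  # soup-corrected valid cells, all samples
    soup_models: dict[str, SoupModel]
    broad_labels: pd.Series
    theta: pd.Series
    retained: list[str]
    fractions: pd.DataFrame
    clusters: ClusterResult
    assignment: pd.Series
    profile: ClusterProfile
    marker_table: pd.DataFrame | None
    interactions: pd.DataFrame | None
    manifest: dict


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 matrices: dict[str, CountMatrix] | None = None
                 ) -> PipelineResult:
    """Execute all stages; ``matrices`` bypasses file loading for in-memory use."""
    t0 = time.time()
    manifest: dict = {"stages": [], "seed": config.seed,
                      "parameters": {k: str(v) for k, v in vars(config).items()}}

    def stage(name: str):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)
        manifest["stages"].append(name)

    # --- load and per-sample soup correction -----------------------------
    stage("load")
    if matrices is None:
        matrices = {s: read_mtx_triplet(d) for s, d in config.samples.items()}
    corrected = []
    soup_models: dict[str, SoupModel] = {}
    stage("soup_correct")
    for s, m in matrices.items():
        if s not in config.empty_ranges:
            raise ValueError(f"no empty-droplet range configured for sample {s!r}")
        valid = ambient.call_cells(m, config.min_cell_umis, config.max_cell_umis)
        empty = ambient.select_empty_droplets(
            m, {s: config.empty_ranges[s] for s in np.unique(m.sample_of)})
        soup = ambient.estimate_rho(m, empty, valid)
        adj = ambient.adjust_counts(m.subset_barcodes(valid), soup)
        soup_models[s] = soup
        corrected.append(adj)
    merged = CountMatrix.concat(corrected)
    manifest["n_valid_cells"] = merged.n_barcodes

    # --- round 1: broad populations on clean raw counts ------------------
    stage("broad_cluster")
    detected = normalize.filter_genes_by_mean(merged, config.min_gene_mean)
    if len(detected) < 10:
        raise ValueError("fewer than 10 genes pass the detection floor")
    gsel = [merged.gene_index()[g] for g in detected]
    raw_frac = pd.DataFrame(
        merged.to_dense().astype(float)[gsel, :], index=detected,
        columns=merged.barcodes)
    raw_frac = raw_frac / raw_frac.sum(axis=0)
    round1 = cluster.cluster_cells(raw_frac, cluster.ClusterParams(
        top_gene_fraction=config.round1_gene_fraction,
        variance_threshold=config.round1_variance_threshold,
        perplexity=config.perplexity, k=config.broad_k, seed=config.seed))
    broad = pd.Series(
        [config.broad_merge.get(int(a), f"broad{a}") for a in round1.assignment],
        index=merged.barcodes, name="broad")

    # --- size factors, band filter, gene fractions ------------------------
    stage("normalize")
    theta = normalize.compute_pooled_size_factors(
        merged, broad.to_numpy(), top_expr_fraction=config.top_expr_fraction)
    retained = normalize.filter_by_size_factor(theta)
    kept = merged.subset_barcodes(retained)
    fractions = normalize.to_gene_fractions(kept, theta).loc[detected]
    fractions = fractions / fractions.sum(axis=0)

    # --- round 2: final clustering ----------------------------------------
    stage("final_cluster")
    round2 = cluster.cluster_cells(fractions, cluster.ClusterParams(
        top_gene_fraction=config.round2_gene_fraction,
        variance_threshold=config.round2_variance_threshold,
        perplexity=config.perplexity, k=config.final_k, seed=config.seed + 1))
    assignment = pd.Series(round2.assignment, index=retained, name="cluster")

    stage("aggregate")
    profile = cluster.aggregate_cluster_expression(kept, assignment)

    marker_table = None
    if config.run_markers and assignment.nunique() >= 2:
        stage("markers")
        marker_table = markers.test_cluster_markers(
            kept, assignment, pd.Series(kept.sample_of, index=kept.barcodes),
            theta.reindex(retained))

    interactions = None
    if config.lr_pairs_file:
        stage("lr_network")
        pairs = read_lr_pairs(config.lr_pairs_file)
        ligands, receptors, pairs_kept = lr_network.filter_lr_genes(
            pairs, kept, assignment)
        if len(pairs_kept):
            gl = lr_network.group_lr_profiles(
                profile.upm.loc[ligands], min(config.k_ligand, len(ligands)),
                seed=config.seed)
            gr = lr_network.group_lr_profiles(
                profile.upm.loc[receptors], min(config.k_receptor, len(receptors)),
                seed=config.seed + 1)
            conn = lr_network.count_connections(gl, gr, pairs_kept)
            interactions = lr_network.test_interactions(conn, alpha=config.lr_alpha)
        else:
            interactions = pd.DataFrame()

    manifest["checksums"] = {
        "theta": _checksum(theta.to_frame()),
        "assignment": _checksum(assignment.to_frame()),
        "upm": _checksum(profile.upm),
    }
    manifest["runtime_s"] = round(time.time() - t0, 2)

    result = PipelineResult(
        merged=merged, soup_models=soup_models, broad_labels=broad,
        theta=theta, retained=retained, fractions=fractions, clusters=round2,
        assignment=assignment, profile=profile, marker_table=marker_table,
        interactions=interactions, manifest=manifest)
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.theta.to_csv(outdir / "size_factors.csv")
    result.broad_labels.to_csv(outdir / "broad_labels.csv")
    result.assignment.to_csv(outdir / "clusters.csv")
    pd.DataFrame({"rho": result.clusters.rho_density,
                  "delta": result.clusters.delta,
                  "gamma": result.clusters.gamma},
                 index=result.assignment.index).to_csv(outdir / "gamma.csv")
    result.profile.upm.to_csv(outdir / "cluster_upm.csv")
    if result.marker_table is not None:
        result.marker_table.to_csv(outdir / "markers.csv", index=False)
    if result.interactions is not None:
        result.interactions.to_csv(outdir / "interactions.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
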
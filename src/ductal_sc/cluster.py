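"""Dimensionality reduction and density-peak clustering.

The clustering chain is: coefficient-of-variation gene selection -> PCA
keeping the minimal number of components above a cumulative explained-
variance threshold -> t-SNE to 2-D -> density-peak clustering on the 2-D
embedding.  Density-peak clustering ranks each cell by gamma = rho * delta
(local density times distance to the nearest denser cell); the k cells with
the largest gamma are cluster centers, and every other cell joins the
cluster of its nearest denser neighbor, resolved in order of decreasing
density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .datatypes import ClusterProfile, ClusterResult, CountMatrix


@dataclass
class ClusterParams:
    """Parameters for one clustering round."""

    top_gene_fraction: float = 0.2
    variance_threshold: float = 0.85
    perplexity: float = 30.0
    k: int = 6
    seed: int = 0


def select_variable_genes(matrix: pd.DataFrame, top_fraction: float) -> list[str]:
    """Top genes by coefficient of variation (sd/mean across cells).

    ``matrix`` is genes x cells.  Returns the top ``ceil(top_fraction * G)``
    gene names; genes with zero mean are excluded from the ranking.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    vals = matrix.to_numpy(dtype=float)
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, -np.inf)
    n_top = int(np.ceil(top_fraction * matrix.shape[0]))
    order = np.argsort(-cv, kind="stable")
    chosen = [i for i in order[:n_top] if cv[i] > -np.inf]
    return [matrix.index[i] for i in chosen]


def run_pca(matrix: np.ndarray, variance_threshold: float,
            max_components: int | None = None) -> np.ndarray:
    """PCA keeping the minimal PCs whose cumulative variance share exceeds
    the threshold.

    ``matrix`` is cells x features (centered internally).  Degenerate
    thresholds <= 0 return a single component.
    """
    if variance_threshold >= 1.0:
        raise ValueError("variance_threshold must be < 1")
    n, p = matrix.shape
    n_comp = min(n, p, max_components or max(n, p))
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(np.asarray(matrix, dtype=float))
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, max(variance_threshold, 0.0), side="right")) + 1
    n_keep = min(n_keep, n_comp)
    return coords[:, :n_keep]


def run_tsne(pcs: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE of the PC coordinates; deterministic for a fixed seed.

    Duplicate rows are allowed.  Requires at least 3x perplexity cells.
    """
    n = pcs.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; "
            "reduce the perplexity to at most n/3")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="random", learning_rate="auto")
    return tsne.fit_transform(np.asarray(pcs, dtype=float))


def density_peak_cluster(embedding2d: np.ndarray, k: int,
                         dc_percentile: float = 2.0) -> ClusterResult:
    """Density-peak clustering of a 2-D embedding.

    rho_i = sum_j exp(-(d_ij/d_c)^2) with a Gaussian kernel whose bandwidth
    d_c is the ``dc_percentile`` percentile of all pairwise distances (the
    original algorithm's rule of thumb).  delta_i is the distance to the
    nearest cell of higher density (ties in rho broken by index; the global
    density maximum gets the largest pairwise distance).  Centers are the k
    largest gamma = rho * delta (ties by index); all other cells are
    assigned the cluster of their nearest denser neighbor, propagated in
    decreasing-density order.
    """
    pts = np.asarray(embedding2d, dtype=float)
    n = pts.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return ClusterResult(rho_density=np.ones(1), delta=np.zeros(1),
                             gamma=np.zeros(1), centers=np.array([0]),
                             assignment=np.zeros(1, dtype=int), embedding2d=pts)
    condensed = pdist(pts)
    d = squareform(condensed)
    positive = condensed[condensed > 0]
    d_c = np.percentile(positive, dc_percentile) if len(positive) else 1.0
    if d_c == 0:
        d_c = 1.0
    np.fill_diagonal(d, np.inf)
    rho = np.exp(-((d / d_c) ** 2)).sum(axis=1)
    np.fill_diagonal(d, 0.0)

    # ordering: higher rho first, index as tie-break
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    nearest_denser = np.full(n, -1, dtype=int)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = d[i].max()
            continue
        denser = order[:pos]
        j = denser[np.argmin(d[i, denser])]
        delta[i] = d[i, j]
        nearest_denser[i] = j
    gamma = rho * delta

    centers = np.sort(np.lexsort((np.arange(n), -gamma))[:k])
    assignment = np.full(n, -1, dtype=int)
    for cid, c in enumerate(centers):
        assignment[c] = cid
    for i in order:
        if assignment[i] < 0:
            assignment[i] = assignment[nearest_denser[i]]
    return ClusterResult(rho_density=rho, delta=delta, gamma=gamma,
                         centers=centers, assignment=assignment,
                         embedding2d=pts)


def cluster_cells(matrix: pd.DataFrame, params: ClusterParams) -> ClusterResult:
    """Full chain: variable genes -> PCA -> t-SNE -> density peaks.

    ``matrix`` is genes x cells (typically gene fractions).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells to cluster")
    genes = select_variable_genes(matrix, params.top_gene_fraction)
    sub = matrix.loc[genes].to_numpy(dtype=float).T  # cells x genes
    pcs = run_pca(sub, params.variance_threshold)
    emb = run_tsne(pcs, perplexity=params.perplexity, seed=params.seed)
    result = density_peak_cluster(emb, params.k)
    result.barcodes = list(matrix.columns)
    return result


def recluster_subset(matrix: pd.DataFrame, cells: list[str],
                     params: ClusterParams) -> ClusterResult:
    """Re-run the whole clustering chain on a subset of cells only."""
    if len(cells) == 0:
        raise ValueError("cell subset is empty")
    return cluster_cells(matrix[cells], params)


def aggregate_cluster_expression(counts: CountMatrix,
                                 assignment: pd.Series) -> ClusterProfile:
    """Aggregate raw counts per cluster into UMIs-per-million (UPM).

    upm_gk = 1e6 * (sum of gene g counts over cluster k's cells) / (total
    UMIs of cluster k); every column sums to one million.
    """
    assignment = assignment.reindex(counts.barcodes)
    if assignment.isna().any():
        raise ValueError("assignment missing for some barcodes")
    dense = counts.to_dense().astype(float)
    clusters = pd.unique(assignment)
    upm = {}
    n_cells = {}
    for cl in clusters:
        cols = np.flatnonzero((assignment == cl).to_numpy())
        tot = dense[:, cols].sum()
        if tot == 0:
            raise ValueError(f"cluster {cl!r} has no counts")
        upm[cl] = 1e6 * dense[:, cols].sum(axis=1) / tot
        n_cells[cl] = len(cols)
    return ClusterProfile(upm=pd.DataFrame(upm, index=counts.genes),
                          n_cells=pd.Series(n_cells))
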
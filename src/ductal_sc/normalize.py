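"""Size-factor normalization.

Cell size factors (theta) are estimated by pool-and-deconvolve within each
broad cell population: overlapping pools of cells are formed on a ring
(cells ordered by library size), each pool's summed expression over the
top-20%-expressed genes is compared to the population's average profile to
yield one linear equation in the member thetas, and the resulting
overdetermined system is solved by least squares.  Pooling cancels the
zero-inflation of individual cells that makes per-cell ratio estimators
unstable at droplet depths.

After estimation, cells whose factor differs from the mean factor by an
order of magnitude or more are discarded (band filter), and counts are
converted to per-cell gene fractions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .datatypes import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_POOL_SIZES = (21, 41, 61, 81, 101)


def filter_genes_by_mean(counts: CountMatrix, min_mean: float) -> list[str]:
    """Genes whose mean count across cells is at least ``min_mean``.

    Weakly detected genes carry almost pure sampling noise; their
    coefficient of variation scales like 1/sqrt(mean) and would otherwise
    dominate CV-based variable-gene ranking.
    """
    means = np.asarray(counts.X.mean(axis=1)).ravel()
    return [g for g, m in zip(counts.genes, means) if m >= min_mean]


def top_expressed_genes(counts: CountMatrix, fraction: float = 0.2) -> np.ndarray:
    """Indices of the top ``fraction`` of genes by mean count across all cells."""
    means = np.asarray(counts.X.mean(axis=1)).ravel()
    n_top = max(1, int(np.ceil(fraction * counts.n_genes)))
    order = np.argsort(-means, kind="stable")
    return np.sort(order[:n_top])


def _deconvolve_group(x: np.ndarray, pool_sizes: tuple[int, ...],
                      anchor_weight: float) -> np.ndarray:
    """Solve pooled size factors for one group.

    ``x`` is genes x cells (already restricted to high-expression genes).
    Cells are placed on a ring ordered by library size; for every pool size
    w and every ring start, the pooled profile's median ratio to the group
    average profile gives one equation  sum_{c in pool} theta_c = b.  Low
    weight per-cell anchor equations (theta_c = library-size guess) make
    the system full rank.  Returns raw thetas with group mean scaled to 1.
    """
    n = x.shape[1]
    lib = x.sum(axis=0).astype(float)
    ring = np.argsort(lib, kind="stable")
    ref = x.mean(axis=1)
    ok = ref > 0
    sizes = sorted({min(w, n) for w in pool_sizes})

    rows, cols, vals, b = [], [], [], []
    eq = 0
    for w in sizes:
        for start in range(n):
            members = ring[(start + np.arange(w)) % n]
            pooled = x[:, members].sum(axis=1)
            ratios = pooled[ok] / ref[ok]
            b.append(np.median(ratios))
            rows.extend([eq] * w)
            cols.extend(members.tolist())
            vals.extend([1.0] * w)
            eq += 1
    guess = lib / lib.mean() if lib.mean() > 0 else np.ones(n)
    for c in range(n):
        rows.append(eq)
        cols.append(c)
        vals.append(anchor_weight)
        b.append(anchor_weight * guess[c])
        eq += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    theta = spla.lsqr(A, np.asarray(b), atol=1e-12, btol=1e-12)[0]

    pos = theta[theta > 0]
    if len(pos) == 0:
        logger.warning("deconvolution produced no positive factors; "
                       "falling back to library sizes")
        theta = guess.copy()
    elif (theta <= 0).any():
        logger.warning("clamping %d non-positive size factors",
                       int((theta <= 0).sum()))
        theta = np.where(theta > 0, theta, pos.min() * 1e-3)
    return theta / theta.mean()


def compute_pooled_size_factors(counts: CountMatrix,
                                broad_labels: np.ndarray | pd.Series,
                                top_expr_fraction: float = 0.2,
                                pool_sizes: tuple[int, ...] = DEFAULT_POOL_SIZES,
                                min_group_size: int = 20,
                                anchor_weight: float = 0.1) -> pd.Series:
    """Pooled-deconvolution size factors, one per barcode.

    Factors are estimated within each broad population on the top
    ``top_expr_fraction`` expressed genes, then rescaled so each group's
    mean factor equals the ratio of its mean library size to the global
    mean library size (making factors comparable across populations).
    Groups below ``min_group_size`` cells fall back to library-size factors
    with a warning.
    """
    labels = np.asarray(broad_labels)
    if len(labels) != counts.n_barcodes:
        raise ValueError("broad_labels must have one entry per barcode")
    top = top_expressed_genes(counts, top_expr_fraction)
    dense = np.asarray(counts.X[top, :].todense()).astype(float)
    full_lib = counts.totals().astype(float)
    global_mean_lib = full_lib.mean()

    theta = np.empty(counts.n_barcodes)
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_group_size:
            logger.warning("group %r has %d cells (< %d); using library-size "
                           "factors", lab, len(idx), min_group_size)
            t = full_lib[idx] / max(full_lib[idx].mean(), 1e-12)
        else:
            t = _deconvolve_group(dense[:, idx], pool_sizes, anchor_weight)
        theta[idx] = t * (full_lib[idx].mean() / global_mean_lib)
    return pd.Series(theta, index=counts.barcodes, name="theta")


def filter_by_size_factor(theta: pd.Series) -> list[str]:
    """Cells whose factor is within one order of magnitude of the mean.

    Retains c with 0.1 * mean(theta) < theta_c < 10 * mean(theta); the mean
    is over all input cells and the filter is applied once, not iterated.
    Boundary values are excluded (strict inequalities).
    """
    m = float(np.mean(theta))
    keep = (theta > 0.1 * m) & (theta < 10.0 * m)
    return list(theta.index[keep])


def to_gene_fractions(counts: CountMatrix, theta: pd.Series) -> pd.DataFrame:
    """Per-cell gene fractions of size-factor-normalized counts.

    x_gc = (counts_gc / theta_c) / sum_g (counts_gc / theta_c); every
    column sums to 1.  (The per-cell normalizer makes the fractions
    algebraically invariant to theta; theta still matters for the band
    filter and as a DE offset.)
    """
    t = theta.reindex(counts.barcodes)
    if t.isna().any():
        raise ValueError("theta missing for some barcodes")
    dense = counts.to_dense().astype(float)
    totals = dense.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; filter cells first")
    norm = dense / t.to_numpy()[None, :]
    frac = norm / norm.sum(axis=0, keepdims=True)
    return pd.DataFrame(frac, index=counts.genes, columns=counts.barcodes)
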
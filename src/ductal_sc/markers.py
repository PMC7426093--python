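"""Marker statistics: negative-binomial differential expression, fold-
enrichment gene selection, the bulk region-enrichment filter, and the
zero-inflated negative binomial (ZINB) expressing-fraction model.

The per-cluster marker test fits, gene by gene, a negative-binomial
log-linear model

    count_c ~ is_cluster_c + batch_c,   offset log(theta_c * nbar)

where theta is the cell size factor and nbar the mean library size, so the
offset is the expected sequencing depth of the cell.  The gene's dispersion
is estimated by an offset-adjusted method of moments and shrunk toward a
mean-dispersion trend; significance comes from a likelihood-ratio test of
the cluster indicator, with Benjamini-Hochberg correction per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .datatypes import ClusterProfile, CountMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dispersion estimation


def _moment_dispersions(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Offset-adjusted method-of-moments NB dispersion per gene.

    With E[y_gc] = s_c * mu_g and Var = s_c mu_g + alpha_g s_c^2 mu_g^2,
    solving the variance identity for alpha gives the estimator below.
    ``y`` is genes x cells, ``s`` the per-cell expected-depth scale.
    """
    mu = (y / s).mean(axis=1)
    mu = np.maximum(mu, 1e-12)
    resid2 = (y - s * mu[:, None]) ** 2
    num = (resid2 - s * mu[:, None]).sum(axis=1)
    den = ((s ** 2)[None, :] * (mu[:, None] ** 2)).sum(axis=1)
    return np.maximum(num / np.maximum(den, 1e-300), 1e-8)


def _trend_shrink(alpha: np.ndarray, mu: np.ndarray,
                  n_bins: int = 20, weight: float = 0.5) -> np.ndarray:
    """Shrink per-gene dispersions toward a running-median mean trend.

    Genes are binned by log mean abundance; the trend is the median log
    dispersion per bin; shrinkage is a weighted average on the log scale.
    """
    order = np.argsort(mu)
    log_a = np.log(alpha)
    trend = np.empty_like(log_a)
    bins = np.array_split(order, min(n_bins, max(1, len(order) // 10)))
    for b in bins:
        trend[b] = np.median(log_a[b])
    return np.exp(weight * trend + (1 - weight) * log_a)


@dataclass
class MarkerStat:
    gene: str
    cluster: str
    log2_fold_change: float
    p_value: float
    fdr: float


def test_cluster_markers(counts: CountMatrix, assignment: pd.Series,
                         batch: pd.Series | None,
                         theta: pd.Series,
                         clusters: list | None = None) -> pd.DataFrame:
    """Cluster-vs-rest NB differential expression for every gene.

    Returns a DataFrame (gene, cluster, log2_fold_change, p_value, fdr);
    the fold change is cluster versus all other cells on the model scale.
    Clusters with fewer than 3 cells are skipped with a warning; all-zero
    genes get p = 1 and log2FC = 0 by convention.
    """
    assignment = assignment.reindex(counts.barcodes)
    theta = theta.reindex(counts.barcodes)
    if assignment.isna().any() or theta.isna().any():
        raise ValueError("assignment/theta missing for some barcodes")
    if assignment.nunique() < 2:
        raise ValueError("need at least 2 clusters for marker testing")

    y_all = counts.to_dense().astype(float)
    nbar = counts.totals().mean()
    s = theta.to_numpy() * nbar
    offset = np.log(np.maximum(s, 1e-12))

    alpha_raw = _moment_dispersions(y_all, s)
    mu_hat = (y_all / s).mean(axis=1)
    alpha = _trend_shrink(alpha_raw, np.maximum(mu_hat, 1e-12))

    if batch is not None:
        batch = batch.reindex(counts.barcodes)
        bdum = pd.get_dummies(batch, drop_first=True).to_numpy(dtype=float)
    else:
        bdum = np.empty((counts.n_barcodes, 0))

    rows = []
    cluster_ids = clusters if clusters is not None else list(pd.unique(assignment))
    for cl in cluster_ids:
        member = (assignment == cl).to_numpy().astype(float)
        if member.sum() < 3:
            logger.warning("cluster %r has <3 cells; skipped", cl)
            continue
        x_full = np.column_stack([np.ones_like(member), member, bdum])
        x_red = np.column_stack([np.ones_like(member), bdum])
        pvals = np.ones(counts.n_genes)
        lfcs = np.zeros(counts.n_genes)
        for g in range(counts.n_genes):
            y = y_all[g]
            if y.sum() == 0:
                continue
            fam = sm.families.NegativeBinomial(alpha=float(alpha[g]))
            try:
                fit_full = sm.GLM(y, x_full, family=fam, offset=offset).fit()
                fit_red = sm.GLM(y, x_red, family=fam, offset=offset).fit()
                lr = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
                pvals[g] = st.chi2.sf(lr, df=1)
                lfcs[g] = fit_full.params[1] / np.log(2.0)
            except Exception:  # numerical failure on a degenerate gene
                pvals[g] = 1.0
                lfcs[g] = 0.0
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for g in range(counts.n_genes):
            rows.append((counts.genes[g], cl, lfcs[g], pvals[g], fdr[g]))
    return pd.DataFrame(rows, columns=["gene", "cluster", "log2_fold_change",
                                       "p_value", "fdr"])


# ---------------------------------------------------------------------------
# enrichment filters


def select_enriched_genes(profile: ClusterProfile, fold_min: float = 4.0,
                          min_expr: float = 0.0) -> list[str]:
    """Genes enriched at least ``fold_min``-fold in some cluster.

    A gene passes if its maximal cluster UPM is at least ``fold_min`` times
    the mean UPM of the remaining clusters (with a 1-UPM pseudocount in the
    denominator) and at least ``min_expr`` UPM.
    """
    upm = profile.upm.to_numpy(dtype=float)
    if upm.shape[1] < 2:
        raise ValueError("need at least 2 clusters for fold enrichment")
    arg = np.argmax(upm, axis=1)
    mx = upm[np.arange(len(upm)), arg]
    total = upm.sum(axis=1)
    mean_others = (total - mx) / (upm.shape[1] - 1)
    keep = (mx >= fold_min * (mean_others + 1.0)) & (mx >= min_expr)
    return [g for g, k in zip(profile.upm.index, keep) if k]


def select_region_enriched_bulk(bulk_ppm: pd.DataFrame,
                                log2fc_min: float = 2.0,
                                min_ppm: float = 20.0,
                                pseudocount: float = 0.1) -> list[str]:
    """Region-enriched genes from a bulk genes x regions ppm table.

    A gene passes if log2(max region / (per-gene median across regions +
    pseudocount)) >= ``log2fc_min`` and its maximum abundance is at least
    ``min_ppm``.
    """
    vals = bulk_ppm.to_numpy(dtype=float)
    mx = vals.max(axis=1)
    med = np.median(vals, axis=1)
    lfc = np.log2(np.maximum(mx, 1e-300) / (med + pseudocount))
    keep = (lfc >= log2fc_min) & (mx >= min_ppm)
    return [g for g, k in zip(bulk_ppm.index, keep) if k]


# ---------------------------------------------------------------------------
# zero-inflated negative binomial


@dataclass
class ZinbFit:
    """Result of a ZINB maximum-likelihood fit."""

    pi_zero: float
    mu: float
    size: float
    frac_expressing: float
    mean_positive: float
    log_likelihood: float
    loglik_trace: list[float]
    converged: bool
    all_zero: bool = False


def _nb_logpmf(x: np.ndarray, mu: float, size: float) -> np.ndarray:
    p = size / (size + mu)
    return st.nbinom.logpmf(x, size, p)


def fit_zinb(x: np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> ZinbFit:
    """EM fit of the mixture  pi * delta_0 + (1 - pi) * NB(mu, size).

    The structural-zero probability pi separates dropout zeros from NB
    sampling zeros; the expressing fraction is 1 - pi.  ``mean_positive``
    is the mean count over cells with x > 0 (which belong to the NB
    component with posterior probability 1).  The observed-data
    log-likelihood is tracked every iteration and is non-decreasing.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if (x == 0).all():
        return ZinbFit(pi_zero=1.0, mu=0.0, size=1.0, frac_expressing=0.0,
                       mean_positive=0.0, log_likelihood=0.0, loglik_trace=[0.0],
                       converged=True, all_zero=True)

    zero = x == 0
    pos = x[~zero]
    pi = 0.5 * zero.mean()
    mu = pos.mean()
    size = 1.0

    def observed_ll(pi_, mu_, size_):
        nb0 = np.exp(_nb_logpmf(np.zeros(1), mu_, size_))[0]
        ll = zero.sum() * np.log(pi_ + (1 - pi_) * nb0 + 1e-300)
        ll += len(pos) * np.log(max(1 - pi_, 1e-300))
        ll += _nb_logpmf(pos, mu_, size_).sum()
        return ll

    trace = [observed_ll(pi, mu, size)]
    converged = False
    for _ in range(max_iter):
        # E-step: posterior structural-zero probability for observed zeros
        nb0 = np.exp(_nb_logpmf(np.zeros(1), mu, size))[0]
        tau = pi / (pi + (1 - pi) * nb0 + 1e-300)
        # M-step: the NB mean MLE is the weighted mean in closed form,
        # leaving a 1-D profile search over the size parameter
        pi_new = (tau * zero.sum()) / len(x)
        w_zero = 1.0 - tau  # weight of the NB component on zeros
        mu_new = pos.sum() / (len(pos) + w_zero * zero.sum())

        def neg_q(log_size):
            s = np.exp(log_size)
            q = w_zero * zero.sum() * _nb_logpmf(np.zeros(1), mu_new, s)[0]
            q += _nb_logpmf(pos, mu_new, s).sum()
            return -q

        res = opt.minimize_scalar(neg_q, bracket=(np.log(max(size, 1e-6)),
                                                  np.log(max(size, 1e-6)) + 0.5),
                                  method="brent", options={"xtol": 1e-10})
        size_new = float(np.exp(res.x))
        pi, mu, size = pi_new, mu_new, size_new
        trace.append(observed_ll(pi, mu, size))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    return ZinbFit(pi_zero=float(pi), mu=float(mu), size=float(size),
                   frac_expressing=float(1 - pi),
                   mean_positive=float(pos.mean()),
                   log_likelihood=float(trace[-1]), loglik_trace=trace,
                   converged=converged)
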
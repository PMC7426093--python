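"""Ligand-receptor cell-cell interaction inference.

From a curated table of cognate ligand-receptor pairs and a clustered
count matrix, the analysis:

1. keeps ligands/receptors expressed (count > 0) in at least 20% of the
   cells of at least one population, and the pairs whose two ends survive;
2. k-means-clusters the row-normalized per-population expression profiles
   of the surviving ligands (and, separately, receptors), labels each
   k-means cluster by the population where its centroid peaks, and merges
   clusters sharing a label;
3. counts, for every (ligand group, receptor group) combination, how many
   retained pairs connect them;
4. scores each combination with an upper-tail hypergeometric test against
   the group margins: drawing n pairs (the receptor group's column total)
   from N total pairs of which K (the ligand group's row total) involve
   the ligand group, what is the chance of seeing at least the observed
   count?

A related hypergeometric test reports over-representation of a cell type
within a sample (compositional enrichment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix


def filter_lr_genes(lr_pairs: pd.DataFrame, counts: CountMatrix,
                    assignment: pd.Series, min_fraction: float = 0.2
                    ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Keep ligands/receptors expressed by >= ``min_fraction`` of cells in
    at least one population; pairs survive iff both ends do.

    Returns (expressed ligands, expressed receptors, retained pair table).
    """
    if not {"ligand", "receptor"} <= set(lr_pairs.columns):
        raise ValueError("pair table must have 'ligand' and 'receptor' columns")
    assignment = assignment.reindex(counts.barcodes)
    if assignment.isna().any():
        raise ValueError("assignment missing for some barcodes")
    gidx = counts.gene_index()
    expressed: dict[str, bool] = {}
    groups = {cl: np.flatnonzero((assignment == cl).to_numpy())
              for cl in pd.unique(assignment)}
    for gene in pd.unique(pd.concat([lr_pairs["ligand"], lr_pairs["receptor"]])):
        gi = gidx.get(gene)
        if gi is None:
            expressed[gene] = False
            continue
        row = np.asarray(counts.X[gi, :].todense()).ravel()
        expressed[gene] = any(
            (row[cols] > 0).mean() >= min_fraction for cols in groups.values())
    ligands = sorted({g for g in lr_pairs["ligand"] if expressed[g]})
    receptors = sorted({g for g in lr_pairs["receptor"] if expressed[g]})
    keep = lr_pairs["ligand"].isin(ligands) & lr_pairs["receptor"].isin(receptors)
    return ligands, receptors, lr_pairs.loc[keep].drop_duplicates().reset_index(drop=True)


def group_lr_profiles(upm: pd.DataFrame, k: int, seed: int = 0,
                      n_restarts: int = 50) -> pd.Series:
    """Group genes by k-means on row-normalized per-population profiles.

    ``upm`` is genes x populations aggregated expression.  Each k-means
    cluster is labeled by the population where its centroid is maximal
    (ties broken by column order) and clusters sharing a label are merged,
    so the returned ``gene -> group`` map uses population names as group
    labels and may have fewer than k groups.
    """
    if k > len(upm):
        raise ValueError(f"k={k} exceeds number of genes ({len(upm)})")
    vals = upm.to_numpy(dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    norm = np.divide(vals, totals, out=np.zeros_like(vals), where=totals > 0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(norm)
    pop_of_cluster = {c: upm.columns[int(np.argmax(km.cluster_centers_[c]))]
                      for c in range(k)}
    return pd.Series([pop_of_cluster[c] for c in labels], index=upm.index,
                     name="group")


def count_connections(groups_l: pd.Series, groups_r: pd.Series,
                      lr_pairs: pd.DataFrame) -> pd.DataFrame:
    """Connection counts: entry (A, B) = number of pairs with the ligand in
    group A and the receptor in group B.  The total equals the number of
    pairs."""
    for gene in lr_pairs["ligand"]:
        if gene not in groups_l.index:
            raise ValueError(f"ligand {gene!r} has no group assignment")
    for gene in lr_pairs["receptor"]:
        if gene not in groups_r.index:
            raise ValueError(f"receptor {gene!r} has no group assignment")
    rows = sorted(groups_l.unique())
    cols = sorted(groups_r.unique())
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for lig, rec in zip(lr_pairs["ligand"], lr_pairs["receptor"]):
        mat.loc[groups_l[lig], groups_r[rec]] += 1
    return mat


def test_interactions(connections: pd.DataFrame, alpha: float = 0.01,
                      bh_correct: bool = False) -> pd.DataFrame:
    """Hypergeometric enrichment of each (ligand group, receptor group) cell.

    For entry (A, B) with N total pairs, row total K, column total n and
    observed k: p = P[X >= k], X ~ Hypergeom(N, K, n); expected = K n / N.
    ``significant`` flags raw p < ``alpha``; optional Benjamini-Hochberg
    correction across entries replaces p with adjusted values (off by
    default, matching the raw-threshold convention).
    """
    N = int(connections.to_numpy().sum())
    row_tot = connections.sum(axis=1)
    col_tot = connections.sum(axis=0)
    rows = []
    for a in connections.index:
        for b in connections.columns:
            k = int(connections.loc[a, b])
            K = int(row_tot[a])
            n = int(col_tot[b])
            if N == 0:
                p, exp = 1.0, 0.0
            else:
                p = float(st.hypergeom.sf(k - 1, N, K, n))
                exp = K * n / N
            rows.append((a, b, k, exp, p))
    out = pd.DataFrame(rows, columns=["ligand_group", "receptor_group",
                                      "observed_pairs", "expected_pairs",
                                      "p_value"])
    if bh_correct and len(out):
        out["p_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] < alpha
    return out


def test_composition_enrichment(assignment: pd.Series,
                                sample_labels: pd.Series) -> pd.DataFrame:
    """Hypergeometric over-representation of each cell type in each sample.

    Population = all cells, successes = cells of the type, draws = cells of
    the sample, observed = cells of the type in the sample; upper-tail p.
    """
    assignment, sample_labels = assignment.align(sample_labels, join="inner")
    if len(assignment) == 0:
        raise ValueError("no overlapping cells between assignment and samples")
    N = len(assignment)
    rows = []
    for ct in sorted(pd.unique(assignment)):
        K = int((assignment == ct).sum())
        for s in sorted(pd.unique(sample_labels)):
            n = int((sample_labels == s).sum())
            k = int(((assignment == ct) & (sample_labels == s)).sum())
            p = float(st.hypergeom.sf(k - 1, N, K, n))
            rows.append((ct, s, k, K * n / N, p))
    return pd.DataFrame(rows, columns=["cell_type", "sample", "observed",
                                       "expected", "p_value"])
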
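"""Self-verification benchmarks on synthetic data.

Every pipeline stage is exercised against planted ground truth at a scale
that runs in seconds: UMI collapse against the exhaustive pairwise oracle,
soup estimation/correction against a known ambient budget, size factors
against planted scalings, clustering against planted cell types, the NB
marker test against null and planted-marker simulations, the ZINB fit
against known mixture parameters, and the ligand-receptor enrichment
against planted and randomized pairings.  Each function returns a plain
dict of measured quantities; thresholds live with the callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import ambient, lr_network, markers, normalize, umi
from .cluster import aggregate_cluster_expression
from .datatypes import CountMatrix
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import (LRProgram, SimConfig, generate_droplets,
                        generate_truth, plant_lr_programs, simulate_dataset)

_DNA = "ACGT"


def umi_collapse_oracle_check(seed: int, n_groups: int = 500,
                              max_umis: int = 30) -> dict:
    """Fast collapse vs the exhaustive O(n^2) pairwise-hamming reference."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        n = int(rng.integers(1, max_umis + 1))
        umis = set()
        while len(umis) < n:
            umis.add("".join(rng.choice(list(_DNA), 6)))
        for u in umis:
            reads = 1 if rng.random() < 0.5 else int(rng.integers(2, 9))
            rows.append((f"bc{g}", "gene", u, reads))
    table = pd.DataFrame(rows, columns=["barcode", "gene", "umi", "reads"])
    fast = umi.collapse_umis(table)
    slow = umi.collapse_umis_bruteforce(table)
    key = ["barcode", "gene", "umi"]
    f = fast.sort_values(key).reset_index(drop=True)
    s = slow.sort_values(key).reset_index(drop=True)
    agree = np.zeros(n_groups, dtype=bool)
    fg = dict(tuple(f.groupby("barcode", sort=False)))
    sg = dict(tuple(s.groupby("barcode", sort=False)))
    for i, g in enumerate(f["barcode"].unique()):
        agree[i] = fg[g].reset_index(drop=True).equals(sg[g].reset_index(drop=True))
    return {
        "agreement_pct": 100.0 * agree.mean(),
        "reads_conserved": bool(fast["reads"].sum() == table["reads"].sum()),
        "n_groups": n_groups,
    }


def contamination_recovery(seed: int, budget: int = 150,
                           samples: tuple[str, ...] = ("caput", "corpus",
                                                       "cauda", "vas")) -> dict:
    """Four-sample soup recovery: modal budget, foreign-marker removal, TV.

    The simulation uses a fixed ambient budget per droplet and exclusive
    marker programs (markers absent outside their own type), so any
    foreign-marker signal in a cell is pure soup.  A compact gene panel
    keeps the per-gene ambient expectation above ~1 UMI, the regime in
    which a per-cell corrector can attribute counts (see docs/methods.md).
    """
    cfg = SimConfig(seed=seed, n_genes=80, markers_per_type=6,
                    exclusive_markers=True, soup_umis_per_droplet=budget,
                    empty_umi_mean=budget, n_empty_droplets=8000,
                    cells_per_type=60)
    truths, counts = simulate_dataset(cfg, list(samples))
    valid = ambient.call_cells(counts, min_umis=700)
    ranges = {s: (int(budget * 0.6), int(budget * 1.4)) for s in samples}
    empty = ambient.select_empty_droplets(counts, ranges)
    soup = ambient.estimate_rho(counts, empty, valid)
    sub = counts.subset_barcodes(valid)
    adj = ambient.adjust_counts(sub, soup, seed=seed)

    raw, ad = sub.to_dense(), adj.to_dense()
    gidx = {g: i for i, g in enumerate(counts.genes)}
    lookup = {b: (t, i) for t in truths for i, b in enumerate(t.barcodes)}
    labels = {b: lookup[b][0].cell_type_labels[lookup[b][1]] for b in valid}
    marker_sets = truths[0].marker_sets

    reductions, tv_raw, tv_adj = [], [], []
    for t in marker_sets:
        cols = [j for j, b in enumerate(valid) if labels[b] == t]
        foreign = [gidx[g] for t2, gs in marker_sets.items()
                   if t2 != t for g in gs]
        reductions.append(1.0 - ad[np.ix_(foreign, cols)].mean()
                          / raw[np.ix_(foreign, cols)].mean())
        q = np.zeros(len(counts.genes))
        for j in cols:
            tr, i = lookup[valid[j]]
            q += np.asarray(tr.endogenous_counts[:, i].todense()).ravel()
        q /= q.sum()
        p = raw[:, cols].sum(axis=1).astype(float)
        tv_raw.append(0.5 * np.abs(p / p.sum() - q).sum())
        p = ad[:, cols].sum(axis=1).astype(float)
        tv_adj.append(0.5 * np.abs(p / p.sum() - q).sum())

    return {
        "mode_abs_error_max": max(abs(m - budget)
                                  for m in soup.modal_empty_umis.values()),
        "modal_umis": dict(soup.modal_empty_umis),
        "foreign_marker_reduction_pct": 100.0 * float(np.mean(reductions)),
        "tv_raw_mean": float(np.mean(tv_raw)),
        "tv_adjusted_mean": float(np.mean(tv_adj)),
        "all_tv_improved": bool(all(a < r for a, r in zip(tv_adj, tv_raw))),
        "n_cells": len(valid),
    }


def size_factor_recovery(seed: int, n_genes: int = 500,
                         n_cells: int = 300) -> dict:
    """Planted per-cell scalings with multinomial resampling noise."""
    rng = np.random.default_rng(seed)
    ref = rng.gamma(2, 1, n_genes) + 0.05
    ref /= ref.sum()
    s = rng.lognormal(0, 0.5, n_cells)
    X = np.stack([rng.multinomial(int(round(2000 * sc)), ref) for sc in s],
                 axis=1)
    import scipy.sparse as sp
    cm = CountMatrix(genes=[f"g{i}" for i in range(n_genes)],
                     barcodes=[f"b{i}" for i in range(n_cells)],
                     X=sp.csr_matrix(X),
                     sample_of=np.full(n_cells, "s1", dtype=object))
    theta = normalize.compute_pooled_size_factors(cm, np.full(n_cells, "p"))
    r = float(np.corrcoef(theta.to_numpy(), s)[0, 1])

    # adversarial band-filter vectors, including exact boundary values
    adversarial = pd.Series(np.concatenate([
        rng.lognormal(0, 2, 200), [1e-8, 1e8, 0.4 / 4.9]]))
    m = adversarial.mean()
    expected = [c for c in adversarial.index
                if 0.1 * m < adversarial[c] < 10 * m]
    band_exact = normalize.filter_by_size_factor(adversarial) == expected
    return {"pearson_r": r, "band_filter_exact": bool(band_exact),
            "n_cells": n_cells}


def clustering_recovery(seed: int) -> dict:
    """End-to-end pipeline ARI on six planted types (marker fold 8)."""
    cfg = SimConfig(seed=seed)
    truth = generate_truth(cfg)
    _, counts = generate_droplets(truth, cfg, with_reads=False)
    pcfg = PipelineConfig(samples={}, empty_ranges={"sample1": (20, 175)},
                          broad_k=6, final_k=6, run_markers=False, seed=seed)
    result = run_pipeline(pcfg, matrices={"sample1": counts})
    bidx = {b: i for i, b in enumerate(truth.barcodes)}
    labels = [truth.cell_type_labels[bidx[b]] for b in result.assignment.index]
    return {"ari": float(adjusted_rand_score(labels,
                                             result.assignment.to_numpy())),
            "n_cells": len(labels)}


def _nb_de_simulation(rng, n_genes, n_cells, n_markers, fold=8.0,
                      frac_in=0.1, alpha=0.3):
    s = rng.lognormal(0, 0.3, n_cells)
    mu = rng.gamma(2, 0.5, n_genes) + 0.2
    n_in = int(frac_in * n_cells)
    cl = np.array(["c1"] * n_in + ["c0"] * (n_cells - n_in))
    batch = np.tile(["b1", "b2"], n_cells // 2)
    size = 1.0 / alpha
    X = np.empty((n_genes, n_cells), dtype=np.int64)
    for g in range(n_genes):
        m = mu[g] * s
        if g < n_markers:
            m = m * np.where(cl == "c1", fold, 1.0)
        X[g] = rng.negative_binomial(size, size / (size + m))
    import scipy.sparse as sp
    cm = CountMatrix(genes=[f"g{i}" for i in range(n_genes)],
                     barcodes=[f"b{i}" for i in range(n_cells)],
                     X=sp.csr_matrix(X), sample_of=np.asarray(batch, dtype=object))
    return (cm, pd.Series(cl, index=cm.barcodes),
            pd.Series(batch, index=cm.barcodes),
            pd.Series(s / s.mean(), index=cm.barcodes))


def marker_calibration(seed: int, n_null_genes: int = 2000) -> dict:
    """Type-I error under an NB null and power on planted 8-fold markers."""
    rng = np.random.default_rng(seed)
    cm, cl, batch, theta = _nb_de_simulation(rng, n_null_genes, 400, 0,
                                             frac_in=0.5)
    null = markers.test_cluster_markers(cm, cl, batch, theta, clusters=["c1"])
    type1 = float((null.p_value < 0.05).mean())

    cm, cl, batch, theta = _nb_de_simulation(rng, 300, 1000, 50)
    planted = markers.test_cluster_markers(cm, cl, batch, theta,
                                           clusters=["c1"]).iloc[:50]
    return {
        "type1_rate_alpha05": type1,
        "n_null_genes": n_null_genes,
        "power_fdr01": float((planted.fdr < 0.01).mean()),
        "log2fc_mean": float(planted.log2_fold_change.mean()),
    }


def zinb_recovery(seed: int, n_reps: int = 50, pi: float = 0.4,
                  mu: float = 5.0, size: float = 2.0, n: int = 2000) -> dict:
    rng = np.random.default_rng(seed)
    errs, monotone = [], True
    for _ in range(n_reps):
        z = rng.random(n) < pi
        x = np.where(z, 0,
                     rng.negative_binomial(size, size / (size + mu), n))
        fit = markers.fit_zinb(x.astype(float))
        errs.append(abs(fit.pi_zero - pi))
        if (np.diff(fit.loglik_trace) < -1e-6).any():
            monotone = False
    return {"mean_abs_pi_error": float(np.mean(errs)),
            "loglik_monotone": monotone, "n_reps": n_reps}


def _lr_simulation(seed: int, plant: bool):
    """Planted sender/receiver programs over a type-structured background.

    Background ligands and receptors are drawn from the cell types' marker
    programs, mirroring real ligand-receptor panels whose members are
    population-restricted; their pairs scatter across sender/receiver
    group combinations while the planted pairs concentrate on one."""
    cfg = SimConfig(seed=seed, n_genes=400, n_cell_types=8, cells_per_type=40,
                    markers_per_type=20, n_empty_droplets=5)
    truth = generate_truth(cfg)
    rng = np.random.default_rng(seed + 1)
    lig = [f"G{i:04d}" for i in range(350, 360)]
    rec = [f"G{i:04d}" for i in range(360, 370)]
    marker_pool = rng.permutation(
        [g for gs in truth.marker_sets.values() for g in gs])
    pairs = pd.DataFrame({"ligand": lig + list(marker_pool[:50]),
                          "receptor": rec + list(marker_pool[50:100])})
    if plant:
        truth = plant_lr_programs(truth, pairs,
                                  [LRProgram("type0", "type1", lig, rec)])
    _, counts = generate_droplets(truth, cfg, with_reads=False)
    sub = counts.subset_barcodes(truth.barcodes)
    assignment = pd.Series(truth.cell_type_labels, index=truth.barcodes)
    return pairs, sub, assignment


def lr_detection(seed: int, n_reps: int = 50) -> dict:
    """Planted sender/receiver programs flagged; shuffled pairings as null."""
    detected = 0
    for rep in range(n_reps):
        pairs, sub, assignment = _lr_simulation(seed + 17 * rep, plant=True)
        ligs, recs, kept = lr_network.filter_lr_genes(pairs, sub, assignment)
        profile = aggregate_cluster_expression(sub, assignment)
        gl = lr_network.group_lr_profiles(profile.upm.loc[ligs],
                                          min(13, len(ligs)), seed=seed)
        gr = lr_network.group_lr_profiles(profile.upm.loc[recs],
                                          min(14, len(recs)), seed=seed + 1)
        conn = lr_network.count_connections(gl, gr, kept)
        tab = lr_network.test_interactions(conn)
        hit = tab[(tab.ligand_group == "type0")
                  & (tab.receptor_group == "type1")]
        if len(hit) and bool(hit.significant.iloc[0]):
            detected += 1

    # null: randomized re-pairings of the expressed genes on one dataset
    rng = np.random.default_rng(seed + 999)
    pairs, sub, assignment = _lr_simulation(seed, plant=False)
    ligs, recs, kept = lr_network.filter_lr_genes(pairs, sub, assignment)
    profile = aggregate_cluster_expression(sub, assignment)
    gl = lr_network.group_lr_profiles(profile.upm.loc[ligs],
                                      min(13, len(ligs)), seed=seed)
    gr = lr_network.group_lr_profiles(profile.upm.loc[recs],
                                      min(14, len(recs)), seed=seed + 1)
    sig, total = 0, 0
    for _ in range(n_reps):
        shuffled = pd.DataFrame({
            "ligand": rng.choice(ligs, len(kept)),
            "receptor": rng.choice(recs, len(kept))})
        conn = lr_network.count_connections(gl, gr, shuffled)
        tab = lr_network.test_interactions(conn)
        sig += int(tab.significant.sum())
        total += len(tab)
    return {"planted_detection_rate": detected / n_reps,
            "null_significant_fraction": sig / total,
            "n_reps": n_reps}


def composition_bias(seed: int) -> dict:
    """Planted 5x over-representation of one type in one sample."""
    rng = np.random.default_rng(seed)
    n, base = 4000, 0.05
    samples = np.repeat(["s1", "s2", "s3", "s4"], n // 4)
    p = np.where(samples == "s4", 5 * base, base * 2 / 3)
    assign = np.where(rng.random(n) < p, "macrophage", "other")
    tab = lr_network.test_composition_enrichment(pd.Series(assign),
                                                 pd.Series(samples))
    row = tab[(tab.cell_type == "macrophage") & (tab["sample"] == "s4")]
    return {"p_value": float(row.p_value.iloc[0]), "n_cells": n}


def filter_rule_exactness(seed: int) -> dict:
    """Brute-force equality checks for every hard filter rule."""
    rng = np.random.default_rng(seed)
    checks = {}

    totals = rng.integers(0, 20000, 400)
    totals[:4] = [349, 350, 15000, 15001]
    import scipy.sparse as sp
    cm = CountMatrix(genes=["g"], barcodes=[f"b{i}" for i in range(400)],
                     X=sp.csr_matrix(totals[None, :]),
                     sample_of=np.full(400, "s1", dtype=object))
    want = {b for b, t in zip(cm.barcodes, totals) if 350 <= t <= 15000}
    checks["call_cells"] = set(ambient.call_cells(cm)) == want

    ranges = {"caput": (20, 175), "corpus": (20, 150),
              "cauda": (20, 150), "vas": (20, 115)}
    totals = rng.integers(0, 250, 400)
    samples = rng.choice(list(ranges), 400)
    cm = CountMatrix(genes=["g"], barcodes=[f"b{i}" for i in range(400)],
                     X=sp.csr_matrix(totals[None, :]),
                     sample_of=samples.astype(object))
    want = {b for b, s, t in zip(cm.barcodes, samples, totals)
            if ranges[s][0] <= t <= ranges[s][1]}
    checks["empty_ranges"] = set(
        ambient.select_empty_droplets(cm, ranges)) == want

    genes = [f"g{i}" for i in range(30)]
    X = rng.poisson(0.4, (30, 90))
    cm = CountMatrix(genes=genes, barcodes=[f"b{i}" for i in range(90)],
                     X=sp.csr_matrix(X), sample_of=np.full(90, "s1", dtype=object))
    assign = pd.Series(rng.choice(["a", "b", "c"], 90), index=cm.barcodes)
    pairs = pd.DataFrame({"ligand": genes[:15], "receptor": genes[15:]})
    ligs, recs, _ = lr_network.filter_lr_genes(pairs, cm, assign)

    def expressed(g):
        gi = genes.index(g)
        return any((X[gi, (assign == p).to_numpy()] > 0).mean() >= 0.2
                   for p in ("a", "b", "c"))

    checks["lr_20pct"] = (ligs == sorted(g for g in genes[:15] if expressed(g))
                          and recs == sorted(g for g in genes[15:]
                                             if expressed(g)))

    from .datatypes import ClusterProfile
    arr = rng.gamma(1, 300, (100, 6))
    prof = ClusterProfile(
        upm=pd.DataFrame(arr, index=[f"g{i}" for i in range(100)]),
        n_cells=pd.Series(1, index=range(6)))
    got = markers.select_enriched_genes(prof, fold_min=4)
    want = [f"g{i}" for i in range(100)
            if arr[i].max() >= 4 * (np.delete(arr[i], arr[i].argmax()).mean()
                                    + 1.0)]
    checks["fourfold_enrichment"] = got == want

    arr = rng.gamma(1, 30, (100, 4))
    tab = pd.DataFrame(arr, index=[f"g{i}" for i in range(100)])
    got = markers.select_region_enriched_bulk(tab)
    want = [f"g{i}" for i in range(100)
            if np.log2(arr[i].max() / (np.median(arr[i]) + 0.1)) >= 2
            and arr[i].max() >= 20]
    checks["bulk_region_filter"] = got == want
    return {k: bool(v) for k, v in checks.items()}


def upm_normalization_check(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    import scipy.sparse as sp
    X = rng.poisson(4, (50, 80)) + 1
    cm = CountMatrix(genes=[f"g{i}" for i in range(50)],
                     barcodes=[f"b{i}" for i in range(80)],
                     X=sp.csr_matrix(X), sample_of=np.full(80, "s1", dtype=object))
    assign = pd.Series(rng.integers(0, 6, 80), index=cm.barcodes)
    prof = aggregate_cluster_expression(cm, assign)
    dev = np.abs(prof.upm.sum(axis=0).to_numpy() - 1e6)
    return {"max_column_deviation": float(dev.max()),
            "n_clusters": prof.upm.shape[1]}
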
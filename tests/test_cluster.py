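"""Variable genes, PCA component choice, t-SNE, density peaks, UPM."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from conftest import make_count_matrix
from ductal_sc.cluster import (ClusterParams, aggregate_cluster_expression,
                               cluster_cells, density_peak_cluster,
                               recluster_subset, run_pca, run_tsne,
                               select_variable_genes)


class TestVariableGenes:
    def test_ceiling_count(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(5, (10, 20)).astype(float))
        assert len(select_variable_genes(m, 0.2)) == 2

    def test_constant_gene_ranks_below_any_varying_gene(self):
        m = pd.DataFrame([[5.0] * 6, [1, 9, 1, 9, 1, 9]], index=["flat", "var"])
        assert select_variable_genes(m, 0.5) == ["var"]

    def test_zero_mean_genes_excluded(self):
        m = pd.DataFrame([[0.0] * 4, [1, 2, 3, 4]], index=["zero", "ok"])
        assert "zero" not in select_variable_genes(m, 1.0)

    def test_matches_bruteforce_cv_ranking(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.gamma(2, 2, (50, 100)),
                         index=[f"g{i}" for i in range(50)])
        got = select_variable_genes(m, 0.3)
        cv = (m.std(axis=1, ddof=0) / m.mean(axis=1)).to_numpy()
        want = [m.index[i] for i in np.argsort(-cv, kind="stable")[:15]]
        assert got == want


def _matrix_with_exact_variance_shares(shares, n=40, seed=0):
    """Cells x features matrix whose PCA explained-variance ratios equal
    ``shares`` exactly (constructed from an exact SVD)."""
    rng = np.random.default_rng(seed)
    p = len(shares)
    raw = rng.normal(size=(n, p))
    raw -= raw.mean(axis=0)  # orthogonal to the ones vector
    u, _ = np.linalg.qr(raw)
    v, _ = np.linalg.qr(rng.normal(size=(p, p)))
    sing = np.sqrt(np.asarray(shares))
    return (u[:, :p] * sing) @ v.T


class TestPca:
    def test_minimal_components_over_threshold(self):
        m = _matrix_with_exact_variance_shares([0.5, 0.3, 0.1, 0.06, 0.04])
        assert run_pca(m, 0.85).shape[1] == 3

    def test_degenerate_threshold_gives_one_component(self):
        m = _matrix_with_exact_variance_shares([0.6, 0.4])
        assert run_pca(m, 0.0).shape[1] == 1

    def test_exact_low_rank(self):
        m = _matrix_with_exact_variance_shares([0.7, 0.3])
        assert run_pca(m, 0.99).shape[1] == 2


class TestTsne:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        pcs = rng.normal(size=(120, 5))
        assert np.array_equal(run_tsne(pcs, 30, seed=7),
                              run_tsne(pcs, 30, seed=7))

    def test_too_few_cells_suggests_smaller_perplexity(self):
        with pytest.raises(ValueError, match="perplexity"):
            run_tsne(np.zeros((10, 3)), perplexity=30)

    def test_duplicate_rows_allowed(self):
        pcs = np.tile(np.arange(10.0)[:, None], (12, 3))
        out = run_tsne(pcs, perplexity=10, seed=0)
        assert out.shape == (120, 2)

    def test_separated_blobs_stay_separable(self):
        rng = np.random.default_rng(3)
        pcs = np.vstack([rng.normal(0, 1, (150, 4)),
                         rng.normal(12, 1, (150, 4))])
        emb = run_tsne(pcs, 30, seed=1)
        labels = [0] * 150 + [1] * 150
        assert silhouette_score(emb, labels) > 0.5


def _reference_density_peaks(pts, k, dc_percentile=2.0):
    """Independent naive implementation used as an oracle."""
    n = len(pts)
    d = squareform(pdist(pts))
    dc = np.percentile(pdist(pts)[pdist(pts) > 0], dc_percentile)
    rho = np.array([sum(np.exp(-((d[i, j] / dc) ** 2))
                        for j in range(n) if j != i) for i in range(n)])
    denser = lambda i, j: (rho[j], -j) > (rho[i], -i)
    delta = np.empty(n)
    uphill = np.full(n, -1)
    for i in range(n):
        cands = [j for j in range(n) if denser(i, j)]
        if not cands:
            delta[i] = d[i].max()
        else:
            uphill[i] = min(cands, key=lambda j: d[i, j])
            delta[i] = d[i, uphill[i]]
    gamma = rho * delta
    centers = sorted(sorted(range(n), key=lambda i: (-gamma[i], i))[:k])
    assign = np.full(n, -1)
    for cid, c in enumerate(centers):
        assign[c] = cid
    for i in sorted(range(n), key=lambda i: (-rho[i], i)):
        if assign[i] < 0:
            assign[i] = assign[uphill[i]]
    return rho, delta, gamma, centers, assign


class TestDensityPeaks:
    # two tight pairs far apart, plus one outlier between them
    FIVE = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0],
                     [5.0, 4.0]])

    def test_five_point_configuration_matches_reference(self):
        res = density_peak_cluster(self.FIVE, 2)
        rho, delta, gamma, centers, assign = _reference_density_peaks(self.FIVE, 2)
        assert np.allclose(res.rho_density, rho)
        assert np.allclose(res.delta, delta)
        assert np.allclose(res.gamma, gamma)
        assert list(res.centers) == centers
        assert adjusted_rand_score(res.assignment, assign) == 1.0
        # the two dense-pair members carry the top gamma values
        assert set(res.centers) <= {0, 1, 2, 3}

    def test_gamma_is_rho_times_delta_and_max_delta_rule(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(60, 2))
        res = density_peak_cluster(pts, 4)
        assert np.allclose(res.gamma, res.rho_density * res.delta)
        top = np.argmax(res.rho_density)
        d = squareform(pdist(pts))
        assert res.delta[top] == pytest.approx(d[top].max())

    def test_k1_single_cluster_centered_on_density_peak(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 2))
        res = density_peak_cluster(pts, 1)
        assert set(res.assignment) == {0}
        assert res.centers[0] == np.argmax(res.rho_density)

    def test_assignment_is_partition_with_centers_in_own_cluster(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(80, 2))
        res = density_peak_cluster(pts, 5)
        assert set(res.assignment) == set(range(5))
        for cid, c in enumerate(res.centers):
            assert res.assignment[c] == cid

    def test_random_configurations_match_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.normal(size=(25, 2))
            k = int(rng.integers(1, 5))
            res = density_peak_cluster(pts, k)
            rho, delta, gamma, centers, assign = _reference_density_peaks(pts, k)
            assert np.allclose(res.rho_density, rho)
            assert np.allclose(res.delta, delta)
            assert list(res.centers) == centers
            assert adjusted_rand_score(res.assignment, assign) == 1.0

    def test_two_planted_blobs_fully_recovered(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.5, (200, 2)),
                         rng.normal(8, 0.5, (200, 2))])
        res = density_peak_cluster(pts, 2)
        labels = [0] * 200 + [1] * 200
        assert adjusted_rand_score(labels, res.assignment) == 1.0

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            density_peak_cluster(np.zeros((3, 2)), 4)


class TestRecluster:
    def test_full_subset_equals_direct_run(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.gamma(2, 1, (40, 150)),
                         columns=[f"c{i}" for i in range(150)])
        params = ClusterParams(k=3, perplexity=20, seed=2)
        direct = cluster_cells(m, params)
        sub = recluster_subset(m, list(m.columns), params)
        assert np.array_equal(direct.assignment, sub.assignment)

    def test_single_cell_subset_rejected(self):
        m = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            recluster_subset(m, ["a"], ClusterParams())

    def test_substructure_revealed_on_recluster(self):
        """Two sub-populations inside one coarse type separate when that
        type is re-clustered, though the coarse run lumps them."""
        rng = np.random.default_rng(10)
        n = 120
        base = np.zeros((30, 3 * n))
        base[0:10, :n] = 50          # type A, subtype A1
        base[0:10, n:2 * n] = 50     # type A, subtype A2
        base[10:15, n:2 * n] = 30    # A2-specific block
        base[20:30, 2 * n:] = 50     # type B
        m = pd.DataFrame(base + rng.poisson(3, base.shape),
                         columns=[f"c{i}" for i in range(3 * n)])
        params = ClusterParams(k=2, perplexity=30, seed=3,
                               variance_threshold=0.6)
        coarse = cluster_cells(m, params)
        a_cells = [c for c, a in zip(m.columns, coarse.assignment)
                   if a == coarse.assignment[0]]
        sub = recluster_subset(m, a_cells, ClusterParams(
            k=2, perplexity=25, seed=3, variance_threshold=0.6))
        true_sub = [0 if int(c[1:]) < n else 1 for c in a_cells]
        assert adjusted_rand_score(true_sub, sub.assignment) > 0.9


class TestAggregateUpm:
    def test_single_cell_arithmetic(self):
        cm = make_count_matrix([[10], [90]])
        prof = aggregate_cluster_expression(cm, pd.Series({"b0": "k"}))
        assert prof.upm.loc["g0", "k"] == pytest.approx(100_000)

    def test_two_cell_toy_matches_hand_computation(self):
        cm = make_count_matrix([[2, 4], [8, 6]])
        prof = aggregate_cluster_expression(
            cm, pd.Series({"b0": "k", "b1": "k"}))
        assert prof.upm["k"].tolist() == pytest.approx([300_000, 700_000])
        assert prof.n_cells["k"] == 2

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(11)
        cm = make_count_matrix(rng.poisson(4, (30, 50)) + 1)
        assign = pd.Series(rng.integers(0, 5, 50), index=cm.barcodes)
        prof = aggregate_cluster_expression(cm, assign)
        assert np.allclose(prof.upm.sum(axis=0), 1e6, atol=1)

    def test_zero_count_cluster_rejected(self):
        cm = make_count_matrix([[1, 0], [1, 0]])
        assign = pd.Series({"b0": "a", "b1": "empty"})
        with pytest.raises(ValueError, match="empty"):
            aggregate_cluster_expression(cm, assign)
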
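"""Ligand-receptor filtering, grouping, connection counting, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix
from ductal_sc.lr_network import (count_connections, filter_lr_genes,
                                  group_lr_profiles)
from ductal_sc.lr_network import test_composition_enrichment as composition_enrichment
from ductal_sc.lr_network import test_interactions as interaction_test


def _pairs(rows):
    return pd.DataFrame(rows, columns=["ligand", "receptor"])


class TestFilter:
    def test_unexpressed_ligand_excluded(self):
        cm = make_count_matrix([[0, 0], [5, 5]], genes=["lig", "rec"])
        assign = pd.Series(["p1", "p1"], index=cm.barcodes)
        ligs, recs, kept = filter_lr_genes(_pairs([("lig", "rec")]), cm, assign)
        assert ligs == [] and len(kept) == 0

    def test_exactly_twenty_percent_is_included(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :2] = 1  # ligand in exactly 20% of the population
        counts[1, :] = 1
        cm = make_count_matrix(counts, genes=["lig", "rec"])
        assign = pd.Series(["p1"] * 10, index=cm.barcodes)
        ligs, recs, kept = filter_lr_genes(_pairs([("lig", "rec")]), cm, assign)
        assert ligs == ["lig"] and len(kept) == 1

    def test_matches_bruteforce_per_population_fractions(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        cm = make_count_matrix(rng.poisson(0.3, (30, 60)), genes=genes)
        assign = pd.Series(rng.choice(["a", "b", "c"], 60), index=cm.barcodes)
        pairs = _pairs([(genes[i], genes[i + 15]) for i in range(15)])
        ligs, recs, kept = filter_lr_genes(pairs, cm, assign)
        dense = cm.to_dense()

        def expressed(g):
            gi = genes.index(g)
            return any((dense[gi, (assign == p).to_numpy()] > 0).mean() >= 0.2
                       for p in ("a", "b", "c"))

        assert ligs == sorted({g for g in pairs.ligand if expressed(g)})
        assert recs == sorted({g for g in pairs.receptor if expressed(g)})
        for _, row in kept.iterrows():
            assert expressed(row.ligand) and expressed(row.receptor)


class TestGrouping:
    def test_one_hot_gene_sets_get_population_labels(self):
        upm = pd.DataFrame({"popA": [100, 90, 0, 0], "popB": [0, 0, 80, 70]},
                           index=["g1", "g2", "g3", "g4"])
        groups = group_lr_profiles(upm, k=2, seed=0)
        assert set(groups[["g1", "g2"]]) == {"popA"}
        assert set(groups[["g3", "g4"]]) == {"popB"}

    def test_clusters_sharing_argmax_population_are_merged(self):
        # three well-separated profile shapes, two peaking in the same place
        upm = pd.DataFrame(
            [[100, 10, 0], [100, 12, 0],        # peak popA, shape 1
             [60, 40, 0], [62, 38, 0],          # peak popA, shape 2
             [0, 5, 95], [0, 8, 92]],           # peak popC
            index=[f"g{i}" for i in range(6)],
            columns=["popA", "popB", "popC"])
        groups = group_lr_profiles(upm, k=3, seed=0)
        assert groups.nunique() == 2
        assert set(groups[:4]) == {"popA"}
        assert set(groups[4:]) == {"popC"}

    def test_k_larger_than_gene_count_rejected(self):
        upm = pd.DataFrame({"p": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            group_lr_profiles(upm, k=5)


class TestConnections:
    def test_single_pair(self):
        mat = count_connections(pd.Series({"l": "A"}), pd.Series({"r": "B"}),
                                _pairs([("l", "r")]))
        assert mat.loc["A", "B"] == 1
        assert mat.to_numpy().sum() == 1

    def test_empty_pair_table_zero_matrix(self):
        mat = count_connections(pd.Series({"l": "A"}), pd.Series({"r": "B"}),
                                _pairs([]))
        assert mat.to_numpy().sum() == 0

    def test_unassigned_gene_rejected(self):
        with pytest.raises(ValueError, match="lx"):
            count_connections(pd.Series({"l": "A"}), pd.Series({"r": "B"}),
                              _pairs([("lx", "r")]))

    def test_twelve_pair_toy_matches_enumeration(self):
        rng = np.random.default_rng(1)
        ligs = [f"l{i}" for i in range(6)]
        recs = [f"r{i}" for i in range(6)]
        gl = pd.Series(rng.choice(["A", "B"], 6), index=ligs)
        gr = pd.Series(rng.choice(["X", "Y"], 6), index=recs)
        pairs = _pairs([(rng.choice(ligs), rng.choice(recs))
                        for _ in range(12)]).drop_duplicates()
        mat = count_connections(gl, gr, pairs)
        for a in mat.index:
            for b in mat.columns:
                want = sum(1 for _, p in pairs.iterrows()
                           if gl[p.ligand] == a and gr[p.receptor] == b)
                assert mat.loc[a, b] == want
        assert mat.to_numpy().sum() == len(pairs)


def _hypergeom_tail_by_enumeration(N, K, n, k):
    """P[X >= k] by enumerating all C(N, n) draws of n pairs from N."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestInteractionTest:
    def test_matches_enumeration_on_all_small_margins(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in (0, 1, N // 2, N):
                    for k in range(min(K, n) + 1):
                        import scipy.stats as st
                        p = float(st.hypergeom.sf(k - 1, N, K, n))
                        assert p == pytest.approx(
                            _hypergeom_tail_by_enumeration(N, K, n, k),
                            abs=1e-12)

    def test_table_p_values_match_enumeration(self):
        conn = pd.DataFrame([[3, 0], [1, 2]], index=["A", "B"],
                            columns=["X", "Y"])
        tab = interaction_test(conn)
        N = 6
        for _, row in tab.iterrows():
            K = conn.loc[row.ligand_group].sum()
            n = conn[row.receptor_group].sum()
            assert row.p_value == pytest.approx(
                _hypergeom_tail_by_enumeration(N, K, n, row.observed_pairs))
            assert row.expected_pairs == pytest.approx(K * n / N)

    def test_zero_row_total_gives_p_one(self):
        conn = pd.DataFrame([[0, 0], [2, 3]], index=["A", "B"],
                            columns=["X", "Y"])
        tab = interaction_test(conn)
        assert (tab.loc[tab.ligand_group == "A", "p_value"] == 1.0).all()

    def test_empty_matrix_all_p_one(self):
        conn = pd.DataFrame(0, index=["A"], columns=["X"])
        assert (interaction_test(conn).p_value == 1.0).all()

    def test_p_monotone_in_observed_count(self):
        import scipy.stats as st
        ps = [float(st.hypergeom.sf(k - 1, 40, 12, 10)) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestComposition:
    def test_proportional_composition_is_unremarkable(self):
        assign = pd.Series(["t1"] * 10 + ["t2"] * 30, dtype=object)
        samples = pd.Series((["s1"] * 5 + ["s2"] * 5) * 4, dtype=object)
        assign.iloc[:] = ["t1"] * 10 + ["t2"] * 30
        samples.iloc[:] = ["s1", "s2"] * 20
        tab = composition_enrichment(assign, samples)
        assert (tab.p_value >= 0.5).all()

    def test_two_by_two_toy_matches_enumeration(self):
        # 20 cells, 5 of type T; sample S holds 4 cells, all of them T
        assign = pd.Series(["T"] * 5 + ["O"] * 15)
        samples = pd.Series(["S"] * 4 + ["R"] * 16)
        tab = composition_enrichment(assign, samples)
        row = tab[(tab.cell_type == "T") & (tab["sample"] == "S")].iloc[0]
        assert row.observed == 4
        assert row.p_value == pytest.approx(
            _hypergeom_tail_by_enumeration(20, 5, 4, 4))

    def test_planted_fivefold_excess_reaches_strong_significance(self):
        # macrophage-style bias: one sample holds 5x its share of a type
        rng = np.random.default_rng(2)
        n, type_frac = 4000, 0.05
        samples = np.repeat(["s1", "s2", "s3", "s4"], n // 4)
        p_type = np.where(samples == "s4", 5 * type_frac, type_frac * 2 / 3)
        assign = np.where(rng.random(n) < p_type, "macrophage", "other")
        tab = composition_enrichment(pd.Series(assign), pd.Series(samples))
        row = tab[(tab.cell_type == "macrophage") & (tab["sample"] == "s4")]
        assert float(row.p_value.iloc[0]) < 1e-7
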
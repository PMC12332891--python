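"""Normalisation, clustering, marker and MIA contracts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fatestrat import spots as sp
from fatestrat.containers import ExpressionMatrix

from conftest import expression_from_array


def _raw(arr, **kw):
    return expression_from_array(arr, layer="raw", **kw)


class TestNormalize:
    def test_zero_count_stays_zero_and_scale_invariance(self):
        counts = _raw([[0, 0], [10, 20], [30, 60]])
        norm, _ = sp.normalize_select_hvg(counts, n_hvg=3)
        assert norm.values.iloc[0].eq(0).all()
        # proportional samples normalise identically
        pd.testing.assert_series_equal(
            norm.values["s0"], norm.values["s1"], check_names=False
        )

    def test_zero_total_spot_dropped_with_warning(self):
        counts = _raw([[1, 0, 3], [2, 0, 4]])
        with pytest.warns(UserWarning, match="zero total"):
            norm, _ = sp.normalize_select_hvg(counts, n_hvg=2)
        assert list(norm.samples) == ["s0", "s2"]

    def test_inflated_variance_genes_lead_hvg_list(self):
        rng = np.random.default_rng(0)
        n = 400
        # quiet genes span the mean axis so the variance trend is identifiable
        quiet_means = np.linspace(3, 80, 60)
        quiet = rng.poisson(np.tile(quiet_means[:, None], (1, n)))
        # bimodal rate with mean 20 but strongly inflated variance
        rate = np.where(rng.random(size=(5, n)) < 0.5, 2.0, 38.0)
        noisy = rng.poisson(rate)
        counts = _raw(np.vstack([noisy, quiet]),
                      genes=[f"hv{i}" for i in range(5)] + [f"q{i}" for i in range(60)])
        _, hvg = sp.normalize_select_hvg(counts, n_hvg=5)
        assert set(hvg) == {f"hv{i}" for i in range(5)}


class TestReduceCluster:
    def test_two_planted_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(30, 40))
        b = rng.normal(10, 1, size=(30, 40))
        norm = expression_from_array(np.hstack([a, b]))
        labels = sp.reduce_cluster(norm, knn=10, seed=0)
        assert labels.nunique() == 2
        assert labels.iloc[:40].nunique() == 1 and labels.iloc[40:].nunique() == 1

    def test_duplicating_spots_keeps_partition(self):
        rng = np.random.default_rng(2)
        X = np.hstack(
            [rng.normal(0, 1, size=(20, 30)), rng.normal(8, 1, size=(20, 30))]
        )
        norm = expression_from_array(X)
        base = sp.reduce_cluster(norm, knn=10, seed=0)
        dup = expression_from_array(
            np.hstack([X, X]), samples=[f"s{j}" for j in range(120)]
        )
        doubled = sp.reduce_cluster(dup, knn=10, seed=0)
        # partition agrees up to relabelling
        joint = pd.crosstab(doubled.iloc[:60].to_numpy(), base.to_numpy())
        assert (joint.gt(0).sum(axis=1) == 1).all()

    def test_too_few_spots_rejected(self):
        norm = expression_from_array(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="knn"):
            sp.reduce_cluster(norm, knn=10)


def _exact_wilcoxon_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating group assignments."""
    pooled = np.r_[x, y]
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    stats_all = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)
    ]
    stats_all = np.array(stats_all)
    mu = stats_all.mean()
    lo = (stats_all <= obs).mean()
    hi = (stats_all >= obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestFindMarkers:
    def test_exact_small_sample_pvalue(self):
        """{1,2,3} vs {4,5,6}: enumeration over C(6,3)=20 splits gives p=0.1."""
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        assert _exact_wilcoxon_p(x, y) == pytest.approx(0.1)
        assert sp._wilcoxon_p(x, y) == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (8, 8, 3)])
    def test_wilcoxon_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        assert sp._wilcoxon_p(x, y) == pytest.approx(_exact_wilcoxon_p(x, y), abs=1e-12)

    def test_identical_gene_excluded(self):
        rng = np.random.default_rng(3)
        X = np.vstack([np.ones(20), rng.normal(size=20)])
        norm = expression_from_array(X, genes=["flat", "noise"])
        labels = pd.Series([0] * 10 + [1] * 10, index=norm.samples)
        table = sp.find_markers(norm, labels, min_lfc=0.0, max_fdr=1.01)
        flat = table[table["gene"] == "flat"]
        assert (flat["log2fc"] == 0).all()
        filtered = sp.find_markers(norm, labels)
        assert "flat" not in set(filtered["gene"])

    def test_planted_marker_detected(self):
        rng = np.random.default_rng(4)
        base = rng.normal(1, 0.3, size=(10, 100)).clip(0)
        base[0, :50] += 2.0  # +2 log-fold in cluster 0
        norm = expression_from_array(base)
        labels = pd.Series([0] * 50 + [1] * 50, index=norm.samples)
        table = sp.find_markers(norm, labels)
        row = table[(table["gene"] == "g0") & (table["cluster"] == 0)]
        assert len(row) == 1
        assert row["log2fc"].iloc[0] > 0 and row["fdr"].iloc[0] < 0.05

    def test_small_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        norm = expression_from_array(rng.normal(size=(5, 13)))
        labels = pd.Series([0] * 10 + [1] * 2 + [2], index=norm.samples)
        with pytest.warns(UserWarning, match="<3 spots"):
            sp.find_markers(norm, labels, min_lfc=0.0, max_fdr=1.01)


class TestAnnotateTypes:
    PANELS = {"malignant": ["CD24", "ALDH18A1"], "immune": ["HLA-DRA"]}

    def test_single_panel_overexpression_assigns_type(self):
        markers = pd.DataFrame(
            {"gene": ["CD24", "ALDH18A1"], "cluster": [0, 0],
             "log2fc": [1.0, 2.0], "pvalue": [0.01] * 2, "fdr": [0.02] * 2}
        )
        labels = pd.Series([0, 0, 0], index=["a", "b", "c"])
        ann = sp.annotate_types(markers, self.PANELS, labels)
        assert ann.cluster_type[0] == "malignant"
        assert (ann.spot_type == "malignant").all()

    def test_tied_scores_stay_unassigned(self):
        markers = pd.DataFrame(
            {"gene": ["CD24", "ALDH18A1", "HLA-DRA"], "cluster": [0] * 3,
             "log2fc": [1.0, 1.0, 1.0], "pvalue": [0.01] * 3, "fdr": [0.02] * 3}
        )
        labels = pd.Series([0], index=["a"])
        ann = sp.annotate_types(markers, self.PANELS, labels)
        assert ann.cluster_type[0] == "unassigned"

    def test_empty_marker_table_all_unassigned(self):
        markers = pd.DataFrame(columns=["gene", "cluster", "log2fc", "pvalue", "fdr"])
        labels = pd.Series([0, 1], index=["a", "b"])
        ann = sp.annotate_types(markers, self.PANELS, labels)
        assert set(ann.cluster_type.values()) == {"unassigned"}

    def test_planted_types_recovered_end_to_end(self, spatial_default):
        _, expr, _, truth = spatial_default
        norm, hvg = sp.normalize_select_hvg(expr, n_hvg=100)
        labels = sp.reduce_cluster(norm, hvg=hvg, knn=15, seed=0)
        markers = sp.find_markers(norm, labels)
        ann = sp.annotate_types(markers, truth.marker_panels, labels)
        assert (ann.spot_type == truth.spot_type).mean() >= 0.95


def _exact_enrichment_p(n_u, n_a, n_b, k):
    total = math.comb(n_u, n_b)
    return sum(
        math.comb(n_a, i) * math.comb(n_u - n_a, n_b - i)
        for i in range(k, min(n_a, n_b) + 1)
    ) / total


class TestMiaOverlap:
    def test_full_overlap_exact_probability(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        res = sp.mia_overlap(a, a, universe)
        assert res["overlap"] == 5
        assert res["p_enrichment"] == pytest.approx(1 / math.comb(20, 5))

    def test_disjoint_sets_enrichment_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = sp.mia_overlap({"g0"}, {"g1"}, universe)
        assert res["overlap"] == 0
        assert res["p_enrichment"] == 1.0

    def test_partial_overlap_matches_enumeration(self):
        universe = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(4)}
        b = {"g0", "g1", "g4", "g5", "g6"}
        res = sp.mia_overlap(a, b, universe)
        assert res["p_enrichment"] == pytest.approx(186 / 252)
        assert res["p_enrichment"] == pytest.approx(_exact_enrichment_p(10, 4, 5, 2))

    def test_monotone_in_overlap(self):
        universe = {f"g{i}" for i in range(25)}
        a = {f"g{i}" for i in range(8)}
        prev = 1.1
        for k in range(0, 7):
            b = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(10, 16)}
            res = sp.mia_overlap(a, b, universe)
            assert res["p_enrichment"] <= prev + 1e-12
            prev = res["p_enrichment"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            sp.mia_overlap(set(), set(), set())


class TestQcFilter:
    def test_thresholds_applied(self):
        counts = pd.DataFrame(
            {
                "ok": [5, 5, 1],
                "too_big": [200_000, 1, 1],
                "mito_heavy": [1, 1, 5],
            },
            index=["GENE1", "GENE2", "MT-CO1"],
        )
        em = ExpressionMatrix(counts, layer="raw")
        kept = sp.qc_filter(em, min_cells_per_gene=0)
        assert list(kept.samples) == ["ok"]
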
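"""Neighborhood statistics vs brute-force oracles; decay and clustering."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_bin_counts, brute_force_neighborhood
from immunoscape import spatial_stats as sp
from immunoscape import synthgen as sg


def _cells(coords_phenos):
    xs, ys, ph = zip(*coords_phenos)
    return pd.DataFrame({"cell_id": range(len(xs)), "x_um": xs, "y_um": ys,
                         "phenotype": ph})


class TestBinnedCounts:
    def test_two_focal_one_target(self):
        cells = _cells([(0, 0, "TEff"), (100, 0, "TEff"), (10, 0, "Tumor"),
                        (90, 0, "Tumor")])
        prof = sp.binned_neighbor_counts(cells, "TEff", "Tumor",
                                         bin_edges=(0, 25, 50))
        assert prof.mean_counts[0] == pytest.approx(1.0)

    def test_boundary_right_closed(self):
        cells = _cells([(0, 0, "TEff"), (25, 0, "Tumor"), (25.01, 10, "Tumor")])
        prof = sp.binned_neighbor_counts(cells, "TEff", "Tumor",
                                         bin_edges=(0, 25, 50))
        assert prof.mean_counts[0] == 1.0   # exactly 25 µm → first bin

    def test_no_targets_zero_profile(self):
        cells = _cells([(0, 0, "TEff")])
        prof = sp.binned_neighbor_counts(cells, "TEff", "Tumor")
        assert (prof.mean_counts == 0).all()

    def test_no_focal_error(self):
        with pytest.raises(ValueError, match="focal"):
            sp.binned_neighbor_counts(_cells([(0, 0, "Tumor")]),
                                      "TEff", "Tumor")

    def test_matches_brute_force(self, random_point_cells):
        sub = random_point_cells.iloc[:400]
        edges = (0, 25, 50, 75, 100)
        prof = sp.binned_neighbor_counts(sub, "TEff", "Tumor", edges)
        oracle = brute_force_bin_counts(sub, "TEff", "Tumor", edges)
        np.testing.assert_allclose(prof.mean_counts, oracle, atol=0)

    def test_self_pairs_excluded_same_phenotype(self):
        cells = _cells([(0, 0, "TEff"), (10, 0, "TEff")])
        prof = sp.binned_neighbor_counts(cells, "TEff", "TEff",
                                         bin_edges=(0, 25))
        assert prof.mean_counts[0] == pytest.approx(1.0)

    def test_pair_count_symmetry(self, random_point_cells):
        sub = random_point_cells.iloc[:600]
        edges = (0, 50, 100)
        a = sp.binned_neighbor_counts(sub, "TEff", "Tumor", edges)
        b = sp.binned_neighbor_counts(sub, "Tumor", "TEff", edges)
        np.testing.assert_allclose(a.mean_counts * a.n_focal,
                                   b.mean_counts * b.n_focal)


class TestDecayGradient:
    def test_closed_form(self):
        # counts [8,4,2,1] at midpoints [12.5,37.5,62.5,87.5]:
        # slope = −ln2/25, λ = 25/ln2 ≈ 36.07 µm
        prof = sp.NeighborProfile(
            focal="a", target="b",
            bin_edges=np.array([0, 25, 50, 75, 100.0]),
            mean_counts=np.array([8, 4, 2, 1.0]),
            enrichment=np.full(4, np.nan), n_focal=1, n_target=15)
        fit = sp.decay_gradient(prof)
        assert fit.decay_length_um == pytest.approx(25 / np.log(2), rel=1e-9)
        assert fit.has_gradient

    def test_flat_profile_not_flagged(self):
        prof = sp.NeighborProfile(
            focal="a", target="b", bin_edges=np.arange(0, 275, 25.0),
            mean_counts=np.full(10, 3.0), enrichment=np.full(10, np.nan),
            n_focal=1, n_target=30)
        assert not sp.decay_gradient(prof).has_gradient

    def test_all_zero_sentinel(self):
        prof = sp.NeighborProfile(
            focal="a", target="b", bin_edges=np.arange(0, 275, 25.0),
            mean_counts=np.zeros(10), enrichment=np.full(10, np.nan),
            n_focal=1, n_target=0)
        fit = sp.decay_gradient(prof)
        assert np.isnan(fit.decay_length_um) and not fit.has_gradient

    def test_enrichment_quantity_fit(self):
        # enrichment decaying as exp(−d/50) with flat raw counts:
        # the enrichment fit must recover λ=50 where the count fit sees none
        edges = np.arange(0, 275, 25.0)
        mids = (edges[:-1] + edges[1:]) / 2
        prof = sp.NeighborProfile(
            focal="a", target="b", bin_edges=edges,
            mean_counts=np.full(10, 4.0),
            enrichment=np.exp(-mids / 50.0), n_focal=1, n_target=40)
        fit = sp.decay_gradient(prof, quantity="enrichment")
        assert fit.decay_length_um == pytest.approx(50.0, rel=1e-9)
        assert not sp.decay_gradient(prof, quantity="counts").has_gradient
        with pytest.raises(ValueError, match="quantity"):
            sp.decay_gradient(prof, quantity="bogus")

    def test_planted_lambda_recovered(self):
        # spot check at 3 seeds; the 20-seed benchmark runs in acceptance
        lams = []
        for seed in range(3):
            cells = sg.simulate_decay_profile(100.0, seed=seed)
            prof = sp.binned_neighbor_counts(cells, "TEff", "Tumor")
            lams.append(sp.decay_gradient(prof).decay_length_um)
        assert np.mean(lams) == pytest.approx(100.0, rel=0.25)


class TestHeatmap:
    def test_single_cell_peak(self):
        cells = _cells([(130, 370, "TEff")])
        raster, extent = sp.density_heatmap(cells, None, 500, 500,
                                            grid_size=25, bandwidth=30)
        iy, ix = np.unravel_index(raster.argmax(), raster.shape)
        assert ix == 130 // 25 and iy == 370 // 25

    def test_integral_equals_count(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({"x_um": rng.uniform(300, 1200, 500),
                              "y_um": rng.uniform(300, 1200, 500)})
        raster, _ = sp.density_heatmap(cells, None, 1500, 1500,
                                       grid_size=25, bandwidth=40)
        assert raster.sum() * 25**2 == pytest.approx(500, rel=0.01)

    def test_two_hotspots(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal((300, 300), 20, (200, 2)),
                         rng.normal((1000, 900), 20, (200, 2))])
        cells = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
        raster, _ = sp.density_heatmap(cells, None, 1300, 1300,
                                       grid_size=25, bandwidth=40)
        iy, ix = np.unravel_index(raster.argmax(), raster.shape)
        assert abs(ix - 300 // 25) <= 1 and abs(iy - 300 // 25) <= 1
        half = raster.copy()
        half[:raster.shape[0] // 2] = 0
        iy2, ix2 = np.unravel_index(half.argmax(), half.shape)
        assert abs(ix2 - 1000 // 25) <= 1 and abs(iy2 - 900 // 25) <= 1

    def test_zero_cells_zero_raster(self):
        raster, _ = sp.density_heatmap(_cells([]).iloc[:0] if False else
                                       pd.DataFrame({"x_um": [], "y_um": []}),
                                       None, 100, 100)
        assert (raster == 0).all()


class TestNeighborhoodFeatures:
    def test_isolated_cell_zero_vector(self):
        cells = _cells([(0, 0, "TEff"), (500, 500, "Tumor")])
        feats = sp.neighborhood_features(cells, radius=50)
        assert (feats.iloc[0] == 0).all()

    def test_counts_within_radius(self):
        cells = _cells([(0, 0, "Tumor"), (10, 0, "TEff"), (0, 20, "TEff"),
                        (30, 30, "TEff"), (100, 0, "TEff")])
        feats = sp.neighborhood_features(cells, radius=50,
                                         phenotypes=("TEff", "Tumor"))
        assert feats.loc[0, "nb_TEff"] == 3

    def test_matches_brute_force(self, random_point_cells):
        sub = random_point_cells.iloc[:500].reset_index(drop=True)
        phen = ("Macrophage", "TEff", "Tumor")
        feats = sp.neighborhood_features(sub, radius=50, phenotypes=phen)
        oracle = brute_force_neighborhood(sub, 50, phen)
        np.testing.assert_array_equal(feats.to_numpy(), oracle)


class TestClustering:
    def _archetype_features(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        a = np.column_stack([rng.poisson(20, n), rng.poisson(1, n)])
        b = np.column_stack([rng.poisson(1, n), rng.poisson(20, n)])
        X = pd.DataFrame(np.vstack([a, b]), columns=["nb_Tumor", "nb_TEff"])
        labels = np.repeat([0, 1], n)
        return X, labels

    def test_two_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        X, truth = self._archetype_features()
        out = sp.cluster_neighborhoods(X, k=2, seed=0)
        assert adjusted_rand_score(truth, out.labels) >= 0.9

    def test_k1_single_cluster(self):
        X, _ = self._archetype_features(n=20)
        out = sp.cluster_neighborhoods(X, k=1, seed=0)
        assert set(out.labels) == {0}

    def test_identical_vectors_identical_labels(self):
        X = pd.DataFrame(np.ones((30, 3)), columns=list("abc"))
        out = sp.cluster_neighborhoods(X, k=2, seed=0)
        assert len(set(out.labels[:15]) | set(out.labels[15:])) <= 2
        first = X.iloc[0].to_numpy()
        same = (X.to_numpy() == first).all(axis=1)
        assert len(set(out.labels[same])) == 1

    def test_k_exceeds_n_error(self):
        X = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError, match="k="):
            sp.cluster_neighborhoods(X, k=5, seed=0)

    def test_seed_reproducible(self):
        X, _ = self._archetype_features(seed=3)
        a = sp.cluster_neighborhoods(X, k=4, seed=9)
        b = sp.cluster_neighborhoods(X, k=4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_umap_embedding_shape(self):
        X, _ = self._archetype_features(n=60, seed=1)
        out = sp.cluster_neighborhoods(X, k=2, seed=0, embed=True)
        assert out.embedding.shape == (len(X), 2)


class TestDifferentialAbundance:
    def test_equal_shares_ratio_one(self):
        labels = np.array([0, 1] * 20)
        groups = np.array(["deceased"] * 20 + ["alive"] * 20)
        tab = sp.differential_cluster_abundance(labels, groups)
        assert tab["ratio_deceased_over_alive"].tolist() == [1.0, 1.0]

    def test_double_share(self):
        labels = np.array([0] * 2 + [1] * 8 + [0] * 1 + [1] * 9)
        groups = np.array(["deceased"] * 10 + ["alive"] * 10)
        tab = sp.differential_cluster_abundance(labels, groups)
        assert tab.loc[tab.cluster == 0,
                       "ratio_deceased_over_alive"].iloc[0] == pytest.approx(2.0)

    def test_shares_sum_100(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, 200)
        groups = rng.choice(["deceased", "alive"], 200)
        tab = sp.differential_cluster_abundance(labels, groups)
        assert tab["pct_deceased"].sum() == pytest.approx(100, abs=1e-9)
        assert tab["pct_alive"].sum() == pytest.approx(100, abs=1e-9)

    def test_zero_share_smoothed_and_flagged(self):
        labels = np.array([0] * 10 + [1] * 10)
        groups = np.array(["deceased"] * 10 + ["alive"] * 10)
        tab = sp.differential_cluster_abundance(labels, groups)
        assert tab["smoothed"].all()
        assert np.isfinite(tab["ratio_deceased_over_alive"]).all()

    def test_missing_group_error(self):
        with pytest.raises(ValueError, match="zero cells"):
            sp.differential_cluster_abundance(
                np.zeros(5, int), np.array(["alive"] * 5))

    def test_planted_deceased_niche_enriched(self):
        # tumor-heavy neighborhoods planted only in deceased samples
        rng = np.random.default_rng(2)
        dec = np.column_stack([rng.poisson(15, 200), rng.poisson(1, 200)])
        ali = np.column_stack([rng.poisson(1, 200), rng.poisson(10, 200)])
        X = pd.DataFrame(np.vstack([dec, ali]),
                         columns=["nb_NOS2_Tumor", "nb_TEff"])
        groups = np.array(["deceased"] * 200 + ["alive"] * 200)
        out = sp.cluster_neighborhoods(X, k=2, seed=0)
        tab = sp.differential_cluster_abundance(out.labels, groups)
        dec_cluster = pd.Series(out.labels[:200]).mode()[0]
        row = tab[tab.cluster == dec_cluster].iloc[0]
        assert row["ratio_deceased_over_alive"] > 1.0
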
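import numpy as np
import pandas as pd
import pytest

from fieldomics.spatial_lme import DegenerateInputError, SphericalCovariance
from fieldomics.spatial_stats import (
    FeatureCluster,
    bh_adjust,
    cluster_autocorrelated_features,
    cluster_phenotype_correlation,
    layer_distance_correlation,
    moran_table,
    morans_i,
)
from fieldomics.synthetic_field import sample_spatial_gp


def brute_force_moran(x, w):
    """Literal double-sum Moran's I, independent of the implementation."""
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
            s0 += w[i, j]
    return (n / s0) * num / (z**2).sum()


class TestMoransI:
    def test_brute_force_oracle_tiny(self, tiny_layout):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        xy = tiny_layout[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        w = np.zeros_like(d)
        off = ~np.eye(4, dtype=bool)
        w[off] = 1.0 / d[off]
        res = morans_i(x, tiny_layout)
        assert res.I == pytest.approx(brute_force_moran(x, w), abs=1e-12)

    def test_brute_force_oracle_random_50(self, small_layout, rng):
        sub = small_layout.iloc[:50].reset_index(drop=True)
        x = rng.standard_normal(50)
        xy = sub[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        w = np.zeros_like(d)
        off = ~np.eye(50, dtype=bool)
        w[off] = 1.0 / d[off]
        res = morans_i(x, sub)
        assert res.I == pytest.approx(brute_force_moran(x, w), abs=1e-12)

    def test_null_mean_matches_expectation(self, small_layout, rng):
        n = len(small_layout)
        vals = [morans_i(rng.standard_normal(n), small_layout).I for _ in range(2000)]
        assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=0.005)

    def test_spatial_signal_power(self, small_layout):
        kernel = SphericalCovariance(1.0, 0.0, 600.0)
        hits = 0
        for seed in range(20):
            x = sample_spatial_gp(small_layout, kernel, np.random.default_rng(seed))
            res = morans_i(x, small_layout)
            hits += (res.I > 0) and (res.p < 0.01)
        assert hits >= 19

    def test_affine_invariance(self, small_layout, rng):
        x = rng.standard_normal(len(small_layout))
        a = morans_i(x, small_layout)
        b = morans_i(3.0 * x + 7.0, small_layout)
        assert a.I == pytest.approx(b.I, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_constant_raises(self, small_layout):
        with pytest.raises(DegenerateInputError):
            morans_i(np.ones(len(small_layout)), small_layout)

    def test_coincident_positions_raise(self, tiny_layout):
        bad = tiny_layout.copy()
        bad.loc[1, ["x", "y"]] = bad.loc[0, ["x", "y"]]
        with pytest.raises(ValueError, match="coincident"):
            morans_i(np.array([1.0, 2, 3, 4]), bad)

    def test_permutation_p_close_to_analytic(self, small_layout):
        kernel = SphericalCovariance(1.0, 0.0, 600.0)
        x = sample_spatial_gp(small_layout, kernel, np.random.default_rng(4))
        analytic = morans_i(x, small_layout)
        perm = morans_i(x, small_layout, permutations=499, rng=1)
        # both should call it significant for a strong spatial draw
        assert analytic.p < 0.05 and perm.p < 0.05


class TestBHAdjust:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_order_preserved_and_bounds(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        # matches statsmodels as an independent reference
        from statsmodels.stats.multitest import multipletests
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClustering:
    def _two_factor_matrix(self, layout, n_per_group=8):
        f1 = sample_spatial_gp(layout, SphericalCovariance(1.0, 0.0, 500.0),
                               np.random.default_rng(1))
        f2 = sample_spatial_gp(layout, SphericalCovariance(1.0, 0.0, 500.0),
                               np.random.default_rng(2))
        rows = [f1 * (1 + 0.01 * i) for i in range(n_per_group)]
        rows += [f2 * (1 + 0.01 * i) for i in range(n_per_group)]
        names = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
        return pd.DataFrame(rows, index=names, columns=layout["plant_id"])

    def test_planted_partition_recovery(self, small_layout):
        matrix = self._two_factor_matrix(small_layout)
        moran = moran_table(matrix, small_layout)
        clusters = cluster_autocorrelated_features(matrix, moran, 0.05, k=2)
        assert len(clusters) == 2
        sets = [set(c.member_features) for c in clusters]
        expected = [{f"a{i}" for i in range(8)}, {f"b{i}" for i in range(8)}]
        assert sets == expected or sets == expected[::-1]

    def test_duplicates_co_cluster(self, small_layout):
        matrix = self._two_factor_matrix(small_layout)
        matrix.loc["a_dup"] = matrix.loc["a0"]
        moran = moran_table(matrix, small_layout)
        clusters = cluster_autocorrelated_features(matrix, moran, 0.05, k=2)
        for c in clusters:
            if "a0" in c.member_features:
                assert "a_dup" in c.member_features

    def test_zscored_profiles(self, small_layout):
        matrix = self._two_factor_matrix(small_layout)
        moran = moran_table(matrix, small_layout)
        clusters = cluster_autocorrelated_features(matrix, moran, 0.05, k=2)
        for c in clusters:
            # mean of per-feature z-scores: mean 0; sd 1 per feature before averaging
            assert abs(np.mean(c.mean_profile)) < 1e-10

    def test_too_few_passing_warns(self, small_layout, rng):
        matrix = pd.DataFrame(rng.standard_normal((3, len(small_layout))),
                              index=list("abc"), columns=small_layout["plant_id"])
        moran = moran_table(matrix, small_layout)
        moran["q"] = 1.0
        with pytest.warns(UserWarning):
            assert cluster_autocorrelated_features(matrix, moran, 0.01, k=2) == []


class TestClusterPhenotypeCorrelation:
    def test_perfect_correlation(self, small_layout):
        profile = np.sin(np.arange(len(small_layout)) / 5)
        profile = (profile - profile.mean()) / profile.std(ddof=1)
        cl = FeatureCluster(1, ["f"], profile)
        phen = pd.DataFrame([profile], index=["t"], columns=small_layout["plant_id"])
        table = cluster_phenotype_correlation([cl], phen)
        assert table.loc[0, "r"] == pytest.approx(1.0)

    def test_sign_flip(self, small_layout, rng):
        profile = rng.standard_normal(len(small_layout))
        cl = FeatureCluster(1, ["f"], profile)
        y = rng.standard_normal(len(small_layout))
        phen = pd.DataFrame([y, -y], index=["t", "neg"], columns=small_layout["plant_id"])
        table = cluster_phenotype_correlation([cl], phen).set_index("phenotype")
        assert table.loc["t", "r"] == pytest.approx(-table.loc["neg", "r"])
        assert table.loc["t", "p"] == pytest.approx(table.loc["neg", "p"])

    def test_null_calibration(self, small_layout, rng):
        # independent phenotype: q <= 0.05 in <= ~5% of repetitions
        profiles = [rng.standard_normal(len(small_layout)) for _ in range(4)]
        clusters = [FeatureCluster(i, [f"f{i}"], p) for i, p in enumerate(profiles)]
        false_hits, total = 0, 0
        for _ in range(100):
            y = rng.standard_normal(len(small_layout))
            phen = pd.DataFrame([y], index=["t"], columns=small_layout["plant_id"])
            table = cluster_phenotype_correlation(clusters, phen)
            false_hits += (table["q"] <= 0.05).sum()
            total += len(table)
        assert false_hits / total <= 0.06

    def test_too_few_plants_raises(self):
        cl = FeatureCluster(1, ["f"], np.array([1.0, 2.0]))
        phen = pd.DataFrame([[1.0, 2.0]], index=["t"], columns=["p1", "p2"])
        with pytest.raises(ValueError):
            cluster_phenotype_correlation([cl], phen)


class TestLayerDistanceCorrelation:
    def test_self_correlation_is_one(self, small_layout, rng):
        m = pd.DataFrame(rng.standard_normal((10, len(small_layout))),
                         columns=small_layout["plant_id"])
        r, p = layer_distance_correlation(m, m)
        assert r == pytest.approx(1.0)

    def test_independent_layers_near_zero(self, small_layout, rng):
        rs = []
        for _ in range(30):
            a = pd.DataFrame(rng.standard_normal((10, len(small_layout))),
                             columns=small_layout["plant_id"])
            b = pd.DataFrame(rng.standard_normal((10, len(small_layout))),
                             columns=small_layout["plant_id"])
            r, _ = layer_distance_correlation(a, b)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_shared_spatial_factor_positive(self, small_layout):
        f = sample_spatial_gp(small_layout, SphericalCovariance(1.0, 0.0, 500.0),
                              np.random.default_rng(9))
        rng = np.random.default_rng(10)
        a = pd.DataFrame([f + 0.3 * rng.standard_normal(len(f)) for _ in range(8)],
                         columns=small_layout["plant_id"])
        b = pd.DataFrame([f + 0.3 * rng.standard_normal(len(f)) for _ in range(8)],
                         columns=small_layout["plant_id"])
        r, p = layer_distance_correlation(a, b, permutations=199, rng=3)
        assert r > 0.3
        assert p < 0.05

    def test_physical_layer_option(self, small_layout, rng):
        m = pd.DataFrame(rng.standard_normal((10, len(small_layout))),
                         columns=small_layout["plant_id"])
        r, p = layer_distance_correlation(m, layout=small_layout)
        assert -1 <= r <= 1

    def test_mismatched_plants_raise(self, small_layout, rng):
        a = pd.DataFrame(rng.standard_normal((5, len(small_layout))),
                         columns=small_layout["plant_id"])
        b = a.iloc[:, ::-1]
        with pytest.raises(ValueError):
            layer_distance_correlation(a, b)
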
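import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import permanova as skbio_permanova

import assemblytrace as at
from oracles import naive_permanova_f_r2


def _euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return at.DistanceMatrix(squareform(pdist(points)), ids, "euclidean",
                             normalized=False)


class TestPermanova:
    def test_two_separated_clusters_closed_form(self):
        # within-group distances 0, between-group distances 1
        n1, n2 = 8, 8
        n = n1 + n2
        vals = np.ones((n, n))
        vals[:n1, :n1] = 0
        vals[n1:, n1:] = 0
        np.fill_diagonal(vals, 0)
        d = at.DistanceMatrix(vals, [f"s{i}" for i in range(n)], "toy")
        groups = ["a"] * n1 + ["b"] * n2
        res = at.permanova(d, groups, n_perm=199, seed=0)
        # all squared distance lies between groups: SS_within = 0, so
        # R^2 = 1 and F is unbounded; only label-preserving permutations
        # reproduce the statistic, so p sits at its floor
        assert res.r_squared == pytest.approx(1.0)
        assert res.pseudo_f > 1e12 or np.isinf(res.pseudo_f)
        assert res.p_value == pytest.approx(1 / 200)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_formula_and_skbio(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3))
        groups = list(rng.choice(["a", "b"], size=6))
        if len(set(groups)) < 2 or min(groups.count("a"), groups.count("b")) < 2:
            groups = ["a", "a", "a", "b", "b", "b"]
        d = _euclidean_dm(pts)
        res = at.permanova(d, groups, n_perm=99, seed=1)
        f_naive, r2_naive = naive_permanova_f_r2(d.values, groups)
        assert res.pseudo_f == pytest.approx(f_naive)
        assert res.r_squared == pytest.approx(r2_naive)
        sk = skbio_permanova(d.to_skbio(), grouping=list(groups), permutations=99)
        assert res.pseudo_f == pytest.approx(sk["test statistic"])

    def test_singleton_group_refused(self):
        d = _euclidean_dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="size 1"):
            at.permanova(d, ["a", "b", "b", "b"], n_perm=99, seed=0)

    def test_p_value_floor_and_determinism(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(5, 0.1, (8, 2))])
        d = _euclidean_dm(pts)
        groups = ["a"] * 8 + ["b"] * 8
        r1 = at.permanova(d, groups, n_perm=199, seed=7)
        r2 = at.permanova(d, groups, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value == pytest.approx(1 / 200)
        assert r1.p_value >= 1 / (r1.n_permutations + 1)


class TestDispersion:
    def test_translated_clouds_equal_dispersion(self):
        rng = np.random.default_rng(1)
        cloud = rng.normal(size=(8, 2))
        pts = np.vstack([cloud, cloud + 20.0])
        d = _euclidean_dm(pts)
        rep = at.dispersion_test(d, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=0)
        diff = rep["median_differences"]["a-b"]
        assert abs(diff) < 1e-9
        assert rep["p"] > 0.5

    def test_inflated_cloud_detected(self):
        rng = np.random.default_rng(2)
        tight = rng.normal(0, 1, size=(10, 2))
        wide = rng.normal(0, 3, size=(10, 2)) + 20.0
        d = _euclidean_dm(np.vstack([tight, wide]))
        rep = at.dispersion_test(d, ["t"] * 10 + ["w"] * 10, n_perm=199, seed=0)
        assert rep["median_dispersion"]["w"] > rep["median_dispersion"]["t"]
        assert rep["p"] < 0.05

    def test_fire_class_more_dispersed_than_reference(self, chronosequence):
        table, tree, md = (chronosequence["table"], chronosequence["tree"],
                           chronosequence["metadata"])
        d = at.unifrac(table, tree, weighted=True)
        rep = at.dispersion_test(d, md.fire_class.reindex(table.sample_ids),
                                 n_perm=199, seed=0)
        assert rep["median_dispersion"]["fire_affected"] > \
            rep["median_dispersion"]["reference"]


class TestOrdination:
    def test_collinear_points_single_axis(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        d = _euclidean_dm(pts)
        ord_res = at.pcoa(d)
        assert ord_res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 4))
        d = _euclidean_dm(pts)
        ord_res = at.pcoa(d)
        recon = squareform(pdist(ord_res.coordinates))
        np.testing.assert_allclose(recon, d.values, atol=1e-8)

    def test_envfit_variable_aligned_with_axis1(self):
        rng = np.random.default_rng(6)
        pts = np.column_stack([np.linspace(0, 10, 12), rng.normal(0, 0.2, 12)])
        d = _euclidean_dm(pts)
        ord_res = at.pcoa(d)
        vars_df = pd.DataFrame({
            "axis1_var": ord_res.coordinates[:, 0],
            "constant": np.ones(12),
        }, index=ord_res.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            fit = at.envfit(ord_res, vars_df, n_perm=99, seed=0)
        assert "constant" not in fit.index
        assert fit.loc["axis1_var", "r_squared"] == pytest.approx(1.0)
        assert abs(fit.loc["axis1_var", "axis1"]) == pytest.approx(1.0, abs=1e-6)
        assert fit.loc["axis1_var", "p"] <= 0.05

    def test_partial_ordination_removes_conditioned_variable(self):
        rng = np.random.default_rng(7)
        grad = np.linspace(-5, 5, 15)
        pts = np.column_stack([grad, rng.normal(0, 1.0, 15)])
        d = _euclidean_dm(pts)
        resid = at.partial_ordination(d, grad)
        r = np.corrcoef(resid.coordinates[:, 0], grad)[0, 1]
        assert abs(r) < 0.1
        with pytest.raises(ValueError, match="constant"):
            at.partial_ordination(d, np.ones(15))


class TestMantel:
    def test_identity_perfect_correlation(self):
        d = _euclidean_dm(np.random.default_rng(0).normal(size=(8, 2)))
        rep = at.mantel(d, d, n_perm=99, seed=0)
        assert rep["r"] == pytest.approx(1.0)
        assert rep["p"] <= 0.05

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(10):
            d1 = _euclidean_dm(rng.normal(size=(18, 3)))
            d2 = _euclidean_dm(rng.normal(size=(18, 3)))
            rs.append(at.mantel(d1, d2, n_perm=99, seed=0)["r"])
        assert abs(np.mean(rs)) < 0.15

    def test_no_spatial_signal_in_neutral_scenario(self, metacommunity):
        # communities assembled with no spatial process: the spatial Mantel
        # should be non-significant in nearly all runs
        rng = np.random.default_rng(9)
        n_sig = 0
        runs = 10
        for i in range(runs):
            t = at.simulate_neutral_local(metacommunity, 400, 0.3, 18,
                                          seed=100 + i)
            xy = rng.uniform(0, 500, size=(18, 2))
            d = at.bray_curtis(t)
            rep = at.spatial_mantel(d, xy, n_perm=199, seed=i)
            n_sig += rep["p"] < 0.05
        assert n_sig <= 1
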
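import numpy as np
import pytest
from scipy.stats import kstest, pearsonr, ttest_ind

import assemblytrace as at


@pytest.fixture(scope="module")
def base_table(metacommunity):
    return at.simulate_neutral_local(metacommunity, N=600, m=0.3, n_samples=12,
                                     seed=41)


class TestNullCommunity:
    def test_margins_preserved_every_iteration(self, base_table):
        rng = np.random.default_rng(0)
        for _ in range(20):
            null = at.null_community(base_table, rng)
            np.testing.assert_array_equal(null.depths, base_table.depths)
            np.testing.assert_array_equal(
                (null.counts > 0).sum(axis=1), (base_table.counts > 0).sum(axis=1)
            )

    def test_single_sample_occurrence_deterministic(self):
        t = at.CommunityTable(np.array([[3, 5, 2]]), ["s"], ["A", "B", "C"])
        null = at.null_community(t, seed=0)
        assert (null.counts > 0).all()

    def test_selection_rate_increases_with_occupancy(self):
        # 4 samples; occupancy gradient across taxa, equalized abundances so
        # only the occupancy weighting drives selection
        counts = np.array([
            [9, 9, 9, 0, 0, 0, 3],
            [9, 9, 0, 9, 0, 0, 3],
            [9, 0, 9, 0, 9, 0, 3],
            [0, 9, 0, 9, 0, 9, 3],
        ])
        t = at.CommunityTable(counts, list("wxyz"), list("ABCDEFG"))
        occupancy = (counts > 0).sum(axis=0)
        rng = np.random.default_rng(1)
        hits = {x: 0 for x in t.taxon_ids}
        for _ in range(1000):
            null = at.null_community(t, rng)
            present = (null.counts > 0).sum(axis=0)
            for x, n in zip(null.taxon_ids, present):
                hits[x] += int(n)
        rates = np.array([hits[x] for x in t.taxon_ids])
        # mean selection rate per occupancy level is strictly increasing
        by_occ = {
            o: rates[occupancy == o].mean() for o in np.unique(occupancy)
        }
        levels = sorted(by_occ)
        assert all(by_occ[a] < by_occ[b] for a, b in zip(levels, levels[1:]))

    def test_impossible_richness_rejected(self):
        t = at.CommunityTable(np.array([[1, 1], [1, 1]]), ["a", "b"], ["A", "B"])
        t.counts = np.array([[1, 1], [1, 1]])  # richness 2 == pool 2: fine
        at.null_community(t, seed=0)


class TestBetaNullDeviation:
    def test_determinism(self, base_table, chronosequence):
        a = at.beta_null_deviation(base_table, metric="bray_curtis", n_iter=99, seed=5)
        b = at.beta_null_deviation(base_table, metric="bray_curtis", n_iter=99, seed=5)
        np.testing.assert_array_equal(a.pairs["deviation"], b.pairs["deviation"])

    def test_self_null_centering(self, base_table):
        # a table drawn from the null generator itself should deviate ~0
        null_draw = at.null_community(base_table, seed=7)
        res = at.beta_null_deviation(null_draw, metric="bray_curtis", n_iter=199,
                                     seed=8)
        assert abs(res.per_sample.mean()) < 0.05

    def test_unifrac_requires_tree(self, base_table):
        with pytest.raises(ValueError, match="tree"):
            at.beta_null_deviation(base_table, metric="weighted_unifrac", n_iter=99)

    def test_low_iteration_warning(self, base_table):
        with pytest.warns(UserWarning, match="noisy"):
            at.beta_null_deviation(base_table, metric="bray_curtis", n_iter=50,
                                   seed=0)

    def test_deviation_definition_exact(self, base_table):
        res = at.beta_null_deviation(base_table, metric="bray_curtis", n_iter=99,
                                     seed=3)
        np.testing.assert_allclose(
            res.pairs["deviation"], res.pairs["d_obs"] - res.pairs["null_mean"]
        )

    def test_divergent_exceeds_neutral_deviation(self, metacommunity):
        hot = at.simulate_divergent_dominants(
            metacommunity, 800, np.linspace(25, 55, 9), 3, seed=11)
        amb = at.simulate_neutral_local(metacommunity, 800, 0.5, 9, seed=11)
        dev_hot = at.beta_null_deviation(hot, metric="bray_curtis", n_iter=99,
                                         seed=1).per_sample.mean()
        dev_amb = at.beta_null_deviation(amb, metric="bray_curtis", n_iter=99,
                                         seed=1).per_sample.mean()
        assert dev_hot > dev_amb

    def test_bray_and_unifrac_deviations_correlated(self, chronosequence):
        table, tree, md = (chronosequence["table"], chronosequence["tree"],
                           chronosequence["metadata"])
        bc = at.beta_null_deviation(table, metric="bray_curtis", n_iter=99, seed=2)
        wu = at.beta_null_deviation(table, tree, metric="weighted_unifrac",
                                    n_iter=99, seed=2)
        db = at.per_sample_deviations(bc, md, scope="within_group")
        dw = at.per_sample_deviations(wu, md, scope="within_group")
        r, p = pearsonr(db, dw.reindex(db.index))
        assert r > 0
        assert p < 0.05


class TestDeviationByGroup:
    def test_single_class_refused(self, base_table, chronosequence):
        import pandas as pd

        res = at.beta_null_deviation(base_table, metric="bray_curtis", n_iter=99,
                                     seed=0)
        md = at.SampleFrame(pd.DataFrame(
            {"fire_class": ["reference"] * base_table.n_samples,
             "temperature": 13.0},
            index=base_table.sample_ids,
        ))
        with pytest.raises(ValueError, match="two fire classes"):
            at.deviation_by_group(res, md)

    def test_group_comparison_on_chronosequence(self, chronosequence):
        table, tree, md = (chronosequence["table"], chronosequence["tree"],
                           chronosequence["metadata"])
        res = at.beta_null_deviation(table, metric="bray_curtis", n_iter=99, seed=4)
        rep = at.deviation_by_group(res, md)
        assert rep["group_means"]["fire_affected"] > rep["group_means"]["recovered"]
        assert rep["welch_t"]["p"] < 0.05
        assert "mann_whitney" in rep
        assert len(rep["trajectory"]) == table.n_samples

    def test_permuted_labels_give_uniform_pvalues(self, chronosequence):
        # permuting class labels breaks the association: Welch p-values
        # should be uniform across label permutations
        table, md = chronosequence["table"], chronosequence["metadata"]
        res = at.beta_null_deviation(table, metric="bray_curtis", n_iter=99, seed=4)
        dev = res.per_sample.to_numpy()
        labels = md.fire_class.reindex(res.per_sample.index).to_numpy()
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(labels)
            a = dev[perm == "fire_affected"]
            b = dev[perm == "recovered"]
            pvals.append(ttest_ind(a, b, equal_var=False).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01
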
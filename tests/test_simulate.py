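import numpy as np
import pytest

import assemblytrace as at


class TestMetacommunity:
    def test_single_taxon_pool(self):
        m = at.make_metacommunity(1, seed=0)
        assert m.p.tolist() == [1.0]

    def test_determinism(self):
        a = at.make_metacommunity(50, seed=9)
        b = at.make_metacommunity(50, seed=9)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.thermal_optimum, b.thermal_optimum)

    def test_rank_abundance_log_linear_mid_ranks(self):
        m = at.make_metacommunity(1000, seed=3)
        ranked = np.sort(m.p)[::-1]
        mid = np.arange(300, 700)
        y = np.log(ranked[mid])
        slope, intercept = np.polyfit(mid, y, 1)
        resid = y - (slope * mid + intercept)
        r2 = 1 - resid.var() / y.var()
        assert slope < 0
        assert r2 > 0.95

    def test_invalid_pools_rejected(self):
        with pytest.raises(ValueError):
            at.Metacommunity(["a"], [0.5], [30.0], [5.0])
        with pytest.raises(ValueError):
            at.Metacommunity(["a", "b"], [0.5, 0.5], [30.0, 40.0], [5.0, -1.0])


class TestNeutralUrn:
    def test_m1_matches_multinomial_moments(self, metacommunity):
        n_samples, N = 200, 400
        t = at.simulate_neutral_local(metacommunity, N, 1.0, n_samples, seed=5)
        rel_mean = t.counts.mean(axis=0)
        expected = N * np.asarray(
            [metacommunity.p[metacommunity.taxon_ids.index(x)] for x in t.taxon_ids]
        )
        se = np.sqrt(expected * (1 - expected / N) / n_samples)
        # all but a few taxa within 3 SE of the multinomial mean
        ok = np.abs(rel_mean - expected) < 3 * np.maximum(se, 1e-9)
        assert ok.mean() > 0.95

    def test_richness_decreases_as_m_shrinks(self, metacommunity):
        rich = []
        for m in (1.0, 0.3, 0.05, 0.01):
            t = at.simulate_neutral_local(metacommunity, 400, m, 12, seed=7)
            rich.append((t.counts > 0).sum(axis=1).mean())
        assert rich == sorted(rich, reverse=True)

    def test_seed_determinism(self, metacommunity):
        a = at.simulate_neutral_local(metacommunity, 200, 0.3, 4, seed=2)
        b = at.simulate_neutral_local(metacommunity, 200, 0.3, 4, seed=2)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_sum_to_N(self, metacommunity):
        t = at.simulate_neutral_local(metacommunity, 250, 0.2, 5, seed=1)
        assert (t.depths == 250).all()

    def test_tiny_N_refused(self, metacommunity):
        with pytest.raises(ValueError, match="N < 10"):
            at.simulate_neutral_local(metacommunity, 5, 0.5, 3, seed=0)
        with pytest.raises(ValueError, match="m must be"):
            at.simulate_neutral_local(metacommunity, 100, 0.0, 3, seed=0)


class TestNicheUrn:
    def test_sigma_zero_identical_to_neutral(self, metacommunity):
        temps = np.full(5, 13.0)
        a = at.simulate_niche_local(metacommunity, 300, 0.3, temps, 0.0, seed=4)
        b = at.simulate_neutral_local(metacommunity, 300, 0.3, 5, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_strong_filter_concentrates_on_local_optima(self, metacommunity):
        T = 55.0
        t = at.simulate_niche_local(metacommunity, 500, 0.3, [T] * 5, 8.0, seed=6)
        opt = np.asarray(
            [metacommunity.thermal_optimum[metacommunity.taxon_ids.index(x)]
             for x in t.taxon_ids]
        )
        near = np.abs(opt - T) < 10
        frac_near = t.counts[:, near].sum() / t.counts.sum()
        assert frac_near > 0.9

    def test_selection_reduces_richness_paired(self, metacommunity):
        neutral = at.simulate_neutral_local(metacommunity, 400, 0.3, 25, seed=8)
        niche = at.simulate_niche_local(
            metacommunity, 400, 0.3, np.full(25, 40.0), 5.0, seed=8
        )
        r0 = (neutral.counts > 0).sum(axis=1).mean()
        r5 = (niche.counts > 0).sum(axis=1).mean()
        assert r5 < r0


class TestDivergentDominants:
    def test_between_group_exceeds_within_group_dissimilarity(self, metacommunity):
        t = at.simulate_divergent_dominants(
            metacommunity, 1000, np.full(9, 45.0), 3, seed=3, n_boost=8
        )
        d = at.bray_curtis(t).values
        g = np.array(t.provenance["group_of_sample"])
        same = g[:, None] == g[None, :]
        iu = np.triu_indices(9, k=1)
        within = d[iu][same[iu]]
        between = d[iu][~same[iu]]
        assert between.mean() > within.mean()

    def test_boosted_taxa_detectable_everywhere(self, metacommunity):
        t = at.simulate_divergent_dominants(
            metacommunity, 2000, np.full(30, 45.0), 3, seed=3, n_boost=8
        )
        boosted = [x for grp in t.provenance["boosted_taxa_by_group"] for x in grp]
        cols = [t.taxon_ids.index(x) for x in boosted]
        occurrence = (t.counts[:, cols] > 0).mean(axis=0)
        assert (occurrence >= 0.9).all()

    def test_single_group_no_extra_divergence(self, metacommunity):
        one = at.simulate_divergent_dominants(
            metacommunity, 800, np.full(6, 45.0), 1, seed=5, n_boost=8
        )
        three = at.simulate_divergent_dominants(
            metacommunity, 800, np.full(6, 45.0), 3, seed=5, n_boost=8
        )
        assert at.bray_curtis(one).condensed().mean() < \
            at.bray_curtis(three).condensed().mean()


class TestSimulateTree:
    def test_two_taxa_cherry(self):
        tree = at.simulate_tree(["A", "B"], seed=1)
        tips = sorted(t.name for t in tree.tips())
        assert tips == ["A", "B"]
        assert len(tree.children) == 2

    def test_tip_set_matches_taxa(self, metacommunity):
        tree = at.simulate_tree(metacommunity.taxon_ids, seed=2)
        assert sorted(t.name for t in tree.tips()) == sorted(metacommunity.taxon_ids)

    def test_clustered_mode_aggregates_thermophiles(self, metacommunity):
        tree = at.simulate_tree(
            metacommunity.taxon_ids, seed=3,
            thermal_optimum=metacommunity.thermal_optimum,
        )
        hot = {
            x for x, o in zip(metacommunity.taxon_ids, metacommunity.thermal_optimum)
            if o >= 38.0
        }
        dm = tree.tip_tip_distances()
        ids = list(dm.ids)
        hot_idx = [i for i, x in enumerate(ids) if x in hot]
        cold_idx = [i for i, x in enumerate(ids) if x not in hot]
        within = dm.data[np.ix_(hot_idx, hot_idx)]
        across = dm.data[np.ix_(hot_idx, cold_idx)]
        n_hot = len(hot_idx)
        within_mean = within[np.triu_indices(n_hot, k=1)].mean()
        assert within_mean < across.mean()


def test_chronosequence_layout(chronosequence):
    table = chronosequence["table"]
    md = chronosequence["metadata"]
    assert table.n_samples == 18
    counts = md.fire_class.value_counts()
    assert counts["reference"] == 2
    assert counts["recovered"] == 7
    assert counts["fire_affected"] == 9
    temps = md.temperature
    hot = md.fire_class == "fire_affected"
    assert temps[hot].between(21, 58).all()
    assert temps[~hot].between(12, 15).all()
    # tree covers the table
    tips = {t.name for t in chronosequence["tree"].tips()}
    assert set(table.taxon_ids) <= tips
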
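"""Enrichment engine: chi-square weighting, running-sum scores against
exhaustive oracles, the gene-label permutation null, and Storey q-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from dgsea import (
    DirectionalGSEA,
    GeneSetCollection,
    chisq_from_p,
    enrichment_score,
    permutation_test,
    qvalues,
)
from conftest import make_stats, random_null_stats


class TestChisqFromP:
    def test_known_quantiles(self):
        assert chisq_from_p(1.0) == pytest.approx(0.0, abs=1e-12)
        # 1-df chi-square median and the classic 0.05 critical value
        assert chisq_from_p(0.5) == pytest.approx(0.45493642, abs=1e-7)
        assert chisq_from_p(0.05) == pytest.approx(3.84145882, abs=1e-7)

    def test_inverse_cdf_round_trip(self):
        x = np.linspace(1e-6, 60.0, 200)
        assert np.allclose(chisq_from_p(sps.chi2.sf(x, 1)), x, atol=1e-9)

    def test_strictly_decreasing(self):
        p = np.linspace(0.01, 1.0, 50)
        assert (np.diff(chisq_from_p(p)) < 0).all()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_is_error(self, bad):
        with pytest.raises(ValueError):
            chisq_from_p(bad)


class TestEnrichmentScore:
    def test_hand_enumerated_singleton(self):
        w = pd.Series([2.0, 1.0, 1.0], index=["g1", "g2", "g3"])
        es, leading = enrichment_score(w, {"g1"})
        assert es == pytest.approx(1.0)
        assert leading == ["g1"]

    def test_bottom_ranked_singleton_is_negative(self):
        w = pd.Series([2.0, 1.0, 0.5], index=["g1", "g2", "g3"])
        es, leading = enrichment_score(w, {"g3"})
        # misses g1, g2 first: running sum reaches -2/2 before the hit
        assert es == pytest.approx(-1.0)
        assert leading == ["g3"]

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        w = pd.Series(rng.exponential(size=50), index=[f"g{i:02d}" for i in range(50)])
        for k in (1, 5, 20):
            es, _ = enrichment_score(w, list(w.index[:k]))
            assert -1.0 <= es <= 1.0

    def test_exhaustive_mean_on_six_gene_universe(self):
        """With equal weights the ES distribution over all k-subsets equals
        the label-permutation distribution; compare the exhaustive mean with
        a Monte-Carlo sample of random subsets."""
        genes = [f"g{i}" for i in range(6)]
        w = pd.Series(1.0, index=genes)
        k = 2
        all_es = [enrichment_score(w, set(s))[0] for s in itertools.combinations(genes, k)]
        exact_mean = np.mean(all_es)
        rng = np.random.default_rng(0)
        mc = [
            enrichment_score(w, set(rng.choice(genes, k, replace=False)))[0]
            for _ in range(3000)
        ]
        se = np.std(mc, ddof=1) / np.sqrt(len(mc))
        assert abs(np.mean(mc) - exact_mean) < 3 * se

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:02d}" for i in range(20)]
        w = rng.exponential(size=20)
        # distinct weights: relabelling genes consistently cannot change ES
        weights = pd.Series(w, index=genes)
        members = genes[3:8]
        es1, _ = enrichment_score(weights, members)
        perm = rng.permutation(20)
        relabel = {genes[i]: genes[perm[i]] for i in range(20)}
        weights2 = pd.Series(w, index=[relabel[g] for g in genes])
        es2, _ = enrichment_score(weights2, [relabel[g] for g in members])
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_zero_weight_set_is_error(self):
        w = pd.Series([1.0, 1.0, 0.0], index=["g1", "g2", "g3"])
        with pytest.raises(ValueError, match="zero total weight"):
            enrichment_score(w, {"g3"})

    def test_set_equal_to_universe_is_error(self):
        w = pd.Series([1.0, 2.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(w, {"g1", "g2"})


def _exhaustive_permutation_p(weights: pd.Series, members) -> float:
    """Oracle: exact gene-label permutation p by full enumeration."""
    genes = list(weights.index)
    w = weights.to_numpy()
    obs, _ = enrichment_score(weights, members)
    es_all = []
    for perm in itertools.permutations(range(len(genes))):
        permuted = pd.Series(w[list(perm)], index=genes)
        es_all.append(enrichment_score(permuted, members)[0])
    return float(np.mean(np.asarray(es_all) >= obs - 1e-12))


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_on_four_genes(self):
        stats = make_stats([2.5, 1.2, -0.3, -1.8], genes=["g1", "g2", "g3", "g4"])
        coll = GeneSetCollection({"S": ["g1", "g2"]})
        weights = stats["chi2_up"]
        p_exact = _exhaustive_permutation_p(weights, ["g1", "g2"])
        n_perm = 10_000
        res = permutation_test(stats, coll, "up", n_perm=n_perm, seed=123, size_min=1)
        p_hat = res["p"].iloc[0]
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_hat - p_exact) < 3 * se + 1 / n_perm

    def test_observed_at_distribution_minimum_gives_p_one(self):
        # the singleton set holds the strictly smallest weight, so the
        # observed ES is -1, the minimum of the permutation distribution:
        # every permuted ES is >= observed and the +1 convention yields p = 1
        stats = make_stats([3.0, 2.0, 1.0, 0.5, 0.2, -2.0])
        worst = stats["chi2_up"].idxmin()
        coll = GeneSetCollection({"S": [worst]})
        res = permutation_test(stats, coll, "up", n_perm=50, seed=0, size_min=1)
        assert res["es"].iloc[0] == pytest.approx(-1.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_p_floor_is_one_over_r_plus_one(self):
        stats = make_stats([6.0, 5.0, 0.1, 0.05, -0.1, -0.2, 0.0, 0.3])
        coll = GeneSetCollection({"S": list(stats.index[:2])})
        res = permutation_test(stats, coll, "up", n_perm=200, seed=1, size_min=1)
        assert res["p"].iloc[0] >= 1 / 201

    def test_reproducible_to_the_bit(self):
        stats = random_null_stats(60, seed=5)
        coll = GeneSetCollection({f"S{i}": list(stats.index[i * 5:(i + 1) * 5]) for i in range(6)})
        a = permutation_test(stats, coll, "down", n_perm=300, seed=9)
        b = permutation_test(stats, coll, "down", n_perm=300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_type_one_error_calibration(self):
        """Disjoint sets on null statistics: directional enrichment p < 0.05
        for about 5% of sets (99% binomial interval)."""
        stats = random_null_stats(600, seed=17)
        coll = GeneSetCollection(
            {f"S{i:02d}": list(stats.index[i * 10:(i + 1) * 10]) for i in range(60)}
        )
        res = permutation_test(stats, coll, "up", n_perm=499, seed=3)
        frac = (res["p"] < 0.05).mean()
        half = 2.58 * np.sqrt(0.05 * 0.95 / 60)
        assert 0.05 - half <= frac <= 0.05 + half

    def test_empty_collection_after_filtering_is_error(self):
        stats = random_null_stats(20, seed=0)
        coll = GeneSetCollection({"S": list(stats.index[:2])})
        with pytest.raises(ValueError, match="too_small=1"):
            permutation_test(stats, coll, "up", n_perm=10, seed=0, size_min=3)

    def test_nperm_below_one_is_error(self):
        stats = random_null_stats(20, seed=0)
        coll = GeneSetCollection({"S": list(stats.index[:5])})
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(stats, coll, "up", n_perm=0, seed=0)


class TestQvalues:
    def test_hand_example_uniform_spacing(self):
        # #{p > 0.5} = 2, pi0 = 2 / (0.5 * 4) = 1; BH then cummin -> all 0.8
        assert np.allclose(qvalues([0.2, 0.4, 0.6, 0.8]), [0.8, 0.8, 0.8, 0.8])

    def test_single_p(self):
        assert qvalues([0.03]) == pytest.approx([0.03])

    def test_all_identical(self):
        q = qvalues([0.2] * 5)
        pi0 = min(1.0, max(0 / (0.5 * 5), 1 / 5))
        assert np.allclose(q, pi0 * 0.2)

    def test_pi0_one_reproduces_bh(self):
        vectors = [
            [0.01, 0.02, 0.8, 0.9, 0.5],
            [0.001, 0.2, 0.2, 0.7, 0.04, 0.9, 1.0],
            list(np.linspace(0.05, 0.95, 10)),
        ]
        for p in vectors:
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(qvalues(p, pi0=1.0), bh, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_and_bounded(self, p):
        q = qvalues(p)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            qvalues([])


class TestRunGsea:
    def test_direction_swap_antisymmetry(self):
        stats = random_null_stats(80, seed=21)
        flipped = make_stats(-stats["stat"].to_numpy(), genes=list(stats.index))
        coll = GeneSetCollection(
            {f"S{i}": list(stats.index[i * 8:(i + 1) * 8]) for i in range(10)}
        )
        up = permutation_test(stats, coll, "up", n_perm=200, seed=4)
        down = permutation_test(flipped, coll, "down", n_perm=200, seed=4)
        assert np.allclose(up["es"], down["es"], atol=1e-12)
        assert np.allclose(up["p"], down["p"], atol=1e-12)

    def test_both_directions_with_separate_qvalues(self, effect_cohort):
        from dgsea import differential_stats

        cm, truth, coll = effect_cohort
        stats = differential_stats(cm).table
        results = DirectionalGSEA(stats, coll, n_perm=300).fit(seed=2)
        table = results.table
        assert set(table["direction"]) == {"up", "down"}
        for direction in ("up", "down"):
            sub = table[table["direction"] == direction]
            assert np.allclose(
                np.sort(sub["q"].to_numpy()),
                np.sort(qvalues(sub["p"].to_numpy())),
            )
        # embedded up-sets carry the smallest up-direction p-values
        up_truth = {s for s, d in truth.set_direction.items() if d == "up"}
        up_tab = table[table["direction"] == "up"].set_index("set")
        best = set(up_tab["p"].nsmallest(len(up_truth)).index)
        assert best == up_truth

    def test_summary_mentions_counts(self, effect_cohort):
        from dgsea import differential_stats

        cm, _, coll = effect_cohort
        stats = differential_stats(cm).table
        res = DirectionalGSEA(stats, coll, n_perm=100).fit(seed=0)
        text = res.summary()
        assert "permutations: 100" in text
        assert "sets tested" in text
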
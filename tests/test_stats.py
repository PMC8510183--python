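"""PERMANOVA, dispersion homogeneity, dissimilarity group tests, the
stored-vs-baseline statistic and negative-binomial differential abundance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from storagefx import stats as sfx_stats
from storagefx.ordination import DistanceMatrix


def _euclidean_dm(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(labels, squareform(pdist(points)))


def _groups(dm, labels):
    return pd.Series(labels, index=list(dm.ids))


class TestPermanova:
    def test_no_between_group_signal(self, rng):
        pts = rng.normal(size=(4, 2))
        dm = _euclidean_dm(np.vstack([pts, pts]))  # group b duplicates group a
        res = sfx_stats.permanova(dm, _groups(dm, ["a"] * 4 + ["b"] * 4), 199, seed=0)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_matches_exhaustive_enumeration_n6(self, rng):
        """Permutation p at n=6 (3 vs 3) agrees with enumerating all C(6,3)
        relabelings."""
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        dm = _euclidean_dm(pts)
        labels = ["a"] * 3 + ["b"] * 3
        res = sfx_stats.permanova(dm, _groups(dm, labels), 999, seed=1)
        d2 = dm.data**2
        f_all = []
        for idx in combinations(range(6), 3):
            codes = np.array([0 if i in idx else 1 for i in range(6)])
            f_all.append(sfx_stats._permanova_stats(d2, codes, 2)[0])
        f_obs = sfx_stats._permanova_stats(
            d2, np.array([0, 0, 0, 1, 1, 1]), 2
        )[0]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
        se = np.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(res.p_value - exact_p) <= 4 * se + 2 / 999

    def test_matches_scikit_bio(self, rng):
        """Independent oracle: pseudo-F equals skbio's PERMANOVA statistic."""
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(12, 3))
        pts[:6, 0] += 1.0
        dm = _euclidean_dm(pts)
        labels = ["a"] * 6 + ["b"] * 6
        res = sfx_stats.permanova(dm, _groups(dm, labels), 99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, list(dm.ids)),
            grouping=labels,
            permutations=99,
        )
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_invariant_to_sample_reordering(self, rng):
        pts = rng.normal(size=(10, 2))
        pts[:5] += 1.0
        dm = _euclidean_dm(pts)
        labels = _groups(dm, ["a"] * 5 + ["b"] * 5)
        res1 = sfx_stats.permanova(dm, labels, 99, seed=0)
        order = list(rng.permutation(list(dm.ids)))
        dm2 = dm.subset(order)
        res2 = sfx_stats.permanova(dm2, labels[order], 99, seed=0)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f, rel=1e-12)
        assert res1.r2 == pytest.approx(res2.r2, rel=1e-12)

    def test_singleton_group_rejected(self, rng):
        dm = _euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="singleton"):
            sfx_stats.permanova(dm, _groups(dm, ["a", "a", "a", "a", "b"]), 99)


class TestBetadisper:
    def test_mirror_image_groups_homogeneous(self, rng):
        pts = rng.normal(size=(10, 2))
        dm = _euclidean_dm(np.vstack([pts, -pts]))  # identical dispersions
        res = sfx_stats.betadisper(
            dm, _groups(dm, ["a"] * 10 + ["b"] * 10), 199, seed=0
        )
        assert res.p_value > 0.2

    def test_detects_dispersion_difference(self):
        """Tight vs diffuse Gaussian clusters: significant in >= 90% of runs."""
        hits = 0
        for k in range(20):
            rng = np.random.default_rng(1000 + k)
            tight = rng.normal(scale=0.2, size=(10, 2))
            diffuse = rng.normal(scale=2.0, size=(10, 2))
            dm = _euclidean_dm(np.vstack([tight, diffuse]))
            res = sfx_stats.betadisper(
                dm, _groups(dm, ["a"] * 10 + ["b"] * 10), 199, seed=k
            )
            hits += res.p_value < 0.05
        assert hits >= 18

    def test_distances_nonnegative_for_euclidean_input(self, rng):
        pts = rng.normal(size=(12, 3))
        dm = _euclidean_dm(pts)
        res = sfx_stats.betadisper(dm, _groups(dm, ["a"] * 6 + ["b"] * 6), 49, seed=0)
        assert (res.distances >= 0).all()

    def test_group_of_one_rejected(self, rng):
        dm = _euclidean_dm(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="two samples"):
            sfx_stats.betadisper(dm, _groups(dm, ["a", "a", "a", "b"]), 49)


class TestDissimilarityGroups:
    def test_hand_computed_kruskal_wallis(self):
        """Three groups of two with distinct values 1..6: H from the rank
        formula 12/(N(N+1)) * sum n_g rbar_g^2 - 3(N+1)."""
        vals = {("a", i): v for i, v in enumerate([1.0, 2.0])}
        vals.update({("b", i): v for i, v in enumerate([3.0, 4.0])})
        vals.update({("c", i): v for i, v in enumerate([5.0, 6.0])})
        # build a star-shaped distance matrix exposing exactly those six
        # pairwise values via a labeler
        labels = [f"x{i}" for i in range(4)]
        d = np.zeros((4, 4))
        pair_vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        pair_groups = ["a", "a", "b", "b", "c", "c"]
        pairs = list(combinations(range(4), 2))
        for (i, j), v in zip(pairs, pair_vals):
            d[i, j] = d[j, i] = v
        dm = DistanceMatrix(labels, d)
        lookup = {
            frozenset((labels[i], labels[j])): g
            for (i, j), g in zip(pairs, pair_groups)
        }
        res = sfx_stats.dissimilarity_groups(
            dm, lambda a, b: lookup[frozenset((a, b))]
        )
        rbar = {"a": 1.5, "b": 3.5, "c": 5.5}
        h_manual = 12 / (6 * 7) * sum(2 * r**2 for r in rbar.values()) - 3 * 7
        assert res.kruskal_h == pytest.approx(h_manual, rel=1e-12)

    def test_disjoint_groups_flagged_by_dunn(self, rng):
        n = 8
        pts_a = rng.normal(scale=0.01, size=(n, 1))
        pts_b = pts_a + 50.0
        dm = _euclidean_dm(np.vstack([pts_a, pts_b]))
        ids = list(dm.ids)

        def labeler(a, b):
            ia, ib = ids.index(a), ids.index(b)
            if ia < n and ib < n:
                return "within_a"
            if ia >= n and ib >= n:
                return "within_b"
            return "between"

        res = sfx_stats.dissimilarity_groups(dm, labeler)
        assert res.kruskal_p < 0.01
        assert res.dunn is not None
        row = res.dunn.set_index(["group_a", "group_b"]).loc[("between", "within_a")]
        assert row["p_adjusted"] < 0.05

    def test_null_calibration(self):
        """All groups from one distribution: KW p roughly uniform."""
        pvals = []
        for k in range(200):
            rng = np.random.default_rng(k)
            vals = rng.random(30)
            groups = np.repeat(["a", "b", "c"], 10)
            from scipy.stats import kruskal

            pvals.append(kruskal(*(vals[groups == g] for g in "abc")).pvalue)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_small_group_excluded_with_warning(self, rng):
        dm = _euclidean_dm(rng.normal(size=(4, 2)))
        ids = list(dm.ids)

        def labeler(a, b):
            return "solo" if {a, b} == {ids[0], ids[1]} else "rest"

        with pytest.warns(UserWarning, match="solo"):
            with pytest.raises(ValueError, match="two groups"):
                sfx_stats.dissimilarity_groups(dm, labeler)


class TestDissimilarityToBaseline:
    @staticmethod
    def _sheet(ids, matrix, conds, times):
        return pd.DataFrame(
            {
                "matrix": matrix,
                "condition": conds,
                "time_h": times,
            },
            index=ids,
        )

    def test_identical_stored_samples_give_zero(self):
        pts = np.array([[0.0], [0.0], [0.0], [0.0], [0.0], [0.0]])
        dm = _euclidean_dm(pts)
        sheet = self._sheet(
            list(dm.ids), "P1", ["0h"] * 3 + ["16h_5C"] * 3, [0] * 3 + [16] * 3
        )
        out = sfx_stats.dissimilarity_to_baseline(dm, sheet)
        stored = out[out["condition"] == "16h_5C"].iloc[0]
        assert stored["mean_dissimilarity"] == 0.0

    def test_zero_hour_row_is_within_replicate_mean(self):
        pts = np.array([[0.0], [1.0], [3.0], [10.0], [10.0], [10.0]])
        dm = _euclidean_dm(pts)
        sheet = self._sheet(
            list(dm.ids), "P1", ["0h"] * 3 + ["64h_22C"] * 3, [0] * 3 + [64] * 3
        )
        out = sfx_stats.dissimilarity_to_baseline(dm, sheet).set_index("condition")
        # within-replicate pairs at 0h: |0-1|, |0-3|, |1-3| -> mean 2
        assert out.loc["0h", "mean_dissimilarity"] == pytest.approx(2.0)
        assert out.loc["0h", "n_pairs"] == 3
        # stored-to-baseline: 9 cross pairs, all |10 - {0,1,3}|
        expected = np.mean([10, 9, 7] * 3)
        assert out.loc["64h_22C", "mean_dissimilarity"] == pytest.approx(expected)
        assert out.loc["64h_22C", "n_pairs"] == 9

    def test_missing_baseline_rejected(self, rng):
        dm = _euclidean_dm(rng.normal(size=(3, 1)))
        sheet = self._sheet(list(dm.ids), "P1", ["16h_5C"] * 3, [16] * 3)
        with pytest.raises(ValueError, match="0 h"):
            sfx_stats.dissimilarity_to_baseline(dm, sheet)


class TestCustomSizeFactors:
    def test_direct_evaluation(self):
        tbl = pd.DataFrame({"s1": [60, 40], "s2": [200, 100]})
        sf = sfx_stats.custom_size_factors(tbl)
        assert sf.tolist() == pytest.approx([0.5, 1.5])

    def test_equal_totals_give_unit_factors(self):
        tbl = pd.DataFrame({"s1": [10, 10], "s2": [5, 15]})
        assert sfx_stats.custom_size_factors(tbl).tolist() == [1.0, 1.0]

    def test_mean_is_one(self, random_table):
        sf = sfx_stats.custom_size_factors(random_table + 1)
        assert sf.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        tbl = pd.DataFrame({"s1": [0, 0], "s2": [5, 15]})
        with pytest.raises(ValueError, match="zero-total"):
            sfx_stats.custom_size_factors(tbl)


def _simulate_nb_pair(rng, n_taxa, lfc_log2, dispersion=0.05, n_rep=3, base=None):
    """Two NB conditions with planted log2 fold changes and size factors."""
    base = base if base is not None else np.exp(rng.normal(np.log(200), 1.0, n_taxa))
    s = np.concatenate([rng.uniform(0.6, 1.4, n_rep), rng.uniform(0.6, 1.4, n_rep)])
    mu = np.outer(base, s[:n_rep])
    mu2 = np.outer(base * 2.0**lfc_log2, s[n_rep:])
    shape = 1.0 / dispersion
    counts = np.hstack(
        [
            rng.poisson(rng.gamma(shape, m * dispersion))
            for m in (mu, mu2)
        ]
    )
    cols = [f"a{r}" for r in range(n_rep)] + [f"b{r}" for r in range(n_rep)]
    tbl = pd.DataFrame(counts, columns=cols, index=[f"t{i}" for i in range(n_taxa)])
    groups = pd.Series(["A"] * n_rep + ["B"] * n_rep, index=cols)
    sf = pd.Series(s, index=cols)
    return tbl, sf, groups


class TestNbWaldTest:
    def test_identical_constant_counts_null(self):
        tbl = pd.DataFrame(
            {c: [50, 120, 7] for c in ["a1", "a2", "a3", "b1", "b2", "b3"]},
            index=["t1", "t2", "t3"],
        )
        sf = pd.Series(1.0, index=tbl.columns)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=tbl.columns)
        res = sfx_stats.nb_wald_test(tbl, sf, groups, comparison=("A", "B"))
        assert np.allclose(res.table["log2_fold_change"], 0.0)
        assert (res.table["p_value"] > 0.9).all()

    def test_planted_lfc_recovered(self, rng):
        tbl, sf, groups = _simulate_nb_pair(rng, 200, lfc_log2=1.0)
        res = sfx_stats.nb_wald_test(tbl, sf, groups, comparison=("A", "B"))
        assert 0.8 <= res.table["log2_fold_change"].mean() <= 1.2

    def test_lfc_sign_matches_planted_direction(self, rng):
        lfc = np.where(rng.random(200) < 0.5, 2.0, -2.0)
        tbl, sf, groups = _simulate_nb_pair(
            rng, 200, lfc_log2=lfc, base=np.full(200, 300.0)
        )
        res = sfx_stats.nb_wald_test(tbl, sf, groups, comparison=("A", "B"))
        strong = res.table["base_mean"] >= 50
        agree = np.sign(res.table.loc[strong, "log2_fold_change"]) == np.sign(
            lfc[strong.to_numpy()]
        )
        assert agree.mean() >= 0.95

    def test_all_zero_taxon_excluded(self, rng):
        tbl, sf, groups = _simulate_nb_pair(rng, 20, lfc_log2=0.0)
        tbl.iloc[0] = 0
        res = sfx_stats.nb_wald_test(tbl, sf, groups, comparison=("A", "B"))
        assert res.excluded == ["t0"]
        assert "t0" not in res.table.index

    def test_single_replicate_rejected(self, rng):
        tbl, sf, groups = _simulate_nb_pair(rng, 10, lfc_log2=0.0)
        cols = ["a0", "b0", "b1", "b2"]
        with pytest.raises(ValueError, match="replicates"):
            sfx_stats.nb_wald_test(
                tbl[cols], sf[cols], groups[cols], comparison=("A", "B")
            )


class TestSignificanceCounts:
    @staticmethod
    def _result(taxa, sig, pair):
        table = pd.DataFrame(
            {
                "p_value": [0.001 if s else 0.5 for s in sig],
                "significant": sig,
            },
            index=taxa,
        )
        return sfx_stats.DiffAbundanceResult(
            table=table, comparison=pair, excluded=[], alpha=0.01
        )

    def test_no_significant_comparisons(self):
        res = {("c1", "c2"): self._result(["t1"], [False], ("c1", "c2"))}
        out = sfx_stats.significance_counts(res)
        assert (out == 0).all().all()

    def test_counts_bounded_by_comparisons(self):
        conds = [f"c{i}" for i in range(4)]
        res = {
            (a, b): self._result(["t1"], [True], (a, b))
            for a, b in combinations(conds, 2)
        }
        out = sfx_stats.significance_counts(res)
        assert (out.loc["t1"] == 3).all()  # each condition in 3 of 6 pairs

    def test_single_condition_effect_stands_out(self):
        conds = ["c1", "c2", "c3"]
        res = {}
        for a, b in combinations(conds, 2):
            sig = "c3" in (a, b)  # only comparisons involving c3 significant
            res[(a, b)] = self._result(["t1"], [sig], (a, b))
        out = sfx_stats.significance_counts(res)
        assert out.loc["t1", "c3"] == 2
        assert out.loc["t1", "c1"] == 1
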
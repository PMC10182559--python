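import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycoscape import enrichment as en
from conftest import make_fm


def exact_rank_sum_oracle(x, y):
    """Brute-force two-sided rank-sum p by full enumeration (independent)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    d_obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 9))
        y = rng.normal(0.5, 1, rng.integers(3, 9))
        _, p = en.wilcoxon_rank_sum(x, y, method="exact")
        assert p == pytest.approx(exact_rank_sum_oracle(x, y), abs=1e-12)

    def test_exact_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 4.0])
        _, p = en.wilcoxon_rank_sum(x, y, method="exact")
        assert p == pytest.approx(exact_rank_sum_oracle(x, y), abs=1e-12)

    def test_constant_feature_p_one(self):
        _, p = en.wilcoxon_rank_sum(np.ones(10), np.ones(12),
                                    method="asymptotic")
        assert p == 1.0

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1, 25)
        _, p = en.wilcoxon_rank_sum(x, y, method="asymptotic")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestRankFeatures:
    def test_spiked_feature_ranks_first(self, panel):
        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 0.3, (120, 12))
        labels = np.repeat([0, 1, 2], 40)
        X[labels == 1, 3] *= 10.0
        fm = make_fm(X, panel)
        table = en.rank_features(fm, labels)
        top = table[table["cluster"] == 1].iloc[0]
        assert top["feature"] == fm.values.columns[3]
        assert top["q"] < 0.05

    def test_permutation_null_fdr_control(self, panel):
        rng = np.random.default_rng(42)
        X = rng.lognormal(0, 0.5, (60, 20))
        n_reps = 200
        frac_sig = []
        for _ in range(n_reps):
            labels = rng.permutation(np.repeat([0, 1], 30))
            t = en.rank_features(X, labels)
            frac_sig.append((t["q"] < 0.05).mean())
        # binomial tolerance: mean fraction of q<0.05 under the null
        assert np.mean(frac_sig) <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / (n_reps * 40)
        )

    def test_single_cluster_rejected(self, panel):
        X = np.random.default_rng(0).random((10, 4))
        with pytest.raises(ValueError, match="2 clusters"):
            en.rank_features(X, np.zeros(10, dtype=int))

    def test_q_at_least_p(self, panel):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 1, (40, 8))
        t = en.rank_features(X, np.repeat([0, 1], 20))
        assert (t["q"] >= t["p"] - 1e-15).all()
        assert ((t["p"] >= 0) & (t["p"] <= 1)).all()

    def test_one_row_per_cluster_feature(self, panel):
        rng = np.random.default_rng(4)
        X = rng.random((30, 6))
        t = en.rank_features(X, np.repeat([0, 1, 2], 10))
        assert len(t) == 3 * 6
        assert not t.duplicated(["cluster", "feature"]).any()


class TestChainProfile:
    def test_total_additive(self, panel, noiseless_fm):
        fm, _ = noiseless_fm
        total = en.total_glycogen(fm)
        cols = fm.class_columns("glycogen_dp")
        half1 = fm.values[cols[:6]].to_numpy().sum(axis=1)
        half2 = fm.values[cols[6:]].to_numpy().sum(axis=1)
        np.testing.assert_allclose(total, half1 + half2, rtol=1e-12)

    def test_single_pixel_total(self, panel):
        dp_count = len(panel.by_class("glycogen_dp"))
        X = np.zeros((1, len(panel)))
        X[0, panel.by_class("glycogen_dp")[:3]] = [1, 2, 3]
        fm = make_fm(X, panel)
        assert en.total_glycogen(fm)[0] == 6.0

    def test_group_ratio_recovers_generator(self, panel, noiseless_fm):
        fm, truth = noiseless_fm
        labels = truth.labels_for(fm.coords)
        sel = np.isin(labels, [1, 2])
        import pandas as pd

        from glycoscape import preprocess as pp

        sub = pp.FeatureMatrix(
            values=fm.values.loc[sel].reset_index(drop=True),
            tic=fm.tic[sel],
            frame=fm.frame.loc[sel].reset_index(drop=True),
            panel=panel,
            normalized=True,
        )
        prof = en.chain_profile(sub, labels[sel])
        # signature ratio 2.4 survives TIC normalization only approximately;
        # compare on the raw per-pixel sums instead
        t1 = prof.total_by_pixel[prof.groups == 1].mean()
        t2 = prof.total_by_pixel[prof.groups == 2].mean()
        assert t2 / t1 == pytest.approx(
            2.4 * (fm.tic[labels == 1][0] / fm.tic[labels == 2][0]),
            rel=1e-9,
        )

    def test_identical_groups_flat_difference(self, panel):
        X = np.tile(np.linspace(1, 2, len(panel)), (20, 1))
        fm = make_fm(X, panel)
        prof = en.chain_profile(fm, np.repeat([0, 1], 10))
        np.testing.assert_allclose(
            prof.mean.loc[0].to_numpy(), prof.mean.loc[1].to_numpy()
        )

    def test_profile_length_equals_dp_count(self, panel, noiseless_fm):
        fm, truth = noiseless_fm
        prof = en.chain_profile(fm, truth.labels_for(fm.coords))
        assert len(prof.dp) == len(panel.by_class("glycogen_dp"))


class TestCompareGroups:
    def test_identical_groups(self):
        x = np.tile(np.arange(10, dtype=float), 2)
        g = np.repeat([0, 1], 10)
        res = en.compare_groups(x, g, design="two_sample_t")
        assert res["p"] == pytest.approx(1.0)
        res = en.compare_groups(
            np.r_[x, x[:10]], np.r_[g, np.full(10, 2)], design="one_way"
        )
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_power_at_two_sigma(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            res = en.compare_groups(
                np.r_[a, b], np.repeat([0, 1], 50), design="two_sample_t"
            )
            rejections += res["p"] < 0.05
        assert rejections / n_sims >= 0.99

    def test_paper_sized_toy_runs(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(1, 0.3, 7), rng.normal(2.4, 0.8, 26)]
        groups = np.r_[np.zeros(7), np.ones(26)]
        res = en.compare_groups(vals, groups, design="two_sample_t")
        assert np.isfinite(res["p"]) and 0 <= res["p"] <= 1

    def test_two_way_anova_with_posthoc(self):
        rng = np.random.default_rng(2)
        dps, groups, vals = [], [], []
        for dp in range(5, 10):
            for g in (0, 1):
                v = rng.normal(dp + (2 if g else 0), 0.5, 6)
                vals.extend(v)
                groups.extend([g] * 6)
                dps.extend([dp] * 6)
        res = en.compare_groups(np.array(vals), np.array(groups),
                                design="two_way", dp=np.array(dps))
        assert res["p_group"] < 1e-6
        assert len(res["posthoc"]) == 5
        assert (res["posthoc"]["p_adj"] >= res["posthoc"]["p"] - 1e-12).all()

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError):
            en.compare_groups(np.arange(3.0), np.array([0, 0, 1]),
                              design="two_sample_t")


class TestOrderedHeatmap:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 5))
        M[4] = M[1]
        res = en.ordered_heatmap(M, top_k=5)
        order = list(res["row_order"])
        assert abs(order.index(1) - order.index(4)) == 1

    def test_blocks_contiguous(self):
        rng = np.random.default_rng(1)
        A = rng.normal(0, 0.1, (10, 8))
        B = rng.normal(5, 0.1, (10, 8))
        M = np.vstack([A, B])
        perm = rng.permutation(20)
        res = en.ordered_heatmap(M[perm], top_k=8)
        ordered_block = (perm < 10)[res["row_order"]]
        # one contiguous run of each block
        changes = np.count_nonzero(np.diff(ordered_block.astype(int)))
        assert changes == 1

    def test_top_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="top_k"):
            en.ordered_heatmap(np.ones((3, 4)), top_k=5)

    def test_nan_rejected(self):
        M = np.ones((4, 4))
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            en.ordered_heatmap(M, top_k=4)

    def test_rank_by_selects_top_features(self):
        M = np.random.default_rng(2).random((5, 10))
        scores = np.arange(10, dtype=float)
        res = en.ordered_heatmap(M, top_k=3, rank_by=scores)
        assert res["columns"] == [7, 8, 9]
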
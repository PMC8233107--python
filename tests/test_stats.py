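"""Split plans, permutation nulls, the three test families, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import brainstates as bs
from brainstates import stats


def test_retained_after_balancing_arithmetic():
    # 3-min blocks at TR 1.5 s are 120 samples; removing one math and one
    # memory presentation from 777 retained points leaves 537
    assert stats.retained_after_balancing(777) == 537
    with pytest.raises(ValueError):
        stats.retained_after_balancing(200)


class TestMakeSplit:
    def test_same_seed_identical(self, mini_features):
        _, tvfc, _ = mini_features
        p1 = stats.make_split(tvfc, seed=5, n_train=40)
        p2 = stats.make_split(tvfc, seed=5, n_train=40)
        assert p1.embed_group == p2.embed_group
        for v in p1.retained_mask:
            assert np.array_equal(p1.retained_mask[v], p2.retained_mask[v])
            assert np.array_equal(p1.train_subsample[v], p2.train_subsample[v])

    def test_groups_partition_volunteers(self, mini_features):
        _, tvfc, _ = mini_features
        plan = stats.make_split(tvfc, seed=2, n_train=40)
        all_vols = sorted(tv.point_meta["volunteer"].iloc[0] for tv in tvfc)
        got = sorted(plan.embed_group + plan.cluster_group + plan.test_group)
        assert got == all_vols
        assert len(plan.embed_group) == len(plan.cluster_group) == \
            len(plan.test_group) == 2

    def test_one_presentation_removed_per_task(self, mini_features):
        _, tvfc, _ = mini_features
        plan = stats.make_split(tvfc, seed=3, n_train=40)
        for tv in tvfc:
            vol = tv.point_meta["volunteer"].iloc[0]
            conds = tv.point_meta["condition"].to_numpy()
            mask = plan.retained_mask[vol]
            for task in ("math", "memory"):
                before = (conds == task).sum()
                after = (conds[mask] == task).sum()
                runs = stats._condition_runs(conds, task)
                assert len(runs) == 2
                assert before - after in {len(r) for r in runs}

    def test_lattice_spacing(self, mini_features):
        _, tvfc, _ = mini_features
        n_train = 40
        plan = stats.make_split(tvfc, seed=4, n_train=n_train)
        for vol, idx in plan.train_subsample.items():
            assert idx.size == n_train
            n_avail = plan.retained_mask[vol].sum()
            gaps = np.diff(np.sort(idx))
            assert gaps.min() >= n_avail // n_train - 1

    def test_indivisible_volunteer_count_errors(self, mini_features):
        _, tvfc, _ = mini_features
        with pytest.raises(ValueError, match="equal groups"):
            stats.make_split(tvfc[:4], seed=1, n_train=40)


class TestPermutationNull:
    def test_identical_labels_degenerate(self):
        a = np.array([1, 1, 2, 2, 2])
        lab = np.array(["x"] * 5)
        df = stats.permutation_null(a, lab, n_perm=50, seed=0)
        assert np.allclose(df["null_sd"], 0.0)
        assert np.allclose(df["observed"], df["null_mean"])

    def test_balanced_binary_labels_hypergeometric_mean(self, rng):
        n = 2000
        a = np.repeat([1, 2], n // 2)
        lab = rng.permutation(np.repeat(["p", "q"], n // 2))
        df = stats.permutation_null(a, lab, n_perm=300, seed=1)
        expect = n / 4  # cluster_size * label_fraction
        for _, row in df.iterrows():
            assert abs(row["null_mean"] - expect) / expect < 0.05

    def test_same_seed_reproducible(self, rng):
        a = rng.integers(1, 4, 200)
        lab = rng.integers(0, 3, 200)
        d1 = stats.permutation_null(a, lab, n_perm=100, seed=9)
        d2 = stats.permutation_null(a, lab, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(d1, d2)

    def test_unassigned_points_excluded(self):
        a = np.array([0, 0, 1, 1])
        lab = np.array(["x", "x", "x", "y"])
        df = stats.permutation_null(a, lab, n_perm=10, seed=0)
        assert df["observed"].sum() == 2  # only the two assigned points


class TestGeneralizability:
    def test_perfectly_mixed_volunteers_all_in_top_bin(self, rng):
        a = np.repeat([1, 2, 3, 4], 240)
        vols = np.tile([f"v{i}" for i in range(6)], 160)
        res = stats.volunteer_generalizability(a, vols, seed=0)
        assert np.isclose(res.bins[6], 100.0)

    def test_volunteer_owned_clusters_in_bottom_bin(self, rng):
        a = np.repeat([1, 2, 3], 300)
        vols = np.repeat(["v0", "v1", "v2"], 300)
        res = stats.volunteer_generalizability(a, vols, seed=0)
        assert res.bins[1] == 100.0

    def test_bins_sum_to_100(self, rng):
        a = rng.integers(0, 5, 600)  # includes unassigned 0s
        vols = rng.choice([f"v{i}" for i in range(6)], 600)
        res = stats.volunteer_generalizability(a, vols, seed=1)
        assert np.isclose(sum(res.bins.values()), 100.0)


class TestStimulusEnrichment:
    def test_random_labels_rarely_flagged(self, rng):
        """Bonferroni-corrected flags on exchangeable labels stay <= alpha
        per comparison."""
        flagged = total = 0
        for rep in range(20):
            a = rng.integers(1, 7, 400)
            lab = rng.choice(["rest", "math", "video"], 400)
            res = stats.stimulus_enrichment(a, lab, seed=rep)
            flagged += len(res.significant)
            total += res.n_clusters * 3
        assert flagged / total <= 0.05

    def test_pure_cluster_fully_colocalized(self, rng):
        a = np.repeat([1, 2], 100)
        lab = np.array(["math"] * 100 + ["rest"] * 100)
        res = stats.stimulus_enrichment(a, lab, seed=0)
        assert (1, "math") in res.significant
        assert np.isclose(res.colocalization["math"], 100.0)

    def test_percentages_bounded(self, rng):
        a = rng.integers(0, 4, 300)
        lab = rng.choice(["a", "b"], 300)
        res = stats.stimulus_enrichment(a, lab, seed=2)
        for v in res.colocalization.values():
            assert 0.0 <= v <= 100.0


class TestEffectSizes:
    def test_cohens_d_zero_for_identical(self, rng):
        x = rng.normal(size=50)
        assert abs(stats.cohens_d(x, x.copy())) < 1e-12

    def test_cohens_d_inf_sentinel(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            d = stats.cohens_d(np.ones(5), np.zeros(5))
        assert np.isinf(d) and d > 0

    def test_permuted_colocalization_shape(self, rng):
        a = rng.integers(1, 4, 200)
        lab = rng.choice(["x", "y"], 200)
        sig = {(1, "x")}
        df = stats.permuted_colocalization(a, lab, sig, n_perm=20, seed=0)
        assert df.shape == (20, 2)
        assert ((df >= 0) & (df <= 100)).all().all()

    def test_effect_size_wrapper(self, rng):
        real = pd.DataFrame({"x": rng.normal(60, 5, 20)})
        null = pd.DataFrame({"x": rng.normal(30, 5, 20)})
        fp = pd.DataFrame({"x": np.zeros(5)})
        res = stats.enrichment_effect_size(real, null, fp)
        assert res.cohen_d["x"] > 2.0


class TestPerformance:
    def test_uniform_performance_no_valence(self, rng):
        a = rng.integers(1, 3, 200)
        cond = np.array(["math"] * 200)
        perf = np.full(200, 0.7)
        res = stats.performance_test(a, cond, perf, "math", [1, 2], seed=0)
        assert res.high_clusters == [] and res.low_clusters == []

    def test_never_both_high_and_low(self, rng):
        a = np.repeat([1, 2], 150)
        cond = np.array(["math"] * 300)
        perf = np.concatenate([np.full(150, 0.95), np.full(150, 0.30)])
        res = stats.performance_test(a, cond, perf, "math", [1, 2], seed=1)
        assert not (set(res.high_clusters) & set(res.low_clusters))
        assert res.high_clusters == [1] and res.low_clusters == [2]

    def test_no_significant_clusters_empty_result(self, rng):
        res = stats.performance_test(np.ones(10), np.array(["m"] * 10),
                                     np.ones(10), "m", [], seed=0)
        assert res.table.empty


class TestDrawAndBootstrap:
    def test_run_draw_leakage_free(self, mini_features):
        """Test statistics use only test-group points."""
        _, _, feats = mini_features
        res = stats.run_draw(feats, "node", seed=12, n_train=40, n_eval=60,
                             n_perm=60, grid_size=64)
        assert set(res.test_meta["volunteer"]) <= set(res.plan.test_group)
        assert set(res.test_meta["volunteer"]).isdisjoint(res.plan.embed_group)
        assert res.test_assignments.size == len(res.test_meta)

    def test_h0_draw_runs(self, mini_features):
        _, _, feats = mini_features
        res = stats.run_draw(feats, "H0", seed=12, n_train=40, n_eval=60,
                             n_perm=60, grid_size=64)
        assert res.n_clusters >= 1
        assert set(res.enrichment.colocalization) <= {
            "rest", "math", "memory", "video", "instruction"}

    def test_bootstrap_single_draw_reduces_to_run(self, mini_features):
        _, _, feats = mini_features
        boot = stats.bootstrap_driver(feats, ["node"], n_boot=1, seed=3,
                                      n_train=40, n_eval=60, n_perm=60,
                                      grid_size=64)
        assert len(boot.draws["node"]) == 1
        assert boot.colocalization["node"].shape[0] == 1
        summ = boot.summary()
        # constant statistic: CI collapses onto the mean
        assert np.allclose(summ["ci_lo"], summ["mean_pct"])

    def test_ci_width_shrinks_with_more_draws(self, mini_features):
        """Monte-Carlo CI narrows roughly like 1/sqrt(n_boot): compare a
        6-draw and a 24-draw aggregate of the same statistic (scaled from
        the production 8-vs-64 comparison for runtime)."""
        _, _, feats = mini_features
        boot = stats.bootstrap_driver(feats, ["node"], n_boot=24, seed=5,
                                      n_train=40, n_eval=60, n_perm=60,
                                      grid_size=64)
        pcts = boot.colocalization["node"].mean(axis=1).to_numpy()

        def half_width(x):
            return 1.96 * x.std(ddof=1) / np.sqrt(x.size)

        assert half_width(pcts[:24]) < half_width(pcts[:6])
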
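"""Combination strategies, CV planning, weight grid search, threshold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atpres import ensemble as ens
from oracles import (
    auc_rank_sum,
    best_threshold_exhaustive,
    weighted_combination_surface,
)


class TestCombine:
    TRACKS = [np.array([0.2]), np.array([0.6]), np.array([0.7])]

    def test_weighted_hand_example(self):
        w = ens.EnsembleWeights(0.2, 0.2, 0.6)
        assert ens.combine(self.TRACKS, "weighted", w)[0] == pytest.approx(
            0.58
        )

    def test_max_min_mean(self):
        assert ens.combine(self.TRACKS, "max")[0] == pytest.approx(0.7)
        assert ens.combine(self.TRACKS, "min")[0] == pytest.approx(0.2)
        assert ens.combine(self.TRACKS, "mean")[0] == pytest.approx(0.5)

    def test_equal_weights_reduce_to_mean(self, rng):
        tracks = [rng.random(40) for _ in range(3)]
        w = ens.EnsembleWeights(1 / 3, 1 / 3, 1 / 3)
        np.testing.assert_allclose(
            ens.combine(tracks, "weighted", w), ens.combine(tracks, "mean")
        )

    def test_degenerate_weights_select_one_track(self, rng):
        tracks = [rng.random(20) for _ in range(3)]
        w = ens.EnsembleWeights(1.0, 0.0, 0.0)
        np.testing.assert_allclose(ens.combine(tracks, "weighted", w),
                                   tracks[0])

    def test_weighted_requires_weights(self):
        with pytest.raises(ValueError):
            ens.combine(self.TRACKS, "weighted")

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2**32 - 1))
    def test_weighted_between_min_and_max(self, seed):
        r = np.random.default_rng(seed)
        tracks = [r.random(5) for _ in range(3)]
        raw = r.random(3)
        w = raw / raw.sum()
        merged = ens.combine(tracks, "weighted",
                             ens.EnsembleWeights(*w))
        lo = ens.combine(tracks, "min")
        hi = ens.combine(tracks, "max")
        assert (merged >= lo - 1e-12).all() and (merged <= hi + 1e-12).all()
        assert (lo <= ens.combine(tracks, "mean")).all()


class TestCvPlan:
    CHAINS = [f"c{i}" for i in range(10)]

    def test_round_robin_sizes(self):
        plan = ens.make_cv_plan(self.CHAINS, k=5, seed=0)
        assert [len(f) for f in plan.folds] == [2] * 5

    def test_seed_reproducibility(self):
        p1 = ens.make_cv_plan(self.CHAINS, k=5, seed=9)
        p2 = ens.make_cv_plan(self.CHAINS, k=5, seed=9)
        assert p1.folds == p2.folds

    def test_partition(self):
        plan = ens.make_cv_plan(self.CHAINS, k=3, seed=1)
        flat = [c for f in plan.folds for c in f]
        assert sorted(flat) == sorted(self.CHAINS)

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            ens.make_cv_plan(self.CHAINS[:3], k=5, seed=0)


class TestOutOfFold:
    def test_coverage_and_leakage(self, dataset_small):
        plan = ens.make_cv_plan(dataset_small.unique_chains(), k=4, seed=0)
        seen_train_chains = []

        def spy_trainer(train_ds, test_ds):
            seen_train_chains.append(
                (set(train_ds.chain_ids), set(test_ds.chain_ids))
            )
            return np.full(len(test_ds), 0.5)

        tracks = ens.out_of_fold_tracks(dataset_small, plan,
                                        [spy_trainer] * 3)
        assert all(t.shape == (len(dataset_small),) for t in tracks)
        assert all(np.isfinite(t).all() for t in tracks)
        for train_chains, test_chains in seen_train_chains:
            assert not train_chains & test_chains  # no self-training


class TestGridSearch:
    def test_grid_has_36_points(self):
        assert len(ens.weight_grid()) == 36

    def test_informative_track_wins_max_weight(self, rng):
        labels = rng.integers(0, 2, size=300)
        tracks = [rng.random(300), rng.random(300),
                  labels + rng.normal(0, 0.01, 300)]
        best, surface = ens.grid_search_weights(tracks, labels)
        assert best.w3 == pytest.approx(0.8)
        assert len(surface) == 36

    def test_sum_constraint(self, rng):
        tracks = [rng.random(50) for _ in range(3)]
        best, _ = ens.grid_search_weights(tracks, rng.integers(0, 2, 50))
        assert best.w1 + best.w2 + best.w3 == pytest.approx(1.0)

    def test_agrees_with_bruteforce_surface(self, rng):
        labels = rng.integers(0, 2, size=60)
        tracks = [rng.random(60) for _ in range(3)]
        best, surface = ens.grid_search_weights(tracks, labels)
        oracle = weighted_combination_surface(tracks, labels)
        for (w1, w2, w3, auc_o), (_, row) in zip(oracle,
                                                 surface.iterrows()):
            assert (w1, w2, w3) == (row.w1, row.w2, row.w3)
            assert auc_o == pytest.approx(row.auc, abs=1e-12)
        oracle_best = max(
            oracle, key=lambda t: (t[3], t[2], t[0])
        )
        assert oracle_best[3] == pytest.approx(
            surface["auc"].max(), abs=1e-12
        )
        assert (best.w1, best.w2, best.w3) == oracle_best[:3]

    def test_flat_surface_returns_largest_w3(self, rng, caplog):
        track = rng.random(40)
        with caplog.at_level("WARNING", logger="atpres"):
            best, _ = ens.grid_search_weights(
                [track, track, track], rng.integers(0, 2, 40)
            )
        assert best.w3 == pytest.approx(0.8)


class TestSelectThreshold:
    def test_separable_returns_midpoint(self):
        track = np.array([0.1, 0.1, 0.9, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert ens.select_threshold(track, labels) == pytest.approx(0.5)

    def test_toy_example(self):
        track = np.array([0.1, 0.2, 0.6, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1])
        assert ens.select_threshold(track, labels) == pytest.approx(0.7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ens.select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_agrees_with_exhaustive_scan(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 20))
            track = rng.random(n).round(2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            thr = ens.select_threshold(track, labels)
            thr_o, mcc_o = best_threshold_exhaustive(track, labels)
            assert thr == pytest.approx(thr_o)
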
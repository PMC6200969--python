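"""Cross-modal MVPA: extraction, classification, group confirmation."""
import numpy as np
import pandas as pd
import pytest

from emorsa.conditions import condition_index
from emorsa.glm import BetaPatterns
from emorsa.mvpa import (
    ClassificationTask,
    _valence_subsample,
    confirmed_clusters,
    crossmodal_classify,
    evaluate_clusters,
    extract_cluster_patterns,
    pair_accuracy,
)
from emorsa.synth import PlantedRegion, SyntheticSpec, generate_betas, generate_null


def null_subject(n_voxels=40, seed=0):
    rng = np.random.default_rng(seed)
    return BetaPatterns(
        subject_id=f"sub-{seed}",
        betas=rng.standard_normal((3, 9, n_voxels)),
        grid_shape=(n_voxels, 1, 1),
    )


class TestClassificationTask:
    def test_chance_levels(self):
        assert ClassificationTask("three_way", "face", "body").chance == pytest.approx(1 / 3)
        assert ClassificationTask("valence", "face", "body").chance == 0.5

    def test_same_train_test_type_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ClassificationTask("three_way", "face", "face")


class TestExtractClusterPatterns:
    def test_shapes_and_labels(self):
        pats = extract_cluster_patterns(null_subject(), np.arange(40))
        assert set(pats) == {"face", "body", "whole_person"}
        for stim, ps in pats.items():
            assert ps.x.shape == (9, 40)
            assert sorted(np.unique(ps.emotions)) == ["angry", "fearful", "happy"]
            assert sorted(np.unique(ps.runs)) == [0, 1, 2]

    def test_values_equal_underlying_betas(self):
        bp = null_subject(seed=3)
        voxels = np.array([5, 17, 30])
        pats = extract_cluster_patterns(bp, voxels)
        sample = pats["body"].x[0]  # run 0, happy
        np.testing.assert_array_equal(
            sample, bp.betas[0, condition_index("happy", "body"), voxels]
        )

    def test_labels_preserved_under_voxel_permutation(self):
        bp = null_subject(seed=4)
        a = extract_cluster_patterns(bp, np.array([1, 2, 3]))
        b = extract_cluster_patterns(bp, np.array([3, 1, 2]))
        np.testing.assert_array_equal(a["face"].emotions, b["face"].emotions)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty cluster"):
            extract_cluster_patterns(null_subject(), np.array([], dtype=int))


class TestValenceSubsampling:
    def test_priors_stay_balanced_every_repetition(self, rng):
        emotions = np.array(["happy", "angry", "fearful"] * 3)
        for _ in range(50):
            keep = _valence_subsample(emotions, rng)
            kept = emotions[keep]
            assert (kept == "happy").sum() == ((kept == "angry") | (kept == "fearful")).sum()
            # roughly half of each negative emotion is retained
            assert 1 <= (kept == "angry").sum() <= 2
            assert 1 <= (kept == "fearful").sum() <= 2


class TestCrossmodalClassify:
    def test_separable_planted_patterns_reach_perfect_accuracy(self):
        spec = SyntheticSpec(
            grid_shape=(8, 8, 8),
            n_subjects=1,
            planted_regions=(PlantedRegion((4, 4, 4), 3.0, 5.0, 1.0),),
            noise_sd=0.01,
            seed=2,
        )
        datasets, truth = generate_betas(spec)
        voxels = np.flatnonzero(truth.planted_mask.reshape(-1))
        pats = extract_cluster_patterns(datasets[0].beta_patterns, voxels)
        for scheme in ("three_way", "valence"):
            assert pair_accuracy(pats, scheme, ("face", "body"), seed=1) == 1.0

    def test_pair_accuracy_symmetric_in_pair_order(self):
        pats = extract_cluster_patterns(null_subject(seed=8), np.arange(40))
        acc_ab = pair_accuracy(pats, "three_way", ("face", "body"))
        acc_ba = pair_accuracy(pats, "three_way", ("body", "face"))
        assert acc_ab == pytest.approx(acc_ba)

    def test_mismatched_pattern_sets_rejected(self):
        pats = extract_cluster_patterns(null_subject(), np.arange(40))
        task = ClassificationTask("three_way", "face", "body")
        with pytest.raises(ValueError, match="stimulus types"):
            crossmodal_classify(pats["body"], pats["face"], task)

    def test_null_accuracy_near_chance(self):
        accs3, accs2 = [], []
        root = np.random.SeedSequence(77)
        for i, child in enumerate(root.spawn(40)):
            rng = np.random.default_rng(child)
            pats = extract_cluster_patterns(null_subject(seed=1000 + i), np.arange(40))
            accs3.append(pair_accuracy(pats, "three_way", ("face", "body"), rng))
            accs2.append(
                pair_accuracy(pats, "valence", ("face", "body"), rng, n_subsample_reps=5)
            )
        for accs, chance in ((accs3, 1 / 3), (accs2, 0.5)):
            se = np.std(accs, ddof=1) / np.sqrt(len(accs))
            assert abs(np.mean(accs) - chance) < 3 * se + 0.02

    def test_label_permutation_restores_chance_on_structured_data(self, rng):
        spec = SyntheticSpec(
            grid_shape=(8, 8, 8),
            n_subjects=1,
            planted_regions=(PlantedRegion((4, 4, 4), 3.0, 2.0, 1.0),),
            noise_sd=1.0,
            seed=6,
        )
        datasets, truth = generate_betas(spec)
        voxels = np.flatnonzero(truth.planted_mask.reshape(-1))
        pats = extract_cluster_patterns(datasets[0].beta_patterns, voxels)
        accs = []
        for _ in range(50):
            shuffled = {k: v for k, v in pats.items()}
            for ps in shuffled.values():
                ps.emotions = rng.permutation(ps.emotions)
            accs.append(pair_accuracy(shuffled, "three_way", ("face", "body")))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 1 / 3) < 3 * se + 0.03


class TestEvaluateClusters:
    def test_t_statistic_matches_textbook_formula(self):
        cohort = [null_subject(seed=s) for s in range(6)]
        voxels = np.arange(40)
        results = evaluate_clusters(
            cohort,
            {1: voxels},
            schemes=("three_way",),
            type_pairs=(("face", "body"),),
            seed=5,
        )
        # recompute the per-subject accuracies with the same seed discipline
        root = np.random.SeedSequence(5)
        rngs = [np.random.default_rng(c) for c in root.spawn(6)]
        accs = np.array(
            [
                pair_accuracy(
                    extract_cluster_patterns(bp, voxels), "three_way", ("face", "body"), rng
                )
                for bp, rng in zip(cohort, rngs)
            ]
        )
        expect_t = (accs.mean() - 1 / 3) / (accs.std(ddof=1) / np.sqrt(6))
        row = results.iloc[0]
        assert row["mean_accuracy"] == pytest.approx(accs.mean())
        assert row["t"] == pytest.approx(expect_t, abs=1e-10)
        assert row["df"] == 5

    def test_significance_rule_handles_degenerate_vectors(self):
        from emorsa.mvpa import significantly_above_chance

        # every subject exactly at chance: maximally null
        res, sig = significantly_above_chance(np.full(8, 0.5), chance=0.5)
        assert res.statistic == 0.0 and res.pvalue == 1.0 and not sig
        # every subject perfect: t -> inf limit, taken as significant
        res, sig = significantly_above_chance(np.ones(8), chance=0.5)
        assert res.degenerate and sig
        # strongly below chance is never "significant" here
        _, sig = significantly_above_chance(np.full(8, 0.1) + np.arange(8) * 1e-3, 0.5)
        assert not sig

    def test_planted_cluster_confirmed_control_not(self):
        spec = SyntheticSpec(
            grid_shape=(10, 10, 10),
            n_subjects=8,
            planted_regions=(PlantedRegion((4, 4, 4), 2.5, 1.5, 0.8),),
            noise_sd=1.0,
            seed=13,
        )
        datasets, truth = generate_betas(spec)
        cohort = [ds.beta_patterns for ds in datasets]
        planted = np.flatnonzero(truth.planted_mask.reshape(-1))
        control = np.flatnonzero(
            ~truth.planted_mask.reshape(-1)
        )[: planted.size]
        results = evaluate_clusters(
            cohort, {1: planted, 2: control}, seed=17, n_subsample_reps=5
        )
        assert confirmed_clusters(results) == [1]


class TestConfirmationRule:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["cluster_id", "scheme", "pair", "significant"]
        )

    def test_two_pairs_in_one_scheme_confirm(self):
        rows = [
            (1, "three_way", "a-b", True),
            (1, "three_way", "a-c", True),
            (1, "three_way", "b-c", False),
            (1, "valence", "a-b", False),
            (1, "valence", "a-c", False),
            (1, "valence", "b-c", False),
        ]
        assert confirmed_clusters(self._frame(rows)) == [1]

    def test_one_pair_per_scheme_does_not_confirm(self):
        rows = [
            (2, "three_way", "a-b", True),
            (2, "three_way", "a-c", False),
            (2, "valence", "a-b", True),
            (2, "valence", "a-c", False),
        ]
        assert confirmed_clusters(self._frame(rows)) == []
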
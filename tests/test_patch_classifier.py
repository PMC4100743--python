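import numpy as np
import pytest

from patchverify import patch_classifier, pipeline
from patchverify.patch_classifier import (
    BIOMETRIC,
    NON_BIOMETRIC,
    choose_threshold,
    classify_patch,
    load_model,
    save_model,
    score_patch,
    train_classifier,
)

TINY_GRID = {"C": [1.0, 16.0], "gamma": [0.01, 0.1]}


def two_blob_data(rng, n=40, gap=6.0, dim=8):
    """Linearly separable clusters: biometric near 0, non-biometric at +gap."""
    Xb = rng.normal(0.0, 0.3, size=(n, dim))
    Xn = rng.normal(gap, 0.3, size=(n, dim))
    X = np.vstack([Xb, Xn])
    y = np.array([BIOMETRIC] * n + [NON_BIOMETRIC] * n)
    return X, y


class TestTrainClassifier:
    def test_separable_blobs_reach_perfect_cv(self, rng):
        X, y = two_blob_data(rng)
        model = train_classifier(X, y, seed=0, param_grid=TINY_GRID)
        assert model.cv_accuracy == 1.0

    def test_conflicting_duplicate_labels_cap_cv_accuracy(self, rng):
        X = np.tile(rng.normal(size=(1, 4)), (30, 1))
        y = np.array([BIOMETRIC, NON_BIOMETRIC] * 15)
        model = train_classifier(X, y, seed=0, param_grid=TINY_GRID)
        assert model.cv_accuracy <= 0.5 + 1e-9

    def test_same_seed_reproduces_hyperparameters(self, rng):
        X, y = two_blob_data(rng, gap=2.0)
        m1 = train_classifier(X, y, seed=3, param_grid=TINY_GRID)
        m2 = train_classifier(X, y, seed=3, param_grid=TINY_GRID)
        assert m1.best_params == m2.best_params
        assert m1.cv_accuracy == m2.cv_accuracy

    def test_single_class_input_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            train_classifier(X, np.array([BIOMETRIC] * 10), param_grid=TINY_GRID)


class TestScoringPolarity:
    def test_cluster_cores_score_on_correct_sides(self, rng):
        X, y = two_blob_data(rng)
        model = train_classifier(X, y, seed=0, param_grid=TINY_GRID)
        bio_core = np.zeros(8)
        non_core = np.full(8, 6.0)
        assert score_patch(model, bio_core) < model.tau
        assert score_patch(model, non_core) >= model.tau

    def test_scoring_deterministic(self, rng):
        X, y = two_blob_data(rng)
        model = train_classifier(X, y, seed=0, param_grid=TINY_GRID)
        d = rng.normal(size=8)
        assert score_patch(model, d) == score_patch(model, d)


class TestClassifyPatch:
    @pytest.mark.parametrize(
        "score,tau,expected",
        [
            (-0.001, 0.0, BIOMETRIC),
            (0.0, 0.0, NON_BIOMETRIC),   # tie goes to non-biometric
            (1.0, 0.0, NON_BIOMETRIC),
        ],
    )
    def test_threshold_rule(self, score, tau, expected):
        assert classify_patch(score, tau) == expected

    def test_monotone_in_score(self, rng):
        scores = np.sort(rng.normal(size=50))
        labels = [classify_patch(s, 0.3) for s in scores]
        flips = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert flips <= 1  # biometric ... then non-biometric, never back


def threshold_oracle(scores, labels, recall):
    """Exhaustive sweep over candidate thresholds for the recall point."""
    bio = scores[labels == BIOMETRIC]
    candidates = np.sort(np.unique(np.concatenate([[scores.min() - 1], scores + 1e-9])))
    feasible = [t for t in candidates if np.mean(bio < t) >= recall]
    return min(feasible) if feasible else None


class TestChooseThreshold:
    def test_separated_scores_give_zero_error_at_eer(self, rng):
        scores = np.concatenate([rng.uniform(-5, -2, 30), rng.uniform(2, 5, 30)])
        labels = np.array([BIOMETRIC] * 30 + [NON_BIOMETRIC] * 30)
        tau = choose_threshold(scores, labels, "eer")
        pred = np.where(scores < tau, BIOMETRIC, NON_BIOMETRIC)
        assert np.all(pred == labels)

    def test_full_recall_sits_above_max_biometric_score(self, rng):
        scores = rng.normal(size=40)
        labels = np.array([BIOMETRIC, NON_BIOMETRIC] * 20)
        tau = choose_threshold(scores, labels, "biometric_recall", recall=1.0)
        assert tau > scores[labels == BIOMETRIC].max()

    def test_matches_exhaustive_sweep_on_toy_scores(self, rng):
        for _ in range(20):
            scores = rng.normal(size=20)
            labels = rng.choice([BIOMETRIC, NON_BIOMETRIC], size=20)
            if len(set(labels)) < 2:
                continue
            for recall in (0.5, 0.8, 0.95):
                tau = choose_threshold(scores, labels, "biometric_recall", recall=recall)
                assert tau == pytest.approx(threshold_oracle(scores, labels, recall))

    def test_unattainable_point_raises(self):
        scores = np.array([0.0, 1.0])
        labels = np.array([BIOMETRIC, NON_BIOMETRIC])
        with pytest.raises(ValueError):
            choose_threshold(scores, labels, "no_such_point")


@pytest.fixture(scope="module")
def trained(small_dataset):
    table = pipeline.extract_descriptors(
        small_dataset.split_images("train"), small_dataset.spec.grid
    )
    return pipeline.train_patch_classifier(
        table,
        seed=0,
        param_grid=patch_classifier.small_param_grid(),
        subsample=800,
    )


class TestFlagMatrix:
    def test_grid_cardinality(self, trained, small_dataset):
        im = small_dataset.split_images("test")[0]
        fm = patch_classifier.flag_matrix(trained, im.face, small_dataset.spec.grid)
        assert fm.shape == (5, 5)

    def test_neutral_face_flags_all_biometric_at_full_recall(
        self, trained, small_dataset
    ):
        # the default 95%-recall threshold flags ~5% of biometric patches
        # by construction; the all-biometric contract holds at the
        # full-recall operating point of this separable fixture
        table = pipeline.extract_descriptors(
            small_dataset.split_images("train"), small_dataset.spec.grid
        )
        scores = patch_classifier.score_patches(trained, table.X)
        tau_full = patch_classifier.choose_threshold(
            scores, table.labels, "biometric_recall", recall=1.0
        )
        neutral = next(
            im for im in small_dataset.split_images("test") if im.face.is_neutral
        )
        fm = patch_classifier.flag_matrix(
            trained, neutral.face, small_dataset.spec.grid, tau=tau_full
        )
        assert np.all(fm == BIOMETRIC)

    def test_occluded_patches_flagged_non_biometric(self, trained, small_dataset):
        disguised = next(
            im
            for im in small_dataset.split_images("test")
            if np.sum(im.annotation == NON_BIOMETRIC) >= 5
        )
        fm = patch_classifier.flag_matrix(trained, disguised.face, small_dataset.spec.grid)
        occluded = disguised.annotation == NON_BIOMETRIC
        # every fully annotated occluded patch is recovered
        assert np.mean(fm[occluded] == NON_BIOMETRIC) >= 0.8

    def test_model_roundtrip(self, trained, tmp_path):
        save_model(trained, tmp_path / "model.joblib")
        back = load_model(tmp_path / "model.joblib")
        assert back.best_params == trained.best_params
        assert back.tau == trained.tau
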
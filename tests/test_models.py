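import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import cross_entropy_sum, kl_divergence, softmax_row
from twocell import (
    KDClassifier,
    KDConfig,
    MLPConfig,
    TemperedMLP,
    cross_entropy,
    kd_loss,
    tempered_softmax,
    train_kd,
    train_mlp,
)
from twocell.models import TrainedModel, predict_proba
from twocell.tworound import compute_entropy

finite_logits = st.lists(
    st.floats(min_value=-30, max_value=30), min_size=2, max_size=6
)


class TestTemperedSoftmax:
    def test_symmetric_logits_give_uniform(self):
        np.testing.assert_allclose(tempered_softmax(np.array([0.0, 0.0])), [[0.5, 0.5]])

    def test_high_temperature_limit_is_uniform(self):
        q = tempered_softmax(np.array([[3.0, -1.0, 7.0, 0.5]]), T=1e6)
        np.testing.assert_allclose(q, 0.25, atol=1e-4)

    def test_direct_evaluation_example(self):
        q = tempered_softmax(np.array([1.0, 2.0, 3.0]), T=1.0)
        np.testing.assert_allclose(
            q.ravel(), softmax_row([1.0, 2.0, 3.0]), atol=1e-10
        )
        np.testing.assert_allclose(q.ravel(), [0.09003057, 0.24472847, 0.66524096], atol=1e-7)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            tempered_softmax(np.zeros((1, 2)), T=0.0)

    @settings(deadline=None, derandomize=True)
    @given(finite_logits, st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-20, max_value=20))
    def test_shift_invariance(self, z, T, c):
        z = np.array([z])
        np.testing.assert_allclose(
            tempered_softmax(z, T), tempered_softmax(z + c, T), atol=1e-9
        )

    @settings(deadline=None, derandomize=True)
    @given(finite_logits)
    def test_row_entropy_nondecreasing_in_temperature(self, z):
        z = np.array([z])
        temps = [0.5, 1.0, 2.0, 5.0, 20.0]
        ents = [compute_entropy(tempered_softmax(z, T))[0] for T in temps]
        assert all(b >= a - 1e-9 for a, b in zip(ents, ents[1:]))


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.array([[1.0, 0.0]])
        assert cross_entropy(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_coin_flip_costs_log_two(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        q = np.full((2, 2), 0.5)
        assert cross_entropy(p, q) == pytest.approx(np.log(2))

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(10)
        p = np.eye(3)[rng.integers(0, 3, size=5)]
        q = rng.dirichlet(np.ones(3), size=5)
        assert cross_entropy(p, q, reduction="sum") == pytest.approx(
            cross_entropy_sum(p, q), abs=1e-10
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cross_entropy(np.eye(2), np.ones((3, 2)) / 2)


class TestKDLoss:
    def test_alpha_one_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(11)
        hard = np.eye(3)[rng.integers(0, 3, size=4)]
        t, s = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        cfg = KDConfig(alpha=1.0, T1=1.0, T2=3.0)
        assert kd_loss(hard, t, s, cfg) == pytest.approx(
            cross_entropy(hard, tempered_softmax(s, 1.0))
        )

    def test_identical_logits_zero_divergence(self):
        rng = np.random.default_rng(12)
        hard = np.eye(2)[rng.integers(0, 2, size=5)]
        z = rng.normal(size=(5, 2))
        cfg = KDConfig(alpha=0.3)
        assert kd_loss(hard, z, z, cfg) == pytest.approx(
            0.3 * cross_entropy(hard, tempered_softmax(z, 1.0))
        )

    def test_matches_hand_oracle_on_fixed_logits(self):
        hard = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([[0.5, -0.2, 1.3], [2.0, 0.0, -1.0]])
        s = np.array([[0.1, 0.4, -0.6], [1.5, -0.5, 0.2]])
        cfg = KDConfig(alpha=0.1, T1=1.0, T2=3.0)
        ce = cross_entropy_sum(hard, [softmax_row(r) for r in s]) / 2
        kl = np.mean([
            kl_divergence(softmax_row(tr, T=3.0), softmax_row(sr, T=3.0))
            for tr, sr in zip(t, s)
        ])
        assert kd_loss(hard, t, s, cfg) == pytest.approx(0.1 * ce + 0.9 * kl, abs=1e-12)

    def test_continuous_in_alpha_with_pure_endpoints(self):
        rng = np.random.default_rng(13)
        hard = np.eye(3)[rng.integers(0, 3, size=6)]
        t, s = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        losses = [kd_loss(hard, t, s, KDConfig(alpha=a)) for a in np.linspace(0, 1, 11)]
        diffs = np.diff(losses)
        assert np.allclose(diffs, diffs[0], atol=1e-9)  # affine in alpha

    def test_t2_square_rescales_divergence_term(self):
        rng = np.random.default_rng(14)
        hard = np.eye(2)[rng.integers(0, 2, size=4)]
        t, s = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        plain = kd_loss(hard, t, s, KDConfig(alpha=0.0, T2=3.0))
        scaled = kd_loss(hard, t, s, KDConfig(alpha=0.0, T2=3.0, t2_square=True))
        assert scaled == pytest.approx(9 * plain)


class TestTemperedMLP:
    def test_separable_blobs_reach_high_training_accuracy(self, blobs):
        X, y = blobs
        clf = TemperedMLP(epochs=50, random_state=2022).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_same_seed_identical_weights(self, blobs):
        X, y = blobs
        a = TemperedMLP(epochs=10, random_state=7).fit(X, y)
        b = TemperedMLP(epochs=10, random_state=7).fit(X, y)
        for k, w in a.core_.get_weights().items():
            np.testing.assert_array_equal(w, b.core_.get_weights()[k])

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(500, 10))
        y = np.array(["A", "B"])[rng.integers(0, 2, size=500)]
        clf = TemperedMLP(epochs=20, random_state=2022).fit(X[:350], y[:350])
        held = (clf.predict(X[350:]) == y[350:]).mean()
        assert abs(held - 0.5) <= 0.1

    def test_probability_rows_sum_to_one_and_duplicates_agree(self, blobs):
        X, y = blobs
        clf = TemperedMLP(epochs=15, random_state=1).fit(X, y)
        X2 = np.vstack([X[:5], X[:5]])
        P = clf.predict_proba(X2)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(P[:5], P[5:])

    def test_blob_centroid_classified_to_its_blob(self, blobs):
        X, y = blobs
        clf = TemperedMLP(epochs=50, random_state=2022).fit(X, y)
        for cls in np.unique(y):
            centroid = X[y == cls].mean(axis=0, keepdims=True)
            assert clf.predict(centroid)[0] == cls

    def test_missing_class_rejected(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError, match="absent"):
            TemperedMLP(epochs=1).fit(X, y, classes=["class0", "class1", "classX"])

    def test_feature_dimension_mismatch_rejected(self, blobs):
        X, y = blobs
        clf = TemperedMLP(epochs=2, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            clf.predict(X[:, :4])


class TestKDClassifier:
    def test_alpha_one_equals_plain_mlp_with_same_init(self, blobs):
        X, y = blobs
        kd = KDClassifier(alpha=1.0, epochs=15, random_state=50).fit(X, y)
        plain = TemperedMLP(epochs=15, patience=None, temperature=1.0,
                            random_state=51).fit(X, y)  # student rng = seed + 1
        np.testing.assert_allclose(kd.predict_proba(X), plain.predict_proba(X), atol=1e-9)

    def test_clean_separable_labels_learned(self, blobs):
        X, y = blobs
        kd = KDClassifier(random_state=2022).fit(X, y)
        assert (kd.predict(X) == y).mean() >= 0.99

    def test_student_tolerates_label_noise_better_than_plain_mlp(self):
        from sklearn.datasets import make_blobs

        wins = []
        for seed in range(10):
            X, y_int = make_blobs(n_samples=300, n_features=10, centers=3,
                                  cluster_std=2.0, center_box=(-6, 6),
                                  random_state=seed)
            y = np.array([f"c{v}" for v in y_int], dtype=object)
            rng = np.random.default_rng(seed)
            noisy = y.copy()
            flip = rng.random(len(y)) < 0.2
            noisy[flip] = [f"c{(int(v[1]) + rng.integers(1, 3)) % 3}" for v in y[flip]]
            tr = rng.random(len(y)) < 0.7
            kd = KDClassifier(epochs=30, random_state=seed).fit(X[tr], noisy[tr])
            plain = TemperedMLP(epochs=30, patience=None,
                                random_state=seed + 1).fit(X[tr], noisy[tr])
            wins.append(
                (kd.predict(X[~tr]) == y[~tr]).mean()
                - (plain.predict(X[~tr]) == y[~tr]).mean()
            )
        assert np.mean(wins) >= 0.0

    def test_single_class_pseudo_labels_rejected(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError, match="2 classes"):
            KDClassifier(epochs=1).fit(X, np.array(["only"] * len(X), dtype=object))


class TestWrappersAndPersistence:
    def test_train_mlp_train_kd_wrappers(self, blobs):
        X, y = blobs
        model = train_mlp(X, y, MLPConfig(epochs=10), seed=3)
        assert set(model.class_names) == set(np.unique(y))
        P = predict_proba(model, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)
        student = train_kd(X, y, MLPConfig(epochs=5), KDConfig(epochs=5), seed=3)
        assert (student.predict(X) == y).mean() > 0.9

    def test_saved_model_round_trips_predictions(self, blobs, tmp_path):
        X, y = blobs
        model = train_mlp(X, y, MLPConfig(epochs=10), seed=4)
        model.save(tmp_path / "model.npz")
        back = TrainedModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.class_names, model.class_names)
        np.testing.assert_allclose(
            back.estimator.predict_proba(X), model.estimator.predict_proba(X), atol=0
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(dropout_rate=1.5)
        with pytest.raises(ValueError):
            KDConfig(alpha=1.2)
        with pytest.raises(ValueError):
            KDConfig(T2=0.0)
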
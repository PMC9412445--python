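import json

import numpy as np
import pytest

import attngate as ag
from attngate.bands import feature_index


def oracle_lda_predict(xtr, ytr, xte):
    """Closed-form pooled-covariance discriminant, written independently.

    w = S^-1 (mu_int - mu_ext); threshold at the log-prior-adjusted
    midpoint; internal iff score > 0.
    """
    xi, xe = xtr[ytr == "internal"], xtr[ytr == "external"]
    mi, me = xi.mean(axis=0), xe.mean(axis=0)
    n = len(xtr)
    s = ((xi - mi).T @ (xi - mi) + (xe - me).T @ (xe - me)) / (n - 2)
    w = np.linalg.solve(s, mi - me)
    b = -0.5 * (mi + me) @ w + np.log(len(xi) / n) - np.log(len(xe) / n)
    score = xte @ w + b
    return np.where(score > 0, "internal", "external")


def random_dataset(rng, n=None, d=None):
    n = n or int(rng.integers(20, 200))
    d = d or int(rng.integers(2, 20))
    mu = rng.normal(scale=1.0, size=d)
    a = rng.normal(size=(d, d))
    cov = a @ a.T / d + np.eye(d) * 0.5
    half = n // 2
    xi = rng.multivariate_normal(mu, cov, size=half)
    xe = rng.multivariate_normal(-mu, cov, size=n - half)
    x = np.vstack([xi, xe])
    y = np.array(["internal"] * half + ["external"] * (n - half))
    return x, y


class TestTrain:
    def test_matches_closed_form_oracle(self, rng):
        """train+predict agrees with the independent discriminant formula
        on every point of 100 random datasets."""
        for _ in range(100):
            x, y = random_dataset(rng)
            model = ag.train(x, y)
            pred, _ = model.predict(x)
            np.testing.assert_array_equal(pred, oracle_lda_predict(x, y, x))

    def test_symmetric_1d_threshold_at_zero(self):
        x = np.array([[-1.2], [-0.8], [-1.0], [0.8], [1.2], [1.0]])
        y = np.array(["external"] * 3 + ["internal"] * 3)
        model = ag.train(x, y)
        assert model.score(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-10)

    def test_label_swap_negates_weights(self, rng):
        x, y = random_dataset(rng, n=100, d=5)
        yswap = np.where(y == "internal", "external", "internal")
        a, b = ag.train(x, y), ag.train(x, yswap)
        np.testing.assert_allclose(a.weights, -b.weights, atol=1e-8)
        pa, _ = a.predict(x)
        pb, _ = b.predict(x)
        assert np.mean(pa == y) == pytest.approx(np.mean(pb == yswap))

    def test_single_class_raises(self, rng):
        x = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            ag.train(x, np.array(["internal"] * 10))

    def test_too_few_per_class_raises(self, rng):
        x = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="at least 2"):
            ag.train(x, np.array(["internal", "external", "external", "external"]))

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        x, y = random_dataset(rng, n=80, d=4)
        x = np.hstack([x, np.ones((80, 1))])  # degenerate constant feature
        with pytest.warns(UserWarning, match="zero-variance"):
            model = ag.train(x, y)
        assert model.weights[-1] == 0.0
        pred, _ = model.predict(x)
        np.testing.assert_array_equal(pred, oracle_lda_predict(x[:, :4], y, x[:, :4]))

    def test_priors_sum_to_one_and_cov_symmetric(self, trained_model):
        assert trained_model.priors.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(trained_model.covariance, trained_model.covariance.T, atol=1e-10)
        eig = np.linalg.eigvalsh(trained_model.covariance)
        assert eig.min() > -1e-10


class TestPredict:
    def test_class_mean_classified_correctly(self, trained_model):
        pred, _ = trained_model.predict(trained_model.class_means)
        assert list(pred) == ["external", "internal"]

    def test_boundary_score_goes_external(self):
        model = ag.AttentionModel(
            weights=np.array([1.0, 0.0]),
            bias=0.0,
            class_means=np.zeros((2, 2)),
            covariance=np.eye(2),
            priors=np.array([0.5, 0.5]),
            feature_order=("f0", "f1"),
        )
        pred, score = model.predict(np.array([[0.0, 3.0]]))
        assert score[0] == 0.0 and pred[0] == "external"

    def test_batch_equals_mapped_single(self, trained_model, rng):
        x = rng.normal(size=(20, 20))
        batch, _ = trained_model.predict(x)
        singles = [trained_model.predict(row)[0][0] for row in x]
        assert list(batch) == singles

    def test_dimension_mismatch_raises(self, trained_model):
        with pytest.raises(ValueError, match="dimension"):
            trained_model.predict(np.zeros(7))


class TestCrossValidate:
    def test_fold_sizes_partition_data(self, calibration_stream):
        cal = ag.cross_validate(calibration_stream, k=5)
        assert cal.n_vectors == 4000
        assert len(cal.fold_accuracies) == 5
        assert cal.mean_accuracy == pytest.approx(np.mean(cal.fold_accuracies))

    def test_separable_classes_perfect_accuracy(self, rng):
        x = np.vstack([rng.normal(10, 0.1, (50, 3)), rng.normal(-10, 0.1, (50, 3))])
        y = np.array(["internal"] * 50 + ["external"] * 50)
        cal = ag.cross_validate(x, y, k=5)
        assert cal.mean_accuracy == 1.0

    def test_permuted_labels_at_chance(self, rng):
        x, y = random_dataset(rng, n=400, d=8)
        accs = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(len(y))
            accs.append(ag.cross_validate(x, y[perm], k=5, seed=seed).mean_accuracy)
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_deterministic_given_seed(self, calibration_stream):
        a = ag.cross_validate(calibration_stream, seed=3)
        b = ag.cross_validate(calibration_stream, seed=3)
        assert a.fold_accuracies == b.fold_accuracies

    def test_contiguous_scheme_more_pessimistic_shape(self, calibration_stream):
        # contiguous (block) folds avoid window-overlap leakage; on i.i.d.
        # synthetic frames both schemes should be close, and both valid
        sh = ag.cross_validate(calibration_stream, scheme="shuffled")
        bl = ag.cross_validate(calibration_stream, scheme="contiguous")
        assert abs(sh.mean_accuracy - bl.mean_accuracy) < 0.1

    def test_unknown_scheme_raises(self, calibration_stream):
        with pytest.raises(ValueError, match="scheme"):
            ag.cross_validate(calibration_stream, scheme="bogus")


class TestSerialization:
    def test_json_roundtrip(self, trained_model, tmp_path, calibration_stream):
        trained_model.calibration = ag.cross_validate(calibration_stream)
        p = tmp_path / "model.json"
        trained_model.save(p)
        loaded = ag.AttentionModel.load(p)
        np.testing.assert_allclose(loaded.weights, trained_model.weights)
        np.testing.assert_allclose(loaded.covariance, trained_model.covariance)
        assert loaded.feature_order == trained_model.feature_order
        assert loaded.calibration.mean_accuracy == trained_model.calibration.mean_accuracy

    def test_version_check(self, trained_model, tmp_path):
        p = tmp_path / "model.json"
        trained_model.save(p)
        d = json.loads(p.read_text())
        d["format_version"] = 99
        p.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="version"):
            ag.AttentionModel.load(p)


class TestParameterRecovery:
    def test_tp10_alpha_carries_largest_weight(self):
        """With the alpha effect confined to TP10 at 2x noise SD, the
        trained discriminant's largest |weight| is the TP10-alpha feature
        in >= 90% of seeded replicates."""
        shift = np.zeros((4, 5))
        shift[3, 2] = 0.5  # 2 x noise SD, TP10 alpha only
        hits = 0
        for seed in range(20):
            plan = ag.make_session_plan(4, 50.0, 50.0, seed=100 + seed)
            params = ag.GeneratorParams(internal_shift=shift)
            s = ag.synthesize_bandpower(plan, params)
            model = ag.train(s)
            hits += int(np.argmax(np.abs(model.weights)) == feature_index("TP10", "alpha"))
        assert hits >= 18
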
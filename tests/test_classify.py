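"""Feature selection, MLDA/SVM training, cross-validation and permutation."""

import numpy as np
import pandas as pd
import pytest

from emostroop.classify import (
    CvScheme,
    cross_validate,
    evaluate_sensitivity_specificity,
    feature_contributions,
    permutation_test,
    select_features,
    train_mlda,
    train_svm_linear,
)
from emostroop.synthetic import GROUP_NEG, GROUP_POS

LABELS_18 = np.array([GROUP_POS] * 11 + [GROUP_NEG] * 7)


def separable_features(rng, n_features=3, gap=8.0):
    X = rng.standard_normal((18, n_features))
    X[:11] += gap  # every feature informative and well separated
    return X


def match_moments(x, mean, sd):
    """Affine-map a sample to exact mean and sd."""
    z = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * z


class TestSelectFeatures:
    def test_truly_different_channels_selected(self, rng):
        n = 200
        labels = np.array([GROUP_POS] * n + [GROUP_NEG] * n)
        cols = {}
        for j in range(9):
            x = rng.standard_normal(2 * n)
            if j < 3:
                x[:n] += 1.0
            cols[f"ch{j}"] = x
        fm, manifest = select_features(pd.DataFrame(cols), labels)
        assert set(manifest["selected"]) == {"ch0", "ch1", "ch2"}
        assert manifest["circular"] is True

    def test_null_selection_rate_matches_threshold(self, rng):
        counts = []
        labels = np.array([GROUP_POS] * 9 + [GROUP_NEG] * 9)
        for _ in range(200):
            cols = {f"c{j}": rng.standard_normal(18) for j in range(20)}
            try:
                fm, man = select_features(pd.DataFrame(cols), labels,
                                          p_threshold=0.05)
                counts.append(len(man["selected"]))
            except ValueError:
                counts.append(0)
        # expected count = 0.05 * 20 = 1; allow generous binomial slack
        assert 0.5 < np.mean(counts) < 1.6

    def test_printed_summary_style_input_selects_bold_channels(self, rng):
        """Channels with clearly separated group summaries are selected and
        indistinguishable ones are not."""
        table4 = {
            "MFG->SMG": ((0.06, 0.04), (0.17, 0.05)),
            "IFG->SMG": ((0.07, 0.06), (0.19, 0.09)),
            "Insula->ACC": ((0.12, 0.11), (0.27, 0.11)),
            "IFG->ACC": ((0.0503, 0.0657), (0.2333, 0.1325)),
            "IFG->Hippo": ((0.04, 0.03), (0.05, 0.03)),
            "IFG->Putamen": ((0.06, 0.04), (0.08, 0.07)),
            "IFG->VTA": ((0.08, 0.04), (0.10, 0.06)),
            "Thal Putamen->IFG": ((0.38, 0.21), (0.44, 0.22)),
            "Thal VTA->IFG": ((0.59, 0.18), (0.62, 0.19)),
        }
        cols = {}
        for name, ((m1, s1), (m2, s2)) in table4.items():
            a = match_moments(rng.standard_normal(11), m1, s1)
            b = match_moments(rng.standard_normal(7), m2, s2)
            cols[name] = np.concatenate([a, b])
        fm, man = select_features(pd.DataFrame(cols), LABELS_18,
                                  p_threshold=0.05)
        assert set(man["selected"]) == {
            "MFG->SMG", "IFG->SMG", "Insula->ACC", "IFG->ACC"
        }

    def test_empty_selection_is_loud(self, rng):
        cols = {"a": rng.standard_normal(18)}
        with pytest.raises(ValueError, match="no feature"):
            select_features(pd.DataFrame(cols), LABELS_18, p_threshold=1e-9)

    def test_nested_mode_keeps_all_candidates(self, rng):
        cols = {f"c{j}": rng.standard_normal(18) for j in range(4)}
        fm, man = select_features(pd.DataFrame(cols), LABELS_18, mode="nested")
        assert fm.values.shape[1] == 4
        assert man["circular"] is False


class TestMlda:
    def test_separable_clouds_perfect_training(self, rng):
        X = np.vstack([rng.standard_normal((10, 2)),
                       rng.standard_normal((10, 2)) + 8.0])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = train_mlda(X, y)
        assert (model.predict(X) == y).all()

    def test_spherical_scatter_gives_mean_difference_direction(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((6, 2))
        base -= base.mean(axis=0)
        # construct exactly spherical within-class scatter
        u, s, vt = np.linalg.svd(base, full_matrices=False)
        spherical = u @ vt * np.sqrt(2.0)
        X = np.vstack([spherical + [0.0, 0.0], spherical + [3.0, 1.0]])
        y = np.array(["a"] * 6 + ["b"] * 6)
        model = train_mlda(X, y)
        diff = np.array([0.0, 0.0]) - np.array([3.0, 1.0])
        cos = model.weights @ diff / (
            np.linalg.norm(model.weights) * np.linalg.norm(diff)
        )
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_two_feature_case(self):
        """S_p = diag(2, 0.5) regularises to (2, 1.25); w follows."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal((40, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)  # orthonormal, still mean-zero columns
        # both classes share this cloud, so the pooled scatter over
        # dof = 80 - 2 is exactly diag(2, 0.5)
        zw = q @ np.diag([np.sqrt(2.0 * 78 / 2), np.sqrt(0.5 * 78 / 2)])
        mu = np.array([1.0, 2.0])
        X = np.vstack([zw, zw + mu])
        y = np.array(["a"] * 40 + ["b"] * 40)
        model = train_mlda(X, y)
        expected = np.array([-mu[0] / 2.0, -mu[1] / 1.25])
        assert np.allclose(model.weights, expected, atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_mlda(np.zeros((4, 2)), np.array(["a"] * 4))


class TestSvm:
    def test_separable_geometry(self):
        X = np.array([[0.0, 0], [1, 1], [4, 4], [5, 5]])
        y = np.array(["A", "A", "B", "B"])
        model = train_svm_linear(X, y)
        assert (model.predict(X) == y).all()
        # margin midpoint between (1,1) and (4,4)
        assert model.decision(np.array([[2.5, 2.5]]))[0] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_duplicated_points_same_decision_function(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((8, 2)),
                       rng.standard_normal((8, 2)) + 8.0])
        y = np.array(["A"] * 8 + ["B"] * 8)
        # separable data with all slack inactive: duplication is a no-op
        m1 = train_svm_linear(X, y, C=10.0)
        m2 = train_svm_linear(np.vstack([X, X]), np.concatenate([y, y]), C=10.0)
        assert np.allclose(m1.weights, m2.weights, atol=1e-6)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)


class TestCrossValidation:
    @pytest.mark.parametrize("kind", ["kfold", "loo_random", "leave_blocks"])
    def test_separable_perfect_accuracy(self, kind, rng):
        X = separable_features(rng)
        scheme = CvScheme(kind=kind, n_repeats=30, seed=1)
        for model in ("svm", "mlda"):
            rep = cross_validate(model, X, LABELS_18, scheme=scheme)
            assert rep.mean_accuracy == 100.0

    def test_exhaustive_loo_equals_enumeration(self, rng):
        X = rng.standard_normal((18, 3))
        X[:11, 0] += 1.2
        rep = cross_validate("mlda", X, LABELS_18,
                             scheme=CvScheme(kind="loo_exhaustive"))
        hits = []
        for i in range(18):
            tr = np.delete(np.arange(18), i)
            mu = X[tr].mean(0)
            sd = X[tr].std(0)
            sd = np.where(sd > 0, sd, 1.0)
            model = train_mlda((X[tr] - mu) / sd, LABELS_18[tr])
            hits.append(model.predict((X[[i]] - mu) / sd)[0] == LABELS_18[i])
        assert rep.mean_accuracy == pytest.approx(100.0 * np.mean(hits))

    def test_learning_curve_non_decreasing(self, rng):
        X = rng.standard_normal((18, 3))
        X[:11] += 2.0
        means = []
        for m in range(1, 5):
            rep = cross_validate(
                "mlda", X, LABELS_18,
                scheme=CvScheme(kind="leave_blocks", n_repeats=150,
                                m_training_blocks=m, seed=5),
            )
            means.append(rep.mean_accuracy)
        assert means[-1] >= means[0] - 1.0
        assert means[-1] > 90.0

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((18, 4))
        scheme = CvScheme(kind="kfold", n_repeats=20, seed=7)
        a = cross_validate("mlda", X, LABELS_18, scheme=scheme)
        b = cross_validate("mlda", X, LABELS_18, scheme=scheme)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            CvScheme(kind="bootstrap")
        with pytest.raises(ValueError):
            CvScheme(kind="leave_blocks", m_training_blocks=5)


class TestPermutation:
    def test_boundary_p_values(self, rng):
        X = separable_features(rng, gap=10.0)
        scheme = CvScheme(kind="kfold", n_repeats=5, seed=2)
        rep = permutation_test("mlda", X, LABELS_18, scheme=scheme,
                               n_permutations=100, seed=3)
        assert rep.permutation_p == pytest.approx(1.0 / 101.0)
        rep2 = permutation_test("mlda", X, LABELS_18, scheme=scheme,
                                n_permutations=100, seed=3,
                                p_definition="paper")
        assert rep2.permutation_p == 0.0

    def test_deterministic(self, rng):
        X = rng.standard_normal((18, 3))
        scheme = CvScheme(kind="loo_random", n_repeats=10, seed=0)
        p1 = permutation_test("mlda", X, LABELS_18, scheme=scheme,
                              n_permutations=100, seed=11).permutation_p
        p2 = permutation_test("mlda", X, LABELS_18, scheme=scheme,
                              n_permutations=100, seed=11).permutation_p
        assert p1 == p2

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_test("mlda", rng.standard_normal((18, 2)), LABELS_18,
                             n_permutations=10)


class TestContributions:
    def test_normalisation_arithmetic(self):
        from emostroop.classify import LinearModel

        m = LinearModel(weights=np.array([0.0, 0.0, 3.0]), intercept=0.0,
                        class_pos="a", class_neg="b")
        assert feature_contributions(m) == {"f0": 0.0, "f1": 0.0, "f2": 1.0}
        m2 = LinearModel(weights=np.array([3.0, 4.0]), intercept=0.0,
                         class_pos="a", class_neg="b")
        contrib = feature_contributions(m2, ["x", "y"])
        assert contrib["x"] == pytest.approx(0.6)
        assert contrib["y"] == pytest.approx(0.8)

    def test_informative_feature_dominates(self, rng):
        wins = 0
        for _ in range(50):
            X = rng.standard_normal((18, 4))
            X[:11, 1] += 2.5
            model = train_mlda(X, LABELS_18)
            contrib = feature_contributions(model)
            wins += max(contrib, key=contrib.get) == "f1"
        assert wins >= 45

    def test_nonlinear_model_rejected(self):
        with pytest.raises(TypeError):
            feature_contributions(object())


class TestSensitivitySpecificity:
    def test_perfect(self):
        y = np.array(["P"] * 4 + ["N"] * 6)
        assert evaluate_sensitivity_specificity(y, y, "P") == (100.0, 100.0)

    def test_all_positive_predictions(self):
        y = np.array(["P"] * 4 + ["N"] * 6)
        pred = np.array(["P"] * 10)
        assert evaluate_sensitivity_specificity(pred, y, "P") == (100.0, 0.0)

    def test_confusion_counts_87_5_and_98(self):
        y = np.array(["P"] * 8 + ["N"] * 50)
        pred = y.copy()
        pred[7] = "N"  # one missed positive: TP=7, FN=1
        pred[8] = "P"  # one false alarm: FP=1, TN=49
        sens, spec = evaluate_sensitivity_specificity(pred, y, "P")
        assert sens == pytest.approx(87.5)
        assert spec == pytest.approx(98.0)

    def test_unseen_class_rejected(self):
        y = np.array(["P", "N"])
        with pytest.raises(ValueError, match="unseen"):
            evaluate_sensitivity_specificity(np.array(["P", "X"]), y, "P")
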
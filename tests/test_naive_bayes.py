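"""Naive Bayes: priors, smoothing variants, posteriors, risk score,
discretization — checked against hand arithmetic, exhaustive enumeration,
and scikit-learn as an independent implementation."""

import itertools

import numpy as np
import pytest

from ganb import naive_bayes as nb


def toy_multinomial_model(smoothing_mode="standard"):
    """Vocabulary {a, b}; class H has counts a=2, b=1, class L a=1, b=3.

    Built from raw documents so the fitted counts are exactly those.
    """
    X = np.array([
        [2, 0],  # H: "a a"
        [0, 1],  # H: "b"
        [1, 0],  # L: "a"
        [0, 3],  # L: "b b b"
    ])
    y = ["high", "high", "low", "low"]
    return nb.fit(X, y, family="multinomial", alpha=1.0, smoothing_mode=smoothing_mode)


class TestFit:
    def test_priors_from_class_counts(self):
        model = nb.fit(np.zeros((4, 1)), ["high"] * 3 + ["low"],
                       family="gaussian")
        assert np.allclose(model.priors, [0.75, 0.25])

    def test_balanced_priors(self):
        model = nb.fit(np.zeros((4, 1)), ["high", "low", "high", "low"])
        assert np.allclose(model.priors, [0.5, 0.5])

    def test_smoothing_standard_vs_unnormalized(self):
        std = toy_multinomial_model("standard")
        raw = toy_multinomial_model("unnormalized")
        # class H: counts a=2 of total 3, alpha=1, V=2
        assert np.exp(std.log_cond[0, 0]) == pytest.approx(3 / 5)  # (2+1)/(3+2)
        assert np.exp(raw.log_cond[0, 0]) == pytest.approx(3 / 4)  # (2+1)/(3+1)

    def test_standard_conditionals_normalize(self):
        std = toy_multinomial_model("standard")
        assert np.allclose(np.exp(std.log_cond).sum(axis=1), 1.0)

    def test_unnormalized_conditionals_sum(self):
        """The single-alpha denominator gives sum (total + V*alpha)/(total + alpha)."""
        raw = toy_multinomial_model("unnormalized")
        sums = np.exp(raw.log_cond).sum(axis=1)
        assert sums[0] == pytest.approx((3 + 2) / (3 + 1))
        assert sums[1] == pytest.approx((4 + 2) / (4 + 1))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no training samples"):
            nb.fit(np.zeros((2, 1)), ["high", "high"], classes=["high", "low"])

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            nb.fit(np.zeros((2, 1)), ["high", "low"], family="multinomial", alpha=-1)

    def test_multinomial_requires_counts(self):
        with pytest.raises(ValueError, match="integer"):
            nb.fit(np.array([[0.5]]), ["high"], family="multinomial",
                   classes=["high"])


class TestPredict:
    def test_worked_posterior(self):
        """Document 'a a': P(H|x) = 0.18 / (0.18 + 0.5*(1/3)^2) = 0.7642."""
        model = toy_multinomial_model("standard")
        post = nb.predict_posterior(model, np.array([2, 0]))
        assert post[0] == pytest.approx(0.18 / (0.18 + 0.5 * (1 / 3) ** 2), abs=1e-4)
        assert post[0] == pytest.approx(0.7642, abs=1e-4)

    def test_posteriors_sum_to_one(self, rng):
        X = rng.standard_normal((20, 3))
        y = ["high"] * 10 + ["low"] * 10
        model = nb.fit(X, y, family="gaussian")
        post = nb.predict_posterior(model, rng.standard_normal((5, 3)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_classes_give_half(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        model = nb.fit(X, ["high", "low", "high", "low"], family="gaussian")
        post = nb.predict_posterior(model, np.array([0.3]))
        assert np.allclose(post, 0.5)

    def test_gaussian_midpoint_symmetry(self):
        X = np.array([[0.0], [0.1], [-0.1], [1.0], [1.1], [0.9]])
        y = ["high"] * 3 + ["low"] * 3
        model = nb.fit(X, y, family="gaussian")
        post = nb.predict_posterior(model, np.array([0.5]))
        assert post[0] == pytest.approx(0.5, abs=1e-9)

    def test_dimension_mismatch(self):
        model = toy_multinomial_model()
        with pytest.raises(ValueError, match="features"):
            nb.predict_log_posterior(model, np.array([1, 0, 0]))


class TestClassify:
    def test_worked_example_label(self):
        model = toy_multinomial_model()
        assert nb.classify(model, np.array([2, 0])) == "high"

    def test_tie_breaks_to_first_class(self):
        X = np.array([[0.0], [0.0]])
        model = nb.fit(X, ["high", "low"], family="gaussian")
        assert nb.classify(model, np.array([0.0])) == "high"

    def test_matches_enumeration_oracle(self):
        """Exhaustive Bayes arithmetic over every discrete input of toy models."""
        rng = np.random.default_rng(5)
        for n_feat, levels in [(2, 2), (2, 4), (3, 3)]:
            X = rng.integers(0, levels, size=(30, n_feat))
            y = ["high" if v else "low" for v in rng.integers(0, 2, size=30)]
            model = nb.fit(X, y, family="multinomial", alpha=1.0,
                           smoothing_mode="standard")
            cond = np.exp(model.log_cond)  # (k, V)
            priors = model.priors
            for x in itertools.product(range(levels), repeat=n_feat):
                x = np.array(x)
                # direct product-form score per class, no logs
                scores = priors * np.prod(cond ** x[None, :], axis=1)
                oracle = model.classes[int(np.argmax(scores))]
                assert nb.classify(model, x) == oracle

    def test_gaussian_agrees_with_sklearn(self, rng):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X = rng.standard_normal((60, 4)) + np.repeat([[0], [1]], 30, axis=0)
        y = ["high"] * 30 + ["low"] * 30
        ours = nb.fit(X, y, family="gaussian")
        ref = sklearn_nb.GaussianNB().fit(X, y)
        Xq = rng.standard_normal((20, 4))
        ours_post = nb.predict_posterior(ours, Xq)
        ref_post = ref.predict_proba(Xq)  # sklearn orders classes alphabetically
        assert np.allclose(ours_post[:, 0], ref_post[:, list(ref.classes_).index("high")],
                           atol=1e-6)

    def test_multinomial_agrees_with_sklearn(self, rng):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X = rng.integers(0, 5, size=(40, 3))
        y = ["high" if v else "low" for v in rng.integers(0, 2, size=40)]
        ours = nb.fit(X, y, family="multinomial", alpha=0.7, smoothing_mode="standard")
        ref = sklearn_nb.MultinomialNB(alpha=0.7).fit(X, y)
        Xq = rng.integers(0, 5, size=(10, 3))
        ours_post = nb.predict_posterior(ours, Xq)
        ref_post = ref.predict_proba(Xq)
        assert np.allclose(ours_post[:, 0], ref_post[:, list(ref.classes_).index("high")],
                           atol=1e-9)


class TestRiskScore:
    @pytest.mark.parametrize("p_high,expected", [(0.5, 1.0), (0.8, 4.0)])
    def test_closed_forms(self, p_high, expected):
        # build a gaussian model then locate an x with the desired posterior
        model = nb.NbModel(classes=["high", "low"],
                           log_priors=np.log([p_high, 1 - p_high]),
                           family="gaussian",
                           means=np.zeros((2, 1)), variances=np.ones((2, 1)),
                           n_features=1)
        assert nb.risk_score(model, np.array([0.0])) == pytest.approx(expected)

    def test_worked_example_score(self):
        model = toy_multinomial_model()
        assert nb.risk_score(model, np.array([2, 0])) == pytest.approx(3.2410, abs=2e-3)

    def test_strictly_increasing_in_p_high(self, rng):
        X = rng.standard_normal((40, 2)) + np.repeat([[0], [2]], 20, axis=0)
        model = nb.fit(X, ["high"] * 20 + ["low"] * 20, family="gaussian")
        Xq = rng.standard_normal((30, 2))
        p = nb.predict_posterior(model, Xq)[:, 0]
        s = nb.risk_score(model, Xq)
        order = np.argsort(p)
        assert np.all(np.diff(s[order]) >= 0)

    def test_saturated_posterior_gives_inf(self):
        model = nb.NbModel(classes=["high", "low"],
                           log_priors=np.log([0.5, 0.5]), family="gaussian",
                           means=np.array([[0.0], [2000.0]]),
                           variances=np.full((2, 1), 1e-4), n_features=1)
        assert nb.risk_score(model, np.array([0.0])) == np.inf

    def test_non_binary_rejected(self):
        model = nb.fit(np.zeros((3, 1)), ["a", "b", "c"], family="gaussian")
        with pytest.raises(ValueError, match="binary"):
            nb.risk_score(model, np.array([0.0]))


class TestParameterRecovery:
    def test_gaussian_fit_recovers_known_normals(self):
        """2000 samples/class from known per-class normals: means within
        3 standard errors, variances within 10%."""
        rng = np.random.default_rng(77)
        n = 2000
        mu = {"high": np.array([0.0, 2.0]), "low": np.array([1.0, -1.0])}
        sd = {"high": np.array([1.0, 0.5]), "low": np.array([2.0, 1.5])}
        X = np.vstack([rng.normal(mu[c], sd[c], size=(n, 2)) for c in ("high", "low")])
        y = ["high"] * n + ["low"] * n
        model = nb.fit(X, y, family="gaussian")
        for i, c in enumerate(model.classes):
            se = sd[c] / np.sqrt(n)
            assert np.all(np.abs(model.means[i] - mu[c]) < 3 * se)
            assert np.all(np.abs(model.variances[i] / sd[c] ** 2 - 1) < 0.10)


class TestDiscretize:
    def test_uniform_two_bins(self):
        codes, edges = nb.discretize(np.array([[1.0], [2.0], [3.0], [4.0]]),
                                     n_bins=2, strategy="uniform")
        assert codes.ravel().tolist() == [0, 0, 1, 1]
        assert edges[0] == pytest.approx([2.5])

    def test_quantile_codes_rank_invariant(self, rng):
        x = rng.standard_normal((50, 1))
        codes, _ = nb.discretize(x, n_bins=4, strategy="quantile")
        codes2, _ = nb.discretize(np.exp(x), n_bins=4, strategy="quantile")
        assert np.array_equal(codes, codes2)

    def test_out_of_range_clamps(self):
        _, edges = nb.discretize(np.array([[1.0], [2.0], [3.0], [4.0]]),
                                 n_bins=2, strategy="uniform")
        codes = nb.apply_bins(np.array([[-100.0], [100.0]]), edges)
        assert codes.ravel().tolist() == [0, 1]

    def test_constant_feature_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            codes, edges = nb.discretize(np.full((5, 1), 3.0), n_bins=3,
                                         strategy="quantile")
        assert np.all(codes >= 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            nb.discretize(np.zeros((3, 1)), n_bins=1)
        with pytest.raises(ValueError):
            nb.discretize(np.zeros((3, 1)), strategy="magic")


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        X = rng.standard_normal((20, 3))
        y = ["high"] * 10 + ["low"] * 10
        model = nb.fit(X, y, family="gaussian")
        nb.save_model(model, tmp_path / "m.json")
        back = nb.load_model(tmp_path / "m.json")
        Xq = rng.standard_normal((4, 3))
        assert np.allclose(nb.predict_posterior(model, Xq),
                           nb.predict_posterior(back, Xq))
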
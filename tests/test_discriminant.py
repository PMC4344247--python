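"""Two-group LDA: closed forms against brute-force Gaussian-Bayes oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from casig import (
    DiscriminantModel,
    classify,
    discriminant_score,
    fit_lda,
    jackknife_posteriors,
    posterior_probabilities,
)


def bayes_posterior_oracle(model: DiscriminantModel, x: np.ndarray) -> np.ndarray:
    """Independent posterior: prior-weighted Gaussian class densities."""
    dens = np.array(
        [
            pi * multivariate_normal.pdf(x, mean=m, cov=model.pooled_cov)
            for m, pi in zip(model.means, model.priors)
        ]
    )
    return dens / dens.sum()


def naive_jackknife(X, y, labels, priors=(0.5, 0.5)):
    """Explicit leave-one-out loop with textbook pooled covariance."""
    X, y = np.asarray(X, float), np.asarray(y)
    out = []
    for i in range(len(y)):
        keep = np.ones(len(y), bool)
        keep[i] = False
        Xk, yk = X[keep], y[keep]
        groups = [Xk[yk == lab] for lab in labels]
        means = [g.mean(axis=0) for g in groups]
        pooled = sum(
            (g - m).T @ (g - m) for g, m in zip(groups, means)
        ) / (len(Xk) - 2)
        dens = np.array(
            [
                pi * multivariate_normal.pdf(X[i], mean=m, cov=pooled)
                for m, pi in zip(means, priors)
            ]
        )
        post = dens / dens.sum()
        out.append(post[0] if y[i] == labels[0] else post[1])
    return np.array(out)


def toy_model(priors=(0.5, 0.5)) -> DiscriminantModel:
    return DiscriminantModel(
        labels=("a", "b"),
        means=np.array([[1.0, 1.0], [-1.0, -1.0]]),
        pooled_cov=np.eye(2),
        priors=priors,
        n_per_group=(5, 5),
    )


def random_model(rng) -> DiscriminantModel:
    A = rng.normal(size=(2, 2))
    cov = A @ A.T + 0.5 * np.eye(2)
    p1 = rng.uniform(0.2, 0.8)
    return DiscriminantModel(
        labels=("a", "b"),
        means=rng.normal(scale=2.0, size=(2, 2)),
        pooled_cov=cov,
        priors=(p1, 1 - p1),
        n_per_group=(5, 5),
    )


class TestScoresAndPosteriors:
    def test_hand_worked_identity_covariance_case(self):
        # means (1,1)/(-1,-1), S=I, equal priors: D((1,1)) = 4
        model = toy_model()
        assert discriminant_score(model, np.array([1.0, 1.0])) == pytest.approx(4.0)
        p = posterior_probabilities(model, np.array([1.0, 1.0]))
        assert p[0] == pytest.approx(1 / (1 + np.exp(-4.0)), rel=1e-12)

    def test_midpoint_of_means_is_on_the_boundary(self):
        model = toy_model()
        mid = model.means.mean(axis=0)
        assert discriminant_score(model, mid) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(posterior_probabilities(model, mid), [0.5, 0.5])
        assert classify(model, mid) == "a"  # boundary ties go to group 1

    def test_prior_ratio_shifts_score_additively(self):
        x = np.array([0.3, -0.7])
        shift = discriminant_score(toy_model((2 / 3, 1 / 3)), x) - discriminant_score(
            toy_model(), x
        )
        assert shift == pytest.approx(np.log(2.0), rel=1e-12)

    def test_posteriors_match_gaussian_bayes_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            model = random_model(rng)
            x = rng.normal(scale=3.0, size=2)
            np.testing.assert_allclose(
                posterior_probabilities(model, x),
                bayes_posterior_oracle(model, x),
                atol=1e-10,
            )

    def test_posterior_pair_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            model = random_model(rng)
            p = posterior_probabilities(model, rng.normal(scale=5.0, size=2))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)

    def test_score_sign_agrees_with_posterior_argmax(self):
        rng = np.random.default_rng(2)
        model = random_model(rng)
        X = rng.normal(scale=4.0, size=(200, 2))
        D = discriminant_score(model, X)
        P = posterior_probabilities(model, X)
        np.testing.assert_array_equal(D > 0, P[:, 0] > 0.5)

    def test_posterior_monotone_along_discriminant_direction(self):
        model = toy_model()
        w = np.linalg.solve(model.pooled_cov, model.means[0] - model.means[1])
        ts = np.linspace(-3, 3, 50)
        probs = [posterior_probabilities(model, t * w)[0] for t in ts]
        assert np.all(np.diff(probs) > 0)


class TestFit:
    def test_pooled_covariance_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = np.array(["a"] * 14 + ["b"] * 16)
        model = fit_lda(X, y, labels=("a", "b"))
        Xa, Xb = X[:14], X[14:]
        np.testing.assert_allclose(model.means, [Xa.mean(0), Xb.mean(0)], rtol=1e-12)
        expected = (
            (Xa - Xa.mean(0)).T @ (Xa - Xa.mean(0))
            + (Xb - Xb.mean(0)).T @ (Xb - Xb.mean(0))
        ) / (30 - 2)
        np.testing.assert_allclose(model.pooled_cov, expected, rtol=1e-12)

    def test_duplicated_points_give_singular_error(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [4.0, 4.0], [4.0, 4.0]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_lda(X, y)

    def test_collinear_within_group_scatter_is_singular(self):
        # both groups vary along x only -> zero variance in y
        X = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 2.0], [6.0, 2.0]])
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(X, y)

    def test_adding_off_axis_points_restores_the_fit(self):
        X = np.array(
            [[0.0, 0.0], [2.0, 0.0], [1.0, 1.0], [4.0, 2.0], [6.0, 2.0], [5.0, 1.0]]
        )
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = fit_lda(X, y)
        # brute-force pooled covariance
        Xa, Xb = X[:3], X[3:]
        expected = (
            (Xa - Xa.mean(0)).T @ (Xa - Xa.mean(0))
            + (Xb - Xb.mean(0)).T @ (Xb - Xb.mean(0))
        ) / 4
        np.testing.assert_allclose(model.pooled_cov, expected, rtol=1e-12)

    def test_too_small_group_is_an_error(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match=">= 2"):
            fit_lda(X, np.array(["a", "b", "b"]))

    def test_posteriors_invariant_under_affine_feature_maps(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(2, 1, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        x0 = rng.normal(size=2)
        base = posterior_probabilities(fit_lda(X, y, labels=("a", "b")), x0)
        for _ in range(10):
            A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
            b = rng.normal(size=2)
            mapped = posterior_probabilities(
                fit_lda(X @ A.T + b, y, labels=("a", "b")), A @ x0 + b
            )
            np.testing.assert_allclose(mapped, base, atol=1e-8)

    def test_agrees_with_sklearn_reference(self):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(1.5, 1, (60, 2))])
        y = np.array(["a"] * 60 + ["b"] * 60)
        model = fit_lda(X, y, labels=("a", "b"))
        ours = posterior_probabilities(model, X)
        ref = sklearn_da.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        theirs = ref.predict_proba(X)[:, list(ref.classes_).index("a")]
        np.testing.assert_allclose(ours[:, 0], theirs, atol=0.02)
        assert np.mean((ours[:, 0] > 0.5) == (theirs > 0.5)) > 0.98


class TestJackknife:
    def test_matches_naive_leave_one_out_loop(self):
        rng = np.random.default_rng(6)
        for n_g in (3, 4, 7, 12, 20):
            X = np.vstack(
                [rng.normal(0, 1, (n_g, 2)), rng.normal(1.0, 1, (n_g, 2))]
            )
            y = np.array(["a"] * n_g + ["b"] * n_g)
            report = jackknife_posteriors(X, y, labels=("a", "b"))
            np.testing.assert_allclose(
                report.own_posteriors(),
                naive_jackknife(X, y, ("a", "b")),
                atol=1e-10,
            )

    def test_well_separated_clusters_classify_perfectly(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(10, 0.1, (8, 2))])
        y = np.array(["a"] * 8 + ["b"] * 8)
        report = jackknife_posteriors(X, y, labels=("a", "b"))
        assert np.all(report.own_posteriors() > 0.99)

    def test_exchangeable_groups_average_near_half(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 2))  # both groups from the same distribution
        y = np.array(["a", "b"] * 200)
        report = jackknife_posteriors(X, y, labels=("a", "b"))
        assert np.nanmean(report.own_posteriors()) == pytest.approx(0.5, abs=0.1)

    def test_requires_three_per_group(self):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [5.0, 5.0], [6.0, 5.5], [5.5, 6.0]])
        y = np.array(["a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            jackknife_posteriors(X, y, labels=("a", "b"))

    def test_converges_to_full_sample_posterior_for_large_n(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (500, 2)), rng.normal(1.2, 1, (500, 2))])
        y = np.array(["a"] * 500 + ["b"] * 500)
        full = fit_lda(X, y, labels=("a", "b"))
        report = jackknife_posteriors(X, y, labels=("a", "b"))
        full_posts = posterior_probabilities(full, X)
        own_full = np.where(y == "a", full_posts[:, 0], full_posts[:, 1])
        np.testing.assert_allclose(report.own_posteriors(), own_full, atol=1e-2)

    def test_report_carries_keys_and_predictions(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 0.2, (4, 2)), rng.normal(5, 0.2, (4, 2))])
        y = np.array(["a"] * 4 + ["b"] * 4)
        keys = [f"obs{i}" for i in range(8)]
        report = jackknife_posteriors(X, y, labels=("a", "b"), keys=keys)
        assert [r.condition_key for r in report.rows] == keys
        assert all(r.predicted_group == r.true_group for r in report.rows)
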
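"""Two-group linear discriminant analysis with jackknifed posteriors.

The classifier is Fisher/Gaussian LDA in its "sample linear function" form:
for group g with sample mean x̄_g, pooled within-group covariance S (divisor
n1 + n2 - 2) and prior π_g,

    d_g(x) = x̄_gᵀ S⁻¹ x - ½ x̄_gᵀ S⁻¹ x̄_g + ln π_g

The decision statistic is the difference D(x) = d_1(x) - d_2(x); D = 0 is the
decision line, and x is assigned to group 1 iff D(x) > 0 (ties to group 1 by
convention).  Under equal-covariance Gaussian class densities the posterior
probability of group 1 is logistic in D: p_1 = 1 / (1 + exp(-D)).

Classifier performance is evaluated by the jackknife (leave-one-out): each
observation is classified by a model refitted without it, and the posterior
probability of its own group is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True, eq=False)
class DiscriminantModel:
    """Fitted two-group LDA: group means, pooled covariance, priors."""

    labels: tuple[str, str]
    means: np.ndarray           # (2, p)
    pooled_cov: np.ndarray      # (p, p), SPD
    priors: tuple[float, float]
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.pooled_cov, dtype=float)
        if means.shape[0] != 2:
            raise ValueError("exactly two group means required")
        p = means.shape[1]
        if cov.shape != (p, p):
            raise ValueError("pooled_cov shape does not match the means")
        if not np.allclose(cov, cov.T):
            raise ValueError("pooled_cov must be symmetric")
        if not np.isclose(sum(self.priors), 1.0):
            raise ValueError("priors must sum to 1")
        if any(pi <= 0 for pi in self.priors):
            raise ValueError("priors must be positive")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular: the feature vectors are "
                "collinear or constant within groups"
            ) from None
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "pooled_cov", cov)


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: tuple[float, float] | None = None,
    labels: tuple[str, str] | None = None,
) -> DiscriminantModel:
    """Fit the two-group LDA.

    Parameters
    ----------
    X
        (n, p) feature matrix.
    y
        Length-n group labels; exactly two distinct values.
    priors
        Prior probabilities in label order; default equal (0.5, 0.5).
    labels
        Explicit (group1, group2) order; default: order of first appearance
        in ``y``.

    Raises
    ------
    ValueError
        Fewer than 2 observations in a group, or not exactly two groups.
    numpy.linalg.LinAlgError
        Singular pooled covariance (degenerate within-group geometry).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if labels is None:
        seen: list = []
        for lab in y:
            if lab not in seen:
                seen.append(lab)
        if len(seen) != 2:
            raise ValueError(f"exactly two groups required, found {len(seen)}")
        labels = (seen[0], seen[1])
    masks = [y == lab for lab in labels]
    if not all(m.any() for m in masks) or masks[0].sum() + masks[1].sum() != len(y):
        raise ValueError("labels must partition the observations into two groups")
    n1, n2 = int(masks[0].sum()), int(masks[1].sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 observations to pool a covariance")
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    # pooled within-group scatter, unbiased divisor n1 + n2 - 2
    scatter = sum(
        (X[m] - mu).T @ (X[m] - mu) for m, mu in zip(masks, means)
    )
    pooled = scatter / (n1 + n2 - 2)
    priors = (0.5, 0.5) if priors is None else (float(priors[0]), float(priors[1]))
    return DiscriminantModel(
        labels=(labels[0], labels[1]),
        means=means,
        pooled_cov=pooled,
        priors=priors,
        n_per_group=(n1, n2),
    )


def _linear_scores(model: DiscriminantModel, x: np.ndarray) -> np.ndarray:
    """Sample linear functions d_g(x); x is (p,) or (n, p) -> (..., 2)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xa = np.atleast_2d(x)
    Sinv_means = np.linalg.solve(model.pooled_cov, model.means.T)  # (p, 2)
    lin = xa @ Sinv_means                                          # (n, 2)
    const = -0.5 * np.sum(model.means * Sinv_means.T, axis=1) + np.log(model.priors)
    d = lin + const
    return d[0] if single else d


def discriminant_score(model: DiscriminantModel, x: np.ndarray):
    """Difference of the two sample linear functions, D(x) = d_1(x) - d_2(x).

    D = 0 is the decision boundary; classify to ``labels[0]`` iff D(x) >= 0.
    """
    d = _linear_scores(model, x)
    return d[..., 0] - d[..., 1]


def posterior_probabilities(model: DiscriminantModel, x: np.ndarray):
    """Posterior pair (p_1, p_2) under equal-covariance Gaussian classes.

    p_g ∝ exp(d_g(x)); the pair sums to 1 and p_1 is logistic in D(x).
    """
    d = _linear_scores(model, x)
    d = d - d.max(axis=-1, keepdims=True)  # stable softmax
    e = np.exp(d)
    return e / e.sum(axis=-1, keepdims=True)


def classify(model: DiscriminantModel, x: np.ndarray):
    """Predicted label(s): group 1 on the boundary (ties to labels[0])."""
    D = np.asarray(discriminant_score(model, x))
    labels = np.where(D >= 0, model.labels[0], model.labels[1])
    return labels[()] if labels.ndim == 0 else labels


@dataclass(frozen=True)
class JackknifeRow:
    """Leave-one-out result for a single observation."""

    condition_key: object
    true_group: str
    own_group_posterior: float
    predicted_group: str
    flagged: bool = False   # singular refit; posterior is NaN


@dataclass(frozen=True)
class JackknifeReport:
    """Per-observation leave-one-out posteriors of the own group."""

    rows: tuple[JackknifeRow, ...]

    def own_posteriors(self) -> np.ndarray:
        return np.array([r.own_group_posterior for r in self.rows])


def jackknife_posteriors(
    X: np.ndarray,
    y: np.ndarray,
    priors: tuple[float, float] | None = None,
    labels: tuple[str, str] | None = None,
    keys: list | None = None,
) -> JackknifeReport:
    """Leave-one-out posterior probability of each observation's own group.

    For each observation the model is refitted on the remaining n - 1
    observations and the held-out point's posterior for its true group is
    recorded along with the predicted group.  Requires >= 3 observations per
    group so every refit keeps >= 2.  A refit with singular covariance flags
    that row (NaN posterior) instead of dropping it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    full = fit_lda(X, y, priors=priors, labels=labels)
    if min(full.n_per_group) < 3:
        raise ValueError("jackknife requires >= 3 observations per group")
    if keys is None:
        keys = list(range(len(y)))
    rows = []
    idx = np.arange(len(y))
    for i in idx:
        keep = idx != i
        try:
            model = fit_lda(X[keep], y[keep], priors=priors, labels=full.labels)
            post = posterior_probabilities(model, X[i])
            g = 0 if y[i] == full.labels[0] else 1
            rows.append(
                JackknifeRow(
                    condition_key=keys[i],
                    true_group=str(y[i]),
                    own_group_posterior=float(post[g]),
                    predicted_group=str(classify(model, X[i])),
                )
            )
        except np.linalg.LinAlgError:
            rows.append(
                JackknifeRow(
                    condition_key=keys[i],
                    true_group=str(y[i]),
                    own_group_posterior=float("nan"),
                    predicted_group="",
                    flagged=True,
                )
            )
    return JackknifeReport(rows=tuple(rows))
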
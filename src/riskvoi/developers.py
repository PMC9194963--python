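"""Model developers: the fitting strategies whose uncertainty is studied.

A *developer* encapsulates the entire model-development recipe — link
function, penalty, cross-validated shrinkage, anything stochastic — behind a
single contract:

    fit(sample, weights=None, rng=None) -> fitted model with predict_risk(X)

``weights`` is a normalized observation-weight vector (Dirichlet weights from
the Bayesian bootstrap, or multinomial counts / n from the ordinary
bootstrap); ``None`` means equal weights.  Developers must be deterministic
given the sample, the weights, and the supplied random generator, so the
Monte Carlo engine can reproduce any draw from its seed alone.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import expit

__all__ = [
    "FitError",
    "FittedRiskModel",
    "ModelDeveloper",
    "LogisticDeveloper",
    "LassoLogisticDeveloper",
    "InterceptOnlyDeveloper",
    "OracleDeveloper",
    "FixedRiskModel",
    "LinearLogisticModel",
    "point_mass_developer",
]


class FitError(RuntimeError):
    """Model development failed on the given (weighted) sample."""


@runtime_checkable
class FittedRiskModel(Protocol):
    def predict_risk(self, X) -> np.ndarray:  # pragma: no cover - protocol
        ...


@runtime_checkable
class ModelDeveloper(Protocol):
    def fit(self, sample, weights=None, rng=None) -> FittedRiskModel:  # pragma: no cover
        ...


def _check_fittable(sample, weights):
    y = sample.outcomes
    if weights is None:
        ev, nv = y.sum(), (1 - y).sum()
    else:
        w = np.asarray(weights, float)
        ev, nv = float(w @ y), float(w @ (1 - y))
    if ev <= 0 or nv <= 0:
        raise FitError("need positive event and non-event mass to fit a risk model")


def _sample_weight(weights, n):
    # scale so the total weight equals n, keeping the likelihood on the
    # usual per-observation scale (matters for penalized fits)
    if weights is None:
        return None
    w = np.asarray(weights, dtype=float).ravel()
    return w * (n / w.sum())


class _SklearnLogisticModel:
    """Fitted logistic model wrapping an sklearn estimator."""

    def __init__(self, estimator, columns):
        self._est = estimator
        self.columns = list(columns)
        self.intercept = float(estimator.intercept_[0])
        self.coefficients = np.asarray(estimator.coef_[0], dtype=float)

    def predict_risk(self, X) -> np.ndarray:
        arr = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
        return expit(self.intercept + arr @ self.coefficients)


class LogisticDeveloper:
    """Maximum-likelihood logistic regression (no penalty).

    Deterministic given the weighted sample; ``rng`` is accepted and
    ignored.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, sample, weights=None, rng=None) -> _SklearnLogisticModel:
        from sklearn.linear_model import LogisticRegression

        _check_fittable(sample, weights)
        X = sample.X
        # standardize for the optimizer; exact for an unpenalized fit, and
        # coefficients are mapped back to the original scale below
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        est = LogisticRegression(
            C=np.inf, solver="newton-cholesky", max_iter=self.max_iter, tol=self.tol
        )
        est.fit(
            (X - mu) / sd,
            sample.outcomes,
            sample_weight=_sample_weight(weights, sample.n),
        )
        est.coef_ = est.coef_ / sd[None, :]
        est.intercept_ = est.intercept_ - est.coef_ @ mu
        return _SklearnLogisticModel(est, sample.covariates.columns)


class LassoLogisticDeveloper:
    """L1-penalized logistic regression with cross-validated shrinkage.

    The penalty strength is selected by k-fold cross-validation *inside
    every call*, with fold assignment drawn from ``rng``, so that
    selection and shrinkage uncertainty propagate through the bootstrap:
    two posterior draws may select different predictors.
    """

    def __init__(self, cv: int = 10, n_penalties: int = 10, max_iter: int = 10_000):
        self.cv = cv
        self.n_penalties = n_penalties
        self.max_iter = max_iter

    def fit(self, sample, weights=None, rng=None) -> _SklearnLogisticModel:
        from sklearn.linear_model import LogisticRegressionCV
        from sklearn.model_selection import StratifiedKFold

        _check_fittable(sample, weights)
        fold_seed = 0 if rng is None else int(rng.integers(2**31))
        splitter = StratifiedKFold(self.cv, shuffle=True, random_state=fold_seed)
        # standardize so the L1 penalty is scale-invariant (as glmnet does);
        # coefficients are mapped back to the original scale below
        X = sample.X
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        est = LogisticRegressionCV(
            Cs=self.n_penalties,
            l1_ratios=[1.0],
            solver="liblinear",
            cv=splitter,
            scoring="neg_log_loss",
            max_iter=self.max_iter,
            use_legacy_attributes=False,
        )
        try:
            est.fit(
                (X - mu) / sd,
                sample.outcomes,
                sample_weight=_sample_weight(weights, sample.n),
            )
        except ValueError as exc:  # e.g. a fold without events
            raise FitError(f"cross-validated lasso fit failed: {exc}") from exc
        est.coef_ = est.coef_ / sd[None, :]
        est.intercept_ = est.intercept_ - est.coef_ @ mu
        return _SklearnLogisticModel(est, sample.covariates.columns)


class _ConstantRiskModel:
    def __init__(self, risk: float):
        self.risk = float(risk)

    def predict_risk(self, X) -> np.ndarray:
        n = len(X)
        return np.full(n, self.risk)


class InterceptOnlyDeveloper:
    """Ignores covariates; predicts the (weighted) event rate for everyone."""

    def fit(self, sample, weights=None, rng=None) -> _ConstantRiskModel:
        y = sample.outcomes
        if weights is None:
            rate = y.mean()
        else:
            w = np.asarray(weights, float)
            rate = float(w @ y) / float(w.sum())
        return _ConstantRiskModel(rate)


class FixedRiskModel:
    """A frozen risk vector for the development sample's own rows."""

    def __init__(self, risks):
        self.risks = np.asarray(risks, dtype=float).ravel()

    def predict_risk(self, X) -> np.ndarray:
        if len(X) != self.risks.size:
            raise ValueError("FixedRiskModel only predicts on its own sample rows")
        return self.risks.copy()


class LinearLogisticModel:
    """inverse-logit(intercept + X @ coefficients); e.g. a DGP's true risk."""

    def __init__(self, intercept: float, coefficients):
        self.intercept = float(intercept)
        self.coefficients = np.asarray(coefficients, dtype=float).ravel()

    def predict_risk(self, X) -> np.ndarray:
        arr = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
        return expit(self.intercept + arr @ self.coefficients)


class OracleDeveloper:
    """A point-mass "developer" that returns a fixed model regardless of the
    weighted sample — a degenerate posterior.  Wrapping the proposed model
    itself yields zero EVPI; wrapping the true risk model of a synthetic DGP
    is the perfect-information limit."""

    def __init__(self, model: FittedRiskModel):
        self.model = model

    def fit(self, sample, weights=None, rng=None) -> FittedRiskModel:
        return self.model


def point_mass_developer(proposed_risks) -> OracleDeveloper:
    """Developer whose every draw reproduces the proposed model's risks."""
    return OracleDeveloper(FixedRiskModel(proposed_risks))
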
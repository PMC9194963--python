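"""Sampling from the posterior of the correct risks.

The unknown quantity in development-phase value-of-information analysis is
the *correct model* — the strongly calibrated map from covariates to true
event probability.  Rather than specifying a parametric posterior, we draw
from P(theta | D) by refitting the model-development recipe on reweighted
copies of the data:

* **Bayesian bootstrap** — continuous Dirichlet(1, ..., 1) observation
  weights, built from n - 1 sorted uniforms; a posterior draw under a
  non-informative prior.
* **ordinary bootstrap** — Multinomial(n; 1/n, ..., 1/n) counts divided by
  n; equivalent to resampling n rows with replacement.
* **likelihood-based MVN** — coefficients drawn from the multivariate
  normal defined by the maximum-likelihood logistic fit and its covariance
  (a large-sample posterior under a flat prior), pushed through the inverse
  link.

Each draw is one length-n vector of correct risks evaluated on the
*original* sample's covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import expit

from .developers import FitError, ModelDeveloper

__all__ = [
    "SamplingScheme",
    "DrawFailure",
    "PosteriorDraw",
    "bayesian_bootstrap_weights",
    "ordinary_bootstrap_weights",
    "draw_correct_risks",
    "LikelihoodMVNSampler",
    "spawn_generators",
]


class SamplingScheme(str, Enum):
    ORDINARY_BOOTSTRAP = "ordinary_bootstrap"
    BAYESIAN_BOOTSTRAP = "bayesian_bootstrap"
    LIKELIHOOD_MVN = "likelihood_mvn"


class DrawFailure(RuntimeError):
    """A posterior draw could not be obtained (degenerate resamples / fit failure)."""


@dataclass
class PosteriorDraw:
    """One draw of correct risks, with the artifacts that produced it."""

    risks: np.ndarray
    weights: np.ndarray | None
    fitted: object | None
    attempts: int


def bayesian_bootstrap_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(1, ..., 1) weights as gaps between n - 1 sorted uniforms.

    With u_0 = 0 and u_n = 1, w_i = u_(i) - u_(i-1); the gaps are
    exchangeable, nonnegative, and telescope to one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = np.empty(n + 1)
    u[0], u[-1] = 0.0, 1.0
    u[1:-1] = np.sort(rng.uniform(size=n - 1))
    return np.diff(u)


def ordinary_bootstrap_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial(n; 1/n, ..., 1/n) counts scaled by 1/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = rng.multinomial(n, np.full(n, 1.0 / n))
    return counts / n


def _weighted_event_counts(weights, y, n):
    w = np.asarray(weights, float)
    return n * float(w @ y), n * float(w @ (1 - y))


def draw_correct_risks(
    sample,
    developer: ModelDeveloper,
    scheme: SamplingScheme,
    rng: np.random.Generator,
    *,
    min_events: int = 1,
    max_redraws: int = 100,
    mvn_sampler: "LikelihoodMVNSampler | None" = None,
) -> PosteriorDraw:
    """One posterior draw of correct risks on the original sample.

    For the bootstrap schemes a drawn weighted sample whose effective event
    count falls below ``min_events`` (or with no non-event mass) is redrawn,
    up to ``max_redraws`` times; exhaustion raises :class:`DrawFailure`,
    which callers record in diagnostics rather than silently dropping.
    """
    scheme = SamplingScheme(scheme)
    n, y = sample.n, sample.outcomes

    if scheme is SamplingScheme.LIKELIHOOD_MVN:
        if mvn_sampler is None:
            mvn_sampler = LikelihoodMVNSampler(sample)
        risks = mvn_sampler.draw_risks(rng)
        return PosteriorDraw(risks=risks, weights=None, fitted=None, attempts=1)

    draw_w = (
        bayesian_bootstrap_weights
        if scheme is SamplingScheme.BAYESIAN_BOOTSTRAP
        else ordinary_bootstrap_weights
    )
    for attempt in range(1, max_redraws + 2):
        w = draw_w(n, rng)
        events, nonevents = _weighted_event_counts(w, y, n)
        if events < min_events or nonevents <= 0:
            if attempt > max_redraws:
                raise DrawFailure(
                    f"no resample with >= {min_events} events in "
                    f"{max_redraws} redraws"
                )
            continue
        try:
            fitted = developer.fit(sample, weights=w, rng=rng)
        except FitError as exc:
            if attempt > max_redraws:
                raise DrawFailure(f"developer failed on resample: {exc}") from exc
            continue
        risks = np.asarray(fitted.predict_risk(sample.covariates), float).ravel()
        if risks.size != n or np.any(risks < 0) or np.any(risks > 1):
            raise DrawFailure("developer returned an invalid risk vector")
        return PosteriorDraw(risks=risks, weights=w, fitted=fitted, attempts=attempt)
    raise DrawFailure("exhausted redraw budget")  # pragma: no cover


class LikelihoodMVNSampler:
    """Large-sample posterior of logistic coefficients: MVN(MLE, cov).

    Fits an unpenalized logistic model (with intercept) by maximum
    likelihood once; each ``draw`` returns one coefficient vector from the
    implied multivariate normal, and ``draw_risks`` pushes it through the
    inverse logit on the sample's design matrix.
    """

    def __init__(self, sample):
        import statsmodels.api as sm

        X = sm.add_constant(sample.X, has_constant="add")
        try:
            res = sm.Logit(sample.outcomes, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises
            raise FitError(f"maximum-likelihood logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise FitError("maximum-likelihood logistic fit did not converge")
        cov = np.asarray(res.cov_params(), float)
        try:
            self._chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise FitError("coefficient covariance is not positive definite") from exc
        self.mle = np.asarray(res.params, float)
        self.cov = cov
        self._X = X

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One coefficient vector ~ MVN(mle, cov)."""
        return self.mle + self._chol @ rng.standard_normal(self.mle.size)

    def draw_risks(self, rng: np.random.Generator) -> np.ndarray:
        return expit(self._X @ self.draw(rng))


def spawn_generators(seed, n: int) -> list[np.random.Generator]:
    """Independent per-draw generators from one master seed.

    Draw ``i`` always sees the same substream regardless of execution order,
    so individual draws can be reproduced in isolation.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in root.spawn(n)]
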
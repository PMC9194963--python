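"""Synthetic logistic development samples with known truth.

Every stage of the package is testable without external data: a
:class:`LogisticDGP` draws covariates, applies the clinically motivated
transforms (truncation of a blood-pressure-like variable, a linear spline
for a pulse-like variable), forms true risks through the inverse logit, and
samples Bernoulli outcomes.  The true risks are returned alongside the
sample for oracle testing only; no fitting path consumes them.

The ``gusto_like`` preset mimics the *structure* of a 30-day mortality
model after acute myocardial infarction — roughly 7% event rate, a mix of
continuous and binary predictors, one truncated and one spline-transformed
variable — with coefficient values that are package defaults, not estimates
from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .developers import LinearLogisticModel, OracleDeveloper
from .sample import DevelopmentSample

__all__ = [
    "truncate_above",
    "linear_spline_basis",
    "apply_transform",
    "PredictorSpec",
    "LogisticDGP",
    "generate_sample",
    "gusto_like",
    "noise_dgp",
    "true_risk_model",
    "oracle_developer",
]


def truncate_above(x, cap: float) -> np.ndarray:
    """Elementwise min(x, cap); risk stops changing above the cap."""
    return np.minimum(np.asarray(x, dtype=float), float(cap))


def linear_spline_basis(x, knot: float) -> tuple[np.ndarray, np.ndarray]:
    """Basis (x, max(0, x - knot)) so the slope can differ across the knot."""
    arr = np.asarray(x, dtype=float)
    return arr, np.maximum(0.0, arr - float(knot))


def apply_transform(x, transform):
    """Dispatch a transform spec to its basis column(s).

    ``None`` -> (x,);  ("truncate_above", c) -> (min(x, c),);
    ("linear_spline", knot) -> (x, max(0, x - knot)).
    """
    if transform is None:
        return (np.asarray(x, dtype=float),)
    kind, param = transform
    if kind == "truncate_above":
        return (truncate_above(x, param),)
    if kind == "linear_spline":
        return linear_spline_basis(x, param)
    raise ValueError(f"unknown transform {kind!r}")


@dataclass(frozen=True)
class PredictorSpec:
    """One raw covariate: its distribution, optional transform, and the true
    coefficient(s) on the resulting basis column(s)."""

    name: str
    dist: tuple  # ("normal", mu, sd) or ("bernoulli", q)
    coef: tuple[float, ...]
    transform: tuple | None = None

    def __post_init__(self):
        kind = self.dist[0]
        if kind not in ("normal", "bernoulli"):
            raise ValueError(f"unknown distribution {kind!r}")
        if kind == "bernoulli" and not 0.0 < self.dist[1] < 1.0:
            raise ValueError("bernoulli probability must be in (0, 1)")
        coef = tuple(float(c) for c in np.atleast_1d(self.coef))
        object.__setattr__(self, "coef", coef)
        n_cols = 2 if (self.transform and self.transform[0] == "linear_spline") else 1
        if len(coef) != n_cols:
            raise ValueError(
                f"{self.name}: {n_cols} basis column(s) but {len(coef)} coefficient(s)"
            )

    def column_names(self) -> list[str]:
        if self.transform and self.transform[0] == "linear_spline":
            return [self.name, f"{self.name}_gt{self.transform[1]:g}"]
        return [self.name]

    def draw_raw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        kind = self.dist[0]
        if kind == "normal":
            _, mu, sd = self.dist
            return rng.normal(mu, sd, size=n)
        _, q = self.dist
        return rng.binomial(1, q, size=n).astype(float)


@dataclass(frozen=True)
class LogisticDGP:
    """True model: risk = expit(intercept + transformed covariates @ coefs)."""

    intercept: float
    predictors: tuple[PredictorSpec, ...]

    def __post_init__(self):
        if len(self.predictors) < 1:
            raise ValueError("need at least one predictor")
        object.__setattr__(self, "predictors", tuple(self.predictors))

    @property
    def column_names(self) -> list[str]:
        return [c for p in self.predictors for c in p.column_names()]

    @property
    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector aligned with ``column_names``."""
        return np.array([c for p in self.predictors for c in p.coef])


def generate_sample(
    dgp: LogisticDGP, n: int, seed
) -> tuple[DevelopmentSample, np.ndarray]:
    """Draw a development sample of size ``n`` and its true risks.

    Returns ``(sample, true_risks)``; the sample's covariates are the
    transformed basis columns (what a developer fits on).  ``true_risks``
    is for oracle tests and never enters a fitting interface.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for spec in dgp.predictors:
        raw = spec.draw_raw(n, rng)
        for name, col in zip(spec.column_names(), apply_transform(raw, spec.transform)):
            cols[name] = col
    design = pd.DataFrame(cols)
    true_risks = expit(dgp.intercept + design.to_numpy() @ dgp.coefficients)
    outcomes = rng.binomial(1, true_risks)
    return DevelopmentSample(design, outcomes), true_risks


# Intercept calibrated once by simulation (n = 2e6) to a ~7% marginal event
# rate under the covariate distributions below.
_GUSTO_LIKE_INTERCEPT = -1.326


def gusto_like() -> LogisticDGP:
    """Preset mimicking an AMI 30-day-mortality development setting.

    Seven candidate predictors: an age-like variable, a truncated systolic
    blood-pressure-like variable (min(X, 100)), a pulse-like variable with a
    linear spline at 50, and four binary comorbidity/severity indicators —
    exercising every supported transform at a ~7% event rate.
    """
    return LogisticDGP(
        intercept=_GUSTO_LIKE_INTERCEPT,
        predictors=(
            PredictorSpec("age", ("normal", 61.0, 11.0), (0.05,)),
            PredictorSpec(
                "sysbp", ("normal", 125.0, 22.0), (-0.07,), ("truncate_above", 100.0)
            ),
            # pulse mean close enough to the knot that both spline pieces
            # are informed (a knot far below the data makes the second
            # basis column collinear with the first plus the intercept)
            PredictorSpec(
                "pulse", ("normal", 70.0, 17.0), (0.025, 0.01), ("linear_spline", 50.0)
            ),
            PredictorSpec("killip_gt1", ("bernoulli", 0.15), (0.7,)),
            PredictorSpec("prev_mi", ("bernoulli", 0.17), (0.4,)),
            PredictorSpec("hypertension", ("bernoulli", 0.38), (0.15,)),
            PredictorSpec("diabetes", ("bernoulli", 0.15), (0.25,)),
        ),
    )


def noise_dgp(k: int = 10, event_rate: float = 0.07) -> LogisticDGP:
    """``k`` standard-normal predictors with zero coefficients: no signal.

    Useful for optimism tests, where any apparent discrimination is pure
    overfitting.
    """
    return LogisticDGP(
        intercept=float(logit(event_rate)),
        predictors=tuple(
            PredictorSpec(f"x{i}", ("normal", 0.0, 1.0), (0.0,)) for i in range(k)
        ),
    )


def true_risk_model(dgp: LogisticDGP) -> LinearLogisticModel:
    """The DGP's own risk function on the transformed design columns."""
    return LinearLogisticModel(dgp.intercept, dgp.coefficients)


def oracle_developer(dgp: LogisticDGP) -> OracleDeveloper:
    """A developer that always returns the true model (perfect information)."""
    return OracleDeveloper(true_risk_model(dgp))
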
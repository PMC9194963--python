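"""Net-benefit arithmetic at a treatment threshold.

Net benefit (NB) evaluates a treat/no-treat rule at a risk threshold ``z``:
a patient is treated when their predicted risk exceeds ``z``, and NB counts
true positives minus false positives weighted by the exchange rate
``z / (1 - z)``, per patient.  Treating no one has NB = 0 by the opt-in
convention; treating everyone and using a model are scored against that
default.

Two families of estimators are provided:

* empirical estimators that use observed binary outcomes ``y``;
* counterfactual estimators that replace ``y`` with a vector of "correct"
  risks ``p`` (one posterior draw of the true event probabilities), which is
  what the value-of-information machinery averages over.

All functions are pure and operate on one-dimensional numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "exchange_rate",
    "nb_empirical_model",
    "nb_empirical_all",
    "nb_model_given_truth",
    "nb_all_given_truth",
    "nb_max_given_truth",
    "c_statistic",
]


def _check_threshold(z: float) -> float:
    z = float(z)
    if not 0.0 <= z < 1.0:
        raise ValueError(f"threshold must lie in [0, 1); got {z}")
    return z


def _as_risk_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.any(~np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} must contain probabilities in [0, 1]")
    return arr


def _as_outcome_vector(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("outcomes must be non-empty")
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("outcomes must be coded 0/1")
    return arr


def _normalized_weights(weights, n: int) -> np.ndarray | None:
    if weights is None:
        return None
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != n:
        raise ValueError(f"weights have length {w.size}, expected {n}")
    if np.any(w < 0) or not np.isfinite(w).all():
        raise ValueError("weights must be finite and nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive total mass")
    return w / total


def exchange_rate(z: float) -> float:
    """Harm-to-benefit weight ``z / (1 - z)`` of a false positive.

    At threshold ``z`` a decision maker is indifferent between treating and
    not treating, which equates the benefit of one true positive with the
    harm of ``(1 - z) / z`` false positives; e.g. z = 0.02 encodes a 49:1
    benefit:harm ratio.
    """
    z = _check_threshold(z)
    return z / (1.0 - z)


def nb_empirical_model(pi, y, z: float, weights=None) -> float:
    """Empirical NB of treating patients with predicted risk ``pi > z``.

    Computes ``(1/n) * sum I(pi_i > z) * [y_i - (1 - y_i) z/(1-z)]`` (with
    optional observation weights, normalized to sum to one, replacing the
    uniform 1/n).  The indicator is strict: a patient whose risk equals the
    threshold exactly is not treated.
    """
    r = exchange_rate(z)
    pi = _as_risk_vector(pi, "pi")
    yv = _as_outcome_vector(y)
    if pi.size != yv.size:
        raise ValueError(f"pi (n={pi.size}) and y (n={yv.size}) differ in length")
    w = _normalized_weights(weights, pi.size)
    terms = (pi > z) * (yv - (1.0 - yv) * r)
    return float(terms.mean() if w is None else terms @ w)


def nb_empirical_all(y, z: float, weights=None) -> float:
    """Empirical NB of treating everyone: ``(1/n) * sum [y_i - (1-y_i) z/(1-z)]``.

    At z = 0 this is the event rate.
    """
    r = exchange_rate(z)
    yv = _as_outcome_vector(y)
    w = _normalized_weights(weights, yv.size)
    terms = yv - (1.0 - yv) * r
    return float(terms.mean() if w is None else terms @ w)


def nb_model_given_truth(pi, p, z: float) -> float:
    """NB of the rule ``pi > z`` when the correct risks ``p`` are known.

    The observed outcome is replaced by its conditional expectation, the
    correct risk: ``(1/n) * sum I(pi_i > z) * [p_i - (1 - p_i) z/(1-z)]``.
    With degenerate risks ``p in {0, 1}`` this reduces to the empirical
    estimator exactly.
    """
    r = exchange_rate(z)
    pi = _as_risk_vector(pi, "pi")
    p = _as_risk_vector(p, "p")
    if pi.size != p.size:
        raise ValueError(f"pi (n={pi.size}) and p (n={p.size}) differ in length")
    return float(((pi > z) * (p - (1.0 - p) * r)).mean())


def nb_all_given_truth(p, z: float) -> float:
    """NB of treating everyone when the correct risks ``p`` are known."""
    r = exchange_rate(z)
    p = _as_risk_vector(p, "p")
    return float((p - (1.0 - p) * r).mean())


def nb_max_given_truth(p, z: float) -> float:
    """NB of the optimal rule: treat exactly the patients whose correct risk
    contribution is positive.

    Each patient's contribution ``p_i - (1 - p_i) z/(1-z)`` is positive iff
    ``p_i > z``, so summing the positive contributions realizes the rule
    "treat iff correct risk exceeds the threshold" and dominates every other
    treat/no-treat assignment on the same ``p`` — in particular the model
    rule and treat-all — term by term.
    """
    r = exchange_rate(z)
    p = _as_risk_vector(p, "p")
    t = p - (1.0 - p) * r
    return float(((t > 0.0) * t).mean())


def c_statistic(pi, y, weights=None) -> float:
    """Concordance (c) statistic: probability a random event case is ranked
    above a random non-event case, ties counting one half.

    Raises ``ValueError`` when the outcome vector (restricted to positive
    weights) contains only events or only non-events, where the c-statistic
    is undefined.
    """
    from sklearn.metrics import roc_auc_score

    pi = _as_risk_vector(pi, "pi")
    yv = _as_outcome_vector(y)
    if pi.size != yv.size:
        raise ValueError(f"pi (n={pi.size}) and y (n={yv.size}) differ in length")
    w = _normalized_weights(weights, pi.size)
    mask = np.ones(pi.size, bool) if w is None else w > 0
    present = np.unique(yv[mask])
    if present.size < 2:
        raise ValueError(
            "c-statistic undefined: need at least one event and one non-event"
        )
    return float(roc_auc_score(yv, pi, sample_weight=w))
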
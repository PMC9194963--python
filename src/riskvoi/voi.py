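"""Monte Carlo expected value of perfect information for model development.

For a development sample D and a proposed model with predicted risks pi, the
engine draws correct-risk vectors p ~ P(theta | D) (see
:mod:`riskvoi.sampling`), evaluates at each threshold z the net benefit of

* using the proposed model (treat when pi > z),
* treating everyone,
* the optimal rule under that draw (treat when p > z),

and averages across draws.  The expected value of perfect information is

    EVPI(z) = NBbar_max(z) - max{0, NBbar_model(z), NBbar_all(z)},

the expected gain in net benefit from knowing the correct risks rather than
acting on current information.  The relative EVPI compares the incremental
NB over the no-model baseline max{0, NBbar_all} under perfect versus current
information; it is >= 1 where defined, +inf when the model offers no
expected gain but the correct model does, and undefined when even perfect
information offers none.

All three posterior means at a given z use the *same* draws.  Per draw the
optimal rule dominates every alternative term by term, and the engine
computes EVPI from sign-definite paired differences, so ``evpi >= 0`` holds
exactly in floating point, not merely in expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .developers import ModelDeveloper
from .netbenefit import _as_risk_vector, _check_threshold
from .sampling import (
    DrawFailure,
    LikelihoodMVNSampler,
    SamplingScheme,
    draw_correct_risks,
    spawn_generators,
)

__all__ = [
    "VoIResult",
    "default_threshold_grid",
    "evpi",
    "relative_evpi",
    "compute_voi",
    "decision_curves_bayes",
    "sample_size_sweep",
]

_STRATEGIES = ("none", "all", "model")  # tie-break order: simpler wins


def default_threshold_grid(extra=None) -> np.ndarray:
    """Thresholds 0.00, 0.01, ..., 0.99 plus any user-specified values."""
    grid = np.round(np.arange(100) / 100.0, 2)
    if extra is not None:
        grid = np.union1d(grid, np.asarray(list(extra), dtype=float))
    for z in grid:
        _check_threshold(z)
    return grid


def evpi(nb_model_bar: float, nb_all_bar: float, nb_max_bar: float) -> float:
    """EVPI from posterior-mean net benefits:
    ``nb_max_bar - max(0, nb_model_bar, nb_all_bar)``."""
    return float(nb_max_bar - max(0.0, nb_model_bar, nb_all_bar))


def relative_evpi(
    nb_model_bar: float, nb_all_bar: float, nb_max_bar: float
) -> float | None:
    """Relative EVPI: incremental NB over the no-model baseline under
    perfect vs. current information.

    Returns a float >= 1 where defined, ``math.inf`` when the denominator is
    zero but the numerator positive, and ``None`` (the undefined flag) when
    the numerator is zero.
    """
    baseline = max(0.0, nb_all_bar)
    numerator = nb_max_bar - baseline
    denominator = max(0.0, nb_model_bar, nb_all_bar) - baseline
    if numerator == 0.0:
        return None
    if denominator == 0.0:
        return math.inf
    return float(numerator / denominator)


@dataclass
class VoIResult:
    """Per-threshold posterior-mean net benefits and value-of-information.

    ``evpi_r`` uses ``inf`` as the explicit +infinity sentinel and ``nan``
    where undefined; ``evpi_r_defined`` flags the defined entries.  ``mc_se``
    is the Monte Carlo standard error of the EVPI estimate; per-mean errors
    for the three NB curves are also kept.
    """

    thresholds: np.ndarray
    nb_model_bar: np.ndarray
    nb_all_bar: np.ndarray
    nb_max_bar: np.ndarray
    evpi: np.ndarray
    evpi_r: np.ndarray
    evpi_r_defined: np.ndarray
    delta_current: np.ndarray
    delta_perfect: np.ndarray
    mc_se: np.ndarray
    mc_se_nb_model: np.ndarray
    mc_se_nb_all: np.ndarray
    mc_se_nb_max: np.ndarray
    best_strategy: np.ndarray
    n_draws_used: int
    n_draws_failed: int
    scheme: str
    seed: object = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per threshold; +inf / undefined kept as float inf / nan."""
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model_bar": self.nb_model_bar,
                "nb_all_bar": self.nb_all_bar,
                "nb_max_bar": self.nb_max_bar,
                "evpi": self.evpi,
                "evpi_r": self.evpi_r,
                "delta_current": self.delta_current,
                "delta_perfect": self.delta_perfect,
                "mc_se": self.mc_se,
                "best_strategy": self.best_strategy,
            }
        )


class VoIAccumulator:
    """Streams per-draw NB statistics over a threshold grid.

    For each draw with correct risks p, let t_i(z) = p_i - (1 - p_i) z/(1-z)
    be patient i's treatment contribution.  Alongside the three NB values the
    accumulator stores the paired differences between the optimal rule and
    each current-information strategy, each assembled from sign-definite
    partial sums so nonnegativity survives floating-point summation.
    """

    def __init__(self, proposed_risks: np.ndarray, grid: np.ndarray, n: int):
        self.grid = np.asarray(grid, dtype=float)
        self.rates = self.grid / (1.0 - self.grid)
        self.n = n
        self.mask_pi = proposed_risks[:, None] > self.grid[None, :]
        self.nb_model: list[np.ndarray] = []
        self.nb_all: list[np.ndarray] = []
        self.nb_max: list[np.ndarray] = []
        self.d_model: list[np.ndarray] = []
        self.d_all: list[np.ndarray] = []

    def update(self, p: np.ndarray) -> None:
        t = p[:, None] - (1.0 - p)[:, None] * self.rates[None, :]
        pos = t > 0.0
        t_pos = np.where(pos, t, 0.0)  # nonnegative entries
        t_neg = np.where(pos, 0.0, t)  # nonpositive entries
        mask = self.mask_pi
        self.nb_model.append((np.where(mask, t, 0.0)).sum(axis=0) / self.n)
        self.nb_all.append(t.sum(axis=0) / self.n)
        self.nb_max.append(t_pos.sum(axis=0) / self.n)
        # optimal-minus-model: add positive terms the model misses, remove
        # nonpositive terms it keeps; both parts have a definite sign
        gain = np.where(~mask, t_pos, 0.0).sum(axis=0)
        loss = np.where(mask, t_neg, 0.0).sum(axis=0)
        self.d_model.append((gain - loss) / self.n)
        self.d_all.append((-t_neg.sum(axis=0)) / self.n)

    @property
    def n_used(self) -> int:
        return len(self.nb_all)

    def finalize(self, *, n_failed: int, scheme: str, seed=None) -> VoIResult:
        if self.n_used == 0:
            raise RuntimeError("all posterior draws failed; cannot compute EVPI")
        nb_model = np.vstack(self.nb_model)
        nb_all = np.vstack(self.nb_all)
        nb_max = np.vstack(self.nb_max)
        d_none = nb_max  # optimal minus treat-none (NB 0)
        d_all = np.vstack(self.d_all)
        d_model = np.vstack(self.d_model)
        used = self.n_used

        m_model = nb_model.mean(axis=0)
        m_all = nb_all.mean(axis=0)
        m_max = nb_max.mean(axis=0)
        d_bars = np.vstack([d_none.mean(axis=0), d_all.mean(axis=0), d_model.mean(axis=0)])
        evpi_vals = d_bars.min(axis=0)  # == m_max - max(0, m_model, m_all)

        # best strategy under current information; argmax takes the first
        # maximizer, so the stacking order enforces none > all > model ties
        cand = np.vstack([np.zeros_like(m_all), m_all, m_model])
        best_idx = cand.argmax(axis=0)
        best = np.array([_STRATEGIES[i] for i in best_idx])

        baseline = np.maximum(0.0, m_all)
        delta_current = np.max(cand, axis=0) - baseline
        delta_perfect = delta_current + evpi_vals

        # ratio built from the same deltas as the paired-difference evpi so
        # that evpi == 0 implies exactly 1 (or the undefined flag)
        evpi_r = np.empty_like(evpi_vals)
        defined = np.empty(evpi_vals.size, dtype=bool)
        for j in range(evpi_vals.size):
            if delta_perfect[j] == 0.0:
                evpi_r[j], defined[j] = np.nan, False
            elif delta_current[j] == 0.0:
                evpi_r[j], defined[j] = np.inf, True
            else:
                evpi_r[j], defined[j] = delta_perfect[j] / delta_current[j], True

        def se(mat):
            if used < 2:
                return np.full(mat.shape[1], np.nan)
            return mat.std(axis=0, ddof=1) / np.sqrt(used)

        d_best = np.take_along_axis(
            np.stack([d_none, d_all, d_model], axis=0),
            best_idx[None, None, :],
            axis=0,
        )[0]
        mc_se = se(d_best)

        result = VoIResult(
            thresholds=self.grid.copy(),
            nb_model_bar=m_model,
            nb_all_bar=m_all,
            nb_max_bar=m_max,
            evpi=evpi_vals,
            evpi_r=evpi_r,
            evpi_r_defined=defined,
            delta_current=delta_current,
            delta_perfect=delta_perfect,
            mc_se=mc_se,
            mc_se_nb_model=se(nb_model),
            mc_se_nb_all=se(nb_all),
            mc_se_nb_max=se(nb_max),
            best_strategy=best,
            n_draws_used=used,
            n_draws_failed=n_failed,
            scheme=str(scheme),
            seed=seed,
        )
        with np.errstate(invalid="ignore"):
            loud = (result.mc_se > 0.1 * result.evpi) & (result.evpi > 0)
        if loud.any():
            warnings.warn(
                "Monte Carlo SE exceeds 10% of EVPI at "
                f"{int(loud.sum())} threshold(s); consider more draws",
                stacklevel=3,
            )
        return result


def compute_voi(
    sample,
    proposed_risks,
    developer: ModelDeveloper,
    *,
    grid=None,
    n_draws: int = 1000,
    scheme: SamplingScheme = SamplingScheme.BAYESIAN_BOOTSTRAP,
    seed=0,
    min_events: int = 1,
    max_redraws: int = 100,
) -> VoIResult:
    """Run the Monte Carlo EVPI algorithm on a development sample.

    Parameters
    ----------
    sample : DevelopmentSample
        The data the analysis conditions on.
    proposed_risks : array-like
        Predicted risks pi of the proposed model on ``sample``'s rows.
    developer : ModelDeveloper
        The model-development recipe refit on every reweighted draw.
    grid : array-like of thresholds, optional
        Defaults to 0.00-0.99 in steps of 0.01.
    n_draws : int
        Posterior draws N; the Table-style default is 1000.
    scheme : SamplingScheme
        ordinary_bootstrap, bayesian_bootstrap, or likelihood_mvn.
    seed : int or numpy SeedSequence
        Master seed; draw i uses substream i regardless of order.
    min_events, max_redraws : int
        Degenerate-resample guard passed to the posterior sampler.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    pi = _as_risk_vector(proposed_risks, "proposed_risks")
    if pi.size != sample.n:
        raise ValueError("proposed_risks not aligned with the sample")
    grid = default_threshold_grid() if grid is None else np.asarray(grid, float)
    for z in grid:
        _check_threshold(z)

    scheme = SamplingScheme(scheme)
    mvn = LikelihoodMVNSampler(sample) if scheme is SamplingScheme.LIKELIHOOD_MVN else None
    acc = VoIAccumulator(pi, grid, sample.n)
    n_failed = 0
    for rng in spawn_generators(seed, n_draws):
        try:
            draw = draw_correct_risks(
                sample,
                developer,
                scheme,
                rng,
                min_events=min_events,
                max_redraws=max_redraws,
                mvn_sampler=mvn,
            )
        except DrawFailure:
            n_failed += 1
            continue
        acc.update(draw.risks)
    if n_failed:
        warnings.warn(f"{n_failed} of {n_draws} posterior draws failed", stacklevel=2)
    return acc.finalize(n_failed=n_failed, scheme=scheme.value, seed=seed)


def decision_curves_bayes(result: VoIResult) -> pd.DataFrame:
    """Incremental-NB curves against the no-model baseline.

    One row per threshold with ``delta_current`` (expected gain of the best
    current-information strategy) and ``delta_perfect`` (expected gain of
    the correct model); their difference is the EVPI.
    """
    return pd.DataFrame(
        {
            "threshold": result.thresholds,
            "delta_current": result.delta_current,
            "delta_perfect": result.delta_perfect,
        }
    )


def sample_size_sweep(
    source,
    sizes,
    *,
    replicates: int = 10,
    z_list=(0.01, 0.02, 0.05, 0.10),
    n_draws: int = 200,
    developer: ModelDeveloper | None = None,
    scheme: SamplingScheme = SamplingScheme.ORDINARY_BOOTSTRAP,
    seed=0,
    min_events_dataset: int = 8,
    min_events: int = 1,
    max_redraws: int = 100,
) -> pd.DataFrame:
    """EVPI as a function of development-sample size.

    ``source`` is either a parent :class:`DevelopmentSample` (subsampled
    without replacement) or a :class:`~riskvoi.simulate.LogisticDGP` (fresh
    data per replicate).  For each (size, replicate) a model is developed on
    the subsample by ``developer`` and its EVPI computed; per (size, z) the
    table reports the mean EVPI and the median relative EVPI across
    replicates.  Data sets with fewer than ``min_events_dataset`` events are
    redrawn (mirroring the practice of discarding sparse resamples in which
    penalized optimizers are unreliable).  Undefined relative-EVPI values
    are excluded from the median and counted; the +inf sentinel participates
    in the median by ordering.
    """
    from .developers import LogisticDeveloper
    from .sample import DevelopmentSample
    from .simulate import LogisticDGP, generate_sample

    sizes = [int(s) for s in sizes]
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    z_list = [_check_threshold(z) for z in z_list]
    developer = developer or LogisticDeveloper()

    is_dgp = isinstance(source, LogisticDGP)
    if not is_dgp and not isinstance(source, DevelopmentSample):
        raise TypeError("source must be a DevelopmentSample or LogisticDGP")
    if not is_dgp and max(sizes) > source.n:
        raise ValueError(f"size {max(sizes)} exceeds parent sample n={source.n}")

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(sizes) * replicates)
    records = []
    for si, size in enumerate(sizes):
        for rep in range(replicates):
            child = children[si * replicates + rep]
            data_ss, voi_ss = child.spawn(2)
            rng = np.random.Generator(np.random.PCG64(data_ss))
            for _ in range(1000):
                if is_dgp:
                    sub, _truth = generate_sample(source, size, rng)
                else:
                    idx = rng.choice(source.n, size=size, replace=False)
                    sub = source.subsample(idx)
                if sub.n_events >= min_events_dataset and sub.n_events < sub.n:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a size-{size} data set with >= "
                    f"{min_events_dataset} events"
                )
            fitted = developer.fit(sub, weights=None, rng=rng)
            pi = np.clip(np.asarray(fitted.predict_risk(sub.covariates), float), 0, 1)
            res = compute_voi(
                sub,
                pi,
                developer,
                grid=z_list,
                n_draws=n_draws,
                scheme=scheme,
                seed=voi_ss,
                min_events=min_events,
                max_redraws=max_redraws,
            )
            for j, z in enumerate(z_list):
                records.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "threshold": z,
                        "evpi": res.evpi[j],
                        "evpi_r": res.evpi_r[j],
                        "evpi_r_defined": bool(res.evpi_r_defined[j]),
                    }
                )
    raw = pd.DataFrame.from_records(records)

    rows = []
    for (size, z), grp in raw.groupby(["size", "threshold"], sort=True):
        defined = grp.loc[grp["evpi_r_defined"], "evpi_r"]
        rows.append(
            {
                "size": size,
                "threshold": z,
                "mean_evpi": grp["evpi"].mean(),
                "median_evpi_r": float(np.median(defined)) if len(defined) else np.nan,
                "n_evpi_r_undefined": int((~grp["evpi_r_defined"]).sum()),
                "n_replicates": len(grp),
            }
        )
    return pd.DataFrame(rows)
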
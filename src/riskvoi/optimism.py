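"""Harrell bootstrap optimism correction, sharable with the EVPI loop.

A model evaluated on its own development sample looks better than it will in
the generating population.  Harrell's bootstrap estimates that *optimism*:
refit the development recipe on a bootstrap resample, score the new model on
the resample and on the original sample, and average the differences over
many resamples; corrected = apparent - mean optimism.

Because each iteration already produces a refit model and its predictions on
the original sample — exactly one posterior draw of correct risks under the
ordinary bootstrap — the optimism correction and the EVPI computation can
share a single resampling pass (:func:`joint_loop`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .developers import ModelDeveloper
from .netbenefit import c_statistic, nb_empirical_model
from .sampling import DrawFailure, SamplingScheme, draw_correct_risks, spawn_generators
from .voi import VoIAccumulator, VoIResult, default_threshold_grid

__all__ = ["OptimismReport", "harrell_correct", "joint_loop"]

# fixed salt so the apparent-model fit uses a stream disjoint from the
# per-iteration substreams, identically in harrell_correct and joint_loop
_APPARENT_SALT = 0x5EED


@dataclass
class OptimismReport:
    """Apparent, optimism, and corrected values; corrected = apparent - optimism."""

    thresholds: np.ndarray
    apparent_nb: np.ndarray
    optimism_nb: np.ndarray
    corrected_nb: np.ndarray
    apparent_c: float
    optimism_c: float
    corrected_c: float
    n_boot: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        """Long layout: one row per (metric, threshold); the c-statistic row
        has an empty threshold."""
        nb = pd.DataFrame(
            {
                "metric": "nb_model",
                "threshold": self.thresholds,
                "apparent": self.apparent_nb,
                "optimism": self.optimism_nb,
                "corrected": self.corrected_nb,
            }
        )
        c = pd.DataFrame(
            {
                "metric": ["c_statistic"],
                "threshold": [np.nan],
                "apparent": [self.apparent_c],
                "optimism": [self.optimism_c],
                "corrected": [self.corrected_c],
            }
        )
        return pd.concat([nb, c], ignore_index=True)


def _apparent_rng(seed):
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        entropy=root.entropy, spawn_key=(_APPARENT_SALT,)
    )))


class _OptimismAccumulator:
    def __init__(self, sample, proposed_risks, grid):
        self.sample = sample
        self.grid = np.asarray(grid, float)
        self.y = sample.outcomes
        self.apparent_nb = np.array(
            [nb_empirical_model(proposed_risks, self.y, z) for z in self.grid]
        )
        self.apparent_c = c_statistic(proposed_risks, self.y)
        self.nb_diffs: list[np.ndarray] = []
        self.c_diffs: list[float] = []

    def update(self, risks: np.ndarray, weights: np.ndarray) -> None:
        # new model scored on the bootstrap sample (= weighted original rows)
        # minus on the original sample
        nb_boot = np.array(
            [nb_empirical_model(risks, self.y, z, weights=weights) for z in self.grid]
        )
        nb_orig = np.array([nb_empirical_model(risks, self.y, z) for z in self.grid])
        self.nb_diffs.append(nb_boot - nb_orig)
        self.c_diffs.append(c_statistic(risks, self.y, weights=weights)
                            - c_statistic(risks, self.y))

    def finalize(self, n_failed: int) -> OptimismReport:
        if not self.nb_diffs:
            raise RuntimeError("all bootstrap replicates failed")
        opt_nb = np.vstack(self.nb_diffs).mean(axis=0)
        opt_c = float(np.mean(self.c_diffs))
        return OptimismReport(
            thresholds=self.grid.copy(),
            apparent_nb=self.apparent_nb,
            optimism_nb=opt_nb,
            corrected_nb=self.apparent_nb - opt_nb,
            apparent_c=self.apparent_c,
            optimism_c=opt_c,
            corrected_c=self.apparent_c - opt_c,
            n_boot=len(self.nb_diffs),
            n_failed=n_failed,
        )


def _run_loop(
    sample,
    developer,
    grid,
    n_iter,
    seed,
    min_events,
    max_redraws,
    *,
    want_voi: bool,
    want_optimism: bool,
    proposed_risks=None,
):
    grid = default_threshold_grid() if grid is None else np.asarray(grid, float)
    if proposed_risks is None:
        apparent = developer.fit(sample, weights=None, rng=_apparent_rng(seed))
        proposed_risks = np.asarray(apparent.predict_risk(sample.covariates), float)
    voi_acc = VoIAccumulator(proposed_risks, grid, sample.n) if want_voi else None
    opt_acc = (
        _OptimismAccumulator(sample, proposed_risks, grid) if want_optimism else None
    )
    n_failed = 0
    for rng in spawn_generators(seed, n_iter):
        try:
            draw = draw_correct_risks(
                sample,
                developer,
                SamplingScheme.ORDINARY_BOOTSTRAP,
                rng,
                min_events=min_events,
                max_redraws=max_redraws,
            )
        except DrawFailure:
            n_failed += 1
            continue
        if voi_acc is not None:
            voi_acc.update(draw.risks)
        if opt_acc is not None:
            opt_acc.update(draw.risks, draw.weights)
    if n_failed:
        warnings.warn(f"{n_failed} of {n_iter} bootstrap replicates failed", stacklevel=3)
    voi_res = (
        voi_acc.finalize(
            n_failed=n_failed,
            scheme=SamplingScheme.ORDINARY_BOOTSTRAP.value,
            seed=seed,
        )
        if voi_acc is not None
        else None
    )
    opt_res = opt_acc.finalize(n_failed) if opt_acc is not None else None
    return voi_res, opt_res


def harrell_correct(
    sample,
    developer: ModelDeveloper,
    *,
    grid=None,
    n_boot: int = 200,
    seed=0,
    min_events: int = 1,
    max_redraws: int = 100,
    proposed_risks=None,
) -> OptimismReport:
    """Optimism-corrected decision-curve NB (per threshold) and c-statistic.

    The apparent model is developed on the full sample (unless
    ``proposed_risks`` is supplied); each of ``n_boot`` ordinary-bootstrap
    replicates refits the recipe and contributes
    ``metric(new model | bootstrap sample) - metric(new model | original)``.
    Replicate fit failures fall under the same degenerate-resample guard as
    the posterior sampler and are reported in the result.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    _, report = _run_loop(
        sample,
        developer,
        grid,
        n_boot,
        seed,
        min_events,
        max_redraws,
        want_voi=False,
        want_optimism=True,
        proposed_risks=proposed_risks,
    )
    return report


def joint_loop(
    sample,
    developer: ModelDeveloper,
    *,
    grid=None,
    n_iter: int = 1000,
    seed=0,
    min_events: int = 1,
    max_redraws: int = 100,
) -> tuple[VoIResult, OptimismReport]:
    """One ordinary-bootstrap pass yielding both EVPI and optimism.

    Each iteration's refit model serves double duty: its predictions on the
    original sample are one posterior draw of correct risks, and its scores
    on resample vs. original give one optimism contribution.  With a shared
    seed the outputs are identical to running :func:`compute_voi`
    (ordinary bootstrap) and :func:`harrell_correct` separately.  The
    classical optimism estimator is defined for resamples, so this loop
    always uses the ordinary bootstrap.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    voi_res, report = _run_loop(
        sample,
        developer,
        grid,
        n_iter,
        seed,
        min_events,
        max_redraws,
        want_voi=True,
        want_optimism=True,
    )
    return voi_res, report
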
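"""The Monte Carlo EVPI engine: formulas, dominance, oracles, sweep."""

import math

import numpy as np
import pytest

from riskvoi import (
    InterceptOnlyDeveloper,
    LogisticDeveloper,
    SamplingScheme,
    compute_voi,
    decision_curves_bayes,
    default_threshold_grid,
    evpi,
    gusto_like,
    generate_sample,
    nb_all_given_truth,
    nb_max_given_truth,
    nb_model_given_truth,
    oracle_developer,
    point_mass_developer,
    relative_evpi,
    sample_size_sweep,
)


class TestEvpiFormula:
    def test_case_study_subtraction(self):
        """The printed 0.0489 - 0.0484 = 0.0005 arithmetic."""
        assert evpi(0.0484, 0.0478, 0.0489) == pytest.approx(0.0005, abs=1e-12)

    def test_zero_when_max_term_dominates(self):
        assert evpi(0.03, 0.02, 0.03) == 0.0

    def test_treat_none_floor(self):
        assert evpi(-0.1, -0.2, 0.0) == 0.0


class TestRelativeEvpi:
    def test_printed_rounded_ratio(self):
        # ratio of the printed, rounded incremental NBs (0.0011 / 0.0006)
        v = relative_evpi(0.0484, 0.0478, 0.0489)
        assert v == pytest.approx(0.0011 / 0.0006, rel=1e-9)
        assert v == pytest.approx(1.83, abs=0.01)

    def test_infinite_when_model_adds_nothing(self):
        assert relative_evpi(0.01, 0.01, 0.011) == math.inf

    def test_undefined_when_perfect_adds_nothing(self):
        assert relative_evpi(0.01, 0.01, 0.01) is None

    def test_at_least_one_where_defined(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m, a = rng.normal(0, 0.05, 2)
            mx = max(0.0, m, a) + rng.uniform(0, 0.05)
            v = relative_evpi(m, a, mx)
            if v is not None:
                assert v >= 1.0


class _SequenceDeveloper:
    """Deterministic sequence of correct-risk draws, for dual-route checks."""

    def __init__(self, draws):
        self.draws = list(draws)
        self.i = 0

    def fit(self, sample, weights=None, rng=None):
        from riskvoi import FixedRiskModel

        p = self.draws[self.i % len(self.draws)]
        self.i += 1
        return FixedRiskModel(p)


class TestComputeVoi:
    def test_point_mass_developer_zero_evpi(self, small_sample, fitted_small):
        sample, _ = small_sample
        _, _, pi = fitted_small
        res = compute_voi(
            sample, pi, point_mass_developer(pi), n_draws=20, seed=11
        )
        assert np.all(res.evpi == 0.0)
        assert np.all(res.evpi_r[res.evpi_r_defined] == 1.0)

    def test_oracle_developer_zero_evpi(self, gusto_dgp):
        sample, truth = generate_sample(gusto_dgp, 400, 99)
        res = compute_voi(
            sample, truth, oracle_developer(gusto_dgp), n_draws=10, seed=2
        )
        assert np.all(res.evpi == 0.0)

    def test_engine_matches_per_threshold_operations(self, small_sample, fitted_small):
        """Dual route: the vectorized engine vs. the scalar NB operations."""
        sample, _ = small_sample
        _, _, pi = fitted_small
        rng = np.random.default_rng(8)
        draws = [np.clip(pi + rng.normal(0, 0.02, pi.size), 0, 1) for _ in range(5)]
        grid = [0.0, 0.02, 0.05, 0.2, 0.5, 0.9]
        res = compute_voi(
            sample, pi, _SequenceDeveloper(draws), grid=grid, n_draws=5, seed=0
        )
        for j, z in enumerate(grid):
            m = np.mean([nb_model_given_truth(pi, p, z) for p in draws])
            a = np.mean([nb_all_given_truth(p, z) for p in draws])
            mx = np.mean([nb_max_given_truth(p, z) for p in draws])
            assert res.nb_model_bar[j] == pytest.approx(m, abs=1e-12)
            assert res.nb_all_bar[j] == pytest.approx(a, abs=1e-12)
            assert res.nb_max_bar[j] == pytest.approx(mx, abs=1e-12)
            assert res.evpi[j] == pytest.approx(evpi(m, a, mx), abs=1e-12)
            expected_r = relative_evpi(m, a, mx)
            if expected_r is None:
                assert not res.evpi_r_defined[j]
            elif math.isinf(expected_r):
                assert math.isinf(res.evpi_r[j])
            else:
                assert res.evpi_r[j] == pytest.approx(expected_r, rel=1e-9)

    def test_exact_nonnegativity_random_data(self):
        rng = np.random.default_rng(21)
        dgp = gusto_like()
        for seed in range(3):
            sample, _ = generate_sample(dgp, 150, rng)
            dev = LogisticDeveloper()
            pi = dev.fit(sample).predict_risk(sample.covariates)
            res = compute_voi(
                sample, np.clip(pi, 0, 1), dev, n_draws=20, seed=seed,
                scheme=SamplingScheme.BAYESIAN_BOOTSTRAP,
            )
            assert np.all(res.evpi >= 0.0)

    def test_all_draws_failed_raises(self, small_sample, fitted_small):
        from riskvoi import FitError

        sample, _ = small_sample
        _, _, pi = fitted_small

        class Hopeless:
            def fit(self, sample, weights=None, rng=None):
                raise FitError("nope")

        with pytest.raises(RuntimeError), pytest.warns(UserWarning):
            compute_voi(
                sample, pi, Hopeless(), n_draws=3, seed=0, max_redraws=1,
                grid=[0.02],
            )

    def test_rejects_misaligned_risks(self, small_sample):
        sample, _ = small_sample
        with pytest.raises(ValueError):
            compute_voi(sample, [0.1, 0.2], LogisticDeveloper(), n_draws=2)

    def test_likelihood_mvn_scheme_runs(self):
        dgp = gusto_like()
        sample, _ = generate_sample(dgp, 500, 31)
        dev = LogisticDeveloper()
        pi = np.clip(dev.fit(sample).predict_risk(sample.covariates), 0, 1)
        res = compute_voi(
            sample, pi, dev, grid=[0.02, 0.1], n_draws=200,
            scheme=SamplingScheme.LIKELIHOOD_MVN, seed=5,
        )
        assert np.all(res.evpi >= 0.0)
        assert res.n_draws_used == 200


class TestDecisionCurves:
    def test_identity_and_shape(self, small_sample, fitted_small):
        sample, _ = small_sample
        dev, _, pi = fitted_small
        res = compute_voi(sample, pi, dev, n_draws=30, seed=13)
        table = decision_curves_bayes(res)
        assert len(table) == res.thresholds.size
        np.testing.assert_array_equal(
            table["delta_perfect"], table["delta_current"] + res.evpi
        )
        assert np.all(table["delta_perfect"] >= table["delta_current"])
        assert np.all(table["delta_current"] >= 0.0)

    def test_point_mass_curves_coincide(self, small_sample, fitted_small):
        sample, _ = small_sample
        _, _, pi = fitted_small
        res = compute_voi(sample, pi, point_mass_developer(pi), n_draws=5, seed=1)
        table = decision_curves_bayes(res)
        np.testing.assert_array_equal(
            table["delta_perfect"], table["delta_current"]
        )


class TestSampleSizeSweep:
    def test_degenerate_sweep_matches_compute_voi(self, gusto_dgp):
        parent, _ = generate_sample(gusto_dgp, 500, 3)
        dev = LogisticDeveloper()
        table = sample_size_sweep(
            parent, [300], replicates=1, z_list=[0.02, 0.05], n_draws=20,
            developer=dev, seed=77, min_events_dataset=8,
        )
        assert len(table) == 2
        # replay the sweep's internal seeding to check the row values
        root = np.random.SeedSequence(77)
        child = root.spawn(1)[0]
        data_ss, voi_ss = child.spawn(2)
        rng = np.random.Generator(np.random.PCG64(data_ss))
        sub = parent.subsample(rng.choice(parent.n, 300, replace=False))
        assert sub.n_events >= 8
        pi = np.clip(dev.fit(sub, rng=rng).predict_risk(sub.covariates), 0, 1)
        res = compute_voi(
            sub, pi, dev, grid=[0.02, 0.05], n_draws=20,
            scheme=SamplingScheme.ORDINARY_BOOTSTRAP, seed=voi_ss,
        )
        np.testing.assert_allclose(table["mean_evpi"].to_numpy(), res.evpi)

    def test_size_exceeding_parent_rejected(self, small_sample):
        sample, _ = small_sample
        with pytest.raises(ValueError):
            sample_size_sweep(sample, [sample.n + 1], replicates=1)

    def test_infinite_median_propagates(self, gusto_dgp):
        """Intercept-only developer: the model never beats treat-all, so the
        relative EVPI is +inf wherever perfect information has value."""
        table = sample_size_sweep(
            gusto_dgp, [200], replicates=3, z_list=[0.02], n_draws=15,
            developer=InterceptOnlyDeveloper(), seed=5,
        )
        row = table.iloc[0]
        assert math.isinf(row["median_evpi_r"]) or row["n_evpi_r_undefined"] == 3


def test_default_grid_and_extras():
    grid = default_threshold_grid()
    assert grid[0] == 0.0 and grid[-1] == 0.99 and grid.size == 100
    grid2 = default_threshold_grid(extra=[0.025])
    assert 0.025 in grid2 and grid2.size == 101
    with pytest.raises(ValueError):
        default_threshold_grid(extra=[1.0])
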
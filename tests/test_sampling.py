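"""Posterior sampling: bootstrap weights, draw reproducibility, MVN sampler."""

import numpy as np
import pytest

from riskvoi import (
    DevelopmentSample,
    DrawFailure,
    InterceptOnlyDeveloper,
    LikelihoodMVNSampler,
    LogisticDeveloper,
    SamplingScheme,
    bayesian_bootstrap_weights,
    draw_correct_risks,
    generate_sample,
    ordinary_bootstrap_weights,
    point_mass_developer,
)
from riskvoi.sampling import spawn_generators


class TestWeights:
    @pytest.mark.parametrize("fn", [bayesian_bootstrap_weights, ordinary_bootstrap_weights])
    def test_single_observation(self, fn):
        assert fn(1, np.random.default_rng(0)).tolist() == [1.0]

    @pytest.mark.parametrize("fn", [bayesian_bootstrap_weights, ordinary_bootstrap_weights])
    def test_rejects_zero(self, fn):
        with pytest.raises(ValueError):
            fn(0, np.random.default_rng(0))

    @pytest.mark.parametrize("fn", [bayesian_bootstrap_weights, ordinary_bootstrap_weights])
    @pytest.mark.parametrize("n", [2, 5, 40])
    def test_simplex(self, fn, n):
        rng = np.random.default_rng(11)
        for _ in range(50):
            w = fn(n, rng)
            assert w.min() >= 0.0
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ordinary_weights_are_multiples_of_one_over_n(self):
        rng = np.random.default_rng(3)
        w = ordinary_bootstrap_weights(7, rng)
        assert np.allclose(w * 7, np.round(w * 7))

    def test_ordinary_mean_matches_multinomial(self):
        n, draws = 3, 30_000
        rng = np.random.default_rng(4)
        w = np.array([ordinary_bootstrap_weights(n, rng) for _ in range(draws)])
        se = w.std(axis=0, ddof=1) / np.sqrt(draws)
        assert np.all(np.abs(w.mean(axis=0) - 1 / n) <= 3 * se)

    def test_bayesian_moments_small(self):
        # Dirichlet(1,..,1) with n=5: mean 1/5, var (1/5)(4/5)/6
        n, draws = 5, 5_000
        rng = np.random.default_rng(9)
        w = np.array([bayesian_bootstrap_weights(n, rng) for _ in range(draws)])
        se_mean = w.std(axis=0, ddof=1) / np.sqrt(draws)
        assert np.all(np.abs(w.mean(axis=0) - 0.2) <= 3 * se_mean)
        centered_sq = (w - w.mean(axis=0)) ** 2
        se_var = centered_sq.std(axis=0, ddof=1) / np.sqrt(draws)
        assert np.all(np.abs(w.var(axis=0, ddof=1) - 0.2 * 0.8 / 6) <= 3 * se_var)


def _toy_sample(n=120, seed=0, event_rate=0.25):
    rng = np.random.default_rng(seed)
    import pandas as pd

    x = rng.normal(size=n)
    from scipy.special import expit, logit

    risk = expit(logit(event_rate) + 0.8 * x)
    y = rng.binomial(1, risk)
    return DevelopmentSample(pd.DataFrame({"x": x}), y)


class TestDrawCorrectRisks:
    def test_point_mass_posterior_returns_pi(self, small_sample, fitted_small):
        sample, _ = small_sample
        _, _, pi = fitted_small
        dev = point_mass_developer(pi)
        for seed in range(3):
            draw = draw_correct_risks(
                sample, dev, SamplingScheme.BAYESIAN_BOOTSTRAP,
                np.random.default_rng(seed),
            )
            assert np.array_equal(draw.risks, pi)

    @pytest.mark.parametrize("scheme", list(SamplingScheme))
    def test_output_contract_and_reproducibility(self, scheme):
        sample = _toy_sample()
        dev = LogisticDeveloper()
        a = draw_correct_risks(sample, dev, scheme, np.random.default_rng(42))
        b = draw_correct_risks(sample, dev, scheme, np.random.default_rng(42))
        assert a.risks.shape == (sample.n,)
        assert a.risks.min() >= 0.0 and a.risks.max() <= 1.0
        assert np.array_equal(a.risks, b.risks)

    def test_intercept_only_posterior_mean_is_event_rate(self):
        sample = _toy_sample(n=80, seed=1)
        dev = InterceptOnlyDeveloper()
        draws = np.array(
            [
                draw_correct_risks(
                    sample, dev, SamplingScheme.BAYESIAN_BOOTSTRAP, rng
                ).risks[0]
                for rng in spawn_generators(7, 2000)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - sample.outcomes.mean()) <= 3 * se

    def test_min_events_guard_fails_eventually(self):
        # one event in 40: a min_events=8 resample is impossible
        import pandas as pd

        y = np.zeros(40, int)
        y[0] = 1
        sample = DevelopmentSample(pd.DataFrame({"x": np.arange(40.0)}), y)
        with pytest.raises(DrawFailure):
            draw_correct_risks(
                sample,
                LogisticDeveloper(),
                SamplingScheme.ORDINARY_BOOTSTRAP,
                np.random.default_rng(0),
                min_events=8,
                max_redraws=5,
            )

    def test_ordinary_bootstrap_equals_resample_then_fit(self):
        sample = _toy_sample(n=200, seed=3)
        dev = LogisticDeveloper()
        rng = np.random.default_rng(17)
        counts = np.round(ordinary_bootstrap_weights(sample.n, rng) * sample.n)
        via_weights = dev.fit(sample, weights=counts / sample.n)
        rows = np.repeat(np.arange(sample.n), counts.astype(int))
        via_rows = dev.fit(sample.subsample(rows))
        np.testing.assert_allclose(
            via_weights.predict_risk(sample.covariates),
            via_rows.predict_risk(sample.covariates),
            atol=1e-6,
        )


class TestLikelihoodMVN:
    def test_draw_mean_and_sd_match_mle(self):
        sample = _toy_sample(n=400, seed=5)
        sampler = LikelihoodMVNSampler(sample)
        draws = np.array([sampler.draw(rng) for rng in spawn_generators(3, 5000)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - sampler.mle) <= 3 * se)
        reported = np.sqrt(np.diag(sampler.cov))
        assert np.all(np.abs(draws.std(axis=0, ddof=1) / reported - 1) < 0.05)

    def test_zero_covariance_limit_returns_mle(self):
        sample = _toy_sample(n=150, seed=6)
        sampler = LikelihoodMVNSampler(sample)
        sampler._chol = np.zeros_like(sampler._chol)
        assert np.array_equal(sampler.draw(np.random.default_rng(0)), sampler.mle)

    def test_failure_is_explicit_on_degenerate_fit(self):
        import pandas as pd

        from riskvoi import FitError

        # perfectly separated data: MLE does not exist
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(int)
        sample = DevelopmentSample(pd.DataFrame({"x": x}), y)
        with pytest.raises(FitError):
            LikelihoodMVNSampler(sample)


def test_substreams_are_order_independent():
    gens = spawn_generators(123, 5)
    third = gens[2].uniform(size=4)
    gens2 = spawn_generators(123, 5)
    gens2[0].uniform(size=10)  # consuming another stream changes nothing
    assert np.array_equal(gens2[2].uniform(size=4), third)
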
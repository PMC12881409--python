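"""AR1 likelihood, MCMC samplers and convergence diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nof1series import (
    GenParams,
    IdentifiabilityError,
    MCMCConfig,
    ParticipantSeries,
    PosteriorDraws,
    PRORecord,
    TrialSchedule,
    ar1_loglik,
    diagnose,
    fit_individual,
    fit_population,
    generate_cohort,
    generate_participant,
)

from conftest import recovery_params

REDUCED = MCMCConfig(burn_in=500, kept_iterations=1000, seed=0)


def dense_ar1_loglik(y, days, mu, rho, sigma):
    """Independent oracle: full stationary covariance + multivariate normal."""
    days = np.asarray(days, dtype=float)
    cov = sigma**2 / (1 - rho**2) * rho ** np.abs(days[:, None] - days[None, :])
    return stats.multivariate_normal(mean=mu, cov=cov, allow_singular=False).logpdf(y)


class TestAr1Loglik:
    def test_standard_normal_point(self):
        assert ar1_loglik([0.0], [1], [0.0], 0.0, 1.0) == pytest.approx(
            -0.9189385, abs=1e-6
        )

    def test_stationary_variance_inflation(self):
        # var = 1/(1-0.64) = 2.7778 => logpdf(0) = -0.5*log(2*pi*2.7778)
        assert ar1_loglik([0.0], [1], [0.0], 0.8, 1.0) == pytest.approx(
            -1.4298, abs=1e-4
        )

    def test_gappy_series_matches_dense_oracle(self):
        days = [1, 2, 5, 6, 9]
        y = [0.3, -1.2, 0.7, 0.1, 2.0]
        mu = [0.5, 0.5, -0.5, -0.5, 0.5]
        for rho in (-0.6, 0.0, 0.8):
            assert ar1_loglik(y, days, mu, rho, 1.3) == pytest.approx(
                dense_ar1_loglik(y, days, mu, rho, 1.3), abs=1e-8
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        rho=st.floats(-0.95, 0.95),
        sigma=st.floats(0.1, 5.0),
        n=st.integers(1, 12),
    )
    def test_property_equals_dense_oracle(self, seed, rho, sigma, n):
        rng = np.random.default_rng(seed)
        days = np.sort(rng.choice(np.arange(1, 40), size=n, replace=False))
        y = rng.normal(size=n)
        mu = rng.normal(size=n)
        assert ar1_loglik(y, days, mu, rho, sigma) == pytest.approx(
            dense_ar1_loglik(y, days, mu, rho, sigma), abs=1e-8
        )

    def test_nonstationary_rho_rejected(self):
        with pytest.raises(ValueError):
            ar1_loglik([0.0], [1], [0.0], 1.0, 1.0)


class TestFitIndividual:
    def test_noise_free_effect_recovered(self, schedule):
        params = recovery_params(
            baseline_mean=5.0, mean_effect=-1.5, innovation_sd=0.01, ar_coefficient=0.8
        )
        series = generate_participant(params, schedule, 42)
        draws = fit_individual(series, "stress_today", REDUCED)
        assert abs(draws.pooled("tau").mean() + 1.5) < 0.1

    def test_single_phase_not_identifiable(self, schedule):
        recs = [
            PRORecord("p", d, "A", stress_today=float(3 + d % 2))
            for d in range(1, 8)
        ]
        series = ParticipantSeries("p", schedule, recs)
        with pytest.raises(IdentifiabilityError, match="not identifiable"):
            fit_individual(series, "stress_today", REDUCED)

    def test_too_few_points_rejected(self, schedule):
        recs = [
            PRORecord("p", 1, "A", stress_today=3.0),
            PRORecord("p", 8, "B", stress_today=4.0),
        ]
        series = ParticipantSeries("p", schedule, recs)
        with pytest.raises(IdentifiabilityError, match=">= 4"):
            fit_individual(series, "stress_today", REDUCED)

    def test_rho_zero_matches_conjugate_ols_posterior(self, schedule):
        # With rho pinned at 0 and complete data, the marginal posterior of
        # (alpha, tau) is multivariate-t around the OLS fit.
        params = recovery_params(ar_coefficient=0.0, innovation_sd=2.0)
        series = generate_participant(params, schedule, 5)
        cfg = MCMCConfig(
            burn_in=500, kept_iterations=4000, seed=1, rho_grid=np.array([0.0])
        )
        draws = fit_individual(series, "stress_today", cfg)
        _, y, x = series.observed("stress_today")
        X = np.column_stack([np.ones_like(y), x])
        beta_hat, ssr = np.linalg.lstsq(X, y, rcond=None)[0], None
        resid = y - X @ beta_hat
        ssr = float(resid @ resid)
        n = len(y)
        # flat (alpha,tau) + Jeffreys sigma^2: marginal posterior of beta is
        # t_{n-2} with scale SSR/(n-2)*(X'X)^-1, hence var = SSR*(X'X)^-1/(n-4)
        cov_t = ssr * np.linalg.inv(X.T @ X) / (n - 4)
        tau = draws.pooled("tau")
        se_mc = tau.std() / np.sqrt(200)  # conservative ESS guess
        assert abs(tau.mean() - beta_hat[1]) < 4 * se_mc
        assert tau.std() == pytest.approx(np.sqrt(cov_t[1, 1]), rel=0.1)

    def test_label_symmetry_flips_effect_sign(self):
        params = recovery_params(mean_effect=-1.0, innovation_sd=1.0)
        a = generate_participant(params, TrialSchedule("ABAB"), 3)
        flipped = [
            PRORecord(
                r.participant_id, r.day_index,
                "A" if r.phase == "B" else "B",
                r.performed, r.stress_today, r.stress_next,
                check_range=False,
            )
            for r in a.records
        ]
        b = ParticipantSeries("p", TrialSchedule("BABA"), flipped)
        da = fit_individual(a, "stress_today", REDUCED)
        db = fit_individual(b, "stress_today", REDUCED)
        mc = 4 * da.pooled("tau").std() / np.sqrt(100)
        assert abs(da.pooled("tau").mean() + db.pooled("tau").mean()) < mc

    def test_draw_domains(self, schedule):
        series = generate_participant(recovery_params(), schedule, 11)
        draws = fit_individual(series, "stress_today", REDUCED)
        assert np.all(draws.pooled("sigma") > 0)
        assert np.all(np.abs(draws.pooled("rho")) < 1)
        assert np.all(np.isfinite(draws.pooled("tau")))


class TestFitPopulation:
    def test_single_participant_directed_to_individual(self):
        cohort = generate_cohort(GenParams(n_participants=1, seed=0))
        with pytest.raises(IdentifiabilityError, match="fit_individual"):
            fit_population(cohort, "stress_today", REDUCED)

    def test_homogeneous_cohort_matches_pooled_single_level_fit(self):
        # sigma_a = sigma_b = 0: every participant shares (alpha, tau), so
        # the hierarchical posterior for tau collapses onto the pooled fit.
        params = recovery_params(
            n_participants=6, baseline_sd_between=0.0, effect_sd_between=0.0,
            mean_effect=-1.0, innovation_sd=1.5, ar_coefficient=0.3, seed=21,
        )
        cohort = generate_cohort(params)
        pop = fit_population(cohort, "stress_today", REDUCED)
        # pooled single-level oracle: concatenate as one GLS problem via a
        # grand fit of each participant separately and precision-weighting
        taus, precisions = [], []
        for p in cohort:
            d = fit_individual(p, "stress_today", REDUCED)
            t = d.pooled("tau")
            taus.append(t.mean())
            precisions.append(1.0 / t.var())
        pooled_mean = np.average(taus, weights=precisions)
        pooled_se = 1.0 / np.sqrt(np.sum(precisions))
        assert abs(pop.pooled("tau").mean() - pooled_mean) < 3 * pooled_se

    def test_variance_draws_positive(self):
        cohort = generate_cohort(GenParams(n_participants=4, seed=2))
        pop = fit_population(cohort, "stress_today", REDUCED)
        for name in ("sigma", "sigma_a", "sigma_b"):
            assert np.all(pop.pooled(name) > 0)


class TestDiagnose:
    def test_well_mixed_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        draws = PosteriorDraws({"theta": rng.normal(size=(2, 5000))})
        report = diagnose(draws)
        assert 1.0 <= report.rhat["theta"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        report = diagnose(PosteriorDraws({"theta": arr}))
        assert report.rhat["theta"] > 1.5

    def test_constant_chain_reported_undefined(self):
        arr = np.zeros((2, 500))
        report = diagnose(PosteriorDraws({"theta": arr}))
        assert "theta" in report.undefined

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            diagnose(PosteriorDraws({"theta": np.zeros((1, 50))}))
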
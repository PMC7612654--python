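"""Latent-model maximum likelihood: closed-form special cases, parameter
recovery and latent-scale test statistics."""

import numpy as np
import pytest
from scipy import stats

from mixedpower import (
    EndpointSpec,
    OutcomeSpec,
    TrialData,
    fit_latent_model,
    latent_test_statistics,
    simulate_trial,
)
from mixedpower.estimation import (
    IdentifiabilityError,
    _free_to_natural,
    _make_loglik,
    _natural_to_free,
    _starting_values,
    _Structure,
)


@pytest.fixture(scope="module")
def binary_spec():
    return EndpointSpec(
        outcomes=(OutcomeSpec(kind="binary", prob_T=0.54, prob_C=0.38),),
        corr=np.eye(1),
    )


@pytest.fixture(scope="module")
def mixed_spec():
    return EndpointSpec(
        outcomes=(
            OutcomeSpec(kind="continuous", effect_obs=0.5, sd=2.0),
            OutcomeSpec(kind="binary", prob_T=0.6, prob_C=0.4),
        ),
        corr=np.array([[1.0, 0.5], [0.5, 1.0]]),
    )


class TestClosedFormCases:
    def test_binary_only_probit_closed_form(self, binary_spec):
        data = simulate_trial(binary_spec, 500, seed=11)
        fit = fit_latent_model(data, binary_spec)
        p_T = data.y[data.arm == 1, 0].mean()
        p_C = data.y[data.arm == 0, 0].mean()
        assert fit.mu_star("T")[0] == pytest.approx(stats.norm.ppf(p_T),
                                                    abs=1e-4)
        assert fit.mu_star("C")[0] == pytest.approx(stats.norm.ppf(p_C),
                                                    abs=1e-4)

    def test_binary_only_fisher_se_closed_form(self, binary_spec):
        data = simulate_trial(binary_spec, 500, seed=11)
        fit = fit_latent_model(data, binary_spec)
        p_T = data.y[data.arm == 1, 0].mean()
        se_closed = np.sqrt(
            p_T * (1 - p_T)
            / (500 * stats.norm.pdf(stats.norm.ppf(p_T)) ** 2)
        )
        assert np.sqrt(fit.cov[0, 0]) == pytest.approx(se_closed, rel=0.01)

    def test_continuous_only_moments(self):
        spec = EndpointSpec(
            outcomes=(OutcomeSpec(kind="continuous", effect_obs=1.0,
                                  sd=3.0),),
            corr=np.eye(1),
        )
        data = simulate_trial(spec, 200, seed=4)
        fit = fit_latent_model(data, spec, compute_cov=False)
        y_T = data.y[data.arm == 1, 0]
        y_C = data.y[data.arm == 0, 0]
        assert fit.mu_star("T")[0] == pytest.approx(y_T.mean(), abs=1e-5)
        assert fit.mu_star("C")[0] == pytest.approx(y_C.mean(), abs=1e-5)
        # Gaussian ML variance: pooled around arm means, 1/n normalisation
        s2_ml = (np.sum((y_T - y_T.mean()) ** 2)
                 + np.sum((y_C - y_C.mean()) ** 2)) / data.y.shape[0]
        assert fit.sds()[0] ** 2 == pytest.approx(s2_ml, rel=1e-3)


class TestFitBehaviour:
    def test_unobserved_level_raises_identifiability(self, binary_spec):
        data = simulate_trial(binary_spec, 50, seed=2)
        y = data.y.copy()
        y[data.arm == 1, 0] = 1.0  # treatment arm all responders
        with pytest.raises(IdentifiabilityError, match="treatment"):
            fit_latent_model(TrialData(arm=data.arm, y=y), binary_spec)

    def test_too_few_patients_rejected(self, binary_spec):
        data = simulate_trial(binary_spec, 5, seed=2)
        with pytest.raises(ValueError, match="10 patients"):
            fit_latent_model(data, binary_spec)

    def test_jittered_starts_agree_in_loglik(self, mixed_spec, rng):
        data = simulate_trial(mixed_spec, 300, seed=9)
        fit = fit_latent_model(data, mixed_spec, compute_cov=False)
        structure = _Structure(fit.kinds, fit.n_levels)
        loglik = _make_loglik(structure, data)
        from scipy import optimize

        x_star = _natural_to_free(structure, fit.values)
        for _ in range(5):
            x0 = x_star + rng.normal(scale=0.25, size=x_star.size)
            res = optimize.minimize(
                lambda x: -loglik(_free_to_natural(structure, x)),
                x0,
                method="L-BFGS-B",
                options={"ftol": 1e-11},
            )
            assert -res.fun == pytest.approx(fit.loglik, abs=1e-4)

    def test_csv_round_trip_and_missing_rows(self, tmp_path, mixed_spec):
        data = simulate_trial(mixed_spec, 30, seed=1)
        path = tmp_path / "pilot.csv"
        data.to_csv(path)
        again = TrialData.from_csv(path)
        assert np.allclose(again.y, data.y)
        # a row with a missing outcome is dropped with a log record
        txt = path.read_text().splitlines()
        txt[1] = txt[1].rsplit(",", 1)[0] + ","
        path.write_text("\n".join(txt) + "\n")
        trimmed = TrialData.from_csv(path)
        assert trimmed.y.shape[0] == data.y.shape[0] - 1

    def test_parameter_recovery_mixed_model(self, mixed_spec):
        """Estimates fall within 3 reported SEs of the generating values
        for nearly all replicates."""
        truth = {
            "mu_T[1]": 0.5,
            "mu_C[1]": 0.0,
            "mu_T[2]": stats.norm.ppf(0.6),
            "mu_C[2]": stats.norm.ppf(0.4),
            "sigma[1]": 2.0,
            "rho[1,2]": 0.5,
        }
        hits = 0
        reps = 50  # the full 200-replicate run lives in the acceptance suite
        for rep in range(reps):
            data = simulate_trial(mixed_spec, 400, seed=5_000 + rep)
            fit = fit_latent_model(data, mixed_spec)
            se = np.sqrt(np.diag(fit.cov))
            ok = all(
                abs(fit.theta[name] - truth[name]) <= 3 * se[i]
                for i, name in enumerate(fit.names)
            )
            hits += ok
        assert hits / reps >= 0.90


class TestLatentTestStatistics:
    def test_zero_for_identical_arms(self, binary_spec):
        data = simulate_trial(binary_spec, 200, seed=3)
        fit = fit_latent_model(data, binary_spec, compute_cov=False)
        flat = fit.with_theta(np.array([0.2, 0.2]))
        z = latent_test_statistics(flat)
        assert z[0] == pytest.approx(0.0, abs=1e-12)

    def test_continuous_matches_classical_two_sample_z(self):
        spec = EndpointSpec(
            outcomes=(OutcomeSpec(kind="continuous", effect_obs=0.4,
                                  sd=1.5),),
            corr=np.eye(1),
        )
        data = simulate_trial(spec, 150, seed=8)
        z = latent_test_statistics(data, sigmas=[1.5])
        y_T = data.y[data.arm == 1, 0]
        y_C = data.y[data.arm == 0, 0]
        classical = (y_T.mean() - y_C.mean()) / (1.5 * np.sqrt(2 / 150))
        assert z[0] == pytest.approx(classical, rel=1e-12)

    def test_model_mode_requires_covariance(self, binary_spec):
        data = simulate_trial(binary_spec, 100, seed=3)
        fit = fit_latent_model(data, binary_spec, compute_cov=False)
        with pytest.raises(ValueError, match="Cov"):
            latent_test_statistics(fit, variance_mode="model")

    def test_model_mode_close_to_nominal_for_binary(self, binary_spec):
        data = simulate_trial(binary_spec, 400, seed=13)
        fit = fit_latent_model(data, binary_spec)
        z_nom = latent_test_statistics(fit, "nominal")
        z_mod = latent_test_statistics(fit, "model")
        # probit information differs from the nominal unit-variance scaling,
        # but the two should agree to leading order
        assert z_mod[0] == pytest.approx(z_nom[0], rel=0.25)

    def test_null_rejection_rate_close_to_alpha(self):
        """One-sided latent z test keeps its nominal 2.5% size."""
        null_spec = EndpointSpec(
            outcomes=(OutcomeSpec(kind="binary", prob_T=0.4, prob_C=0.4),),
            corr=np.eye(1),
        )
        from mixedpower import SimulationPlan, empirical_power

        plan = SimulationPlan(
            spec=null_spec,
            n_per_group=200,
            reps=10_000,
            seed=42,
            endpoint_type="coprimary",
            alpha=0.025,
        )
        r = empirical_power(plan)
        assert abs(r.estimate - 0.025) <= 3 * np.sqrt(0.025 * 0.975 / 10_000)
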
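"""The latent-mass hierarchical model: joint density, sampler, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from matalloc import (AllocationModel, McmcSettings, ModelSpec, PriorSpec,
                      ReferenceProfile, build_standardization, log_joint,
                      predict_reference)
from matalloc.design import StandardizationTable
from matalloc.model import PosteriorDraws, prepare_model_data


def make_draws(beta_draws, labels, std, response="proportion"):
    """Assemble a PosteriorDraws object from externally supplied coefficient
    draws (single chain, degenerate everything else)."""
    beta = np.asarray(beta_draws, dtype=float)[None]
    s = beta.shape[1]
    spec = ModelSpec(response=response, age_form="null",
                     covariates=("maternal_mass", "measurement_days")
                     if response == "proportion" else None)
    return PosteriorDraws(
        spec=spec, labels=list(labels), beta=beta,
        sigma_resid=np.full((1, s), 0.1), sigma_year=np.zeros((1, s)),
        sigma_ind=np.zeros((1, s)), u_year=np.zeros((1, s, 1)),
        u_ind=np.zeros((1, s, 1)), m1=np.full((1, s, 1), 450.0),
        mu_mass=np.full((1, s), 450.0), sigma_mass=np.full((1, s), 55.0),
        z=None,
        year_levels=np.array([2002]), ind_levels=np.array(["M0"]),
        standardization=std)


@pytest.fixture(scope="module")
def simple_std():
    return StandardizationTable(
        centers={"maternal_mass": 450.0, "measurement_days": 33.0,
                 "age": 17.0, "afr": 8.0, "birthdate": 27.0,
                 "pup_birth_mass": 29.0, "ln_age": np.log(17.0)},
        scales={"maternal_mass": 110.0, "measurement_days": 4.0,
                "age": 12.0, "afr": 4.0, "birthdate": 14.0,
                "pup_birth_mass": 10.0, "ln_age": 0.8})


class TestLogJoint:
    def _model(self, small_colony, response="weaning"):
        _, obs, _ = small_colony
        spec = ModelSpec(response=response, age_form="linear")
        return AllocationModel(obs, spec)

    def _state(self, model, rng):
        d = model.data
        state = {"beta": np.zeros(len(d.labels)), "sigma_resid": 1.0,
                 "u_year": np.zeros(len(d.year_levels)),
                 "u_ind": np.zeros(len(d.ind_levels)),
                 "sigma_year": 0.5, "sigma_ind": 0.5,
                 "mu_mass": 450.0, "sigma_mass": 60.0,
                 "m1": np.clip(d.m1, *d.priors.latent_mass_range)}
        if d.spec.response != "weaning":
            state["z"] = d.z_init.copy()
        return state

    def test_out_of_bounds_parameters_give_minus_inf(self, small_colony, rng):
        model = self._model(small_colony)
        state = self._state(model, rng)
        assert np.isfinite(log_joint(model.data, state))
        bad = dict(state, sigma_resid=-1.0)
        assert log_joint(model.data, bad) == -np.inf
        bad = dict(state, beta=state["beta"] + 100.0)
        assert log_joint(model.data, bad) == -np.inf
        bad = dict(state, m1=np.full_like(state["m1"], 50.0))
        assert log_joint(model.data, bad) == -np.inf

    def test_five_observation_weaning_fixture_matches_hand_sum(self):
        # independent oracle: sum the individual normal log-densities with
        # scipy.stats on a tiny hand-built dataset
        obs = pd.DataFrame({
            "obs_id": [f"o{i}" for i in range(5)],
            "mother_id": ["A", "B", "C", "D", "E"],
            "year": [2002, 2002, 2003, 2003, 2004],
            "maternal_age": [8, 12, 16, 20, 24],
            "afr": [6, 7, 8, 9, 10],
            "status_prev": ["experienced_bred"] * 5,
            "birthdate": [20, 24, 27, 30, 34],
            "pup_sex": ["F", "M", "F", "M", "F"],
            "maternal_mass_birth": [380.0, 420.0, 450.0, 480.0, 520.0],
            "maternal_se_birth": [15.0] * 5,
            "pup_mass_birth": [24.0, 27.0, 29.0, 31.0, 34.0],
            "pup_mass_late": [80.0, 95.0, 100.0, 105.0, 118.0],
        })
        spec = ModelSpec(response="weaning", age_form="null")
        data = prepare_model_data(obs, spec)
        latent = np.array([390.0, 410.0, 455.0, 470.0, 525.0])
        beta = np.full(len(data.labels), 0.5)
        beta[0] = 99.0
        u_year = np.array([1.0, -0.5, 0.25])
        u_ind = np.array([0.1, -0.1, 0.2, -0.2, 0.0])
        state = {"beta": beta, "sigma_resid": 11.0, "sigma_year": 2.0,
                 "sigma_ind": 1.0, "u_year": u_year, "u_ind": u_ind,
                 "m1": latent, "mu_mass": 440.0, "sigma_mass": 58.0}
        x = data.x.copy()
        x[:, data.mass_col] = (latent - data.mass_center) / data.mass_scale
        mu = x @ beta + u_year[data.year_idx] + u_ind[data.ind_idx]
        expected = (stats.norm.logpdf(latent, 440.0, 58.0).sum()
                    + stats.norm.logpdf(obs["maternal_mass_birth"], latent, 15.0).sum()
                    + stats.norm.logpdf(obs["pup_mass_late"], mu, 11.0).sum()
                    + stats.norm.logpdf(u_year, 0, 2.0).sum()
                    + stats.norm.logpdf(u_ind, 0, 1.0).sum())
        assert log_joint(data, state) == pytest.approx(expected, rel=1e-12)

    def test_finite_at_generator_truth(self, small_colony):
        # the generator and fitter share one design builder, so the truth
        # is inside the model's support with finite density
        config, obs, truth = small_colony
        spec = ModelSpec(response="proportion", age_form="quadratic",
                         include_birthdate_quadratic=True)
        model = AllocationModel(obs, spec,
                                standardization=truth.standardization)
        d = model.data
        t = truth.observations.set_index("obs_id").loc[
            d.observations["obs_id"]]
        coeffs = config.true_coefficients["proportion"]
        beta = np.array([coeffs.get(lab, 0.0) for lab in d.labels])
        state = {
            "beta": beta,
            "sigma_resid": config.sigma_residual["proportion"],
            "sigma_year": config.sigma_year["proportion"],
            "sigma_ind": config.sigma_individual["proportion"],
            "u_year": truth.year_effects.set_index("year").loc[
                d.year_levels, "u_proportion"].to_numpy(),
            "u_ind": truth.mothers.set_index("mother_id").loc[
                d.ind_levels, "u_proportion"].to_numpy(),
            "m1": t["true_mass_birth"].to_numpy(),
            "mu_mass": config.mass_mean, "sigma_mass": config.mass_sd,
            "z": logit(t["true_proportion"].to_numpy()),
        }
        assert np.isfinite(log_joint(model.data, state))


class TestFitModel:
    def test_conjugate_subcase_matches_closed_form(self):
        # error-free masses, no random effects, known residual SD: the
        # coefficient posterior is the textbook normal linear-model posterior
        from matalloc import SimulationConfig, generate_colony
        config = SimulationConfig(seed=11, n_mothers=40, n_years=5,
                                  photo_error_sd=0.0)
        obs, _ = generate_colony(config)
        spec = ModelSpec(response="weaning", age_form="linear",
                         random_effects=())
        model = AllocationModel(obs, spec)
        sigma = 12.0
        draws = model.fit(McmcSettings(n_chains=2, n_iter=4000, n_burn=200,
                                       seed=3),
                          fixed={"sigma_resid": sigma},
                          check_convergence=False)
        x, y = model.data.x, model.data.y
        mean_cf = np.linalg.solve(x.T @ x, x.T @ y)
        sd_cf = sigma * np.sqrt(np.diag(np.linalg.inv(x.T @ x)))
        beta = draws.flat("beta")
        mc_se = sd_cf / np.sqrt(len(beta) / 20)  # generous ESS discount
        np.testing.assert_array_less(np.abs(beta.mean(0) - mean_cf), 4 * mc_se)
        np.testing.assert_allclose(beta.std(0), sd_cf, rtol=0.10)

    def test_same_seed_reproduces_draws(self, small_colony):
        _, obs, _ = small_colony
        spec = ModelSpec(response="proportion", age_form="null")
        mcmc = McmcSettings(n_chains=2, n_iter=150, n_burn=80, seed=21)
        a = AllocationModel(obs, spec).fit(mcmc, check_convergence=False)
        b = AllocationModel(obs, spec).fit(mcmc, check_convergence=False)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.m1, b.m1)

    def test_covariate_shift_only_moves_intercept(self, small_colony):
        # standardization re-centers, so shifting age by a constant leaves
        # every non-intercept coefficient posterior unchanged
        _, obs, _ = small_colony
        spec = ModelSpec(response="weaning", age_form="linear")
        mcmc = McmcSettings(n_chains=1, n_iter=300, n_burn=150, seed=4)
        a = AllocationModel(obs, spec).fit(mcmc, check_convergence=False)
        shifted = obs.copy()
        shifted["maternal_age"] = shifted["maternal_age"] + 7
        b = AllocationModel(shifted, spec).fit(mcmc, check_convergence=False)
        ia = a.labels.index("age")
        np.testing.assert_allclose(a.flat("beta")[:, ia],
                                   b.flat("beta")[:, ia], rtol=1e-9)

    def test_zero_variance_random_effects_match_fixed_only_fit(
            self, small_colony):
        _, obs, _ = small_colony
        mcmc = McmcSettings(n_chains=1, n_iter=600, n_burn=300, seed=8)
        hier = AllocationModel(
            obs, ModelSpec(response="weaning", age_form="null")).fit(
                mcmc, fixed={"sigma_year": 0.0, "sigma_ind": 0.0},
                check_convergence=False)
        flat = AllocationModel(
            obs, ModelSpec(response="weaning", age_form="null",
                           random_effects=())).fit(
                mcmc, check_convergence=False)
        assert np.all(hier.flat("u_year") == 0)
        ba, bb = hier.flat("beta"), flat.flat("beta")
        se = bb.std(0) / 3  # Monte-Carlo tolerance
        np.testing.assert_array_less(np.abs(ba.mean(0) - bb.mean(0)), 4 * se)

    def test_latent_masses_shrink_toward_truth(self, small_colony):
        # posterior-mean latent parturition masses should usually sit
        # closer to the true masses than the raw error-laden estimates
        _, obs, truth = small_colony
        spec = ModelSpec(response="proportion", age_form="null")
        model = AllocationModel(obs, spec)
        draws = model.fit(McmcSettings(n_chains=1, n_iter=600, n_burn=300,
                                       seed=2), check_convergence=False)
        d = model.data
        t = truth.observations.set_index("obs_id").loc[
            d.observations["obs_id"], "true_mass_birth"].to_numpy()
        post = draws.flat("m1").mean(0)
        improved = np.abs(post - t) < np.abs(d.m1 - t)
        assert improved.mean() > 0.5


class TestPredictReference:
    def test_intercept_only_prediction_is_inverse_logit(self, simple_std):
        labels = ["intercept", "maternal_mass", "measurement_days"]
        c = logit(0.37)
        beta = np.column_stack([np.full(50, c), np.zeros(50), np.zeros(50)])
        draws = make_draws(beta, labels, simple_std)
        summ = predict_reference(draws, draws.spec, simple_std)
        np.testing.assert_allclose(summ.draws, 0.37, rtol=1e-12)
        assert summ.mean == pytest.approx(0.37)

    def test_kg_allocated_is_drawwise_product(self, simple_std):
        labels = ["intercept", "maternal_mass", "measurement_days"]
        rng = np.random.default_rng(5)
        beta = np.column_stack([rng.normal(logit(0.342), 0.05, 400),
                                np.zeros(400), np.zeros(400)])
        draws = make_draws(beta, labels, simple_std)
        prop = predict_reference(draws, draws.spec, simple_std,
                                 ReferenceProfile(maternal_mass=450.0))
        kg = predict_reference(draws, draws.spec, simple_std,
                               ReferenceProfile(maternal_mass=450.0),
                               quantity="kg_allocated")
        np.testing.assert_allclose(kg.draws, prop.draws * 450.0, rtol=1e-12)

    def test_jensen_gap_for_skewed_linear_predictor(self, simple_std):
        labels = ["intercept", "maternal_mass", "measurement_days"]
        rng = np.random.default_rng(9)
        lp = logit(0.2) + rng.exponential(1.5, 2000)  # right-skewed
        beta = np.column_stack([lp, np.zeros(2000), np.zeros(2000)])
        draws = make_draws(beta, labels, simple_std)
        summ = predict_reference(draws, draws.spec, simple_std)
        assert summ.mean != pytest.approx(float(expit(lp.mean())), abs=1e-3)

    def test_out_of_range_profile_warns_not_raises(self, simple_std, caplog):
        labels = ["intercept", "maternal_mass", "measurement_days"]
        draws = make_draws(np.zeros((30, 3)), labels, simple_std)
        with caplog.at_level("WARNING"):
            predict_reference(draws, draws.spec, simple_std,
                              ReferenceProfile(maternal_mass=5000.0))
        assert any("outside" in r.message for r in caplog.records)
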
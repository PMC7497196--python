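"""Hierarchical Bayesian allocation models with latent true maternal masses.

The three suites share one structure.  For observation i with year j(i) and
mother k(i):

* photogrammetric estimates are noisy readings of latent true masses:
  ``m_occ,i ~ Normal(M_occ,i, se_occ,i)``;
* the latent response — logit of the latent proportion or transfer
  efficiency, or pup weaning mass in kg — is normal around a linear
  predictor: ``resp_i ~ Normal(x_i' beta + u_year[j] + u_ind[k],
  sigma_resid^2)``, where the maternal-mass covariate inside x_i is the
  standardized *latent* parturition mass;
* random effects are zero-mean normal with SDs sigma_year, sigma_ind;
* priors are uniform (see :class:`~matalloc.config.PriorSpec`).

Latents are parametrized as (true parturition mass M1, latent logit
response z); the second occasion's true mass is derived, so the latent
proportion/efficiency lies in (0, 1) by construction and the logit is
never evaluated out of range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import diagnostics
from .config import (ConfigurationError, McmcSettings, ModelSpec, PriorSpec,
                     ReferenceProfile)
from .design import (StandardizationTable, build_design,
                     build_standardization, profile_row,
                     response_efficiency, response_proportion)
from .sampler import GibbsSampler, _norm_logpdf

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data preparation

@dataclass
class ModelData:
    """Everything the sampler needs, extracted from an observation table."""

    spec: ModelSpec
    priors: PriorSpec
    observations: pd.DataFrame
    x: np.ndarray
    labels: list
    beta_bounds: np.ndarray
    mass_col: int
    mass_center: float
    mass_scale: float
    year_idx: np.ndarray
    year_levels: np.ndarray
    ind_idx: np.ndarray
    ind_levels: np.ndarray
    m1: np.ndarray
    se1: np.ndarray
    m2: np.ndarray | None
    se2: np.ndarray | None
    y: np.ndarray | None
    pup_gain: np.ndarray | None
    z_init: np.ndarray | None
    standardization: StandardizationTable = None
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def use_year(self) -> bool:
        return "year" in self.spec.random_effects

    @property
    def use_ind(self) -> bool:
        return "individual" in self.spec.random_effects


def eligible_mask(obs: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Rows with every occasion/covariate the response requires."""
    def ok(col):
        return obs[col].notna().to_numpy() if col in obs.columns \
            else np.zeros(len(obs), dtype=bool)

    mask = (ok("maternal_age") & ok("afr") & ok("status_prev") & ok("pup_sex")
            & ok("maternal_mass_birth"))
    if spec.include_birthdate_quadratic:
        mask &= ok("birthdate")
    if spec.response == "proportion":
        mask &= ok("maternal_mass_late") & ok("day_birth") & ok("day_late")
    elif spec.response == "efficiency":
        mask &= (ok("maternal_mass_mid") & ok("pup_mass_birth")
                 & ok("pup_mass_mid") & ok("day_birth") & ok("day_mid"))
        with np.errstate(invalid="ignore"):
            gain = (obs.get("pup_mass_mid", np.nan)
                    - obs.get("pup_mass_birth", np.nan)).to_numpy(dtype=float)
        mask &= np.nan_to_num(gain, nan=-1.0) > 0
    else:
        mask &= ok("pup_mass_late") & ok("pup_mass_birth")
    return mask


def prepare_model_data(obs: pd.DataFrame, spec: ModelSpec,
                       priors: PriorSpec | None = None,
                       standardization: StandardizationTable | None = None
                       ) -> ModelData:
    priors = priors if priors is not None else PriorSpec.for_response(spec.response)
    mask = eligible_mask(obs, spec)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d observation(s) ineligible for the %s suite",
                    n_dropped, spec.response)
    data = obs.loc[mask].reset_index(drop=True)
    if len(data) == 0:
        raise ConfigurationError(f"no eligible observations for {spec.response}")
    if standardization is None:
        standardization = build_standardization(data)
    x, labels = build_design(data, spec, standardization)
    beta_bounds = np.array([priors.intercept_bound if lab == "intercept"
                            else priors.beta_bound for lab in labels])
    mass_col = labels.index("maternal_mass")
    year_levels, year_idx = np.unique(data["year"].to_numpy(), return_inverse=True)
    ind_levels, ind_idx = np.unique(data["mother_id"].to_numpy(), return_inverse=True)

    def col(name, default=None):
        if name in data.columns:
            return data[name].to_numpy(dtype=float)
        return default

    m1 = col("maternal_mass_birth")
    se1 = col("maternal_se_birth", np.zeros(len(data)))
    m2 = se2 = y = pup_gain = z_init = None
    if spec.response == "proportion":
        m2 = col("maternal_mass_late")
        se2 = col("maternal_se_late", np.zeros(len(data)))
        raw = response_proportion(m1, m2)
        z_init = logit(np.clip(raw, 0.02, 0.98))
    elif spec.response == "efficiency":
        m2 = col("maternal_mass_mid")
        se2 = col("maternal_se_mid", np.zeros(len(data)))
        pup_gain = col("pup_mass_mid") - col("pup_mass_birth")
        raw = response_efficiency(col("pup_mass_birth"), col("pup_mass_mid"),
                                  m1, m2, col("day_birth"), col("day_mid"))
        # keep the implied latent mid-lactation mass positive at the start:
        # efficiency below gain / (0.8 * M1) would put M2 below 0.2 * M1
        low = np.minimum(0.9, pup_gain / (0.8 * m1))
        z_init = logit(np.clip(np.nan_to_num(raw, nan=0.5),
                               np.maximum(0.05, low), 0.95))
    else:
        y = col("pup_mass_late")

    md = ModelData(spec=spec, priors=priors, observations=data, x=x,
                   labels=labels, beta_bounds=beta_bounds, mass_col=mass_col,
                   mass_center=standardization.center("maternal_mass"),
                   mass_scale=standardization.scales["maternal_mass"],
                   year_idx=year_idx, year_levels=year_levels,
                   ind_idx=ind_idx, ind_levels=ind_levels,
                   m1=m1, se1=se1, m2=m2, se2=se2, y=y, pup_gain=pup_gain,
                   z_init=z_init, standardization=standardization,
                   n_dropped=n_dropped)

    # fully pinned latent responses require raw values inside (0, 1)
    if spec.response in ("proportion", "efficiency"):
        pinned = (se1 == 0) & (se2 == 0)
        if pinned.any():
            if spec.response == "proportion":
                raw = response_proportion(m1, m2)
            else:
                raw = pup_gain / (m1 - m2)
            bad = pinned & ~((raw > 0) & (raw < 1))
            if bad.any():
                logger.warning(
                    "dropping %d error-free observation(s) with raw %s "
                    "outside (0, 1)", int(bad.sum()), spec.response)
                return prepare_model_data(data.loc[~bad], spec, priors,
                                          standardization)
            md.z_init[pinned] = logit(raw[pinned])
    return md


# ---------------------------------------------------------------------------
# joint density (reference target for the sampler; used directly in tests)

def log_joint(data: ModelData, state: dict) -> float:
    """Log joint density of parameters, latents and data.

    ``state`` holds the coefficient vector, variance components, random
    effects, the latent parturition masses ``m1`` with their population
    layer ``(mu_mass, sigma_mass)``, and (for the logit suites) the latent
    logit responses ``z``.  Returns ``-inf`` outside the uniform prior
    bounds or where latent masses imply a proportion/efficiency outside
    (0, 1) (derived mid-lactation mass non-positive).
    """
    p = data.priors
    beta = np.asarray(state["beta"], dtype=float)
    if np.any(np.abs(beta) > data.beta_bounds):
        return -np.inf
    sig_r = float(state["sigma_resid"])
    if not 0 < sig_r <= p.sigma_bound:
        return -np.inf
    m1 = np.asarray(state["m1"], dtype=float)
    lo, hi = p.latent_mass_range
    if np.any((m1 < lo) | (m1 > hi)):
        return -np.inf
    mu_mass = float(state["mu_mass"])
    sigma_mass = float(state["sigma_mass"])
    if not (lo <= mu_mass <= hi and 0 < sigma_mass <= p.latent_mass_sd_bound):
        return -np.inf

    total = float(np.sum(_norm_logpdf(m1, mu_mass, sigma_mass)))
    # observation terms (se = 0 pins the latent to the observed value)
    free1 = data.se1 > 0
    if np.any(~free1 & (np.abs(m1 - data.m1) > 1e-8)):
        return -np.inf
    total += float(np.sum(_norm_logpdf(data.m1[free1], m1[free1], data.se1[free1])))

    x_eff = data.x.copy()
    x_eff[:, data.mass_col] = (m1 - data.mass_center) / data.mass_scale
    mu = x_eff @ beta
    mu += np.asarray(state["u_year"])[data.year_idx]
    mu += np.asarray(state["u_ind"])[data.ind_idx]

    if data.spec.response in ("proportion", "efficiency"):
        z = np.asarray(state["z"], dtype=float)
        if data.spec.response == "proportion":
            second = m1 * (1.0 - expit(z))
        else:
            with np.errstate(over="ignore"):
                second = m1 - data.pup_gain / expit(z)
        if np.any(second <= 0):
            return -np.inf
        free2 = data.se2 > 0
        if np.any(~free2 & (np.abs(second - data.m2) > 1e-6)):
            return -np.inf
        total += float(np.sum(_norm_logpdf(data.m2[free2], second[free2],
                                           data.se2[free2])))
        total += float(np.sum(_norm_logpdf(z, mu, sig_r)))
    else:
        total += float(np.sum(_norm_logpdf(data.y, mu, sig_r)))

    for which, use in (("year", data.use_year), ("ind", data.use_ind)):
        if not use:
            continue
        sig = float(state[f"sigma_{which}"])
        if not 0 <= sig <= p.sigma_bound:
            return -np.inf
        u = np.asarray(state[f"u_{which}"], dtype=float)
        if sig == 0:
            if np.any(u != 0):
                return -np.inf
        else:
            total += float(np.sum(_norm_logpdf(u, 0.0, sig)))
    return total


# ---------------------------------------------------------------------------
# posterior draws container

@dataclass
class PosteriorDraws:
    """Labelled MCMC draws, shape (n_chains, n_draws, ...)."""

    spec: ModelSpec
    labels: list
    beta: np.ndarray
    sigma_resid: np.ndarray
    sigma_year: np.ndarray
    sigma_ind: np.ndarray
    u_year: np.ndarray
    u_ind: np.ndarray
    m1: np.ndarray
    mu_mass: np.ndarray
    sigma_mass: np.ndarray
    z: np.ndarray | None
    year_levels: np.ndarray
    ind_levels: np.ndarray
    standardization: StandardizationTable
    final_states: list = field(default_factory=list)
    psrf: pd.DataFrame | None = None
    geweke_z: dict | None = None
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws with the chain dimension collapsed."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def beta_column(self, label: str) -> np.ndarray:
        return self.flat("beta")[:, self.labels.index(label)]

    def coefficient_table(self, mass: float = 0.90) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.labels):
            draws = self.flat("beta")[:, i]
            interval = diagnostics.hdi(draws, mass=mass)
            rows.append({"term": lab, "mean": float(draws.mean()),
                         "sd": float(draws.std(ddof=1)),
                         "hdi_lower": interval.lower,
                         "hdi_upper": interval.upper,
                         "excludes_zero": not (interval.lower <= 0 <= interval.upper)})
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        """Serialize draws (chain/draw indexed) to an .npz container."""
        np.savez_compressed(
            path, beta=self.beta, sigma_resid=self.sigma_resid,
            sigma_year=self.sigma_year, sigma_ind=self.sigma_ind,
            u_year=self.u_year, u_ind=self.u_ind, m1=self.m1,
            mu_mass=self.mu_mass, sigma_mass=self.sigma_mass,
            z=self.z if self.z is not None else np.empty(0),
            labels=np.array(self.labels, dtype=str),
            year_levels=np.asarray(self.year_levels, dtype=str),
            ind_levels=np.asarray(self.ind_levels, dtype=str))


# ---------------------------------------------------------------------------
# the model facade

class AllocationModel:
    """One response suite bound to an observation table.

    Provides fitting, leave-one-out refits and held-out predictive
    densities (the protocol :mod:`matalloc.selection` scores), reference
    prediction and goodness of fit.
    """

    def __init__(self, observations: pd.DataFrame, spec: ModelSpec,
                 priors: PriorSpec | None = None,
                 standardization: StandardizationTable | None = None):
        self.spec = spec
        self.data = prepare_model_data(observations, spec, priors,
                                       standardization)
        self.priors = self.data.priors

    @property
    def n_units(self) -> int:
        return self.data.n

    # -- fitting ----------------------------------------------------------
    def fit(self, mcmc: McmcSettings, fixed: dict | None = None,
            check_convergence: bool = True) -> PosteriorDraws:
        """Run ``mcmc.n_chains`` independent chains and pool the draws.

        Convergence is assessed with the Gelman-Rubin PSRF (coefficients
        and SDs) and the Geweke diagnostic; non-converged draws are
        returned flagged, not discarded.
        """
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        stores, finals = [], []
        for c in range(mcmc.n_chains):
            rng = np.random.default_rng(seeds[c])
            sampler = GibbsSampler(self.data, rng, fixed=fixed)
            store, final = sampler.run(mcmc.iter_effective, mcmc.burn_effective,
                                       thin=mcmc.thin,
                                       jitter=0.05 * c)
            stores.append(store)
            finals.append(final)
        n_keep = min(len(s["beta"]) for s in stores)

        def stack(key):
            return np.stack([s[key][:n_keep] for s in stores])

        draws = PosteriorDraws(
            spec=self.spec, labels=list(self.data.labels),
            beta=stack("beta"), sigma_resid=stack("sigma_resid"),
            sigma_year=stack("sigma_year"), sigma_ind=stack("sigma_ind"),
            u_year=stack("u_year"), u_ind=stack("u_ind"), m1=stack("m1"),
            mu_mass=stack("mu_mass"), sigma_mass=stack("sigma_mass"),
            z=stack("z") if "z" in stores[0] else None,
            year_levels=self.data.year_levels, ind_levels=self.data.ind_levels,
            standardization=self.data.standardization, final_states=finals)
        if check_convergence and mcmc.n_chains >= 2 and n_keep >= 10:
            self._attach_diagnostics(draws)
        return draws

    def _attach_diagnostics(self, draws: PosteriorDraws,
                            psrf_threshold: float = 1.1) -> None:
        monitored = {f"beta[{lab}]": draws.beta[:, :, i]
                     for i, lab in enumerate(self.data.labels)}
        monitored["sigma_resid"] = draws.sigma_resid
        if self.data.use_year:
            monitored["sigma_year"] = draws.sigma_year
        if self.data.use_ind:
            monitored["sigma_ind"] = draws.sigma_ind
        draws.psrf = diagnostics.psrf_table(monitored, threshold=psrf_threshold)
        gz = {}
        all_z = []
        if draws.n_draws >= 100:
            for name, arr in monitored.items():
                zs = [diagnostics.geweke(chain) for chain in arr]
                all_z.extend(z for z in zs if np.isfinite(z))
                gz[name] = float(np.nanmax(np.abs(zs)))
        draws.geweke_z = gz
        finite = draws.psrf["psrf"].dropna()
        psrf_ok = bool((finite < psrf_threshold).all()) if len(finite) else True
        # under stationarity each Geweke z is ~N(0,1); flag only when the
        # share of |z| > 3 across parameters and chains is clearly excessive.
        # the spectral variance estimate needs a few thousand draws to be
        # trustworthy, so short desk-scale chains are gated on PSRF alone
        # (Geweke values are still reported)
        all_z = np.abs(np.asarray(all_z))
        geweke_ok = True
        if len(all_z) and draws.n_draws >= 2000:
            geweke_ok = bool(np.mean(all_z > 3.0) <= 0.1)
        draws.converged = psrf_ok and geweke_ok
        if not draws.converged:
            logger.warning("fit flagged non-converged (max PSRF %.3f)",
                           float(finite.max()) if len(finite) else np.nan)

    # -- leave-one-out protocol -------------------------------------------
    def refit_without(self, index: int, mcmc: McmcSettings,
                      warm_state: dict | None = None) -> PosteriorDraws:
        """Refit with observation ``index``'s likelihood contribution omitted.

        For the proportion and efficiency suites the omission unit is the
        pair of maternal mass observations (parturition + late, or
        parturition + mid); because the latent logit response then
        integrates to one, this is equivalent to removing the
        observation's every likelihood term.  For weaning only the
        response term is omitted (the parturition-mass observation still
        informs the latent covariate).  A single chain is run, warm-started
        from a converged state of the full fit when provided.
        """
        if not 0 <= index < self.data.n:
            raise IndexError(index)
        resp_weight = np.ones(self.data.n)
        resp_weight[index] = 0.0
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(mcmc.seed, index)))
        sampler = GibbsSampler(self.data, rng, resp_weight=resp_weight)
        if self.spec.response in ("proportion", "efficiency"):
            # paired-mass omission == drop the whole row: freeze its latents
            sampler.m1_free = sampler.m1_free.copy()
            sampler.m1_free[index] = False
            sampler.z_free = sampler.z_free.copy()
            sampler.z_free[index] = False
            sampler.w = resp_weight  # also drop its mass-observation terms
        store, final = sampler.run(mcmc.iter_effective, mcmc.burn_effective,
                                   thin=mcmc.thin, init_state=warm_state)

        def one(key):
            return store[key][None] if key in store else None

        return PosteriorDraws(
            spec=self.spec, labels=list(self.data.labels), beta=one("beta"),
            sigma_resid=one("sigma_resid"), sigma_year=one("sigma_year"),
            sigma_ind=one("sigma_ind"), u_year=one("u_year"),
            u_ind=one("u_ind"), m1=one("m1"), mu_mass=one("mu_mass"),
            sigma_mass=one("sigma_mass"), z=one("z"),
            year_levels=self.data.year_levels, ind_levels=self.data.ind_levels,
            standardization=self.data.standardization, final_states=[final])

    def heldout_logdensity(self, index: int, draws: PosteriorDraws,
                           rng: np.random.Generator | None = None,
                           n_inner: int = 16) -> np.ndarray:
        """Per-draw log predictive density of the held-out unit.

        The latent parturition mass is integrated by Monte Carlo.  Per
        posterior draw the structural layer gives ``M1 ~ N(mu_M,
        sigma_M^2)``; combined with the (omitted or retained)
        parturition-mass observation density this is again normal, so
        inner draws ``M1*`` — and latent responses ``z* ~ N(mu(M1*),
        sigma)`` for the logit suites — average the held-out densities
        exactly.  For the paired-mass schemes the marginal factor
        ``N(m1; mu_M, sigma_M^2 + se1^2)`` of the omitted parturition
        estimate is included in the product density.
        """
        d = self.data
        rng = rng if rng is not None else np.random.default_rng(0)
        beta = draws.flat("beta")
        s = len(beta)
        sig_r = draws.flat("sigma_resid")
        mu_m = draws.flat("mu_mass")
        sig_m = draws.flat("sigma_mass")
        j, k = d.year_idx[index], d.ind_idx[index]
        u = draws.flat("u_year")[:, j] + draws.flat("u_ind")[:, k]
        x0 = d.x[index].copy()
        x0[d.mass_col] = 0.0
        mu_base = beta @ x0 + u
        beta_m = beta[:, d.mass_col]

        # posterior of M1 given the structural layer and the parturition
        # estimate: N(m1, se1) x N(mu_M, sigma_M) -> normal
        se1 = d.se1[index]
        if se1 > 0:
            post_var = 1.0 / (1.0 / sig_m ** 2 + 1.0 / se1 ** 2)
            post_mean = post_var * (mu_m / sig_m ** 2 + d.m1[index] / se1 ** 2)
            post_sd = np.sqrt(post_var)
        else:
            post_mean, post_sd = np.full(s, d.m1[index]), np.zeros(s)
        m1_star = post_mean[:, None] + post_sd[:, None]             * rng.standard_normal((s, n_inner))
        lo, hi = d.priors.latent_mass_range
        in_range = (m1_star >= lo) & (m1_star <= hi)
        mu = mu_base[:, None] + beta_m[:, None] * (
            (m1_star - d.mass_center) / d.mass_scale)

        if self.spec.response == "weaning":
            dens = _norm_pdf(d.y[index], mu, sig_r[:, None])
            dens = np.where(in_range, dens, 0.0)
            return _log_mean(dens, axis=1)

        # marginal density of the omitted parturition-mass estimate
        log_marg = _norm_logpdf(d.m1[index], mu_m,
                                np.sqrt(sig_m ** 2 + se1 ** 2))
        z_star = mu + sig_r[:, None] * rng.standard_normal((s, n_inner))
        if self.spec.response == "proportion":
            second = m1_star * (1.0 - expit(z_star))
        else:
            with np.errstate(over="ignore"):
                second = m1_star - d.pup_gain[index] / expit(z_star)
        dens = np.where((second > 0) & in_range,
                        _norm_pdf(d.m2[index], second, d.se2[index]), 0.0)
        return _log_mean(dens * np.exp(log_marg[:, None]
                                       - log_marg.max()), axis=1)             + log_marg.max()

    # -- derived quantities -----------------------------------------------
    def linear_predictor(self, draws: PosteriorDraws,
                         include_random_effects: bool = True) -> np.ndarray:
        """Fitted means per flattened draw, (n_draws_total, n_obs)."""
        d = self.data
        beta = draws.flat("beta")
        x0 = d.x.copy()
        x0[:, d.mass_col] = 0.0
        mu = beta @ x0.T
        mu += draws.flat("beta")[:, d.mass_col][:, None] * (
            (draws.flat("m1") - d.mass_center) / d.mass_scale)
        if include_random_effects:
            mu += draws.flat("u_year")[:, d.year_idx]
            mu += draws.flat("u_ind")[:, d.ind_idx]
        return mu

    def gof(self, draws: PosteriorDraws, rng: np.random.Generator | None = None,
            max_draws: int = 500) -> diagnostics.GofResult:
        """Ordered-z-score posterior-predictive discrepancy for this fit."""
        rng = rng if rng is not None else np.random.default_rng(0)
        mu = self.linear_predictor(draws)
        resp = draws.flat("z") if self.spec.response != "weaning" else self.data.y
        sig = draws.flat("sigma_resid")
        if len(sig) > max_draws:
            idx = np.linspace(0, len(sig) - 1, max_draws).astype(int)
            mu, sig = mu[idx], sig[idx]
            if resp.ndim == 2:
                resp = resp[idx]
        return diagnostics.gof_ordered_z(resp, mu, sig, rng)


def _norm_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (np.sqrt(2 * np.pi) * sd)


def _log_mean(dens: np.ndarray, axis=None) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.mean(dens, axis=axis))


# ---------------------------------------------------------------------------
# reference prediction

@dataclass(frozen=True)
class PredictionSummary:
    mean: float
    hdi_lower: float
    hdi_upper: float
    mass: float
    quantity: str
    draws: np.ndarray

    def __repr__(self) -> str:  # keep the draws out of the repr
        return (f"PredictionSummary({self.quantity}: mean={self.mean:.4g}, "
                f"{int(self.mass * 100)}% HDI [{self.hdi_lower:.4g}, "
                f"{self.hdi_upper:.4g}])")


def predict_reference(draws: PosteriorDraws, spec: ModelSpec,
                      standardization: StandardizationTable,
                      profile: ReferenceProfile | None = None,
                      quantity: str = "response",
                      mass: float = 0.90) -> PredictionSummary:
    """Posterior prediction for a reference individual (random effects 0).

    ``quantity='response'`` gives the model's natural scale: a proportion
    or efficiency in (0, 1) via the inverse logit, or weaning mass in kg.
    ``quantity='kg_allocated'`` multiplies the proportion draw-wise by the
    profile's parturition mass.
    """
    profile = profile if profile is not None else ReferenceProfile()
    row = profile_row(profile, spec, standardization)
    for name, value in (("age", profile.maternal_age),
                        ("maternal_mass", profile.maternal_mass),
                        ("birthdate", profile.birthdate)):
        if value is not None and name in standardization:
            z = abs(standardization.standardize(name, value))
            if z > 2.0:
                logger.warning("profile %s=%s lies far outside the observed "
                               "range (|z| = %.1f)", name, value, z)
    lp = draws.flat("beta") @ row
    if spec.response in ("proportion", "efficiency"):
        pred = expit(lp)
    else:
        pred = lp
    if quantity == "kg_allocated":
        if spec.response != "proportion":
            raise ConfigurationError("kg_allocated applies to the proportion suite")
        mass_kg = profile.maternal_mass
        if mass_kg is None:
            mass_kg = standardization.center("maternal_mass")
        pred = pred * mass_kg
    elif quantity != "response":
        raise ConfigurationError(f"unknown quantity {quantity!r}")
    interval = diagnostics.hdi(pred, mass=mass)
    return PredictionSummary(mean=float(pred.mean()), hdi_lower=interval.lower,
                             hdi_upper=interval.upper, mass=mass,
                             quantity=quantity, draws=pred)
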
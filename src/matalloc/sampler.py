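"""Adaptive Metropolis-within-Gibbs kernel for the latent-mass models.

The joint target is :func:`matalloc.model.log_joint`.  Conditional
structure makes most blocks exact Gibbs draws:

* coefficients: conditionally multivariate normal given latents (the
  latent logit responses are linear in beta), drawn jointly, redrawn on
  the rare event a draw leaves its uniform prior bounds;
* year and individual effects: conjugate normal, vectorized over levels;
* variance components and the latent-mass population layer (mu_M,
  sigma_M): with flat/uniform priors these conditionals are normal and
  inverse-gamma, drawn exactly and redrawn if an SD exceeds its bound;
* latent parturition masses and latent logit responses: per-observation
  random-walk Metropolis, vectorized across observations (they are
  conditionally independent), with per-coordinate proposal scales adapted
  toward a 0.44 acceptance rate during burn-in.

Observations with a zero prediction SE have their latent mass pinned to
the observed value; if every relevant SE is zero the latent response is
pinned too, which degenerates to exact arithmetic on observed values (the
naive, error-blind fit).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_LOG_2PI = float(np.log(2.0 * np.pi))


def _norm_logpdf(x, mu, sd):
    return -0.5 * (_LOG_2PI + 2.0 * np.log(sd) + ((x - mu) / sd) ** 2)


def _draw_variance(rng, ss: float, k: int, bound: float, current: float) -> float:
    """sigma | rest with U(0, bound) prior on sigma: sigma^2 is
    InvGamma((k-1)/2, ss/2); redraw while out of bounds."""
    alpha = 0.5 * (k - 1)
    if alpha <= 0 or ss <= 0:
        return current
    for _ in range(50):
        g = rng.gamma(alpha, 2.0 / ss)
        if g <= 0:
            continue
        sigma = 1.0 / np.sqrt(g)
        if sigma < bound:
            return float(sigma)
    return current


class GibbsSampler:
    """One-chain sampler bound to a prepared :class:`~matalloc.model.ModelData`.

    ``resp_weight`` (0/1 per observation) removes response-likelihood
    contributions (used by leave-one-out refits of the weaning suite).
    """

    def __init__(self, data, rng: np.random.Generator,
                 resp_weight: np.ndarray | None = None,
                 fixed: dict | None = None):
        self.d = data
        self.rng = rng
        n = data.n
        self.w = (np.ones(n) if resp_weight is None
                  else np.asarray(resp_weight, dtype=float))
        self.fixed = dict(fixed or {})
        self.is_logit = data.spec.response in ("proportion", "efficiency")
        # pinned latents: se == 0 means the latent equals the observed value
        self.m1_free = data.se1 > 0
        if self.is_logit:
            self.z_free = (data.se1 > 0) | (data.se2 > 0)
        # adaptive proposal scales
        self.s_m1 = np.full(n, max(1.0, np.median(data.se1[self.m1_free]))
                            if self.m1_free.any() else 1.0)
        self.s_z = np.full(n, 0.2)
        self._acc_m1 = np.zeros(n)
        self._acc_z = np.zeros(n)
        self._adapt_count = 0

    # -- state ------------------------------------------------------------
    def initial_state(self, jitter: float = 0.0) -> dict:
        d, rng = self.d, self.rng
        m1 = np.clip(d.m1, *d.priors.latent_mass_range)
        state = {"m1": m1.copy()}
        if self.is_logit:
            state["z"] = d.z_init.copy()
        resp = state.get("z", d.y)
        x_eff = d.x.copy()
        x_eff[:, d.mass_col] = (m1 - d.mass_center) / d.mass_scale
        beta, *_ = np.linalg.lstsq(x_eff, resp, rcond=None)
        resid = resp - x_eff @ beta
        state["beta"] = np.clip(beta, -d.beta_bounds, d.beta_bounds)
        state["sigma_resid"] = self.fixed.get(
            "sigma_resid", float(max(np.std(resid), 1e-3)))
        state["u_year"] = np.zeros(len(d.year_levels))
        state["u_ind"] = np.zeros(len(d.ind_levels))
        state["sigma_year"] = self.fixed.get(
            "sigma_year", 0.1 * state["sigma_resid"]) if d.use_year else 0.0
        state["sigma_ind"] = self.fixed.get(
            "sigma_ind", 0.1 * state["sigma_resid"]) if d.use_ind else 0.0
        state["mu_mass"] = float(np.mean(m1))
        state["sigma_mass"] = float(max(np.std(m1, ddof=1), 1.0))
        if jitter > 0:
            state["beta"] = state["beta"] + jitter * rng.standard_normal(
                len(beta)) * (np.abs(state["beta"]) + 0.1)
            state["sigma_resid"] *= float(np.exp(jitter * rng.standard_normal()))
            if self.is_logit:
                state["z"] = state["z"] + jitter * rng.standard_normal(d.n) * 0.2
        return state

    # -- helpers ----------------------------------------------------------
    def _mass_z(self, m1):
        return (m1 - self.d.mass_center) / self.d.mass_scale

    def _mu_base(self, state):
        """Linear predictor with the mass column zeroed out."""
        d = self.d
        x0 = d.x.copy()
        x0[:, d.mass_col] = 0.0
        mu = x0 @ state["beta"]
        mu += state["u_year"][d.year_idx]
        mu += state["u_ind"][d.ind_idx]
        return mu

    def _derived_second(self, m1, z):
        """Latent mid/late maternal mass implied by (M1, latent response)."""
        d = self.d
        if d.spec.response == "proportion":
            return m1 * (1.0 - expit(z))
        return m1 - d.pup_gain / expit(z)  # efficiency

    def _latent_obs_logp(self, m1, z, mu_base, beta_mass, sigma,
                         mu_mass, sigma_mass):
        """Per-observation log target terms that involve the latents."""
        d = self.d
        lo, hi = d.priors.latent_mass_range
        lp = np.where((m1 < lo) | (m1 > hi), -np.inf, 0.0)
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            lp = lp + _norm_logpdf(m1, mu_mass, sigma_mass)
            if self.m1_free.any():
                lp = lp + np.where(self.m1_free,
                                   _norm_logpdf(d.m1, m1, np.where(d.se1 > 0, d.se1, 1.0)),
                                   0.0)
            mu = mu_base + beta_mass * self._mass_z(m1)
            if self.is_logit:
                second = self._derived_second(m1, z)
                lp = lp + np.where(second <= 0, -np.inf, 0.0)
                lp = lp + np.where(d.se2 > 0,
                                   _norm_logpdf(d.m2, second, np.where(d.se2 > 0, d.se2, 1.0)),
                                   0.0)
                lp = lp + self.w * _norm_logpdf(z, mu, sigma)
            else:
                lp = lp + self.w * _norm_logpdf(d.y, mu, sigma)
        return np.where(np.isnan(lp), -np.inf, lp)

    # -- block updates ----------------------------------------------------
    def _update_latents(self, state, adapt: bool):
        d, rng = self.d, self.rng
        beta_mass = state["beta"][d.mass_col]
        sigma = state["sigma_resid"]
        mm, sm = state["mu_mass"], state["sigma_mass"]
        mu_base = self._mu_base(state)
        m1 = state["m1"]
        z = state.get("z")

        with np.errstate(invalid="ignore"):
            if self.m1_free.any():
                prop = m1 + self.s_m1 * rng.standard_normal(d.n)
                prop = np.where(self.m1_free, prop, m1)
                cur_lp = self._latent_obs_logp(m1, z, mu_base, beta_mass, sigma, mm, sm)
                new_lp = self._latent_obs_logp(prop, z, mu_base, beta_mass, sigma, mm, sm)
                accept = (np.log(rng.random(d.n)) < new_lp - cur_lp) & self.m1_free
                m1 = np.where(accept, prop, m1)
                state["m1"] = m1
                self._acc_m1 += accept

            if self.is_logit and self.z_free.any():
                prop = z + self.s_z * rng.standard_normal(d.n)
                prop = np.where(self.z_free, prop, z)
                cur_lp = self._latent_obs_logp(m1, z, mu_base, beta_mass, sigma, mm, sm)
                new_lp = self._latent_obs_logp(m1, prop, mu_base, beta_mass, sigma, mm, sm)
                accept = (np.log(rng.random(d.n)) < new_lp - cur_lp) & self.z_free
                state["z"] = np.where(accept, prop, z)
                self._acc_z += accept

        self._adapt_count += 1
        if adapt and self._adapt_count % 50 == 0:
            step = min(0.5, 5.0 / np.sqrt(self._adapt_count))
            self.s_m1 *= np.exp(step * (self._acc_m1 / 50 - 0.44))
            self.s_z *= np.exp(step * (self._acc_z / 50 - 0.44))
            self._acc_m1[:] = 0.0
            self._acc_z[:] = 0.0

    def _update_beta(self, state):
        d, rng = self.d, self.rng
        x_eff = d.x.copy()
        x_eff[:, d.mass_col] = self._mass_z(state["m1"])
        resp = state.get("z", d.y)
        target = resp - state["u_year"][d.year_idx] - state["u_ind"][d.ind_idx]
        xw = x_eff * self.w[:, None]
        sigma2 = state["sigma_resid"] ** 2
        a = xw.T @ x_eff / sigma2
        b = xw.T @ target / sigma2
        for ridge in (0.0, 1e-8, 1e-4):
            try:
                chol = np.linalg.cholesky(a + ridge * np.eye(len(b)) * max(a.max(), 1.0))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            return
        mean = np.linalg.solve(a, b) if np.all(np.isfinite(b)) else state["beta"]
        for _ in range(10):
            draw = mean + np.linalg.solve(chol.T, rng.standard_normal(len(b)))
            if np.all(np.abs(draw) <= d.beta_bounds):
                state["beta"] = draw
                return
        state["beta"] = np.clip(mean, -d.beta_bounds, d.beta_bounds)

    def _update_random_effects(self, state):
        d, rng = self.d, self.rng
        resp = state.get("z", d.y)
        x_eff = d.x.copy()
        x_eff[:, d.mass_col] = self._mass_z(state["m1"])
        fitted_fix = x_eff @ state["beta"]
        sigma2 = state["sigma_resid"] ** 2
        for which, idx, levels in (("year", d.year_idx, d.year_levels),
                                   ("ind", d.ind_idx, d.ind_levels)):
            use = d.use_year if which == "year" else d.use_ind
            key, skey = f"u_{which}", f"sigma_{which}"
            if not use:
                continue
            other = state["u_ind"][d.ind_idx] if which == "year" \
                else state["u_year"][d.year_idx]
            sig_u = state[skey]
            if sig_u == 0.0:
                state[key] = np.zeros(len(levels))
                continue
            res = resp - fitted_fix - other
            counts = np.bincount(idx, weights=self.w, minlength=len(levels))
            sums = np.bincount(idx, weights=self.w * res, minlength=len(levels))
            prec = counts / sigma2 + 1.0 / sig_u ** 2
            mean = sums / sigma2 / prec
            state[key] = mean + rng.standard_normal(len(levels)) / np.sqrt(prec)

    def _update_sigmas(self, state):
        d, rng = self.d, self.rng
        resp = state.get("z", d.y)
        x_eff = d.x.copy()
        x_eff[:, d.mass_col] = self._mass_z(state["m1"])
        resid = resp - x_eff @ state["beta"] \
            - state["u_year"][d.year_idx] - state["u_ind"][d.ind_idx]
        if "sigma_resid" not in self.fixed:
            ss = float(np.sum(self.w * resid ** 2))
            state["sigma_resid"] = _draw_variance(
                rng, ss, int(self.w.sum()), d.priors.sigma_bound,
                state["sigma_resid"])
        for which, use in (("year", d.use_year), ("ind", d.use_ind)):
            key = f"sigma_{which}"
            if not use or key in self.fixed:
                continue
            u = state[f"u_{which}"]
            state[key] = _draw_variance(rng, float(np.sum(u ** 2)), len(u),
                                        d.priors.sigma_bound, state[key])
        self._update_mass_hypers(state)

    def _update_mass_hypers(self, state):
        """Population layer for true parturition mass: conjugate normal for
        mu_M (flat hyperprior) and inverse-gamma for sigma_M^2."""
        d, rng = self.d, self.rng
        m1 = state["m1"]
        n = len(m1)
        sm = state["sigma_mass"]
        lo, hi = d.priors.latent_mass_range
        if "mu_mass" not in self.fixed:
            for _ in range(20):
                draw = m1.mean() + sm / np.sqrt(n) * rng.standard_normal()
                if lo <= draw <= hi:
                    state["mu_mass"] = float(draw)
                    break
        if "sigma_mass" not in self.fixed:
            ss = float(np.sum((m1 - state["mu_mass"]) ** 2))
            state["sigma_mass"] = _draw_variance(
                rng, ss, n, d.priors.latent_mass_sd_bound, sm)

    def step(self, state, adapt: bool = False):
        self._update_latents(state, adapt)
        self._update_beta(state)
        self._update_random_effects(state)
        self._update_sigmas(state)
        return state

    # -- driver -----------------------------------------------------------
    def run(self, n_iter: int, n_burn: int, thin: int = 1,
            init_state: dict | None = None, jitter: float = 0.0):
        """Run the chain; returns (stored draws dict, final state)."""
        state = init_state if init_state is not None \
            else self.initial_state(jitter=jitter)
        state = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                 for k, v in state.items()}
        for _ in range(n_burn):
            self.step(state, adapt=True)
        keep = max(1, n_iter // thin)
        store = {
            "beta": np.empty((keep, len(state["beta"]))),
            "sigma_resid": np.empty(keep),
            "sigma_year": np.empty(keep),
            "sigma_ind": np.empty(keep),
            "u_year": np.empty((keep, len(state["u_year"]))),
            "u_ind": np.empty((keep, len(state["u_ind"]))),
            "m1": np.empty((keep, self.d.n)),
            "mu_mass": np.empty(keep),
            "sigma_mass": np.empty(keep),
        }
        if self.is_logit:
            store["z"] = np.empty((keep, self.d.n))
        j = 0
        for i in range(n_iter):
            self.step(state, adapt=False)
            if i % thin == 0 and j < keep:
                store["beta"][j] = state["beta"]
                store["sigma_resid"][j] = state["sigma_resid"]
                store["sigma_year"][j] = state["sigma_year"]
                store["sigma_ind"][j] = state["sigma_ind"]
                store["u_year"][j] = state["u_year"]
                store["u_ind"][j] = state["u_ind"]
                store["m1"][j] = state["m1"]
                store["mu_mass"][j] = state["mu_mass"]
                store["sigma_mass"][j] = state["sigma_mass"]
                if self.is_logit:
                    store["z"][j] = state["z"]
                j += 1
        for key in store:
            store[key] = store[key][:j]
        return store, state
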
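"""Oracle models implementing the leave-one-out protocol exactly.

These drive the same CPO/BPIC machinery as the allocation models but have
closed-form answers, so they serve as independent references.
"""

import numpy as np
from scipy import stats


class FixedDensityModel:
    """Parameter-free model: every observation has a fixed standard-normal
    density, so log CPO_i = log phi(y_i) exactly, refit or not."""

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float)

    @property
    def n_units(self):
        return len(self.y)

    def refit_without(self, index, mcmc, warm_state=None):
        return {"n_draws": max(1, mcmc.iter_effective)}

    def heldout_logdensity(self, index, draws, rng=None, **kw):
        return np.full(draws["n_draws"], stats.norm.logpdf(self.y[index]))


class ConjugateNormalMeanModel:
    """y_i ~ N(mu, sigma^2) with known sigma and a flat prior on mu.

    The leave-one-out posterior is exactly N(mean(y_-i), sigma^2/(n-1)),
    sampled directly, so the machinery's Monte-Carlo log CPO can be
    compared with the closed-form predictive
    N(y_i; mean(y_-i), sigma^2 (1 + 1/(n-1))).
    """

    def __init__(self, y, sigma=1.0):
        self.y = np.asarray(y, dtype=float)
        self.sigma = sigma

    @property
    def n_units(self):
        return len(self.y)

    def loo_mean(self, index):
        keep = np.delete(self.y, index)
        return keep.mean(), len(keep)

    def closed_form_log_cpo(self, index):
        m, k = self.loo_mean(index)
        sd = self.sigma * np.sqrt(1 + 1 / k)
        return float(stats.norm.logpdf(self.y[index], m, sd))

    def refit_without(self, index, mcmc, warm_state=None):
        m, k = self.loo_mean(index)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(mcmc.seed, index, 99)))
        return m + self.sigma / np.sqrt(k) * rng.standard_normal(
            mcmc.iter_effective)

    def heldout_logdensity(self, index, draws, rng=None, **kw):
        return stats.norm.logpdf(self.y[index], draws, self.sigma)


def mc_se_of_log_mean(log_values):
    """Delta-method Monte-Carlo standard error of a log-mean-exp."""
    w = np.exp(log_values - log_values.max())
    return w.std(ddof=1) / (w.mean() * np.sqrt(len(w)))
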
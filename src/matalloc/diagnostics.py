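"""Convergence diagnostics, highest-density intervals and goodness of fit.

Implements the three diagnostics the analysis relies on — the Gelman-Rubin
potential scale-reduction factor, the Geweke early/late z-score, and a
posterior-predictive discrepancy based on squared differences between
ordered z-scores — plus the 90% HDI used for every reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["gelman_rubin", "psrf_table", "geweke", "hdi", "HdiInterval",
           "gof_ordered_z", "GofResult", "blom_scores"]


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale-reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Returns NaN (flagged, not
    raised) for constant or degenerate chains; values slightly below 1 are
    possible for short chains and are reported as-is.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    m, n = x.shape
    within = x.var(axis=1, ddof=1).mean()
    between = n * x.mean(axis=1).var(ddof=1)
    if within == 0:
        return np.nan
    v_hat = (n - 1) / n * within + (1 + 1 / m) * between / n
    return float(np.sqrt(v_hat / within))


def psrf_table(draws: dict, threshold: float = 1.1) -> pd.DataFrame:
    """PSRF per parameter from a dict of (n_chains, n_draws) arrays."""
    rows = []
    for name, x in draws.items():
        r = gelman_rubin(x)
        rows.append({"parameter": name, "psrf": r,
                     "pass": bool(r < threshold) if np.isfinite(r) else False})
    return pd.DataFrame(rows)


def _spectral_variance(segment: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed
    autocovariance sum (Newey-West), divided by the segment length."""
    n = len(segment)
    x = segment - segment.mean()
    # a wide Bartlett window (10% of the segment) keeps the estimate
    # honest for strongly autocorrelated chains
    lag = min(n - 1, max(10, int(round(0.1 * n))))
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    weights = 1.0 - np.arange(1, lag + 1) / (lag + 1)
    s0 = acov[0] + 2.0 * np.sum(weights * acov[1:lag + 1])
    return max(s0, 0.0) / n


def geweke(chain: np.ndarray, frac_early: float = 0.1,
           frac_late: float = 0.5) -> float:
    """Geweke convergence z: early-segment mean vs late-segment mean,
    standardized by spectral-density variance estimates of each segment.

    Returns NaN (flagged) if either segment is constant.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1 or len(x) < 100:
        raise ValueError("need a 1-D chain of length >= 100")
    if not (0 < frac_early < 1 and 0 < frac_late < 1 and frac_early + frac_late <= 1):
        raise ValueError("invalid segment fractions")
    n = len(x)
    a = x[: int(np.floor(frac_early * n))]
    b = x[n - int(np.floor(frac_late * n)):]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    var = _spectral_variance(a) + _spectral_variance(b)
    if var <= 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(var))


@dataclass(frozen=True)
class HdiInterval:
    lower: float
    upper: float
    mass: float

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hdi(draws: np.ndarray, mass: float = 0.90) -> HdiInterval:
    """Highest-density interval: the shortest contiguous window of the
    sorted draws containing ``ceil(mass * n)`` draws.

    Ties between equally short windows break to the lowest starting index.
    """
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 20:
        raise ValueError(f"need >= 20 draws for an HDI, got {n}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    start = int(np.argmin(widths))  # argmin takes the first minimum: low-index tie-break
    return HdiInterval(lower=float(x[start]), upper=float(x[start + k - 1]), mass=mass)


def blom_scores(n: int) -> np.ndarray:
    """Expected standard-normal order statistics (Blom approximation)."""
    i = np.arange(1, n + 1)
    return stats.norm.ppf((i - 0.375) / (n + 0.25))


@dataclass(frozen=True)
class GofResult:
    """Ordered-z-score discrepancy: observed and replicated values per
    posterior draw, and the Bayesian p-value Pr(T_rep >= T_obs)."""

    t_obs: np.ndarray
    t_rep: np.ndarray
    degenerate: bool = False

    @property
    def p_value(self) -> float:
        return float(np.mean(self.t_rep >= self.t_obs))


def gof_ordered_z(response, mu, sigma, rng: np.random.Generator) -> GofResult:
    """Posterior-predictive check of mean structure and residual normality.

    Per posterior draw, standardized residuals of the observed responses
    and of a replicated dataset simulated from the same draw are sorted and
    compared with expected standard-normal order statistics m_i; the
    discrepancy is T = sum_i (z_(i) - m_i)^2.

    ``response``: observed responses, (n,) or per-draw (S, n) when the
    response itself is latent; ``mu``: fitted means (S, n); ``sigma``:
    residual SD per draw (S,).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    s, n = mu.shape
    if n < 10:
        raise ValueError("ordered-z discrepancy needs >= 10 observations")
    response = np.asarray(response, dtype=float)
    if response.ndim == 1:
        response = np.broadcast_to(response, (s, n))
    degenerate = bool(np.any(sigma == 0))
    sig = np.where(sigma == 0, np.nan, sigma)[:, None]
    m = blom_scores(n)
    z_obs = np.sort((response - mu) / sig, axis=1)
    z_rep = np.sort(rng.standard_normal((s, n)), axis=1)
    t_obs = np.sum((z_obs - m) ** 2, axis=1)
    t_rep = np.sum((z_rep - m) ** 2, axis=1)
    return GofResult(t_obs=t_obs, t_rep=t_rep, degenerate=degenerate)


def trace_plot(draws: dict, path=None):
    """Trace plots for a dict of (n_chains, n_draws) arrays (for eyes, not
    auto-scored).  Requires matplotlib; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(draws)
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 1.8 * len(names)),
                             squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        for chain in np.atleast_2d(draws[name]):
            ax.plot(chain, lw=0.4)
        ax.set_ylabel(name, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
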
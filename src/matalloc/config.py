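"""Configuration and domain types shared across the package.

The analysis revolves around three allocation responses measured on
mother-pup pairs of a capital-breeding phocid over a lactation season:

``proportion``
    fraction of maternal body mass lost from parturition to late lactation,
    modelled on the logit scale;
``efficiency``
    pup mass gained per kg of maternal mass lost over early lactation,
    modelled on the logit scale;
``weaning``
    pup mass at late lactation, modelled in kg.

Maternal masses are photogrammetric estimates carrying a prediction
standard error, so the models treat true maternal masses as latent
variables (see :mod:`matalloc.model`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RESPONSES = ("proportion", "efficiency", "weaning")
AGE_FORMS = ("null", "linear", "quadratic", "log")

#: previous-year reproductive status levels; first entry is the reference.
STATUS_LEVELS = (
    "experienced_bred",
    "first_time_last_year",
    "prebreeder_last_year",
    "experienced_skipped",
)

#: indicator column labels for the non-reference status levels
STATUS_COLUMNS = {
    "first_time_last_year": "status_first_time",
    "prebreeder_last_year": "status_prebreeder",
    "experienced_skipped": "status_skipped",
}

#: sampling windows (days post-parturition) for the three weighing occasions
MEASUREMENT_WINDOWS = ((1, 4), (15, 25), (30, 40))


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a documented invariant."""


@dataclass(frozen=True)
class MassEstimate:
    """A mass point estimate with its prediction standard error.

    ``se`` is the prediction SE of the estimation method; directly weighed
    (platform) masses carry se = 0 by convention.
    """

    value: float
    se: float
    method: str = "platform"

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ConfigurationError(f"mass value must be positive, got {self.value}")
        if not np.isfinite(self.se) or self.se < 0:
            raise ConfigurationError(f"mass se must be >= 0, got {self.se}")


def default_covariates(response: str) -> tuple[str, ...]:
    """Non-age fixed-effect covariates for a response suite, in table order."""
    base = [
        "afr",
        "maternal_mass",
        "status_first_time",
        "status_prebreeder",
        "status_skipped",
    ]
    if response == "proportion":
        base.append("measurement_days")
    if response == "weaning":
        base.insert(2, "pup_birth_mass")
    base.append("pup_sex_M")
    return tuple(base)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response x age form x covariates x random effects."""

    response: str
    age_form: str = "quadratic"
    covariates: tuple[str, ...] | None = None
    random_effects: tuple[str, ...] = ("year", "individual")
    include_birthdate_quadratic: bool = False

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ConfigurationError(f"unknown response {self.response!r}")
        if self.age_form not in AGE_FORMS:
            raise ConfigurationError(f"unknown age form {self.age_form!r}")
        if self.covariates is None:
            object.__setattr__(self, "covariates", default_covariates(self.response))
        else:
            object.__setattr__(self, "covariates", tuple(self.covariates))
        cov = set(self.covariates)
        if self.response == "weaning" and "pup_birth_mass" not in cov:
            raise ConfigurationError("weaning models must include pup_birth_mass")
        if self.response == "proportion" and "measurement_days" not in cov:
            raise ConfigurationError("proportion models must include measurement_days")
        if self.response in ("efficiency", "weaning") and "measurement_days" in cov:
            raise ConfigurationError(
                f"{self.response} models must exclude measurement_days"
            )
        for re_name in self.random_effects:
            if re_name not in ("year", "individual"):
                raise ConfigurationError(f"unknown random effect {re_name!r}")

    def with_birthdate(self) -> "ModelSpec":
        """The same model with the quadratic birthdate terms added."""
        return replace(self, include_birthdate_quadratic=True)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds.

    Fixed effects get U(-beta_bound, beta_bound): 10 for the logit-scale
    suites (proportion, efficiency) and 30 for weaning (kg scale).  Random
    effect SDs get U(0, 50).

    Latent true parturition masses get a structural prior
    ``M1_i ~ Normal(mu_M, sigma_M^2)`` truncated to ``latent_mass_range``,
    with a flat hyperprior on ``mu_M`` and ``U(0, latent_mass_sd_bound)``
    on ``sigma_M``; relating covariate estimates to *true* mass through a
    population layer is what lets the model undo attenuation from
    photogrammetric error (a purely flat latent prior cannot).
    """

    beta_bound: float = 10.0
    sigma_bound: float = 50.0
    latent_mass_range: tuple[float, float] = (100.0, 800.0)
    latent_mass_sd_bound: float = 200.0
    #: the intercept carries the response's mean level (e.g. ~99 kg weaning
    #: mass), which the slope bound cannot contain; it gets its own bound
    intercept_bound: float = 1000.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta_bound) and self.beta_bound > 0):
            raise ConfigurationError("beta_bound must be positive and finite")
        if not (np.isfinite(self.sigma_bound) and self.sigma_bound > 0):
            raise ConfigurationError("sigma_bound must be positive and finite")
        lo, hi = self.latent_mass_range
        if not (0 <= lo < hi and np.isfinite(hi)):
            raise ConfigurationError("latent_mass_range must satisfy 0 <= lo < hi")
        if not self.latent_mass_sd_bound > 0:
            raise ConfigurationError("latent_mass_sd_bound must be positive")

    @classmethod
    def for_response(cls, response: str) -> "PriorSpec":
        return cls(beta_bound=30.0 if response == "weaning" else 10.0)


#: production chain lengths per suite: (n_iter retained, n_burn)
DEFAULT_CHAIN_LENGTHS = {
    "weaning": (40_000, 20_000),
    "proportion": (70_000, 30_000),
    "efficiency": (250_000, 300_000),
}


@dataclass(frozen=True)
class McmcSettings:
    """Sampler run lengths.  ``scale`` divides iteration counts for
    desk-scale runs (scale=1 reproduces the production lengths)."""

    n_chains: int = 3
    n_iter: int = 40_000
    n_burn: int = 20_000
    thin: int = 1
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.n_burn < 0 or self.thin < 1 or self.n_chains < 1:
            raise ConfigurationError("invalid MCMC settings")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")

    @classmethod
    def for_response(cls, response: str, seed: int = 0, scale: float = 1.0,
                     n_chains: int = 3) -> "McmcSettings":
        n_iter, n_burn = DEFAULT_CHAIN_LENGTHS[response]
        return cls(n_chains=n_chains, n_iter=n_iter, n_burn=n_burn, seed=seed,
                   scale=scale)

    @property
    def iter_effective(self) -> int:
        return max(20, int(round(self.n_iter / self.scale)))

    @property
    def burn_effective(self) -> int:
        return max(10, int(round(self.n_burn / self.scale)))


@dataclass(frozen=True)
class ReferenceProfile:
    """Covariate values defining a prediction target.

    ``None`` means "use the data mean" (the standardization center).  The
    default profile is the reference mother: an experienced breeder that
    reproduced the previous season, at mean age / age-at-first-reproduction
    / birthdate / parturition mass, with a female pup of mean birth mass and
    random effects zero.
    """

    maternal_age: float | None = None
    afr: float | None = None
    maternal_mass: float | None = None
    birthdate: float | None = None
    measurement_days: float | None = None
    pup_birth_mass: float | None = None
    pup_sex: str = "F"
    status_prev: str = "experienced_bred"

    def __post_init__(self) -> None:
        if self.status_prev not in STATUS_LEVELS:
            raise ConfigurationError(f"unknown status level {self.status_prev!r}")
        if self.pup_sex not in ("F", "M"):
            raise ConfigurationError(f"pup_sex must be F or M, got {self.pup_sex!r}")


def _check_prob_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be a probability vector summing to 1")
    return p


# Generator truth defaults: coefficient values on the model scale for each
# response, keyed by design-column label.  Age enters quadratically for the
# proportion and efficiency truths and logarithmically for weaning.
DEFAULT_TRUE_COEFFICIENTS = {
    "proportion": {
        "intercept": -0.672, "age": -0.184, "age2": 0.172, "afr": -0.044,
        "maternal_mass": 0.204, "status_first_time": -0.059,
        "status_prebreeder": -0.226, "status_skipped": -0.064,
        "measurement_days": 0.123, "pup_sex_M": 0.028,
        "birthdate": 0.112, "birthdate2": -0.007,
    },
    "efficiency": {
        "intercept": 0.065, "age": 0.380, "age2": -0.195, "afr": 0.038,
        "maternal_mass": -0.363, "status_first_time": 0.147,
        "status_prebreeder": -0.142, "status_skipped": 0.053,
        "pup_sex_M": -0.007, "birthdate": -0.053, "birthdate2": -0.239,
    },
    "weaning": {
        "intercept": 99.14, "ln_age": 1.15, "afr": 1.33,
        "pup_birth_mass": 7.83, "maternal_mass": 13.99,
        "status_first_time": 1.00, "status_prebreeder": -9.40,
        "status_skipped": 1.90, "pup_sex_M": 0.06,
        "birthdate": 2.70, "birthdate2": -0.89,
    },
}

#: ages 4..14 inclusive; roughly unimodal around age 7-8
DEFAULT_AFR_PROBS = (0.02, 0.06, 0.12, 0.18, 0.18, 0.15, 0.11,
                     0.08, 0.05, 0.03, 0.02)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the synthetic colony generator needs.

    Defaults emulate the study colony: ~531 observations from 362 mothers
    over 15 years, mean proportion allocation ~0.33, mean transfer
    efficiency ~0.5, mean weaning mass ~99 kg, photogrammetric maternal
    mass error of 15 kg prediction SE.
    """

    n_mothers: int = 362
    n_years: int = 15
    seed: int = 0
    first_year: int = 2002

    # demography of the observed-season process
    afr_min: int = 4
    afr_probs: tuple[float, ...] = DEFAULT_AFR_PROBS
    #: P(another observed season after each observed season); 0.36 yields
    #: the 249/74/26/13 one/two/three/four-plus-season mother profile
    repeat_prob: float = 0.36
    #: P(next observed season is the immediately following year)
    consecutive_prob: float = 0.8
    #: P(a mother's first observed season is her first-ever reproduction)
    first_breeding_prob: float = 0.4
    #: for experienced first observations: P(skipped | not first-time)
    skip_prob: float = 0.3
    #: years since first reproduction at first observation for experienced
    #: mothers: negative binomial (n, mean)
    experience_gap: tuple[float, float] = (2.0, 9.0)
    max_age: int = 32

    # covariate marginals
    mass_mean: float = 450.0
    mass_sd: float = 55.0
    pup_birth_mean: float = 29.0
    pup_birth_sd: float = 5.0
    birthdate_mean: float = 27.0
    birthdate_sd: float = 7.0

    # truth: per-response coefficient dicts on the model scale
    true_coefficients: dict = field(
        default_factory=lambda: {r: dict(v) for r, v in
                                 DEFAULT_TRUE_COEFFICIENTS.items()})
    sigma_year: dict = field(
        default_factory=lambda: {"proportion": 0.09, "efficiency": 0.15,
                                 "weaning": 5.0})
    sigma_individual: dict = field(
        default_factory=lambda: {"proportion": 0.04, "efficiency": 0.15,
                                 "weaning": 5.0})
    sigma_residual: dict = field(
        default_factory=lambda: {"proportion": 0.15, "efficiency": 0.35,
                                 "weaning": 12.0})

    # measurement process
    photo_error_sd: float = 15.0
    platform_error_sd: float = 0.0
    measurement_window_days: tuple = MEASUREMENT_WINDOWS

    def __post_init__(self) -> None:
        if self.n_mothers < 1 or self.n_years < 1:
            raise ConfigurationError("n_mothers and n_years must be positive")
        _check_prob_vector(np.asarray(self.afr_probs), "afr_probs")
        for name in ("repeat_prob", "consecutive_prob", "first_breeding_prob",
                     "skip_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("mass_sd", "pup_birth_sd", "birthdate_sd",
                     "photo_error_sd", "platform_error_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        for name in ("sigma_year", "sigma_individual", "sigma_residual"):
            d = getattr(self, name)
            for r in RESPONSES:
                if r not in d:
                    raise ConfigurationError(f"{name} missing response {r!r}")
                if d[r] < 0:
                    raise ConfigurationError(f"{name}[{r!r}] must be >= 0")
        wins = self.measurement_window_days
        if len(wins) != 3:
            raise ConfigurationError("measurement_window_days needs 3 windows")
        for (lo, hi), (wlo, whi) in zip(wins, MEASUREMENT_WINDOWS):
            if not (wlo <= lo <= hi <= whi):
                raise ConfigurationError(
                    f"window ({lo},{hi}) outside sampling design [{wlo},{whi}]")

    @property
    def afr_values(self) -> np.ndarray:
        return np.arange(self.afr_min, self.afr_min + len(self.afr_probs))
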
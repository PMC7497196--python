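"""Seeded synthetic colonies with known truth.

The generator reproduces the statistical structure the analysis assumes:
mothers with individual effects and an age-at-first-reproduction, repeated
observed breeding seasons across years with year effects, true maternal and
pup masses tied together through the three allocation responses, and
photogrammetric measurement error on maternal masses.  Every latent
quantity is recorded so parameter-recovery and attenuation experiments can
be scored against truth.

The generative chain for one mother-season:

1. true parturition mass M1 ~ Normal(mass_mean, mass_sd);
2. logit(true proportion) = x'b + u_year + u_mother + e  ->  M3 = M1 (1 - p);
3. the day-20 mass interpolates linearly in measurement days between M1 and M3;
4. logit(true efficiency) likewise  ->  pup mid mass = pup birth mass +
   e_transfer * (M1 - M2);
5. true weaning mass from the kg-scale weaning model, redrawn (bounded
   retries) if it would fall below the mid-lactation pup mass.

The same design builder used for fitting computes x, so the generative and
inferential linear predictors agree by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (RESPONSES, STATUS_LEVELS, ConfigurationError, ModelSpec,
                     SimulationConfig)
from .design import StandardizationTable, build_design, build_standardization

logger = logging.getLogger(__name__)

_MAX_WEANING_RETRIES = 500


@dataclass(frozen=True)
class SyntheticTruth:
    """All latent state behind a synthetic colony."""

    config: SimulationConfig
    mothers: pd.DataFrame          # id, cohort, afr, u_<response> columns
    year_effects: pd.DataFrame     # year, u_<response> columns
    observations: pd.DataFrame     # true observation table (see generate_seasons)
    standardization: StandardizationTable

    @property
    def true_betas(self) -> dict:
        return {r: dict(self.config.true_coefficients[r]) for r in RESPONSES}


def _spec_for_truth(response: str, coeffs: dict) -> ModelSpec:
    if "age2" in coeffs:
        age_form = "quadratic"
    elif "ln_age" in coeffs:
        age_form = "log"
    elif "age" in coeffs:
        age_form = "linear"
    else:
        age_form = "null"
    has_bd = "birthdate" in coeffs
    from .config import default_covariates
    return ModelSpec(response=response, age_form=age_form,
                     covariates=default_covariates(response),
                     include_birthdate_quadratic=has_bd)


def generate_population(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the mother table: id, cohort, AFR, per-response individual effects.

    Also draws each mother's first observed season (year within the study,
    age, previous-year status), which anchors her cohort.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_mothers
    afr = rng.choice(config.afr_values, size=n, p=np.asarray(config.afr_probs))
    first_year = rng.integers(0, config.n_years, size=n)

    is_first_breeding = rng.random(n) < config.first_breeding_prob
    gap_n, gap_mean = config.experience_gap
    gaps = rng.negative_binomial(gap_n, gap_n / (gap_n + gap_mean), size=n)
    first_age = np.where(is_first_breeding, afr,
                         np.minimum(afr + 1 + gaps, config.max_age))
    status = np.empty(n, dtype=object)
    status[is_first_breeding] = "prebreeder_last_year"
    experienced = ~is_first_breeding
    just_primiparous = experienced & (first_age == afr + 1)
    status[just_primiparous] = "first_time_last_year"
    rest = experienced & ~just_primiparous
    skipped = rng.random(n) < config.skip_prob
    status[rest & skipped] = "experienced_skipped"
    status[rest & ~skipped] = "experienced_bred"

    mothers = pd.DataFrame({
        "mother_id": [f"M{i:04d}" for i in range(n)],
        "afr": afr.astype(int),
        "first_year": config.first_year + first_year,
        "first_age": first_age.astype(int),
        "first_status": status,
    })
    mothers["cohort"] = mothers["first_year"] - mothers["first_age"]
    for r in RESPONSES:
        mothers[f"u_{r}"] = rng.normal(0.0, config.sigma_individual[r], size=n)
    return mothers


def generate_seasons(mothers: pd.DataFrame,
                     config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Unroll each mother's observed seasons and generate the full truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    years = np.arange(config.first_year, config.first_year + config.n_years)
    year_eff = pd.DataFrame({"year": years})
    for r in RESPONSES:
        year_eff[f"u_{r}"] = rng.normal(0.0, config.sigma_year[r], size=len(years))

    rows = []
    last_year = years[-1]
    for m in mothers.itertuples(index=False):
        year, age, status = int(m.first_year), int(m.first_age), m.first_status
        first_ever = status == "prebreeder_last_year"
        while True:
            rows.append((m.mother_id, year, age, int(m.afr), status))
            if rng.random() >= config.repeat_prob:
                break
            step = 1 if rng.random() < config.consecutive_prob else 2
            year, age = year + step, age + step
            if year > last_year or age > config.max_age:
                break
            if step == 1:
                status = "first_time_last_year" if first_ever else "experienced_bred"
            else:
                status = "experienced_skipped"
            first_ever = False
    obs = pd.DataFrame(rows, columns=["mother_id", "year", "maternal_age",
                                      "afr", "status_prev"])
    n = len(obs)
    obs.insert(0, "obs_id", [f"obs{i:05d}" for i in range(n)])

    # covariates
    obs["birthdate"] = np.clip(np.rint(rng.normal(
        config.birthdate_mean, config.birthdate_sd, size=n)), 1, 60).astype(int)
    obs["pup_sex"] = np.where(rng.random(n) < 0.5, "M", "F")
    (w1, w2, w3) = config.measurement_window_days
    obs["day_birth"] = rng.integers(w1[0], w1[1] + 1, size=n)
    obs["day_mid"] = rng.integers(w2[0], w2[1] + 1, size=n)
    obs["day_late"] = rng.integers(w3[0], w3[1] + 1, size=n)
    obs["true_pup_mass_birth"] = np.maximum(
        rng.normal(config.pup_birth_mean, config.pup_birth_sd, size=n), 8.0)
    obs["true_mass_birth"] = np.maximum(
        rng.normal(config.mass_mean, config.mass_sd, size=n), 150.0)

    # design shared with the fitter; mass column reads maternal_mass_birth
    frame = obs.copy()
    frame["maternal_mass_birth"] = obs["true_mass_birth"]
    frame["pup_mass_birth"] = obs["true_pup_mass_birth"]
    std = build_standardization(frame)

    u_year = {r: year_eff.set_index("year")[f"u_{r}"] for r in RESPONSES}
    u_ind = {r: mothers.set_index("mother_id")[f"u_{r}"] for r in RESPONSES}
    lp = {}
    for r in RESPONSES:
        coeffs = config.true_coefficients[r]
        spec = _spec_for_truth(r, coeffs)
        x, labels = build_design(frame, spec, std)
        missing = set(coeffs) - set(labels)
        if missing:
            raise ConfigurationError(
                f"true_coefficients[{r!r}] has unknown terms {sorted(missing)}")
        beta = np.array([coeffs.get(lab, 0.0) for lab in labels])
        lp[r] = (x @ beta
                 + u_year[r].loc[obs["year"]].to_numpy()
                 + u_ind[r].loc[obs["mother_id"]].to_numpy())

    # proportion -> M3, M2
    z_p = lp["proportion"] + rng.normal(0, config.sigma_residual["proportion"], n)
    p = expit(z_p)
    m1 = obs["true_mass_birth"].to_numpy()
    m3 = m1 * (1.0 - p)
    frac = ((obs["day_mid"] - obs["day_birth"])
            / (obs["day_late"] - obs["day_birth"])).to_numpy(dtype=float)
    m2 = m1 - (m1 - m3) * frac

    # efficiency -> pup mid mass
    sigma_e = config.sigma_residual["efficiency"]
    z_e = lp["efficiency"] + rng.normal(0, sigma_e, n)
    eff = expit(z_e)
    pup_birth = obs["true_pup_mass_birth"].to_numpy()
    pup_mid = pup_birth + eff * (m1 - m2)

    # weaning model in kg; if a draw falls below the mid-lactation pup mass
    # (a biologically impossible trajectory) both the efficiency and the
    # weaning residual are redrawn, a bounded number of times
    sigma_w = config.sigma_residual["weaning"]
    pup_late = lp["weaning"] + rng.normal(0, sigma_w, n)
    for _ in range(_MAX_WEANING_RETRIES):
        bad = pup_late <= pup_mid
        if not bad.any():
            break
        nb = int(bad.sum())
        z_e[bad] = lp["efficiency"][bad] + rng.normal(0, sigma_e, nb)
        eff = expit(z_e)
        pup_mid = pup_birth + eff * (m1 - m2)
        pup_late[bad] = lp["weaning"][bad] + rng.normal(0, sigma_w, nb)
    else:
        raise ConfigurationError(
            "could not draw weaning masses above mid-lactation pup masses; "
            "check weaning intercept / sigma_residual configuration")

    obs["true_mass_mid"] = m2
    obs["true_mass_late"] = m3
    obs["true_proportion"] = p
    obs["true_efficiency"] = eff
    obs["true_pup_mass_mid"] = pup_mid
    obs["true_pup_mass_late"] = pup_late
    return SyntheticTruth(config=config, mothers=mothers, year_effects=year_eff,
                          observations=obs, standardization=std)


def apply_measurement_error(truth: SyntheticTruth,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Perturb true masses into the observation table the pipeline reads.

    Maternal masses get zero-mean normal photogrammetric error and carry
    its SD as their prediction SE; pup (platform) masses get
    ``platform_error_sd`` (0 by default: error-free scales).
    """
    config = truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    obs = truth.observations
    n = len(obs)
    out = obs[["obs_id", "mother_id", "year", "maternal_age", "afr",
               "status_prev", "birthdate", "pup_sex",
               "day_birth", "day_mid", "day_late"]].copy()
    pe, se_col = config.photo_error_sd, float(config.photo_error_sd)
    for occ in ("birth", "mid", "late"):
        true = obs[f"true_mass_{occ}"].to_numpy()
        out[f"maternal_mass_{occ}"] = true + rng.normal(0, pe, n) if pe > 0 else true
        out[f"maternal_se_{occ}"] = se_col
    ppe = config.platform_error_sd
    for occ in ("birth", "mid", "late"):
        true = obs[f"true_pup_mass_{occ}"].to_numpy()
        out[f"pup_mass_{occ}"] = true + rng.normal(0, ppe, n) if ppe > 0 else true
    return out


def generate_colony(config: SimulationConfig):
    """Population -> seasons -> measurement error, all from ``config.seed``.

    Returns ``(observations, truth)``: the error-contaminated observation
    table the pipeline reads and the truth sidecar behind it.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(3)]
    mothers = generate_population(config, rngs[0])
    truth = generate_seasons(mothers, config, rngs[1])
    observed = apply_measurement_error(truth, rngs[2])
    return observed, truth
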
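"""End-to-end orchestration: tables in, results bundle out.

A suite run mirrors the study protocol: candidate age forms (null /
linear / log / quadratic) are fitted *without* birthdate terms and scored
by leave-one-out BPIC; the top model is then refit with the quadratic
birthdate terms added (they were a late addition to the top model, after
selection), and that refit supplies coefficient tables, random-effect
summaries, reference predictions, convergence diagnostics and the
goodness-of-fit p-value.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import (AGE_FORMS, STATUS_LEVELS, ConfigurationError,
                     McmcSettings, ModelSpec, PriorSpec, ReferenceProfile)
from .model import AllocationModel, eligible_mask, predict_reference
from .selection import bpic, selection_table

logger = logging.getLogger(__name__)

#: canonical observation-table columns, one row per mother-season
OBSERVATION_COLUMNS = [
    "obs_id", "mother_id", "year", "maternal_age", "afr", "status_prev",
    "birthdate", "pup_sex", "day_birth", "day_mid", "day_late",
    "maternal_mass_birth", "maternal_se_birth", "maternal_mass_mid",
    "maternal_se_mid", "maternal_mass_late", "maternal_se_late",
    "pup_mass_birth", "pup_mass_mid", "pup_mass_late",
]

_REQUIRED = ["obs_id", "mother_id", "year", "maternal_age", "afr",
             "status_prev", "pup_sex", "maternal_mass_birth"]


def read_observations(path) -> pd.DataFrame:
    """Read a delimited observation table, validate it, and attach
    per-suite eligibility flags (``eligible_<response>`` columns)."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ConfigurationError(f"observation table missing columns {missing}")
    status = df["status_prev"].astype(str)
    bad = ~status.isin(STATUS_LEVELS)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ConfigurationError(
            f"unknown status level {status[bad].iloc[0]!r} at line {line}")
    sex = df["pup_sex"].astype(str)
    bad = ~sex.isin(["F", "M"])
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ConfigurationError(
            f"unknown pup_sex {sex[bad].iloc[0]!r} at line {line}")
    for col in ("maternal_age", "afr", "maternal_mass_birth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ConfigurationError(f"malformed {col} at line {line}")
        df[col] = vals
    for response in ("proportion", "efficiency", "weaning"):
        spec = ModelSpec(response=response, age_form="null")
        mask = eligible_mask(df, spec)
        df[f"eligible_{response}"] = mask
        logger.info("%s suite: %d eligible, %d excluded", response,
                    int(mask.sum()), int((~mask).sum()))
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


@dataclass(frozen=True)
class SuiteConfig:
    """One response suite's run plan."""

    response: str
    age_forms: tuple = ("null", "linear", "log", "quadratic")
    seed: int = 0
    scale: float = 1.0
    n_chains: int = 3
    loocv_iter: int = 10_000
    loocv_burn: int = 1_000
    min_rows: int = 30
    reference_ages: tuple = (8.0, 17.0, 26.0)
    reference_masses: tuple = (350.0, 450.0, 550.0)
    reference_birthdates: tuple = (20.0, 27.0, 37.0)

    def __post_init__(self) -> None:
        if not self.age_forms:
            raise ConfigurationError("candidate age-form set is empty")
        for form in self.age_forms:
            if form not in AGE_FORMS:
                raise ConfigurationError(f"unknown age form {form!r}")

    def mcmc(self) -> McmcSettings:
        return McmcSettings.for_response(self.response, seed=self.seed,
                                         scale=self.scale,
                                         n_chains=self.n_chains)

    def mcmc_loocv(self) -> McmcSettings:
        return McmcSettings(n_chains=1, n_iter=self.loocv_iter,
                            n_burn=self.loocv_burn, seed=self.seed + 1,
                            scale=self.scale)


@dataclass
class ResultsBundle:
    """Everything a suite run produced, as plain tables plus provenance."""

    response: str
    coefficients: pd.DataFrame
    selection: pd.DataFrame
    random_effects: pd.DataFrame
    predictions: pd.DataFrame
    diagnostics: pd.DataFrame
    gof_p: float
    top_age_form: str
    n_observations: int
    provenance: dict = field(default_factory=dict)


def _sigma_summary(draws, mass: float = 0.90) -> pd.DataFrame:
    from . import diagnostics as diag
    rows = []
    names = [("sigma_resid", True),
             ("sigma_year", "year" in draws.spec.random_effects),
             ("sigma_ind", "individual" in draws.spec.random_effects)]
    for name, used in names:
        if not used:
            continue
        x = draws.flat(name)
        interval = diag.hdi(x, mass=mass)
        rows.append({"component": name, "mean": float(x.mean()),
                     "sd": float(x.std(ddof=1)),
                     "hdi_lower": interval.lower, "hdi_upper": interval.upper})
    return pd.DataFrame(rows)


def _prediction_table(model, draws, suite: SuiteConfig) -> pd.DataFrame:
    std = draws.standardization
    rows = []

    def add(tag, profile, quantity="response"):
        summ = predict_reference(draws, model.spec, std, profile,
                                 quantity=quantity)
        rows.append({"profile": tag, "quantity": quantity,
                     "mean": summ.mean, "hdi_lower": summ.hdi_lower,
                     "hdi_upper": summ.hdi_upper})

    add("reference", ReferenceProfile())
    for age in suite.reference_ages:
        add(f"age_{age:g}", ReferenceProfile(maternal_age=age))
    for kg in suite.reference_masses:
        add(f"mass_{kg:g}", ReferenceProfile(maternal_mass=kg))
        if model.spec.response == "proportion":
            add(f"mass_{kg:g}", ReferenceProfile(maternal_mass=kg),
                "kg_allocated")
    if model.spec.include_birthdate_quadratic:
        for bd in suite.reference_birthdates:
            add(f"birthdate_{bd:g}", ReferenceProfile(birthdate=bd))
    for status in STATUS_LEVELS[1:]:
        add(f"status_{status}", ReferenceProfile(status_prev=status))
    return pd.DataFrame(rows)


def run_suite(observations: pd.DataFrame, suite: SuiteConfig) -> ResultsBundle:
    """Fit all candidate age forms, select by BPIC, refit the top model
    with birthdate terms, and assemble the results bundle."""
    t0 = time.time()
    spec0 = ModelSpec(response=suite.response, age_form="null")
    n_eligible = int(eligible_mask(observations, spec0).sum())
    if n_eligible < suite.min_rows:
        raise ConfigurationError(
            f"{suite.response} suite has {n_eligible} eligible rows; "
            f"floor is {suite.min_rows}")

    mcmc, mcmc_loo = suite.mcmc(), suite.mcmc_loocv()
    results, fits, models = [], {}, {}
    for form in suite.age_forms:
        spec = ModelSpec(response=suite.response, age_form=form)
        model = AllocationModel(observations, spec)
        draws = model.fit(replace(mcmc, seed=mcmc.seed + 100 * AGE_FORMS.index(form)))
        models[form], fits[form] = model, draws
        if not draws.converged:
            logger.warning("%s/%s flagged non-converged; excluded from "
                           "selection", suite.response, form)
            continue
        warm = draws.final_states[0]
        results.append(bpic(model, mcmc_loo, label=form, warm_state=warm))
    if not results:
        raise ConfigurationError("no candidate model converged")
    sel = selection_table(results)
    top_form = sel.loc[sel["is_top"], "model"].iloc[0]

    # phase 2: add the quadratic birthdate terms to the selected model
    top_spec = ModelSpec(response=suite.response,
                         age_form=top_form).with_birthdate()
    top_model = AllocationModel(observations, top_spec)
    top_draws = top_model.fit(replace(mcmc, seed=mcmc.seed + 9000))

    gof = top_model.gof(top_draws,
                        rng=np.random.default_rng(suite.seed + 17))
    diag_rows = top_draws.psrf.copy() if top_draws.psrf is not None \
        else pd.DataFrame(columns=["parameter", "psrf", "pass"])
    if top_draws.geweke_z:
        diag_rows["geweke_max_abs_z"] = diag_rows["parameter"].map(
            top_draws.geweke_z)

    bundle = ResultsBundle(
        response=suite.response,
        coefficients=top_draws.coefficient_table(),
        selection=sel,
        random_effects=_sigma_summary(top_draws),
        predictions=_prediction_table(top_model, top_draws, suite),
        diagnostics=diag_rows,
        gof_p=gof.p_value,
        top_age_form=top_form,
        n_observations=top_model.n_units,
        provenance={
            "seed": suite.seed, "scale": suite.scale,
            "version": _version,
            "converged": bool(top_draws.converged),
            "config_hash": hashlib.sha256(
                repr(suite).encode()).hexdigest()[:16],
            "runtime_s": round(time.time() - t0, 2),
        })
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir) -> list:
    """Write the bundle as delimited text plus a JSON manifest.

    Re-reading the tables reproduces the numbers to full precision
    (floats are written with 17 significant digits).
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("coefficients", "selection", "random_effects",
                 "predictions", "diagnostics"):
        path = out / f"{bundle.response}_{name}.csv"
        getattr(bundle, name).to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    manifest = {
        "response": bundle.response,
        "top_age_form": bundle.top_age_form,
        "n_observations": bundle.n_observations,
        "gof_p": bundle.gof_p,
        "provenance": bundle.provenance,
    }
    mpath = out / f"{bundle.response}_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    written.append(mpath)
    return written
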
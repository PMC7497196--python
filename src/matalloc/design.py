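"""Design construction: responses, 2-SD standardization, design matrices.

Continuous covariates are centred at their sample mean and scaled by twice
their sample SD so that their coefficients are comparable with those of
binary indicators (a standardized column has SD 0.5, the SD of a balanced
0/1 indicator).  Binary indicators pass through unscaled.

One builder serves both the synthetic generator and the fitting machinery,
so generative and inferential linear predictors agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import STATUS_COLUMNS, STATUS_LEVELS, ConfigurationError, ModelSpec

#: continuous design covariates and how to read them off an observation table
_CONTINUOUS_SOURCES = {
    "age": lambda df: df["maternal_age"].to_numpy(dtype=float),
    "ln_age": lambda df: np.log(df["maternal_age"].to_numpy(dtype=float)),
    "afr": lambda df: df["afr"].to_numpy(dtype=float),
    "maternal_mass": lambda df: df["maternal_mass_birth"].to_numpy(dtype=float),
    "birthdate": lambda df: df["birthdate"].to_numpy(dtype=float),
    "measurement_days": lambda df: (df["day_late"] - df["day_birth"]).to_numpy(dtype=float),
    "pup_birth_mass": lambda df: df["pup_mass_birth"].to_numpy(dtype=float),
}


# ---------------------------------------------------------------------------
# responses

def response_proportion(mass_birth, mass_late):
    """Proportion of maternal mass allocated: loss over parturition mass.

    Raw, error-contaminated inputs may produce values outside (0, 1); the
    latent-variable model never does, because latent masses are constrained.
    """
    mass_birth = np.asarray(mass_birth, dtype=float)
    if np.any(mass_birth <= 0):
        raise ValueError("parturition mass must be positive")
    return (mass_birth - np.asarray(mass_late, dtype=float)) / mass_birth


def response_efficiency(pup_birth, pup_mid, mass_birth, mass_mid,
                        day_birth, day_mid):
    """Mass transfer efficiency: pup daily gain over maternal daily loss.

    Both rates are taken over the shared early-lactation interval, so the
    day offsets cancel algebraically; they are accepted to document the
    construction and to validate the interval.
    """
    day_span = np.asarray(day_mid, dtype=float) - np.asarray(day_birth, dtype=float)
    if np.any(day_span <= 0):
        raise ValueError("day_mid must be after day_birth")
    loss = np.asarray(mass_birth, dtype=float) - np.asarray(mass_mid, dtype=float)
    gain = np.asarray(pup_mid, dtype=float) - np.asarray(pup_birth, dtype=float)
    out = np.divide(gain, loss, out=np.full(np.shape(loss), np.nan, dtype=float),
                    where=loss != 0)
    return out


# ---------------------------------------------------------------------------
# standardization

@dataclass(frozen=True)
class StandardizationTable:
    """Centers (means) and scales (2 x SD) for continuous covariates."""

    centers: dict
    scales: dict

    def standardize(self, name: str, values):
        return (np.asarray(values, dtype=float) - self.centers[name]) / self.scales[name]

    def center(self, name: str) -> float:
        return self.centers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.centers

    def to_frame(self) -> pd.DataFrame:
        names = sorted(self.centers)
        return pd.DataFrame({"covariate": names,
                             "center": [self.centers[n] for n in names],
                             "scale": [self.scales[n] for n in names]})


def build_standardization(observations: pd.DataFrame,
                          names=None) -> StandardizationTable:
    """Compute centers and 2-SD scales for the continuous covariates.

    Maternal parturition mass is standardized using its raw point
    estimates; the centers and scales are held fixed during MCMC even
    though the mass covariate itself is latent.
    """
    if names is None:
        names = [n for n, src in _CONTINUOUS_SOURCES.items()
                 if _source_available(observations, n)]
    centers, scales = {}, {}
    for name in names:
        values = _CONTINUOUS_SOURCES[name](observations)
        values = values[np.isfinite(values)]
        if len(np.unique(values)) < 2:
            raise ConfigurationError(f"covariate {name!r} is constant; cannot scale")
        center = float(np.mean(values))
        scale = float(2.0 * np.std(values, ddof=1))
        if not scale > 1e-12 * max(1.0, abs(center)):
            raise ConfigurationError(
                f"covariate {name!r} is effectively constant; cannot scale")
        centers[name] = center
        scales[name] = scale
    return StandardizationTable(centers=centers, scales=scales)


def _source_available(df: pd.DataFrame, name: str) -> bool:
    needed = {"age": ["maternal_age"], "ln_age": ["maternal_age"],
              "afr": ["afr"], "maternal_mass": ["maternal_mass_birth"],
              "birthdate": ["birthdate"],
              "measurement_days": ["day_late", "day_birth"],
              "pup_birth_mass": ["pup_mass_birth"]}[name]
    return all(c in df.columns and df[c].notna().any() for c in needed)


# ---------------------------------------------------------------------------
# design matrix

def design_columns(spec: ModelSpec) -> list[str]:
    """Ordered design-column labels for a model spec (intercept first)."""
    cols = ["intercept"]
    if spec.age_form == "linear":
        cols.append("age")
    elif spec.age_form == "quadratic":
        cols += ["age", "age2"]
    elif spec.age_form == "log":
        cols.append("ln_age")
    cols += list(spec.covariates)
    if spec.include_birthdate_quadratic:
        cols += ["birthdate", "birthdate2"]
    return cols


_BINARY_COLUMNS = {"pup_sex_M"} | set(STATUS_COLUMNS.values())


def build_design(observations: pd.DataFrame, spec: ModelSpec,
                 standardization: StandardizationTable):
    """Build the fixed-effects design matrix for ``spec``.

    Returns ``(X, labels)``; quadratic terms are squares of the already
    standardized linear terms, categorical status expands to indicators
    against the experienced-bred reference level.
    """
    labels = design_columns(spec)
    n = len(observations)
    cols = []
    for label in labels:
        if label == "intercept":
            cols.append(np.ones(n))
        elif label in ("age2", "birthdate2"):
            base = label[:-1]
            z = standardization.standardize(base, _CONTINUOUS_SOURCES[base](observations))
            cols.append(z ** 2)
        elif label in _CONTINUOUS_SOURCES:
            if label not in standardization:
                raise ConfigurationError(f"no standardization for covariate {label!r}")
            cols.append(standardization.standardize(
                label, _CONTINUOUS_SOURCES[label](observations)))
        elif label in _BINARY_COLUMNS:
            cols.append(_binary_column(observations, label))
        else:
            raise ConfigurationError(f"unknown covariate {label!r}")
    return np.column_stack(cols), labels


def _binary_column(df: pd.DataFrame, label: str) -> np.ndarray:
    if label == "pup_sex_M":
        sex = df["pup_sex"].astype(str)
        bad = ~sex.isin(["F", "M"])
        if bad.any():
            raise ConfigurationError(
                f"unknown pup_sex value(s) {sorted(sex[bad].unique())}")
        return (sex == "M").to_numpy(dtype=float)
    status = df["status_prev"].astype(str)
    bad = ~status.isin(STATUS_LEVELS)
    if bad.any():
        raise ConfigurationError(
            f"unknown status level(s) {sorted(status[bad].unique())}")
    level = {v: k for k, v in STATUS_COLUMNS.items()}[label]
    return (status == level).to_numpy(dtype=float)


def profile_row(profile, spec: ModelSpec,
                standardization: StandardizationTable) -> np.ndarray:
    """A single design row for a reference profile (random effects zero)."""
    values = {
        "maternal_age": profile.maternal_age, "afr": profile.afr,
        "maternal_mass_birth": profile.maternal_mass,
        "birthdate": profile.birthdate,
        "pup_mass_birth": profile.pup_birth_mass,
    }
    # fill "mean" requests from the standardization centers
    fills = {"maternal_age": "age", "afr": "afr",
             "maternal_mass_birth": "maternal_mass", "birthdate": "birthdate",
             "pup_mass_birth": "pup_birth_mass"}
    for col, std_name in fills.items():
        if values[col] is None and std_name in standardization:
            values[col] = standardization.center(std_name)
    df = pd.DataFrame({k: [v] for k, v in values.items()})
    df["pup_sex"] = profile.pup_sex
    df["status_prev"] = profile.status_prev
    md = profile.measurement_days
    if md is None and "measurement_days" in standardization:
        md = standardization.center("measurement_days")
    df["day_birth"] = 0.0
    df["day_late"] = md if md is not None else 0.0
    x, _ = build_design(df, spec, standardization)
    return x[0]
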
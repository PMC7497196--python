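"""Photogrammetric mass calibration.

Morphometric measurements taken from photographs (a scalar for the 2D
technique, optionally a small vector for the 3D technique) are related to
platform-weighed masses by ordinary least squares.  The fitted line turns a
new morphometric measurement into a mass estimate, and the textbook
prediction variance for a new observation — residual variance plus
coefficient-estimation variance — becomes the estimate's standard error,
which downstream models propagate as measurement error on maternal mass.

Image processing (extracting the morphometric from photographs) is out of
scope; calibration starts from the scalar/vector measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ConfigurationError, MassEstimate

PHOTO_METHODS = ("photo2D", "photo3D")


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationFit:
    """An OLS mass-estimation fit with the sufficient statistics needed to
    compute prediction variances for new points.

    ``xtx_inv`` is (X'X)^{-1} for the design including the intercept, so
    the prediction SE at x0 is residual_sd * sqrt(1 + x0' (X'X)^{-1} x0).
    """

    method: str
    coefficients: np.ndarray  # (intercept, slope(s))
    residual_sd: float
    n: int
    xtx_inv: np.ndarray
    x_mean: np.ndarray

    @property
    def n_predictors(self) -> int:
        return len(self.coefficients) - 1

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficients": self.coefficients.tolist(),
            "residual_sd": self.residual_sd,
            "n": self.n,
            "xtx_inv": self.xtx_inv.tolist(),
            "x_mean": self.x_mean.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(method=d["method"],
                   coefficients=np.asarray(d["coefficients"], dtype=float),
                   residual_sd=float(d["residual_sd"]), n=int(d["n"]),
                   xtx_inv=np.asarray(d["xtx_inv"], dtype=float),
                   x_mean=np.asarray(d["x_mean"], dtype=float))


def _as_predictor_matrix(morphometric) -> np.ndarray:
    x = np.asarray(morphometric, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise CalibrationError("morphometric must be a vector or 2-D array")
    if not np.all(np.isfinite(x)):
        raise CalibrationError("non-finite morphometric values")
    return x


def fit_calibration(samples: pd.DataFrame) -> CalibrationFit:
    """Fit an OLS calibration relating morphometrics to platform mass.

    ``samples`` must contain columns ``method``, ``platform_mass`` and one
    or more ``morphometric*`` columns; all rows must share one method.
    """
    methods = samples["method"].unique()
    if len(methods) != 1:
        raise CalibrationError(f"mixed calibration methods: {sorted(methods)}")
    method = str(methods[0])
    if method not in PHOTO_METHODS:
        raise CalibrationError(f"unknown photogrammetric method {method!r}")
    morph_cols = [c for c in samples.columns if c.startswith("morphometric")]
    if not morph_cols:
        raise CalibrationError("no morphometric columns found")
    x = _as_predictor_matrix(samples[morph_cols].to_numpy())
    y = samples["platform_mass"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise CalibrationError("platform masses must be positive")
    n, k = x.shape
    if n < max(3, k + 2):
        raise CalibrationError(f"need at least {max(3, k + 2)} samples, got {n}")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CalibrationError("rank-deficient calibration design")
    res = sm.OLS(y, design).fit()
    residual_sd = float(np.sqrt(res.scale))  # unbiased residual variance
    xtx_inv = np.linalg.inv(design.T @ design)
    return CalibrationFit(method=method, coefficients=np.asarray(res.params),
                          residual_sd=residual_sd, n=n, xtx_inv=xtx_inv,
                          x_mean=x.mean(axis=0))


def predict_mass(fit: CalibrationFit, morphometric) -> MassEstimate:
    """Predict mass (kg) for a new morphometric measurement.

    The SE is the prediction standard error for a *new* observation:
    ``residual_sd * sqrt(1 + x0' (X'X)^{-1} x0)`` with x0 including the
    intercept, so it is never smaller than the residual SD and grows with
    distance from the training mean.
    """
    x0 = np.atleast_1d(np.asarray(morphometric, dtype=float))
    if x0.ndim != 1 or len(x0) != fit.n_predictors:
        raise CalibrationError(
            f"expected {fit.n_predictors} morphometric value(s), got {x0.shape}")
    if not np.all(np.isfinite(x0)):
        raise CalibrationError("non-finite morphometric input")
    row = np.concatenate(([1.0], x0))
    value = float(row @ fit.coefficients)
    se = float(fit.residual_sd * np.sqrt(1.0 + row @ fit.xtx_inv @ row))
    if value <= 0:
        raise CalibrationError(
            f"calibration predicts non-positive mass ({value:.1f} kg) at {x0}")
    return MassEstimate(value=value, se=se, method=fit.method)


def read_calibration_table(path) -> pd.DataFrame:
    """Read a delimited calibration table (method, morphometric*, platform_mass)."""
    df = pd.read_csv(path)
    required = {"method", "platform_mass"}
    missing = required - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration table missing columns {sorted(missing)}")
    return df
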
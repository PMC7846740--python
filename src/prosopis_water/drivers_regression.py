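"""Multiple linear regression of daily water use on micrometeorological drivers.

The model is the fixed five-predictor OLS used throughout the field:
response ~ solar radiation + wind speed + soil moisture + VPD + ETo, fitted
at the daily grain with an intercept, reported as an estimate / standard
error / t / p table plus overall fit statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._met import vpd as _vpd

__all__ = ["DEFAULT_PREDICTORS", "compute_vpd", "fit_drivers", "DriversFit"]

DEFAULT_PREDICTORS = (
    "solar_radiation",  # MJ/m^2/day
    "wind_speed",       # m/s
    "soil_moisture",    # volumetric %
    "vpd",              # kPa
    "eto",              # mm/day
)


def compute_vpd(t_c, rh_pct):
    """Vapour pressure deficit, kPa, from air temperature and RH (FAO-56 es)."""
    return _vpd(t_c, rh_pct)


@dataclass(frozen=True)
class DriversFit:
    """OLS fit of a water-use response on the five standard drivers."""

    response: str
    coefficients: pd.DataFrame  # index: term; columns: Estimate, Std. Error, t value, Pr(>|t|)
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    residual_se: float
    df_resid: int
    n_obs: int

    def to_csv(self, path) -> None:
        self.coefficients.to_csv(path, index_label="term")


def _collinear_columns(x: pd.DataFrame) -> list[str]:
    """Columns that do not increase the design rank when added in order."""
    cols: list[str] = []
    acc = np.ones((len(x), 1))
    rank = 1
    for name in x.columns:
        cand = np.column_stack([acc, x[name].to_numpy(dtype=float)])
        r = np.linalg.matrix_rank(cand)
        if r == rank:
            cols.append(name)
        else:
            acc, rank = cand, r
    return cols


def fit_drivers(matrix: pd.DataFrame, response: str,
                predictors: tuple[str, ...] = DEFAULT_PREDICTORS) -> DriversFit:
    """Fit response ~ intercept + predictors by OLS on complete daily rows.

    Raises when fewer than ``len(predictors) + 2`` rows remain or when the
    design is rank-deficient (the offending collinear columns are named).
    """
    cols = [response, *predictors]
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"driver matrix missing columns: {missing}")
    data = matrix[cols].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} complete rows, got {len(data)}"
        )
    x = data[list(predictors)]
    design = sm.add_constant(x.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(x)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    model = sm.OLS(data[response].to_numpy(dtype=float), design).fit()
    terms = ["(Intercept)", *predictors]
    coef = pd.DataFrame(
        {
            "Estimate": model.params,
            "Std. Error": model.bse,
            "t value": model.tvalues,
            "Pr(>|t|)": model.pvalues,
        },
        index=terms,
    )
    return DriversFit(
        response=response,
        coefficients=coef,
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        residual_se=float(np.sqrt(model.mse_resid)),
        df_resid=int(model.df_resid),
        n_obs=int(model.nobs),
    )
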
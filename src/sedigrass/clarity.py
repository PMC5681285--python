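"""Water clarity and benthic light.

The chain is: a linear model predicts Secchi depth Z_SD (m) from the monthly
bay-wide sediment load S and three static spatial covariates (depth z,
distance to open ocean D_O, distance to river mouths D_R); Secchi depth maps
to the diffuse attenuation coefficient K_d = lambda / Z_SD (lambda ~ 1.7);
percent benthic irradiance follows Lambert-Beer, I(z)/I0 = exp(-K_d z); and
the habitat model consumes L, the log of mean percent irradiance over a
trailing window (default the 6 months before the mapping date).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .grid import BayGrid
from .reference import LAMBDA, PCT_LIGHT_FLOOR, SECCHI_FLOOR
from .sediment import SedimentSeries

#: Design-column order used throughout.
SECCHI_FEATURES = ("sediment", "depth", "d_ocean", "d_river")


def _find_collinear(X: np.ndarray, names: tuple[str, ...]) -> str:
    """Name one column that is (near-)linearly dependent on the others."""
    Xc = np.column_stack([np.ones(len(X)), X])
    for j, name in enumerate(names):
        others = np.delete(Xc, j + 1, axis=1)
        coef, *_ = np.linalg.lstsq(others, Xc[:, j + 1], rcond=None)
        resid = Xc[:, j + 1] - others @ coef
        scale = np.linalg.norm(Xc[:, j + 1]) + 1e-30
        if np.linalg.norm(resid) / scale < 1e-10:
            return name
    return names[0]


class SecchiLinearModel(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares model of Secchi depth.

    Design matrix columns are ``(sediment, depth, d_ocean, d_river)`` in that
    order; no interaction terms are used.  Observations at or below the
    reporting floor are treated as left-censored and dropped before fitting,
    which keeps the fit unbiased by clamped values.

    Parameters
    ----------
    floor : minimum physically reported Secchi depth (m); predictions are
        clamped here and near-floor observations are excluded from the fit.
    drop_floored : exclude observations <= floor + 1e-9 from the fit.

    Attributes (after fit)
    ----------------------
    intercept_ : float
    coef_ : ndarray of shape (4,), aligned with ``SECCHI_FEATURES``.
    bse_ : standard errors (intercept first, then features).
    adj_r2_ : adjusted R-squared.
    n_obs_ : observations used in the fit.
    """

    def __init__(self, floor: float = SECCHI_FLOOR, drop_floored: bool = True):
        self.floor = floor
        self.drop_floored = drop_floored

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(SECCHI_FEATURES):
            raise ValueError(f"X must have columns {SECCHI_FEATURES}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.drop_floored:
            keep = y > self.floor + 1e-9
            X, y = X[keep], y[keep]
        if len(y) < len(SECCHI_FEATURES) + 2:
            raise ValueError("too few usable observations to fit the Secchi model")
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "rank-deficient design: column "
                f"{_find_collinear(X, SECCHI_FEATURES)!r} is collinear "
                "(e.g. a single month makes sediment confounded with the intercept)"
            )
        res = sm.OLS(y, design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.bse_ = np.asarray(res.bse, dtype=float)
        self.adj_r2_ = float(res.rsquared_adj)
        self.n_obs_ = int(res.nobs)
        return self

    def predict(self, X, clip: bool = True):
        """Linear predictor, clamped below at the reporting floor by default."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        pred = self.intercept_ + X @ self.coef_
        if clip:
            pred = np.maximum(pred, self.floor)
        return pred

    def coefficients(self) -> dict[str, float]:
        check_is_fitted(self, "coef_")
        out = {"intercept": self.intercept_}
        out.update(dict(zip(SECCHI_FEATURES, map(float, self.coef_))))
        return out

    @classmethod
    def from_coefficients(cls, coeffs: dict[str, float], floor: float = SECCHI_FLOOR):
        """Build a pre-fitted model from named coefficients (reference configs)."""
        model = cls(floor=floor)
        model.intercept_ = float(coeffs["intercept"])
        model.coef_ = np.array([coeffs[k] for k in SECCHI_FEATURES], dtype=float)
        model.bse_ = np.full(5, np.nan)
        model.adj_r2_ = float(coeffs.get("adj_r2", np.nan))
        model.n_obs_ = int(coeffs.get("n_obs", 0))
        return model


def assemble_secchi_design(
    obs: pd.DataFrame, grid: BayGrid, monthly: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Join station observations with covariates.

    ``obs`` needs columns ``row, col, month, secchi_m``; sediment S is the
    bay-wide total of the observation's month (one scalar per month), and
    z, D_O, D_R come from the station's cell.
    """
    grid.require_distances()
    months = pd.PeriodIndex(obs["month"])
    S = monthly.reindex(months).to_numpy()
    if np.any(np.isnan(S)):
        raise ValueError("observation months missing from the sediment series")
    r = obs["row"].to_numpy()
    c = obs["col"].to_numpy()
    X = np.column_stack(
        [S, grid.depth[r, c], grid.d_ocean[r, c], grid.d_river[r, c]]
    )
    return X, obs["secchi_m"].to_numpy(dtype=float)


def fit_secchi_model(
    obs: pd.DataFrame, grid: BayGrid, sediment: SedimentSeries, **kwargs
) -> SecchiLinearModel:
    """Fit the Secchi OLS from station observations (>=10 obs over >=2 months)."""
    if len(obs) < 10:
        raise ValueError("need at least 10 Secchi observations")
    if pd.PeriodIndex(obs["month"]).nunique() < 2:
        raise ValueError(
            "rank-deficient design: column 'sediment' is collinear "
            "(observations span a single month)"
        )
    X, y = assemble_secchi_design(obs, grid, sediment.monthly_totals())
    return SecchiLinearModel(**kwargs).fit(X, y)


def predict_secchi_raster(
    model: SecchiLinearModel, s_month: float, grid: BayGrid
) -> np.ndarray:
    """Monthly Secchi-depth raster (m); land cells NaN, floor-clamped."""
    if s_month < 0:
        raise ValueError("monthly sediment load must be non-negative")
    grid.require_distances()
    mask = grid.water_mask
    X = np.column_stack(
        [
            np.full(mask.sum(), s_month),
            grid.depth[mask],
            grid.d_ocean[mask],
            grid.d_river[mask],
        ]
    )
    out = np.full(mask.shape, np.nan)
    out[mask] = model.predict(X)
    return out


def kd_from_secchi(z_sd, lam: float = LAMBDA):
    """Diffuse attenuation coefficient K_d = lambda / Z_SD (1/m)."""
    z_sd = np.asarray(z_sd, dtype=float)
    if np.any(z_sd[np.isfinite(z_sd)] <= 0):
        raise ValueError("Secchi depth must be positive")
    out = lam / z_sd
    return float(out) if out.ndim == 0 else out


def percent_light(kd, z):
    """Percent surface irradiance reaching depth z: 100 * exp(-K_d z)."""
    kd = np.asarray(kd, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(kd[np.isfinite(kd)] < 0):
        raise ValueError("K_d must be non-negative")
    if np.any(z[np.isfinite(z)] < 0):
        raise ValueError("depth must be non-negative")
    out = 100.0 * np.exp(-kd * z)
    return float(out) if out.ndim == 0 else out


def light_history(
    pct_stack: np.ndarray,
    t: int,
    window: int = 6,
    include_current: bool = False,
    log_base: str = "e",
    floor: float = PCT_LIGHT_FLOOR,
) -> np.ndarray:
    """Log of mean percent benthic irradiance over the trailing window.

    Averages ``pct_stack`` over months ``t-window .. t-1`` (or ``.. t`` when
    ``include_current``), using whatever subset of those months exists
    (at least one), then takes the log of the mean — never the mean of logs.
    """
    pct_stack = np.asarray(pct_stack, dtype=float)
    hi = t + 1 if include_current else t
    lo = max(0, hi - window)
    if hi <= 0 or lo >= pct_stack.shape[0] or hi > pct_stack.shape[0]:
        raise ValueError(f"no months available before index {t}")
    if hi - lo < 1:
        raise ValueError(f"no months available before index {t}")
    mean_pct = pct_stack[lo:hi].mean(axis=0)
    mean_pct = np.maximum(mean_pct, floor)
    if log_base == "e":
        return np.log(mean_pct)
    if log_base == "10":
        return np.log10(mean_pct)
    raise ValueError(f"unknown log base {log_base!r}")


@dataclass
class LightStack:
    """Monthly clarity/light rasters on one grid.

    ``light`` (L) is defined from the second month onwards (a trailing window
    needs at least one prior month); entries before that are None.
    """

    months: pd.PeriodIndex
    secchi: np.ndarray  # (T, rows, cols)
    kd: np.ndarray
    pct_light: np.ndarray
    light: list  # list of (rows, cols) arrays or None
    lam: float = LAMBDA


def build_light_stack(
    model: SecchiLinearModel,
    grid: BayGrid,
    monthly: pd.Series,
    lam: float = LAMBDA,
    window: int = 6,
    include_current: bool = False,
    log_base: str = "e",
) -> LightStack:
    """Run the clarity chain for every month of a sediment series."""
    months = pd.PeriodIndex(monthly.index)
    secchi = np.stack(
        [predict_secchi_raster(model, float(s), grid) for s in monthly.to_numpy()]
    )
    kd = lam / secchi
    pct = 100.0 * np.exp(-kd * grid.depth[None, :, :])
    light: list = [None] * len(months)
    start = 0 if include_current else 1
    for t in range(start, len(months)):
        light[t] = light_history(
            pct, t, window=window, include_current=include_current, log_base=log_base
        )
    return LightStack(months=months, secchi=secchi, kd=kd, pct_light=pct,
                      light=light, lam=lam)
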
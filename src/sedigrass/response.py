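"""Sediment -> suitable-habitat-area response.

Monthly habitat areas are averaged over each water year's Nov-Mar wet season
(the limiting period for seagrass) and paired with that year's sediment load.
The dose-response is an OLS fit of area on S and/or S^2, with the candidate
set {intercept-only, {S}, {S^2}, {S, S^2}} compared by BIC; the quadratic-only
candidate is included so a pure-S^2 response is reachable.  The sensitivity
analysis repeats the fit across four classification thresholds and two
pairing timescales (annual, monthly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .sediment import WET_MONTHS, SedimentSeries, annual_sediment_estimate, water_year

#: Candidate predictor sets, ordered smallest-first so BIC ties resolve
#: toward the simpler model.
CANDIDATES: tuple[tuple[str, ...], ...] = ((), ("S",), ("S2",), ("S", "S2"))


def _design(S: np.ndarray, terms: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones_like(S)]
    if "S" in terms:
        cols.append(S)
    if "S2" in terms:
        cols.append(S**2)
    return np.column_stack(cols)


class SedimentResponseModel(BaseEstimator, RegressorMixin):
    """Quadratic-family OLS of habitat area on annual sediment load, with
    BIC model simplification.

    BIC is computed as ``n * ln(RSS/n) + k * ln(n)`` with k the number of
    estimated coefficients (intercept included).  The mean-squared residual is
    floored at ``(1e-8 * scale(y))^2`` so that numerically exact fits tie and
    the parameter penalty selects the smaller model.

    Attributes (after fit)
    ----------------------
    included_terms_ : tuple, subset of ("S", "S2") minimising BIC.
    intercept_, coef_s_, coef_s2_ : coefficients (0.0 for excluded terms).
    bic_table_ : dict candidate -> BIC.
    adj_r2_, f_stat_, df_, p_value_ : summaries of the selected fit.
    """

    def __init__(self, candidates: tuple[tuple[str, ...], ...] = CANDIDATES):
        self.candidates = candidates

    def fit(self, S, area):
        S = np.asarray(S, dtype=float).ravel()
        y = np.asarray(area, dtype=float).ravel()
        if len(S) != len(y):
            raise ValueError("S and area length mismatch")
        max_params = 1 + max(len(t) for t in self.candidates)
        if len(y) < max_params + 1:
            raise ValueError(
                f"need at least {max_params + 1} (S, area) pairs to compare candidates"
            )
        n = len(y)
        scale = max(1.0, float(np.sqrt(np.mean(y**2))))
        ms_floor = (1e-8 * scale) ** 2
        # standardise columns internally for conditioning; BIC uses raw residuals
        s_scale = max(1.0, float(np.abs(S).max()))
        bic_table: dict[tuple[str, ...], float] = {}
        fits: dict[tuple[str, ...], np.ndarray] = {}
        for terms in self.candidates:
            X = _design(S / s_scale, terms)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ coef) ** 2))
            k = X.shape[1]
            bic_table[terms] = n * np.log(max(rss / n, ms_floor)) + k * np.log(n)
            fits[terms] = coef
        best = min(bic_table, key=lambda t: (bic_table[t], len(t)))
        coef = fits[best]
        self.included_terms_ = best
        self.intercept_ = float(coef[0])
        i = 1
        self.coef_s_ = 0.0
        self.coef_s2_ = 0.0
        if "S" in best:
            self.coef_s_ = float(coef[i] / s_scale)
            i += 1
        if "S2" in best:
            self.coef_s2_ = float(coef[i] / s_scale**2)
        self.bic_table_ = {"+".join(t) or "1": float(b) for t, b in bic_table.items()}
        self._summaries(S, y, best)
        return self

    def _summaries(self, S, y, terms):
        n = len(y)
        k = len(terms)
        resid = y - self.predict(S)
        rss = float(np.sum(resid**2))
        tss = float(np.sum((y - y.mean()) ** 2))
        if k == 0 or tss == 0:
            self.adj_r2_ = 0.0
            self.f_stat_ = np.nan
            self.df_ = (k, n - k - 1)
            self.p_value_ = np.nan
            return
        r2 = 1.0 - rss / tss
        self.adj_r2_ = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        if rss <= 0:
            self.f_stat_ = np.inf
            self.p_value_ = 0.0
        else:
            self.f_stat_ = ((tss - rss) / k) / (rss / (n - k - 1))
            self.p_value_ = float(stats.f.sf(self.f_stat_, k, n - k - 1))
        self.df_ = (k, n - k - 1)

    def predict(self, S):
        check_is_fitted(self, "included_terms_")
        S = np.asarray(S, dtype=float)
        return self.intercept_ + self.coef_s_ * S + self.coef_s2_ * S**2


def fit_response(S, area, candidates=CANDIDATES) -> SedimentResponseModel:
    """Fit the sediment-area response with BIC candidate selection."""
    return SedimentResponseModel(candidates=candidates).fit(S, area)


def annual_habitat(
    monthly_areas: pd.Series,
    sediment: SedimentSeries,
    method: str = "paper",
) -> pd.DataFrame:
    """Wet-season mean habitat area per water year, paired with annual sediment.

    ``monthly_areas`` is indexed by monthly Period.  For each complete water
    year with all five Nov-Mar areas available, the mean wet-season area is
    paired with the annual sediment estimate (``method`` as in
    :func:`sedigrass.sediment.annual_sediment_estimate`; "exact" uses the
    direct July-June total).
    """
    months = pd.PeriodIndex(monthly_areas.index)
    wet = monthly_areas[months.month.isin(WET_MONTHS)]
    wy = water_year(pd.PeriodIndex(wet.index))
    counts = wet.groupby(wy).count()
    complete = counts.index[counts == len(WET_MONTHS)]
    if len(complete) == 0:
        raise ValueError("no complete Nov-Mar wet season in the monthly areas")
    mean_area = wet.groupby(wy).mean().loc[complete]
    wet_totals = sediment.wet_season_totals()
    annual_totals = sediment.annual_totals("water")
    rows = []
    for year in complete:
        if method == "exact":
            if year not in annual_totals.index:
                continue
            s = float(annual_totals.loc[year])
        else:
            if year not in wet_totals.index:
                continue
            s = annual_sediment_estimate(float(wet_totals.loc[year]), method=method)
        rows.append({"water_year": int(year), "mean_wet_area": float(mean_area.loc[year]),
                     "annual_S": s})
    if not rows:
        raise ValueError("no water year with both habitat and sediment coverage")
    return pd.DataFrame(rows)


def monthly_pairs(monthly_areas: pd.Series, sediment: SedimentSeries) -> pd.DataFrame:
    """Each month's habitat area paired with that month's sediment total."""
    monthly = sediment.monthly_totals()
    months = pd.PeriodIndex(monthly_areas.index)
    S = monthly.reindex(months)
    keep = S.notna().to_numpy()
    return pd.DataFrame(
        {
            "month": months[keep].astype(str),
            "area": monthly_areas.to_numpy()[keep],
            "S": S.to_numpy()[keep],
        }
    )


def sensitivity_analysis(
    areas_by_threshold: dict[str, pd.Series],
    thresholds: dict[str, float],
    sediment: SedimentSeries,
    timescales: tuple[str, ...] = ("annual", "monthly"),
    method: str = "paper",
) -> pd.DataFrame:
    """Response fits for every threshold criterion x timescale combination.

    Returns one row per combination with the selected model's intercept,
    S and S^2 coefficients (0 when excluded), F statistic, degrees of freedom
    and p value — the machine analogue of a published sensitivity table.
    """
    rows = []
    for timescale in timescales:
        for label, areas in areas_by_threshold.items():
            if timescale == "annual":
                pairs = annual_habitat(areas, sediment, method=method)
                S, a = pairs["annual_S"].to_numpy(), pairs["mean_wet_area"].to_numpy()
            elif timescale == "monthly":
                pairs = monthly_pairs(areas, sediment)
                S, a = pairs["S"].to_numpy(), pairs["area"].to_numpy()
            else:
                raise ValueError(f"unknown timescale {timescale!r}")
            model = fit_response(S, a)
            rows.append(
                {
                    "timescale": timescale,
                    "metric": label,
                    "threshold": thresholds[label],
                    "intercept": model.intercept_,
                    "sediment": model.coef_s_,
                    "sediment2": model.coef_s2_,
                    "terms": "+".join(model.included_terms_) or "1",
                    "F": model.f_stat_,
                    "df": f"{model.df_[0]},{model.df_[1]}",
                    "p": model.p_value_,
                }
            )
    return pd.DataFrame(rows)
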
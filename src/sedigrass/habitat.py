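"""Seagrass habitat-suitability model.

A binomial GLM with logit link predicts presence probability from benthic
light (L, the log of trailing-mean percent irradiance), significant wave
height (Hs), and their interaction:

    g(x) = b0 + b_L L + b_H Hs + b_HL (Hs x L),      p = 1 / (1 + exp(-g))

A probability threshold converts p to presence/absence; thresholds are chosen
on a calibration map by maximising Cohen's kappa (the headline criterion),
maximising percent correctly classified, equalising sensitivity and
specificity, or fixed at 0.5.  Suitable-habitat area is the count of water
cells meeting the threshold times the cell area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

THRESHOLD_CRITERIA = ("kappa", "maxPC", "sens_spec", "default")

#: Candidate thresholds examined by the grid search (matches the granularity
#: of commonly reported optimal thresholds).
THRESHOLD_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


class SeagrassHabitatModel(BaseEstimator, ClassifierMixin):
    """Binomial GLM (logit link) for seagrass presence.

    ``X`` has two columns, ``(L, Hs)``; the Hs x L interaction is added
    internally.  Fitting uses iteratively reweighted least squares.  No
    spatial-autocorrelation term is included: the model is meant to predict
    periods other than the calibration date, where such a term's assumptions
    would not hold.

    Attributes (after fit)
    ----------------------
    intercept_ : float
    coef_ : ndarray (b_L, b_H, b_HL)
    bse_ : standard errors (intercept, b_L, b_H, b_HL)
    thresholds_ : dict criterion -> probability threshold (set by
        :meth:`select_thresholds`).
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X: np.ndarray) -> np.ndarray:
        L, hs = X[:, 0], X[:, 1]
        return np.column_stack([np.ones(len(X)), L, hs, hs * L])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (light L, wave height Hs)")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("y must be binary (0/1)")
        if classes.size < 2:
            raise ValueError("both presence and absence are required to fit the GLM")
        design = self._design(X)
        glm = sm.GLM(y, design, family=sm.families.Binomial())
        try:
            res = glm.fit(maxiter=self.max_iter, tol=self.tol)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise ValueError(f"GLM fit failed (possible complete separation): {exc}")
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e6:
            raise ValueError("complete separation: coefficients diverged")
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.bse_ = np.asarray(res.bse, dtype=float)
        self.n_obs_ = int(res.nobs)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def linear_predictor(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self._design(X)[:, 1:] @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        g = self.linear_predictor(X)
        p1 = 1.0 / (1.0 + np.exp(-g))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def select_thresholds(self, y_obs, prob) -> dict[str, float]:
        """Pick one threshold per criterion on calibration data; stores result."""
        self.thresholds_ = {
            crit: select_threshold(y_obs, prob, crit) for crit in THRESHOLD_CRITERIA
        }
        return self.thresholds_

    def coefficients(self) -> dict[str, float]:
        check_is_fitted(self, "coef_")
        return {
            "intercept": self.intercept_,
            "light": float(self.coef_[0]),
            "waves": float(self.coef_[1]),
            "waves_x_light": float(self.coef_[2]),
        }

    @classmethod
    def from_coefficients(cls, coeffs: dict, thresholds: dict | None = None):
        """Build a pre-fitted model from named coefficients (reference configs)."""
        model = cls()
        model.intercept_ = float(coeffs["intercept"])
        model.coef_ = np.array(
            [coeffs["light"], coeffs["waves"], coeffs["waves_x_light"]], dtype=float
        )
        model.bse_ = np.full(4, np.nan)
        model.n_obs_ = 0
        model.classes_ = np.array([0.0, 1.0])
        if thresholds is not None:
            model.thresholds_ = dict(thresholds)
        return model


def predict_probability(
    model: SeagrassHabitatModel, light: np.ndarray, hs: np.ndarray
) -> np.ndarray:
    """Probability-of-presence raster; NaN where light or waves are NaN (land)."""
    light = np.asarray(light, dtype=float)
    hs = np.asarray(hs, dtype=float)
    if light.shape != hs.shape:
        raise ValueError("light and wave rasters must share one shape")
    valid = np.isfinite(light) & np.isfinite(hs)
    out = np.full(light.shape, np.nan)
    X = np.column_stack([light[valid], hs[valid]])
    out[valid] = model.predict_proba(X)[:, 1]
    return out


def fit_sdm(
    presence: np.ndarray, light: np.ndarray, hs: np.ndarray, **kwargs
) -> SeagrassHabitatModel:
    """Fit the habitat GLM on co-registered rasters (water cells only)."""
    presence = np.asarray(presence, dtype=float)
    light = np.asarray(light, dtype=float)
    hs = np.asarray(hs, dtype=float)
    if not (presence.shape == light.shape == hs.shape):
        raise ValueError("presence, light and wave rasters must share one shape")
    valid = np.isfinite(presence) & np.isfinite(light) & np.isfinite(hs)
    X = np.column_stack([light[valid], hs[valid]])
    return SeagrassHabitatModel(**kwargs).fit(X, presence[valid])


def _counts_for_thresholds(obs: np.ndarray, prob: np.ndarray, grid: np.ndarray):
    pred = prob[None, :] >= grid[:, None]  # (n_thresholds, n_obs)
    pos = obs == 1
    tp = (pred & pos[None, :]).sum(axis=1)
    fp = (pred & ~pos[None, :]).sum(axis=1)
    fn = ((~pred) & pos[None, :]).sum(axis=1)
    tn = ((~pred) & ~pos[None, :]).sum(axis=1)
    return tp, fp, tn, fn


def _kappa_from_counts(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(pe == 1.0, np.where(po == 1.0, 1.0, 0.0),
                         (po - pe) / (1.0 - pe))
    return kappa


def select_threshold(obs, prob, criterion: str, grid: np.ndarray = THRESHOLD_GRID) -> float:
    """Choose a presence threshold on calibration data.

    "kappa" maximises Cohen's kappa; "maxPC" maximises the percent correctly
    classified; "sens_spec" minimises |sensitivity - specificity|; "default"
    returns 0.5 regardless of the data.  Ties go to the smallest threshold.
    """
    if criterion == "default":
        return 0.5
    if criterion not in THRESHOLD_CRITERIA:
        raise ValueError(f"unknown threshold criterion {criterion!r}")
    obs = np.asarray(obs, dtype=float)
    prob = np.asarray(prob, dtype=float)
    if obs.shape != prob.shape:
        raise ValueError("obs and prob must have the same length")
    if np.unique(obs).size < 2:
        raise ValueError("both classes must be present to select a threshold")
    tp, fp, tn, fn = _counts_for_thresholds(obs, prob, grid)
    # scores are rounded so exact rational ties resolve to the smallest
    # threshold (argmax/argmin return the first of equal entries)
    if criterion == "kappa":
        score = np.round(_kappa_from_counts(tp, fp, tn, fn), 12)
        idx = int(np.argmax(score))
    elif criterion == "maxPC":
        score = np.round((tp + tn) / (tp + fp + tn + fn), 12)
        idx = int(np.argmax(score))
    else:  # sens_spec
        with np.errstate(divide="ignore", invalid="ignore"):
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
        idx = int(np.argmin(np.round(np.abs(sens - spec), 12)))
    return float(grid[idx])


@dataclass
class ConfusionSummary:
    """Confusion-matrix counts and derived accuracy statistics."""

    tp: int
    fp: int
    tn: int
    fn: int
    pcc: float
    kappa: float
    sensitivity: float
    specificity: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "pcc": self.pcc, "kappa": self.kappa,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def confusion_stats(obs, pred) -> ConfusionSummary:
    """Counts, accuracy (PCC), Cohen's kappa, sensitivity and specificity.

    Kappa uses the marginal-product expected agreement,
    kappa = (p_o - p_e) / (1 - p_e); a constant prediction scores 0.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have the same length")
    tp = int(np.sum((obs == 1) & (pred == 1)))
    fp = int(np.sum((obs == 0) & (pred == 1)))
    tn = int(np.sum((obs == 0) & (pred == 0)))
    fn = int(np.sum((obs == 1) & (pred == 0)))
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty input")
    pcc = (tp + tn) / n
    kappa = float(
        _kappa_from_counts(np.array([tp]), np.array([fp]), np.array([tn]), np.array([fn]))[0]
    )
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return ConfusionSummary(tp, fp, tn, fn, pcc, kappa, sens, spec)


def habitat_area(prob: np.ndarray, threshold: float, cell_area_ha: float = 1.0) -> float:
    """Suitable-habitat area (ha): cells with p >= threshold, times cell area."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    prob = np.asarray(prob, dtype=float)
    return float(np.sum(prob[np.isfinite(prob)] >= threshold) * cell_area_ha)
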
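"""Univariate and multivariate feature selection against visual acuity.

Pearson's r (linear association) and Spearman's rho (monotone
association, via the rank-difference formula) are computed directly from
their defining formulas; multivariate selection wraps scikit-learn's
cross-validated recursive feature elimination (with a gradient-boosted
scorer) and L1-penalised linear regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.feature_selection import RFE, RFECV
from sklearn.linear_model import LassoCV, LinearRegression

from .records import FEATURE_NAMES, EyeSeries

__all__ = [
    "pearson",
    "spearman",
    "univariate_report",
    "zero_variance_filter",
    "rfe_select",
    "lasso_select",
]


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def pearson(x, y) -> float:
    """Pearson correlation: sum of centred cross-products over the norm product."""
    x, y = _check_pair(x, y)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx * dx) * np.sum(dy * dy)))


def spearman(x, y) -> float:
    """Spearman rank correlation: rho = 1 - 6 * sum(d_i^2) / (n (n^2 - 1)).

    Ranks are average ranks, so ties are tolerated, but the rank-difference
    formula itself assumes tie-free data; with heavy ties prefer Pearson on
    ranks.
    """
    x, y = _check_pair(x, y)
    rx, ry = rankdata(x), rankdata(y)
    d = rx - ry
    n = len(x)
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1)))


def univariate_report(cohort: list[EyeSeries]) -> pd.DataFrame:
    """Per-feature correlation with decimal VA, pooled over all visits.

    One row per OCT scalar (22 rows) with Pearson r and Spearman rho; a
    degenerate feature yields NaN coefficients.
    """
    feats, vas = [], []
    for series in cohort:
        for visit in series.visits:
            if visit.va is None:
                continue
            feats.append(visit.feature_vector())
            vas.append(visit.va)
    x = np.array(feats)
    y = np.array(vas, dtype=float)
    rows = []
    for j, name in enumerate(FEATURE_NAMES):
        col = x[:, j]
        ok = ~np.isnan(col)
        try:
            r = pearson(col[ok], y[ok])
            rho = spearman(col[ok], y[ok])
        except ValueError:
            r = rho = np.nan
        zone = name.split("_")[0] if name[0] in "CNSTI" and name[1].isdigit() else "global"
        rows.append({"feature": name, "zone": zone, "r": r, "rho": rho, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def zero_variance_filter(blocks: list[np.ndarray]) -> np.ndarray:
    """Indices of features whose variance is nonzero in at least one series.

    ``blocks`` is one (visits x features) array per series; a feature is
    dropped only if it is constant within *every* series.
    """
    if not blocks:
        raise ValueError("no series given")
    n_feat = blocks[0].shape[1]
    keep = np.zeros(n_feat, dtype=bool)
    for block in blocks:
        keep |= np.nanvar(np.asarray(block, dtype=float), axis=0) > 0
    return np.flatnonzero(keep)


def rfe_select(
    x: np.ndarray,
    y: np.ndarray,
    estimator=None,
    cv: int = 10,
    n_features_to_select: int | None = None,
    seed: int = 0,
) -> dict:
    """Recursive feature elimination, step 1, cross-validated scoring.

    With ``n_features_to_select`` given, plain RFE to that count; otherwise
    RFECV picks the count by CV R². Returns ranking (1 = retained first)
    and the selected feature indices.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("RFE needs at least 2 features")
    estimator = estimator or GradientBoostingRegressor(random_state=seed)
    cv = min(cv, len(x) // 2)
    if n_features_to_select is not None:
        selector = RFE(estimator, n_features_to_select=n_features_to_select, step=1)
    else:
        selector = RFECV(estimator, step=1, cv=cv, scoring="r2", min_features_to_select=1)
    try:
        selector.fit(x, y)
    except (RuntimeError, ValueError) as exc:
        if "importance" in str(exc) or "coef" in str(exc):
            raise ValueError("estimator must expose feature importances or coefficients") from exc
        raise
    return {
        "ranking": selector.ranking_.tolist(),
        "selected": np.flatnonzero(selector.support_).tolist(),
        "method": "rfe",
    }


def lasso_select(x: np.ndarray, y: np.ndarray, cv: int = 10, seed: int = 0) -> dict:
    """L1-penalised linear fit with CV-chosen penalty; zero-weight features drop.

    ``cv=0`` requests the unpenalised limit (ordinary least squares
    weights), useful as a reference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if cv == 0:
        ols = LinearRegression().fit(x, y)
        weights = ols.coef_
        alpha = 0.0
    else:
        model = LassoCV(cv=min(cv, len(x) // 2), random_state=seed, max_iter=50_000)
        model.fit(x, y)
        weights = model.coef_
        alpha = float(model.alpha_)
    retained = np.flatnonzero(weights != 0)
    return {
        "weights": weights.tolist(),
        "selected": retained.tolist(),
        "alpha": alpha,
        "method": "lasso",
    }
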
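"""VI-to-trait retrieval: unit conversions, OLS fits and their evaluation.

Retrieval models are simple linear regressions of a crop trait on a
vegetation index, evaluated by the coefficient of determination on the
full fit and by root-mean-squared error from repeated k-fold
cross-validation.  Confidence and prediction bands use the standard OLS
interval formulas; per-date mean errors follow the observed-minus-
predicted sign convention, so a positive mean error means the model
underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpadCalibration",
    "RetrievalModel",
    "spad_to_chl",
    "canopy_chlorophyll",
    "fit_ols",
    "cv_rmse",
    "intervals",
    "mean_error_by_date",
    "model_matrix",
]


@dataclass(frozen=True)
class SpadCalibration:
    """SPAD-to-chlorophyll calibration, exponential form a * exp(b * SPAD).

    Coefficients come from configuration, not from this package: the
    published calibrations differ by crop and environment, so the
    choice is the user's.  The mapping must be strictly increasing over
    SPAD 0-60, which for the exponential form means a > 0 and b > 0.
    """

    a: float
    b: float
    form: str = "exponential"

    def __post_init__(self):
        if self.form != "exponential":
            raise ValueError(f"unknown calibration form {self.form!r}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError(
                "exponential SPAD calibration must be strictly increasing "
                "(a > 0 and b > 0)"
            )


def spad_to_chl(spad, calib: SpadCalibration):
    """Leaf chlorophyll content (ug cm^-2) from SPAD meter readings."""
    spad = np.asarray(spad, float)
    if np.any(spad < 0):
        raise ValueError("SPAD readings must be >= 0")
    out = calib.a * np.exp(calib.b * spad)
    return float(out) if out.ndim == 0 else out


def canopy_chlorophyll(leaf_chl, lai):
    """Canopy chlorophyll (g m^-2) = leaf chlorophyll (ug cm^-2) x LAI x 0.01."""
    leaf_chl = np.asarray(leaf_chl, float)
    lai = np.asarray(lai, float)
    if np.any(leaf_chl < 0) or np.any(lai < 0):
        raise ValueError("leaf_chl and lai must be non-negative")
    out = leaf_chl * lai * 0.01
    return float(out) if out.ndim == 0 else out


@dataclass
class RetrievalModel:
    """A fitted VI-to-trait simple linear regression and its scores."""

    trait: str
    index: str
    sensor_label: str
    slope: float
    intercept: float
    r2_full: float
    rmse_cv: float = np.nan
    mean_errors: dict = field(default_factory=dict)  # dap -> trait units
    interval_level: float = 0.95
    n: int = 0
    x_mean: float = np.nan
    sxx: float = np.nan
    residual_var: float = np.nan

    def __post_init__(self):
        if not -1e-12 <= self.r2_full <= 1 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if not np.isnan(self.rmse_cv) and self.rmse_cv < 0:
            raise ValueError("rmse must be >= 0")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


def fit_ols(
    x, y, trait: str = "trait", index: str = "index", sensor_label: str = ""
) -> RetrievalModel:
    """Ordinary-least-squares simple regression of y on x.

    R^2 is computed on the full fit; for simple regression it equals
    the squared Pearson correlation.  Degenerate inputs (fewer than 3
    points or zero variance in x) are rejected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in the predictor")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RetrievalModel(
        trait=trait,
        index=index,
        sensor_label=sensor_label,
        slope=slope,
        intercept=intercept,
        r2_full=r2,
        n=n,
        x_mean=float(x.mean()),
        sxx=sxx,
        residual_var=ss_res / (n - 2) if n > 2 else np.nan,
    )


def cv_rmse(x, y, k: int = 10, repeats: int = 100, seed: int = 0) -> float:
    """Repeated k-fold cross-validated RMSE of the simple regression.

    Each repeat draws a fresh random partition into k near-equal folds;
    the model is refit on k-1 folds and squared errors are pooled over
    the held-out folds before taking the root, then RMSE is averaged
    over repeats.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(repeats)]
    rmses = np.empty(repeats)
    for r, rng in enumerate(rngs):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        sq_sum = 0.0
        for fold in folds:
            train = np.setdiff1d(perm, fold, assume_unique=True)
            xt, yt = x[train], y[train]
            sxx = np.sum((xt - xt.mean()) ** 2)
            if sxx == 0:
                raise ValueError("zero predictor variance within a training fold")
            slope = np.sum((xt - xt.mean()) * (yt - yt.mean())) / sxx
            intercept = yt.mean() - slope * xt.mean()
            err = y[fold] - (intercept + slope * x[fold])
            sq_sum += float(np.sum(err**2))
        rmses[r] = np.sqrt(sq_sum / n)
    return float(rmses.mean())


def intervals(model: RetrievalModel, x_grid, level: float = 0.95):
    """Confidence and prediction bands of the fitted regression.

    Returns a dict with keys ``fit``, ``conf_lo/conf_hi`` (mean
    response) and ``pred_lo/pred_hi`` (new observation), using t
    quantiles with n - 2 degrees of freedom.
    """
    if not 0 < level < 1:
        raise ValueError("interval level must lie in (0, 1)")
    x_grid = np.asarray(x_grid, float)
    if model.n < 3 or np.isnan(model.residual_var):
        raise ValueError("model carries no residual variance information")
    s = np.sqrt(model.residual_var)
    tq = stats.t.ppf(0.5 + level / 2.0, model.n - 2)
    leverage = 1.0 / model.n + (x_grid - model.x_mean) ** 2 / model.sxx
    fit = model.predict(x_grid)
    half_conf = tq * s * np.sqrt(leverage)
    half_pred = tq * s * np.sqrt(1.0 + leverage)
    return {
        "fit": fit,
        "conf_lo": fit - half_conf,
        "conf_hi": fit + half_conf,
        "pred_lo": fit - half_pred,
        "pred_hi": fit + half_pred,
    }


def mean_error_by_date(model: RetrievalModel, x, y, dap) -> dict[int, float]:
    """Mean residual (observed - predicted) per acquisition date.

    Positive values mean the model underestimates the trait on that
    date.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dap = np.asarray(dap)
    out: dict[int, float] = {}
    for d in np.unique(dap):
        sel = dap == d
        if not sel.any():
            raise ValueError(f"empty group for dap {d}")
        out[int(d)] = float(np.mean(y[sel] - model.predict(x[sel])))
    return out


def model_matrix(
    vi_table: pd.DataFrame,
    trait_table: pd.DataFrame,
    traits: list[str],
    indices: list[str],
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every index x trait x sensor combination; score R^2 and CV-RMSE.

    ``vi_table`` needs columns plot_id, dap, sensor and one column per
    index; ``trait_table`` needs plot_id, dap and one column per trait.
    The returned frame has one row per combination with a ``best``
    flag marking, per (sensor, trait), the lowest cross-validated RMSE.
    """
    merged = vi_table.merge(trait_table, on=["plot_id", "dap"], how="inner")
    rows = []
    for sensor, grp in merged.groupby("sensor", sort=True):
        for trait in traits:
            for index in indices:
                sub = grp[[index, trait, "dap"]].dropna()
                model = fit_ols(
                    sub[index].to_numpy(),
                    sub[trait].to_numpy(),
                    trait=trait,
                    index=index,
                    sensor_label=str(sensor),
                )
                rmse = cv_rmse(
                    sub[index].to_numpy(),
                    sub[trait].to_numpy(),
                    k=k,
                    repeats=repeats,
                    seed=seed,
                )
                rows.append(
                    {
                        "sensor": sensor,
                        "trait": trait,
                        "index": index,
                        "r2": model.r2_full,
                        "rmse_cv": rmse,
                        "slope": model.slope,
                        "intercept": model.intercept,
                        "n": model.n,
                    }
                )
    table = pd.DataFrame(rows)
    table["best"] = False
    for (_, _), grp in table.groupby(["sensor", "trait"]):
        table.loc[grp["rmse_cv"].idxmin(), "best"] = True
    return table
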
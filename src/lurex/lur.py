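"""Land use regression: stepwise selection, diagnostics and raster prediction.

The LUR is an ordinary least squares model

    PM2.5 = b0 + sum_k b_k * cov_k@radius_k

built by bidirectional stepwise selection: at each forward step the
candidate whose coefficient t-test p-value is smallest enters if it is
below ``p_enter``; at each backward step any included term whose p-value
exceeds ``p_remove`` leaves. Candidates too collinear (|Pearson r| above a
gate) with an included term are skipped. Because p_enter <= p_remove a
variable cannot cycle in and out on fixed data, so the procedure terminates.

The selection core is the sklearn-style estimator
:class:`StepwiseLinearRegression`; the module-level functions wrap it in
the domain vocabulary (seasonal models, buffered covariate terms, LOOCV).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .raster import GridRaster, focal_mean

logger = logging.getLogger(__name__)

_TERM_RE = re.compile(r"^(?P<cov>.*?)(?P<radius>\d+(?:\.\d+)?)m$")


@dataclass(frozen=True)
class LURConfig:
    """Stepwise selection settings.

    p_enter / p_remove are the significance levels for entering and
    removing a predictor (defaults 0.05 / 0.10); collinearity_r_max gates
    candidates whose pairwise |r| with an included term is too high.
    """

    p_enter: float = 0.05
    p_remove: float = 0.10
    collinearity_r_max: float = 0.8
    max_terms: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_enter <= self.p_remove < 1):
            raise ValueError("require 0 < p_enter <= p_remove < 1")


@dataclass
class LURTerm:
    covariate: str
    radius_m: float
    coefficient: float

    @property
    def column(self) -> str:
        return f"{self.covariate}{self.radius_m:g}m"


@dataclass
class LURModel:
    """Fitted LUR: intercept (μg/m³) plus buffered covariate terms.

    ``diagnostics`` may hold model R², adjusted R², CV R², MAE and RMSE
    (μg/m³ where applicable); ``season`` labels the averaging period
    (a season name, or "yearly").
    """

    intercept: float
    terms: list[LURTerm]
    season: str = "yearly"
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return [t.column for t in self.terms]

    def evaluate(self, covariate_values: dict[str, float]) -> float:
        """Predicted concentration (μg/m³) for one set of covariate values.

        ``covariate_values`` is keyed by covariate name (``"DTS"``) or by
        full column name (``"DTS2400m"``); a missing value is an error.
        """
        total = self.intercept
        for t in self.terms:
            if t.column in covariate_values:
                v = covariate_values[t.column]
            elif t.covariate in covariate_values:
                v = covariate_values[t.covariate]
            else:
                raise KeyError(
                    f"no value supplied for model term {t.column!r}"
                )
            total += t.coefficient * float(v)
        return total

    def to_dict(self) -> dict:
        return {
            "season": self.season,
            "intercept": self.intercept,
            "terms": [
                {"covariate": t.covariate, "radius_m": t.radius_m,
                 "coefficient": t.coefficient}
                for t in self.terms
            ],
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LURModel":
        return cls(
            intercept=float(d["intercept"]),
            terms=[
                LURTerm(t["covariate"], float(t["radius_m"]),
                        float(t["coefficient"]))
                for t in d["terms"]
            ],
            season=d.get("season", "yearly"),
            diagnostics=dict(d.get("diagnostics", {})),
        )


def parse_term_column(column: str) -> tuple[str, float]:
    """Split ``"DTS2400m"`` into ``("DTS", 2400.0)``."""
    m = _TERM_RE.match(column)
    if not m:
        raise ValueError(f"column {column!r} is not of the form <cov><radius>m")
    return m.group("cov"), float(m.group("radius"))


class StepwiseLinearRegression(BaseEstimator, RegressorMixin):
    """Bidirectional stepwise OLS with p-value entry/removal thresholds.

    Parameters
    ----------
    p_enter : float, default 0.05
        A candidate enters when its coefficient t-test p-value in the
        augmented model is the smallest among candidates and below this.
    p_remove : float, default 0.10
        An included term leaves when its p-value exceeds this.
    collinearity_r_max : float, default 0.8
        Candidates whose |Pearson r| with any included column exceeds this
        are skipped at entry.
    max_terms : int or None
        Optional cap on the number of selected terms.

    Attributes
    ----------
    selected_features_ : list of str
        Names of the selected columns, in entry order.
    intercept_ : float
    coef_ : ndarray, aligned with ``selected_features_``.
    pvalues_ : ndarray, coefficient p-values aligned with the features.
    conf_int_ : ndarray of shape (n_terms, 2), 95% coefficient intervals.
    results_ : statsmodels OLSResults of the final fit.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 collinearity_r_max: float = 0.8,
                 max_terms: int | None = None):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.collinearity_r_max = collinearity_r_max
        self.max_terms = max_terms

    def _ols(self, X: pd.DataFrame, y: np.ndarray, cols: list[str]):
        design = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, design).fit()

    def fit(self, X, y):
        """Run stepwise selection on a DataFrame of candidate columns."""
        LURConfig(self.p_enter, self.p_remove,
                  self.collinearity_r_max, self.max_terms)  # validates
        X = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if not np.isfinite(X.to_numpy()).all() or not np.isfinite(y).all():
            raise ValueError("X and y must be finite")
        candidates = list(X.columns)
        corr = X.corr().abs()
        included: list[str] = []
        max_iter = 2 * len(candidates) + 2
        for _ in range(max_iter):
            changed = False
            # forward step
            if self.max_terms is None or len(included) < self.max_terms:
                best_p, best_col = np.inf, None
                for col in candidates:
                    if col in included:
                        continue
                    if X[col].std() == 0:
                        continue
                    if any(corr.loc[col, inc] > self.collinearity_r_max
                           for inc in included):
                        continue
                    if X.shape[0] < len(included) + 3:
                        continue
                    res = self._ols(X, y, included + [col])
                    p = res.pvalues.get(col, np.inf)
                    if np.isfinite(p) and p < best_p:
                        best_p, best_col = p, col
                if best_col is not None and best_p < self.p_enter:
                    included.append(best_col)
                    changed = True
            # backward step
            if included:
                res = self._ols(X, y, included)
                pvals = res.pvalues.drop("const")
                worst = pvals.idxmax()
                if pvals[worst] > self.p_remove:
                    included.remove(worst)
                    changed = True
            if not changed:
                break
        if not included:
            logger.warning("no candidate entered; fitting intercept-only model")
        res = self._ols(X, y, included)
        self.selected_features_ = included
        self.intercept_ = float(res.params["const"])
        self.coef_ = res.params.drop("const").to_numpy(dtype=float)
        self.pvalues_ = res.pvalues.drop("const").to_numpy(dtype=float)
        ci = res.conf_int(alpha=0.05)
        self.conf_int_ = ci.drop(index="const").to_numpy(dtype=float)
        self.results_ = res
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "selected_features_")
        X = pd.DataFrame(X).astype(float)
        out = np.full(X.shape[0], self.intercept_)
        for col, b in zip(self.selected_features_, self.coef_):
            out = out + b * X[col].to_numpy(dtype=float)
        return out


def fit_metrics(y_obs: np.ndarray, y_pred: np.ndarray,
                n_terms: int) -> dict[str, float]:
    """R², adjusted R², MAE and RMSE of predictions against observations.

    Adjusted R² uses ``n`` and the number of predictors and is NaN when
    n <= n_terms + 1 (undefined).
    """
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    resid = y_obs - y_pred
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    sse = float(np.sum(resid ** 2))
    n = y_obs.size
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    if n > n_terms + 1 and sst > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_terms - 1)
    else:
        adj = float("nan")
    return {
        "r2": r2,
        "adj_r2": adj,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid ** 2))),
    }


def stepwise_select(features: pd.DataFrame, config: LURConfig | None = None,
                    response: str = "pm25",
                    season: str = "yearly") -> LURModel:
    """Stepwise LUR construction from a feature table.

    ``features`` has one row per site, buffered-covariate columns named
    ``{cov}{radius}m`` and the observed response column. Returns the fitted
    model with modeling diagnostics (R², adjusted R², MAE, RMSE) attached.
    If no candidate passes the entry threshold the result is an
    intercept-only model (with a warning), not an error.
    """
    config = config or LURConfig()
    X = features.drop(columns=[response])
    y = features[response].to_numpy(dtype=float)
    est = StepwiseLinearRegression(
        p_enter=config.p_enter, p_remove=config.p_remove,
        collinearity_r_max=config.collinearity_r_max,
        max_terms=config.max_terms,
    ).fit(X, y)
    terms = [
        LURTerm(*parse_term_column(col), coefficient=float(b))
        for col, b in zip(est.selected_features_, est.coef_)
    ]
    model = LURModel(intercept=est.intercept_, terms=terms, season=season)
    model.diagnostics.update(
        fit_metrics(y, est.predict(X), n_terms=len(terms))
    )
    model._estimator = est  # kept for CI access; not serialized
    return model


def loocv(features: pd.DataFrame, model: LURModel,
          response: str = "pm25") -> dict[str, float]:
    """Leave-one-out cross-validation of a fixed term set.

    For each site the *selected* terms are kept and only the coefficients
    are refit on the remaining n-1 sites; the held-out site is predicted.
    CV R² is 1 - SSE/SST over the pooled held-out predictions, with SST
    about the observed mean. Selection is deliberately not repeated per
    fold so that CV R² measures the chosen model, not the selector.
    """
    cols = model.columns
    y = features[response].to_numpy(dtype=float)
    n = len(features)
    if n < len(cols) + 3:
        raise ValueError("too few sites for leave-one-out validation")
    preds = np.full(n, np.nan)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        Xtr = features.iloc[keep]
        design = sm.add_constant(Xtr[cols], has_constant="add")
        try:
            res = sm.OLS(y[keep], design).fit()
        except Exception:  # singular subset
            logger.warning("LOOCV fold %d singular; reported missing", i)
            continue
        row = sm.add_constant(
            features.iloc[[i]][cols], has_constant="add"
        ).reindex(columns=design.columns, fill_value=1.0)
        preds[i] = float(res.predict(row).iloc[0])
    ok = np.isfinite(preds)
    resid = y[ok] - preds[ok]
    sst = float(np.sum((y[ok] - y[ok].mean()) ** 2))
    cv_r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else float("nan")
    return {
        "cv_r2": cv_r2,
        "cv_mae": float(np.mean(np.abs(resid))),
        "cv_rmse": float(np.sqrt(np.mean(resid ** 2))),
    }


def evaluate_model(model: LURModel, covariate_values: dict[str, float]) -> float:
    """Evaluate a prediction function at one set of covariate values."""
    return model.evaluate(covariate_values)


def predict_surface(model: LURModel,
                    covariates: dict[str, GridRaster]) -> GridRaster:
    """Apply a fitted LUR over covariate rasters to map concentrations.

    Focal means are computed at each term's radius, the linear predictor is
    evaluated per cell, and negative predictions are floored at 0 μg/m³
    (with the floored-cell count logged). Nodata propagates.
    """
    if not covariates:
        raise ValueError("no covariate rasters supplied")
    geom_ref = next(iter(covariates.values()))
    acc = np.full(geom_ref.values.shape, model.intercept, dtype=float)
    valid = np.ones(geom_ref.values.shape, dtype=bool)
    for t in model.terms:
        if t.covariate not in covariates:
            raise KeyError(f"missing covariate raster {t.covariate!r}")
        raster = covariates[t.covariate]
        if not raster.same_geometry(geom_ref):
            raise ValueError(
                f"raster geometry mismatch for covariate {t.covariate!r}"
            )
        buffered = focal_mean(raster, t.radius_m).masked()
        valid &= np.isfinite(buffered)
        acc = acc + t.coefficient * np.where(np.isfinite(buffered), buffered, 0.0)
    n_neg = int(np.sum(valid & (acc < 0)))
    if n_neg:
        logger.info("floored %d negative predicted cells at 0", n_neg)
    acc = np.maximum(acc, 0.0)
    acc[~valid] = geom_ref.nodata
    return geom_ref.with_values(acc, units="ug/m3",
                                name=f"pm25_{model.season}")


# -- model file I/O ---------------------------------------------------------

def save_models(models: list[LURModel], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([m.to_dict() for m in models], indent=1))
    return path


def load_models(path: str | Path) -> list[LURModel]:
    data = json.loads(Path(path).read_text())
    return [LURModel.from_dict(d) for d in data]


def load_printed_models() -> list[LURModel]:
    """The five published Beijing prediction functions bundled with the
    package (spring, summer, autumn, winter, yearly), for worked-example
    evaluation. Units: intercepts and predictions in μg/m³; DTS in km;
    slope in percent; NDVI, AOD and road-area ratio unitless."""
    ref = resources.files("lurex.data").joinpath("printed_models.json")
    models = [LURModel.from_dict(d) for d in json.loads(ref.read_text())]
    if len(models) != 5:
        raise ValueError("bundled model file corrupted: expected 5 models")
    return models
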
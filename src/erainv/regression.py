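"""Bioactivity (pIC50) regression: training, evaluation, family comparison
and Shapley dependence profiles.

Five model families are supported, mirroring the usual QSAR contenders on
descriptor tables: an MLP, an RBF-kernel SVM, two gradient-boosted tree
backends (LightGBM, XGBoost), and a random forest; a plain linear model is
kept as the classical baseline. Boosted trees are the workhorse — they need
no feature scaling and capture the interaction/threshold structure that
drives potency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ConfigError, SplitSpec, split_dataset
from .metrics import mean_squared_error, r_squared
from .shapley import shap_importance

FAMILIES = ("mlp", "svm", "gbt_a", "gbt_b", "rf", "linear")
_ALIASES = {"gbt": "gbt_a", "lgb": "gbt_a", "lightgbm": "gbt_a",
            "xgb": "gbt_b", "xgboost": "gbt_b"}


def _make_estimator(family: str, hyperparams: dict | None, seed: int):
    hp = dict(hyperparams or {})
    if family == "gbt_a":
        from lightgbm import LGBMRegressor
        defaults = dict(n_estimators=200, random_state=seed, n_jobs=1,
                        deterministic=True, force_row_wise=True, verbose=-1)
        defaults.update(hp)
        return LGBMRegressor(**defaults)
    if family == "gbt_b":
        from xgboost import XGBRegressor
        defaults = dict(n_estimators=200, random_state=seed, n_jobs=1,
                        verbosity=0)
        defaults.update(hp)
        return XGBRegressor(**defaults)
    if family == "rf":
        from sklearn.ensemble import RandomForestRegressor
        defaults = dict(n_estimators=200, random_state=seed, n_jobs=1)
        defaults.update(hp)
        return RandomForestRegressor(**defaults)
    if family == "mlp":
        from sklearn.neural_network import MLPRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        defaults = dict(hidden_layer_sizes=(64, 32), max_iter=500,
                        random_state=seed)
        defaults.update(hp)
        return make_pipeline(StandardScaler(), MLPRegressor(**defaults))
    if family == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR
        return make_pipeline(StandardScaler(), SVR(**hp))
    if family == "linear":
        from sklearn.linear_model import LinearRegression
        return LinearRegression(**hp)
    raise ConfigError(f"unknown model family {family!r}; choose from {FAMILIES}")


@dataclass
class RegressionModel:
    """A fitted pIC50 regressor; predict() expects the training features in order."""

    family: str
    estimator: object
    feature_names: list[str]
    seed: int

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ConfigError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X), dtype=float).ravel()


@dataclass
class EvalMetrics:
    r2: float
    mse: float
    n: int


@dataclass
class ComparisonTable:
    """Replicate R^2 per family plus mean/std summaries."""

    families: list[str]
    r2: dict[str, np.ndarray]
    reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "family": self.families,
            "r2_mean": [float(np.mean(self.r2[f])) for f in self.families],
            "r2_std": [float(np.std(self.r2[f], ddof=1)) for f in self.families],
            "reps": self.reps,
        })


def resolve_family(family: str) -> str:
    family = _ALIASES.get(family, family)
    if family not in FAMILIES:
        raise ConfigError(f"unknown model family {family!r}; choose from {FAMILIES}")
    return family


def train_regressor(X, y, family: str = "gbt_a", hyperparams: dict | None = None,
                    seed: int = 0) -> RegressionModel:
    """Fit one regressor; deterministic given the seed."""
    family = resolve_family(family)
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 10:
        raise ConfigError("need at least 10 samples to fit")
    if not np.isfinite(y).all():
        raise ConfigError("target contains non-finite values")
    est = _make_estimator(family, hyperparams, seed)
    est.fit(X, y)
    return RegressionModel(family, est, feature_names, seed)


def evaluate_regression(model: RegressionModel, X, y) -> EvalMetrics:
    """R^2 and MSE on (X, y); zero-variance targets are an error, not NaN."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = model.predict(X)
    return EvalMetrics(r2=r_squared(y, y_hat),
                       mse=mean_squared_error(y, y_hat), n=y.size)


def compare_model_families(X, y, families: Sequence[str] = ("rf", "gbt_b", "gbt_a", "svm", "mlp"),
                           reps: int = 20, seed: int = 0,
                           ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                           hyperparams: dict[str, dict] | None = None,
                           ) -> ComparisonTable:
    """Replicate train/test resampling per family; summary mirrors the usual
    model-comparison table (mean and std of held-out R^2 over ``reps`` trials)."""
    if reps < 2:
        raise ConfigError("need at least 2 replicates")
    families = [resolve_family(f) for f in families]
    if isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        Xdf = pd.DataFrame(np.asarray(X, dtype=float))
        Xdf.columns = [f"x{j}" for j in range(Xdf.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n = Xdf.shape[0]
    out: dict[str, np.ndarray] = {f: np.empty(reps) for f in families}
    for rep in range(reps):
        tr, _va, te = split_dataset(n, SplitSpec(ratios, seed=seed + rep))
        for fam in families:
            try:
                model = train_regressor(Xdf.iloc[tr], y[tr], fam,
                                        (hyperparams or {}).get(fam), seed=seed + rep)
                out[fam][rep] = evaluate_regression(model, Xdf.iloc[te], y[te]).r2
            except Exception as exc:
                raise RuntimeError(f"family {fam!r} failed on replicate {rep}") from exc
    return ComparisonTable(list(families), out, reps)


@dataclass
class DependenceCurve:
    """(descriptor value, attribution) pairs sorted by value, plus the
    descriptor's influence rank by mean |phi| across all features."""

    descriptor: str
    values: np.ndarray
    phi: np.ndarray
    rank: int
    mean_abs_phi: float


def dependence_profile(model: RegressionModel, X, background=None,
                       descriptor: str | None = None, seed: int = 0) -> DependenceCurve:
    """Shapley dependence profile of one descriptor (sensitivity analysis)."""
    if descriptor is None:
        raise ConfigError("descriptor name required")
    if descriptor not in model.feature_names:
        raise ConfigError(f"unknown descriptor {descriptor!r}")
    attrib, ranking = shap_importance(model, X, background, seed=seed)
    j = model.feature_names.index(descriptor)
    if isinstance(X, pd.DataFrame):
        col = X[descriptor].to_numpy(dtype=float)
    else:
        col = np.asarray(X, dtype=float)[:, j]
    # shap_importance may subsample rows; recompute the column it used
    if attrib.values.shape[0] != col.size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(col.size, size=attrib.values.shape[0], replace=False)
        col = col[idx]
    phi = attrib.values[:, j]
    order = np.argsort(col, kind="stable")
    rank = ranking.names.index(descriptor) + 1
    return DependenceCurve(descriptor, col[order], phi[order], rank,
                           float(np.abs(phi).mean()))
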
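"""Multi-output ADMET classification and the single- vs multi-output comparison.

Five binary endpoints are modeled: Caco-2 permeability, CYP3A4
metabolizability, hERG cardiotoxicity, human oral bioavailability and
micronucleus genotoxicity. The "multi" mode is an XGBoost model per target
managed behind one interface; the "single" mode is five independent LightGBM
fits — the two ecosystems whose agreement is assessed with a Mann-Whitney U
test on replicate accuracies. Classification uses a strict 0.5 threshold:
probability exactly 0.5 maps to class 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data_model import ADMET_PROPERTIES, ConfigError, SplitSpec, split_dataset
from .metrics import UndefinedMetricError, accuracy, roc_auc

THRESHOLD = 0.5


def _check_labels(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[1] != len(ADMET_PROPERTIES):
        raise ConfigError(f"Y must have {len(ADMET_PROPERTIES)} columns, got shape {Y.shape}")
    if not np.isin(Y, (0, 1)).all():
        raise ConfigError("Y must be strictly binary")
    for k, prop in enumerate(ADMET_PROPERTIES):
        if len(np.unique(Y[:, k])) < 2:
            raise ConfigError(f"property {prop!r} has a single class")
    return Y.astype(int)


@dataclass
class AdmetModel:
    """Five per-property probabilistic classifiers behind one interface."""

    mode: str                      # "single" (LightGBM) or "multi" (XGBoost)
    estimators: list               # one fitted classifier per property
    feature_names: list[str]
    seed: int
    threshold: float = THRESHOLD

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ConfigError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return np.column_stack([est.predict_proba(X)[:, 1] for est in self.estimators])


def train_admet(X, Y, mode: str = "multi", seed: int = 0,
                hyperparams: dict | None = None) -> AdmetModel:
    """Fit the five-endpoint classifier; deterministic given seed.

    mode="multi": one jointly-managed XGBoost multi-output model (a shared
    seed across targets). mode="single": five independent LightGBM fits with
    per-property derived seeds. The external contract is identical.
    """
    if mode not in ("single", "multi"):
        raise ConfigError(f"mode must be 'single' or 'multi', got {mode!r}")
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    Y = _check_labels(Y)
    hp = dict(hyperparams or {})
    estimators = []
    for k in range(Y.shape[1]):
        if mode == "multi":
            from xgboost import XGBClassifier
            params = dict(n_estimators=200, random_state=seed, n_jobs=1,
                          verbosity=0, eval_metric="logloss")
            params.update(hp)
            est = XGBClassifier(**params)
        else:
            from lightgbm import LGBMClassifier
            params = dict(n_estimators=200, random_state=seed + k, n_jobs=1,
                          deterministic=True, force_row_wise=True, verbose=-1)
            params.update(hp)
            est = LGBMClassifier(**params)
        est.fit(X, Y[:, k])
        estimators.append(est)
    return AdmetModel(mode, estimators, feature_names, seed)


def predict_admet(model: AdmetModel, X) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, labels); label 1 iff probability strictly exceeds 0.5."""
    probs = model.predict_proba(X)
    labels = (probs > model.threshold).astype(int)
    return probs, labels


@dataclass
class ClassMetrics:
    properties: list[str]
    acc: np.ndarray
    auc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"property": self.properties,
                             "acc": self.acc, "roc_auc": self.auc})


def evaluate_admet(model: AdmetModel, X, Y) -> ClassMetrics:
    Y = _check_labels(Y)
    probs, labels = predict_admet(model, X)
    acc = np.array([accuracy(Y[:, k], labels[:, k]) for k in range(Y.shape[1])])
    try:
        auc = np.array([roc_auc(Y[:, k], probs[:, k]) for k in range(Y.shape[1])])
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(f"AUC undefined: {exc}") from exc
    return ClassMetrics(list(ADMET_PROPERTIES), acc, auc)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class MWUResult:
    u_a: float
    u_b: float
    p_value: float
    significant: bool              # at alpha = 0.05
    method: str                    # "exact" or "normal"


def mannwhitney_compare(sample_a, sample_b, alternative: str = "two-sided",
                        exact_limit: int = 8) -> MWUResult:
    """Mann-Whitney U test on two samples of replicate accuracies.

    Exact p by enumeration of all rank assignments when both samples have at
    most ``exact_limit`` observations (ties handled through midranks);
    otherwise the normal approximation with tie correction and continuity
    correction. U_A + U_B = n_A * n_B always holds.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ConfigError("both samples must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    u_b = float(na * nb - u_a)

    if na <= exact_limit and nb <= exact_limit:
        total = math.comb(na + nb, na)
        mu = na * nb / 2.0
        obs_dev = abs(u_a - mu)
        count = 0
        idx_all = range(na + nb)
        for combo in combinations(idx_all, na):
            u = float(ranks[list(combo)].sum() - na * (na + 1) / 2.0)
            if alternative == "two-sided":
                hit = abs(u - mu) >= obs_dev - 1e-12
            elif alternative == "greater":
                hit = u >= u_a - 1e-12
            elif alternative == "less":
                hit = u <= u_a + 1e-12
            else:
                raise ConfigError(f"unknown alternative {alternative!r}")
            count += hit
        p = count / total
        method = "exact"
    else:
        n = na + nb
        mu = na * nb / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "two-sided":
                z = (abs(u_a - mu) - 0.5) / sd
                p = 2.0 * norm.sf(max(z, 0.0))
            elif alternative == "greater":
                z = (u_a - mu - 0.5) / sd
                p = float(norm.sf(z))
            elif alternative == "less":
                z = (u_a - mu + 0.5) / sd
                p = float(norm.cdf(z))
            else:
                raise ConfigError(f"unknown alternative {alternative!r}")
            p = min(float(p), 1.0)
        method = "normal"
    return MWUResult(u_a, u_b, float(p), p < 0.05, method)


@dataclass
class MWUReport:
    properties: list[str]
    results: list[MWUResult]
    acc_multi: np.ndarray          # (reps, 5)
    acc_single: np.ndarray
    auc_multi: np.ndarray
    auc_single: np.ndarray
    reps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "property": self.properties,
            "U": [r.u_a for r in self.results],
            "p_value": [r.p_value for r in self.results],
            "significant_at_0.05": [r.significant for r in self.results],
            "multi_acc_mean": self.acc_multi.mean(axis=0),
            "multi_acc_std": self.acc_multi.std(axis=0, ddof=1),
            "single_acc_mean": self.acc_single.mean(axis=0),
            "single_acc_std": self.acc_single.std(axis=0, ddof=1),
            "multi_auc_mean": self.auc_multi.mean(axis=0),
            "single_auc_mean": self.auc_single.mean(axis=0),
        })


def compare_single_vs_multi(X, Y, reps: int = 20, seed: int = 0,
                            ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                            ) -> MWUReport:
    """Replicate both modes over resampled splits and compare per-property
    accuracies with a two-sided Mann-Whitney U test at 95% confidence."""
    if reps < 5:
        raise ConfigError("need at least 5 replicates")
    if isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        Xdf = pd.DataFrame(np.asarray(X, dtype=float))
        Xdf.columns = [f"x{j}" for j in range(Xdf.shape[1])]
    Y = _check_labels(Y)
    n = Xdf.shape[0]
    acc_m = np.empty((reps, 5))
    acc_s = np.empty((reps, 5))
    auc_m = np.empty((reps, 5))
    auc_s = np.empty((reps, 5))
    for rep in range(reps):
        tr, _va, te = split_dataset(n, SplitSpec(ratios, seed=seed + rep))
        for mode, acc_out, auc_out in (("multi", acc_m, auc_m),
                                       ("single", acc_s, auc_s)):
            model = train_admet(Xdf.iloc[tr], Y[tr], mode=mode, seed=seed + rep)
            m = evaluate_admet(model, Xdf.iloc[te], Y[te])
            acc_out[rep] = m.acc
            auc_out[rep] = m.auc
    results = [mannwhitney_compare(acc_m[:, k], acc_s[:, k]) for k in range(5)]
    return MWUReport(list(ADMET_PROPERTIES), results, acc_m, acc_s,
                     auc_m, auc_s, reps)
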
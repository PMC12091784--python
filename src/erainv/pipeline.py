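"""End-to-end orchestration of the four phases:

1. descriptor analysis (Shapley ranking + LassoNet group scores, candidate
   set, optional count sweep, hybrid 50-descriptor selection, perturbation
   validation);
2. bioactivity regression on the selected descriptors;
3. ADMET classification on the same descriptors;
4. GA inverse design with nearest-compound decoding.

A single global seed fans out to fixed per-phase offsets, so each phase is
individually reproducible and the whole run is reproducible from its
manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admet import compare_single_vs_multi, evaluate_admet, train_admet
from .data_model import ConfigError, SplitSpec, fit_scaler, load_tables, split_dataset
from .ga import GAConfig, match_nearest, optimize
from .lassonet import group_importance, lassonet_path
from .regression import compare_model_families, evaluate_regression, train_regressor
from .selection import (build_candidate_set, default_grid, perturbation_validation,
                        select_final, sweep_descriptor_count)
from .shapley import shap_importance
from .synthetic import SyntheticConfig, generate

# per-phase seed offsets
_SEED_SPLIT = 11
_SEED_SHAP = 23
_SEED_LASSONET = 37
_SEED_SWEEP = 41
_SEED_VALIDATE = 53
_SEED_REGRESSION = 67
_SEED_ADMET = 79
_SEED_GA = 97


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    data_dir: str | None = None
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    n_total: int = 50
    k_groups: int = 5
    per_group: int = 2
    model_family: str = "gbt_a"
    run_sweep: bool = False
    sweep_max_k: int = 290
    sweep_reps: int = 20
    run_validation: bool = True
    validation_reps: int = 20
    compare_families: bool = False
    compare_admet_modes: bool = False
    reps: int = 20
    #: the full-descriptor model used for the Shapley ranking subsamples
    #: columns per tree so attribution spreads over correlated descriptors
    #: instead of collapsing onto one representative per family
    importance_hyperparams: dict = field(
        default_factory=lambda: {"colsample_bytree": 0.3, "n_estimators": 300})
    shap_max_samples: int = 256
    shap_max_background: int = 64
    lassonet_hidden: tuple[int, int] = (64, 32)
    lassonet_M: float = 10.0
    ga: GAConfig = field(default_factory=GAConfig.desk_scale)
    match_k: int = 3
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ConfigError("provide exactly one of synthetic config or data_dir")
        if any(r <= 0 for r in self.ratios):
            raise ConfigError("all split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError("split ratios must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if d.get("ga"):
            d["ga"] = GAConfig(**d["ga"])
        d["ratios"] = tuple(d["ratios"])
        d["lassonet_hidden"] = tuple(d["lassonet_hidden"])
        return cls(**d)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        return cls.from_dict(payload["config"])


@dataclass
class RunReport:
    selected_descriptors: list[str]
    candidate_count: int
    group_ranking: list[str]
    regression_r2: float
    regression_mse: float
    admet_acc: dict[str, float]
    admet_auc: dict[str, float]
    ga_predicted_pic50: float
    ga_admet_sum: int
    ga_feasible: bool
    best_observed_pic50: float
    matches: list[dict]
    validation_means: dict[str, float] | None
    sweep_chosen_count: int | None
    family_r2_means: dict[str, float] | None
    admet_mwu_p: dict[str, float] | None
    output_paths: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the four phases in order; any failure names its phase."""
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save_frame(df: pd.DataFrame, name: str) -> None:
        if outdir:
            p = outdir / name
            df.to_csv(p, index=False)
            paths[name] = str(p)

    # ----- data -------------------------------------------------------
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            dataset = generate(syn)
            table, activity, admet = (dataset.descriptor_table, dataset.activity,
                                      dataset.admet)
        else:
            base = Path(config.data_dir)
            table, activity, admet = load_tables(
                base / "descriptors.csv", base / "activity.csv",
                base / "admet.csv", base / "groups.csv")
    except Exception as exc:
        raise RuntimeError(f"phase 'data' failed: {exc}") from exc

    X = table.to_frame()
    y = activity.pic50
    n = table.n_compounds
    tr, va, te = split_dataset(n, SplitSpec(config.ratios, seed=config.seed + _SEED_SPLIT))

    # ----- phase 1: descriptor analysis -------------------------------
    try:
        full_model = train_regressor(X.iloc[tr], y[tr], config.model_family,
                                     hyperparams=config.importance_hyperparams,
                                     seed=config.seed + _SEED_SHAP)
        _attrib, ranking = shap_importance(
            full_model, X.iloc[tr], max_samples=config.shap_max_samples,
            max_background=config.shap_max_background,
            seed=config.seed + _SEED_SHAP)
        path = lassonet_path(X.iloc[tr], y[tr], hidden_sizes=config.lassonet_hidden,
                             M=config.lassonet_M, seed=config.seed + _SEED_LASSONET)
        groups = group_importance(path, table.group_map)
        candidates = build_candidate_set(ranking)

        sweep_chosen = None
        if config.run_sweep:
            grid = default_grid(min(config.sweep_max_k, len(candidates)))
            sweep = sweep_descriptor_count(
                X, y, candidates, grid=grid, reps=config.sweep_reps,
                model_family=config.model_family,
                seed=config.seed + _SEED_SWEEP, ratios=config.ratios)
            sweep_chosen = sweep.chosen_count
            _save_frame(sweep.to_frame(), "sweep.csv")

        selected = select_final(ranking, groups, n_total=config.n_total,
                                k_groups=config.k_groups,
                                per_group=config.per_group)
        _save_frame(selected.to_frame(), "selected_descriptors.csv")
        _save_frame(pd.DataFrame({"descriptor": ranking.names,
                                  "score": ranking.scores}), "shap_ranking.csv")
        _save_frame(pd.DataFrame({"group": groups.group_names,
                                  "score": groups.scores}), "group_scores.csv")

        validation_means = None
        if config.run_validation:
            report = perturbation_validation(
                X, y, ranking, candidates, reps=config.validation_reps,
                model_family=config.model_family,
                seed=config.seed + _SEED_VALIDATE, ratios=config.ratios)
            validation_means = {g: float(np.mean(report.r2[g]))
                                for g in report.groups}
            _save_frame(report.to_frame(), "validation.csv")
    except Exception as exc:
        raise RuntimeError(f"phase 'descriptor-analysis' failed: {exc}") from exc

    Xs = X[selected.names]

    # ----- phase 2: bioactivity regression ----------------------------
    try:
        f_hat = train_regressor(Xs.iloc[tr], y[tr], config.model_family,
                                seed=config.seed + _SEED_REGRESSION)
        reg_metrics = evaluate_regression(f_hat, Xs.iloc[te], y[te])
        family_means = None
        if config.compare_families:
            cmp_table = compare_model_families(
                Xs, y, reps=config.reps, seed=config.seed + _SEED_REGRESSION,
                ratios=config.ratios)
            family_means = {f: float(np.mean(cmp_table.r2[f]))
                            for f in cmp_table.families}
            _save_frame(cmp_table.to_frame(), "family_comparison.csv")
    except Exception as exc:
        raise RuntimeError(f"phase 'bioactivity-regression' failed: {exc}") from exc

    # ----- phase 3: ADMET classification ------------------------------
    try:
        g_hat = train_admet(Xs.iloc[tr], admet.y[tr], mode="multi",
                            seed=config.seed + _SEED_ADMET)
        adm_metrics = evaluate_admet(g_hat, Xs.iloc[te], admet.y[te])
        mwu_p = None
        if config.compare_admet_modes:
            mwu = compare_single_vs_multi(Xs, admet.y, reps=config.reps,
                                          seed=config.seed + _SEED_ADMET,
                                          ratios=config.ratios)
            mwu_p = {p: r.p_value for p, r in zip(mwu.properties, mwu.results)}
            _save_frame(mwu.to_frame(), "admet_mode_comparison.csv")
        _save_frame(adm_metrics.to_frame(), "admet_metrics.csv")
    except Exception as exc:
        raise RuntimeError(f"phase 'admet-classification' failed: {exc}") from exc

    # ----- phase 4: GA inverse design ---------------------------------
    try:
        scaler = fit_scaler(Xs.to_numpy(), selected.names, reference_rows=tr)
        ga_cfg = dataclasses.replace(config.ga, seed=config.seed + _SEED_GA)
        result = optimize(f_hat, g_hat, scaler, ga_cfg)
        matches = match_nearest(result.x_best, table, scaler, k=config.match_k,
                                activity=activity, feature_names=selected.names)
        _save_frame(matches.to_frame(), "nearest_matches.csv")
        _save_frame(pd.DataFrame({"generation": np.arange(result.best_trace.size),
                                  "best_fitness": result.best_trace}),
                    "ga_trace.csv")
        if outdir:
            p = outdir / "ga_result.json"
            p.write_text(json.dumps(result.to_dict(), indent=1))
            paths["ga_result.json"] = str(p)
    except Exception as exc:
        raise RuntimeError(f"phase 'ga-optimization' failed: {exc}") from exc

    report = RunReport(
        selected_descriptors=selected.names,
        candidate_count=len(candidates),
        group_ranking=groups.group_names,
        regression_r2=reg_metrics.r2,
        regression_mse=reg_metrics.mse,
        admet_acc=dict(zip(adm_metrics.properties, adm_metrics.acc.tolist())),
        admet_auc=dict(zip(adm_metrics.properties, adm_metrics.auc.tolist())),
        ga_predicted_pic50=result.predicted_pic50,
        ga_admet_sum=result.admet_sum,
        ga_feasible=result.feasible,
        best_observed_pic50=float(np.max(y)),
        matches=[{"SMILES": s, "distance": float(d),
                  "pIC50": float(p)}
                 for s, d, p in zip(matches.smiles, matches.distances,
                                    matches.pic50)],
        validation_means=validation_means,
        sweep_chosen_count=sweep_chosen,
        family_r2_means=family_means,
        admet_mwu_p=mwu_p,
        output_paths=paths,
    )

    if outdir:
        manifest = {"config": config.to_dict(), "version": __version__,
                    "seed": config.seed}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return report
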
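"""Shared fixtures.

Expensive artifacts (the full-size synthetic dataset, its importance
ranking, the per-seed recovery runs) are session-scoped and shared across
test modules so the suite stays within a desk-scale time budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from erainv.data_model import SplitSpec, split_dataset
from erainv.lassonet import group_importance, lassonet_path
from erainv.regression import train_regressor
from erainv.selection import build_candidate_set, select_final
from erainv.shapley import shap_importance
from erainv.synthetic import SyntheticConfig, generate

warnings.filterwarnings(
    "ignore", message="X does not have valid feature names")

#: hyperparameters of the full-descriptor importance model: column
#: subsampling spreads attribution over correlated descriptors
IMPORTANCE_HP = {"colsample_bytree": 0.3, "n_estimators": 300}

SMALL_CONFIG = SyntheticConfig(n_compounds=400, n_descriptors=60, n_groups=6,
                               n_informative=6, seed=7)
STUDY_CONFIG = SyntheticConfig()        # n=1500, d=200, 20 groups, 10 informative


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def study_dataset():
    return generate(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def study_ranking(study_dataset):
    """Importance model + Shapley ranking on the study-size dataset."""
    X = study_dataset.descriptor_table.to_frame()
    y = study_dataset.activity.pic50
    tr, _va, _te = split_dataset(X.shape[0], SplitSpec(seed=11))
    model = train_regressor(X.iloc[tr], y[tr], "gbt_a", IMPORTANCE_HP, seed=0)
    attrib, ranking = shap_importance(model, X.iloc[tr], max_samples=256,
                                      max_background=64, seed=0)
    return {"model": model, "attrib": attrib, "ranking": ranking,
            "train_idx": tr}


@dataclass
class RecoveryRun:
    seed: int
    top10_recovered: int
    final50_recovered: int
    signal_groups_in_top5: bool


@pytest.fixture(scope="session")
def recovery_runs(study_dataset, study_ranking):
    """Planted-signal recovery over five generator seeds.

    Each run regenerates the dataset, refits the importance model, reruns
    the LassoNet path and applies the hybrid 50-descriptor selection.
    """
    runs = []
    for seed in range(5):
        if seed == 0:
            ds, ranking = study_dataset, study_ranking["ranking"]
            tr = study_ranking["train_idx"]
        else:
            ds = generate(SyntheticConfig(seed=seed))
            X = ds.descriptor_table.to_frame()
            y = ds.activity.pic50
            tr, _va, _te = split_dataset(X.shape[0], SplitSpec(seed=11 + seed))
            model = train_regressor(X.iloc[tr], y[tr], "gbt_a", IMPORTANCE_HP,
                                    seed=seed)
            _, ranking = shap_importance(model, X.iloc[tr], max_samples=256,
                                         max_background=64, seed=seed)
        X = ds.descriptor_table.to_frame()
        y = ds.activity.pic50
        path = lassonet_path(X.iloc[tr], y[tr], seed=seed)
        groups = group_importance(path, ds.descriptor_table.group_map)
        selected = select_final(ranking, groups)
        informative = set(ds.truth.informative_set)
        signal_groups = {ds.descriptor_table.group_map[n] for n in informative}
        runs.append(RecoveryRun(
            seed=seed,
            top10_recovered=len(set(ranking.names[:10]) & informative),
            final50_recovered=len(set(selected.names) & informative),
            signal_groups_in_top5=signal_groups <= set(groups.top(5)),
        ))
    return runs
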
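"""Candidate construction, descriptor-count sweep, hybrid 50-descriptor
selection, and the perturbation-analysis validation.

The selection rule is hybrid: the Shapley ranking supplies a candidate set C
(descriptors with nonzero mean-|phi| score, sorted descending) and a count
sweep locates the plateau; the final list takes the top-scoring members of
the most important LassoNet groups first ("group-quota" picks) and fills the
remainder from the global Shapley ranking ("global-rank" picks).

Validation fits replicate models on five 50-descriptor strata — ranks 1-50,
51-100, 101-150, a random draw, and the complement of C — and checks that
test R^2 deteriorates from the first stratum to the last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admet import mannwhitney_compare
from .data_model import ConfigError, SplitSpec, split_dataset
from .lassonet import GroupScores
from .regression import evaluate_regression, train_regressor
from .shapley import ImportanceRanking

SCORE_EPS = 1e-12


@dataclass
class CandidateSet:
    """Descriptors with score > 1e-12, in importance order."""

    names: list[str]

    def __len__(self) -> int:
        return len(self.names)


def build_candidate_set(ranking: ImportanceRanking) -> CandidateSet:
    names = [n for n, s in zip(ranking.names, ranking.scores) if s > SCORE_EPS]
    if not names:
        raise ConfigError("all importance scores are zero; no candidates")
    return CandidateSet(names)


def default_grid(max_k: int = 290) -> np.ndarray:
    """The descriptor-count grid 2, 5, 8, ... up to ``max_k``."""
    return np.arange(2, max_k + 1, 3)


@dataclass
class SweepResult:
    grid: np.ndarray
    r2_mean: np.ndarray
    r2_std: np.ndarray
    mse_mean: np.ndarray
    mse_std: np.ndarray
    reps: int
    chosen_count: int
    delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.grid, "r2_mean": self.r2_mean,
                             "r2_std": self.r2_std, "mse_mean": self.mse_mean,
                             "mse_std": self.mse_std})


def sweep_descriptor_count(X: pd.DataFrame, y, candidates: CandidateSet,
                           grid=None, reps: int = 20, model_family: str = "gbt_a",
                           seed: int = 0, delta: float = 0.01,
                           ratios=(0.7, 0.15, 0.15),
                           hyperparams: dict | None = None) -> SweepResult:
    """Mean/std of test R^2 and MSE per descriptor count over ``reps``
    resampled splits; the chosen count is the smallest k whose mean R^2 is
    within ``delta`` of the grid maximum."""
    if grid is None:
        grid = default_grid(min(290, len(candidates)))
    grid = np.asarray(grid, dtype=int)
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("grid must be strictly increasing")
    if grid.max() > len(candidates):
        raise ConfigError(
            f"grid value {grid.max()} exceeds candidate count {len(candidates)}")
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    r2 = np.empty((grid.size, reps))
    mse = np.empty((grid.size, reps))
    for rep in range(reps):
        tr, _va, te = split_dataset(n, SplitSpec(ratios, seed=seed + rep))
        for gi, k in enumerate(grid):
            feats = candidates.names[:k]
            model = train_regressor(X[feats].iloc[tr], y[tr], model_family,
                                    hyperparams, seed=seed + rep)
            m = evaluate_regression(model, X[feats].iloc[te], y[te])
            r2[gi, rep] = m.r2
            mse[gi, rep] = m.mse
    r2_mean = r2.mean(axis=1)
    chosen = int(grid[np.argmax(r2_mean >= r2_mean.max() - delta)])
    return SweepResult(grid, r2_mean, r2.std(axis=1, ddof=1), mse.mean(axis=1),
                       mse.std(axis=1, ddof=1), reps, chosen, delta)


@dataclass
class SelectedDescriptors:
    names: list[str]
    provenance: dict[str, str]      # "group-quota" or "global-rank"

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"descriptor": self.names,
                             "provenance": [self.provenance[n] for n in self.names]})


def select_final(ranking: ImportanceRanking, group_scores: GroupScores,
                 n_total: int = 50, k_groups: int = 5, per_group: int = 2,
                 ) -> SelectedDescriptors:
    """Hybrid pick: ``per_group`` top-Shapley members from each of the
    ``k_groups`` best LassoNet groups, filled to ``n_total`` with the best
    remaining Shapley descriptors. Deterministic tie-breaks throughout."""
    if n_total > len(ranking):
        raise ConfigError("not enough descriptors to select from")
    score = ranking.as_dict()
    chosen: list[str] = []
    provenance: dict[str, str] = {}
    for group in group_scores.top(k_groups):
        members = sorted(group_scores.members[group],
                         key=lambda nm: (-score.get(nm, 0.0), nm))
        for nm in members[:per_group]:
            if nm not in provenance and len(chosen) < n_total:
                chosen.append(nm)
                provenance[nm] = "group-quota"
    for nm in ranking.names:
        if len(chosen) >= n_total:
            break
        if nm not in provenance:
            chosen.append(nm)
            provenance[nm] = "global-rank"
    if len(chosen) != n_total:
        raise ConfigError(
            f"could only select {len(chosen)} of {n_total} descriptors")
    return SelectedDescriptors(chosen, provenance)


CONTROL_GROUP_LABELS = ("top_1_50", "rank_51_100", "rank_101_150",
                        "random_50", "complement_of_C")


@dataclass
class ValidationReport:
    groups: list[str]
    r2: dict[str, np.ndarray]      # replicate R^2 per control group
    members: dict[str, list[str]]
    reps: int
    p_first_vs_last: float
    monotone_within_noise: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.groups,
            "r2_mean": [float(np.mean(self.r2[g])) for g in self.groups],
            "r2_std": [float(np.std(self.r2[g], ddof=1)) for g in self.groups],
            "reps": self.reps,
        })


def perturbation_validation(X: pd.DataFrame, y, ranking: ImportanceRanking,
                            candidates: CandidateSet, reps: int = 20,
                            model_family: str = "gbt_a", seed: int = 0,
                            group_size: int = 50, ratios=(0.7, 0.15, 0.15),
                            hyperparams: dict | None = None) -> ValidationReport:
    """Independent variable perturbation analysis over five control strata.

    Strata: top ``group_size`` by importance; ranks 51-100; ranks 101-150;
    a random ``group_size`` from the entire set; a random ``group_size`` from
    the complement of the candidate set (zero-score descriptors). The two
    random strata are redrawn on every replicate (with replicate-derived
    seeds, so a fixed base seed reproduces the same selections); the reported
    members are the first replicate's draws. If the complement is too small,
    the lowest-ranked descriptors are sampled instead, with a warning.
    """
    if len(ranking) < 3 * group_size:
        raise ConfigError(
            f"need at least {3 * group_size} ranked descriptors, have {len(ranking)}")
    names = ranking.names
    complement = [n for n in names if n not in set(candidates.names)]
    fixed: dict[str, list[str]] = {
        CONTROL_GROUP_LABELS[0]: names[:group_size],
        CONTROL_GROUP_LABELS[1]: names[group_size:2 * group_size],
        CONTROL_GROUP_LABELS[2]: names[2 * group_size:3 * group_size],
    }
    if len(complement) >= group_size:
        pool = complement
    else:
        warnings.warn(
            "complement of the candidate set has fewer than "
            f"{group_size} descriptors; sampling from the {group_size} "
            "lowest-ranked descriptors instead", stacklevel=2)
        pool = names[-group_size:]

    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    members: dict[str, list[str]] = dict(fixed)
    r2: dict[str, np.ndarray] = {g: np.empty(reps) for g in CONTROL_GROUP_LABELS}
    for rep in range(reps):
        rng = np.random.default_rng(seed + 1 + rep)
        tr, _va, te = split_dataset(n, SplitSpec(ratios, seed=seed + 1 + rep))
        draws = {
            CONTROL_GROUP_LABELS[3]: sorted(
                rng.choice(names, size=group_size, replace=False).tolist()),
            CONTROL_GROUP_LABELS[4]: sorted(
                rng.choice(pool, size=min(group_size, len(pool)),
                           replace=False).tolist()),
        }
        if rep == 0:
            members.update(draws)
        for g in CONTROL_GROUP_LABELS:
            feats = draws.get(g, fixed.get(g))
            model = train_regressor(X[feats].iloc[tr], y[tr], model_family,
                                    hyperparams, seed=seed + 1 + rep)
            r2[g][rep] = evaluate_regression(model, X[feats].iloc[te], y[te]).r2

    means = [float(np.mean(r2[g])) for g in CONTROL_GROUP_LABELS]
    stds = [float(np.std(r2[g], ddof=1)) for g in CONTROL_GROUP_LABELS]
    # a step counts as a violation only if the later mean exceeds the earlier
    # one by more than twice the pooled replicate spread: the verdict asks
    # whether the decline holds up to the noise of individual replicates
    # (the two random strata are redrawn per replicate, so their spread
    # includes selection randomness)
    monotone = all(
        means[i] >= means[i + 1]
        - 2.0 * np.sqrt(stds[i] ** 2 + stds[i + 1] ** 2)
        for i in range(4))
    p = mannwhitney_compare(r2[CONTROL_GROUP_LABELS[0]],
                            r2[CONTROL_GROUP_LABELS[4]],
                            alternative="greater").p_value
    return ValidationReport(list(CONTROL_GROUP_LABELS), r2, members, reps,
                            p, monotone)
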
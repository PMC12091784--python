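import numpy as np
import pandas as pd
import pytest

from erainv.data_model import ConfigError
from erainv.lassonet import GroupScores
from erainv.selection import (
    build_candidate_set,
    default_grid,
    perturbation_validation,
    select_final,
    sweep_descriptor_count,
)
from erainv.shapley import ImportanceRanking


def make_group_scores(scores: dict[str, float], members: dict[str, list[str]]):
    names = list(scores)
    return GroupScores(names, np.array([scores[g] for g in names]), members,
                       {m: 0.0 for ms in members.values() for m in ms})


# ---------------------------------------------------------------------------
# Candidate set


def test_candidate_set_excludes_zero_scores():
    ranking = ImportanceRanking(["a", "b", "c"], np.array([3.0, 0.0, 1.0]))
    assert build_candidate_set(ranking).names == ["a", "c"]


def test_candidate_set_all_zero_rejected():
    ranking = ImportanceRanking(["a", "b"], np.zeros(2))
    with pytest.raises(ConfigError):
        build_candidate_set(ranking)


def test_candidate_set_all_positive_is_permutation():
    rng = np.random.default_rng(0)
    names = [f"d{j}" for j in range(30)]
    ranking = ImportanceRanking(names, rng.uniform(0.1, 1, 30))
    assert sorted(build_candidate_set(ranking).names) == sorted(names)


# ---------------------------------------------------------------------------
# Sweep


def test_default_grid_is_the_printed_sequence():
    grid = default_grid()
    assert grid[0] == 2 and grid[1] == 5 and grid[2] == 8 and grid[-1] == 290
    assert len(grid) == 97
    assert np.all(np.diff(grid) == 3)


def test_sweep_deterministic_and_validated(small_dataset):
    X = small_dataset.descriptor_table.to_frame()
    y = small_dataset.activity.pic50
    names = list(X.columns)
    ranking = ImportanceRanking(names, np.linspace(1, 0.1, len(names)))
    C = build_candidate_set(ranking)
    grid = np.array([2, 5, 8])
    s1 = sweep_descriptor_count(X, y, C, grid=grid, reps=2, seed=3)
    s2 = sweep_descriptor_count(X, y, C, grid=grid, reps=2, seed=3)
    np.testing.assert_array_equal(s1.r2_mean, s2.r2_mean)
    assert s1.chosen_count in grid
    with pytest.raises(ConfigError):
        sweep_descriptor_count(X, y, C, grid=np.array([2, 1000]), reps=2, seed=3)


# ---------------------------------------------------------------------------
# Final selection


def test_select_final_toy_hand_enumeration():
    # 3 groups; quota picks the two best-scoring members of the top group(s)
    names = [f"d{j}" for j in range(9)]
    scores = np.array([9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    ranking = ImportanceRanking(names, scores)
    groups = make_group_scores(
        {"g1": 5.0, "g2": 3.0, "g3": 1.0},
        {"g1": ["d6", "d7", "d8"], "g2": ["d3", "d4", "d5"],
         "g3": ["d0", "d1", "d2"]})
    sel = select_final(ranking, groups, n_total=6, k_groups=2, per_group=2)
    # quota: g1 -> d6,d7 ; g2 -> d3,d4 ; fill: d0, d1
    assert sel.names == ["d6", "d7", "d3", "d4", "d0", "d1"]
    assert sel.provenance["d6"] == "group-quota"
    assert sel.provenance["d0"] == "global-rank"


def test_select_final_dedup_keeps_target_size():
    names = [f"d{j}" for j in range(10)]
    ranking = ImportanceRanking(names, np.linspace(10, 1, 10))
    groups = make_group_scores({"g1": 2.0, "g2": 1.0},
                               {"g1": names[:5], "g2": names[5:]})
    sel = select_final(ranking, groups, n_total=6, k_groups=2, per_group=2)
    assert len(sel) == 6
    assert len(set(sel.names)) == 6


def test_select_final_size_property_random_configs():
    rng = np.random.default_rng(7)
    for _ in range(50):
        d = int(rng.integers(20, 60))
        names = [f"d{j}" for j in range(d)]
        ranking = ImportanceRanking(names, rng.uniform(0, 1, d))
        n_groups = int(rng.integers(2, 6))
        assign = rng.integers(0, n_groups, d)
        members = {f"g{g}": [names[j] for j in np.flatnonzero(assign == g)]
                   for g in range(n_groups)}
        members = {g: ms for g, ms in members.items() if ms}
        gs = make_group_scores({g: float(rng.uniform()) for g in members}, members)
        n_total = int(rng.integers(5, d))
        sel = select_final(ranking, gs, n_total=n_total,
                           k_groups=min(3, len(members)), per_group=2)
        assert len(sel) == n_total
        assert len(set(sel.names)) == n_total


def test_select_final_small_group_falls_back_to_global():
    names = [f"d{j}" for j in range(8)]
    ranking = ImportanceRanking(names, np.linspace(8, 1, 8))
    groups = make_group_scores({"tiny": 5.0, "big": 1.0},
                               {"tiny": ["d7"], "big": names[:7]})
    sel = select_final(ranking, groups, n_total=4, k_groups=1, per_group=2)
    assert "d7" in sel.names and len(sel) == 4


# ---------------------------------------------------------------------------
# Perturbation validation


def test_control_group_definitions(small_dataset):
    X = small_dataset.descriptor_table.to_frame()
    y = small_dataset.activity.pic50
    names = list(X.columns)
    rng = np.random.default_rng(0)
    ranking = ImportanceRanking(names, rng.uniform(0.1, 1, len(names)))
    C = build_candidate_set(ranking)
    with pytest.warns(UserWarning, match="complement"):
        report = perturbation_validation(X, y, ranking, C, reps=2, seed=1,
                                         group_size=20)
    assert report.members["top_1_50"] == ranking.names[:20]
    assert report.members["rank_51_100"] == ranking.names[20:40]
    assert report.members["rank_101_150"] == ranking.names[40:60]
    assert len(report.members["random_50"]) == 20


def test_validation_random_groups_reproducible(small_dataset):
    X = small_dataset.descriptor_table.to_frame()
    y = small_dataset.activity.pic50
    names = list(X.columns)
    ranking = ImportanceRanking(names, np.linspace(1, 0.01, len(names)))
    C = build_candidate_set(ranking)
    kwargs = dict(reps=2, seed=5, group_size=15)
    with pytest.warns(UserWarning):
        r1 = perturbation_validation(X, y, ranking, C, **kwargs)
    with pytest.warns(UserWarning):
        r2 = perturbation_validation(X, y, ranking, C, **kwargs)
    assert r1.members == r2.members
    for g in r1.groups:
        np.testing.assert_array_equal(r1.r2[g], r2.r2[g])


def test_validation_requires_enough_descriptors(small_dataset):
    X = small_dataset.descriptor_table.to_frame()
    y = small_dataset.activity.pic50
    ranking = ImportanceRanking(list(X.columns)[:10], np.linspace(1, 0.1, 10))
    C = build_candidate_set(ranking)
    with pytest.raises(ConfigError):
        perturbation_validation(X, y, ranking, C, reps=2, seed=0, group_size=50)
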
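import numpy as np
import pytest

from erainv.data_model import ConfigError, MinMaxScaler, fit_scaler
from erainv.ga import GAConfig, admet_score, match_nearest, optimize


def unit_scaler(d: int) -> MinMaxScaler:
    return MinMaxScaler([f"x{j}" for j in range(d)], np.zeros(d), np.ones(d))


def sphere(P: np.ndarray) -> np.ndarray:
    return -((P - 0.5) ** 2).sum(axis=1)


class StepAdmet:
    """Favorable Caco-2 label iff x0 > cut; everything else unfavorable."""

    threshold = 0.5

    def __init__(self, cut: float, d: int):
        self.cut = cut
        self.feature_names = [f"x{j}" for j in range(d)]

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        p = np.zeros((X.shape[0], 5))
        p[:, 0] = (X[:, 0] > self.cut).astype(float)
        p[:, 2] = 0.9
        p[:, 4] = 0.9
        return p


def test_config_validation():
    with pytest.raises(ConfigError):
        GAConfig(population_size=101)
    with pytest.raises(ConfigError):
        GAConfig(t=6)
    with pytest.raises(ConfigError):
        GAConfig(crossover_rate=1.2)


def test_unconstrained_sphere_reaches_optimum():
    cfg = GAConfig(population_size=100, generations=200, t=0, seed=0,
                   mutation_switch_generation=100)
    res = optimize(sphere, None, unit_scaler(5), cfg)
    assert res.fitness > -1e-3
    np.testing.assert_allclose(res.x_best, 0.5, atol=0.05)


def test_constrained_optimum_on_boundary():
    cfg = GAConfig(population_size=100, generations=200, t=1, seed=0,
                   mutation_switch_generation=100)
    res = optimize(sphere, StepAdmet(0.7, 5), unit_scaler(5), cfg)
    assert res.feasible
    assert res.x_best[0] > 0.7
    assert res.x_best[0] < 0.75          # near the constraint boundary
    assert res.fitness == pytest.approx(-(res.x_best[0] - 0.5) ** 2
                                        - ((res.x_best[1:] - 0.5) ** 2).sum(),
                                        abs=1e-12)


def test_trace_non_decreasing_and_box_respected():
    cfg = GAConfig(population_size=60, generations=80, t=0, seed=3,
                   mutation_switch_generation=40)
    res = optimize(sphere, None, unit_scaler(4), cfg)
    assert np.all(np.diff(res.best_trace) >= 0)
    assert np.all((res.x_best >= 0) & (res.x_best <= 1))


def test_deterministic_given_seed():
    cfg = GAConfig(population_size=50, generations=50, t=0, seed=11,
                   mutation_switch_generation=25)
    r1 = optimize(sphere, None, unit_scaler(3), cfg)
    r2 = optimize(sphere, None, unit_scaler(3), cfg)
    np.testing.assert_array_equal(r1.x_best, r2.x_best)
    np.testing.assert_array_equal(r1.best_trace, r2.best_trace)


def test_saturation_on_surrogate():
    """Once converged, doubling the generation budget buys < 1e-4: the
    best-so-far trace at twice the convergence generation barely improves
    on the value at the convergence generation."""
    cfg = GAConfig(population_size=100, generations=1200, t=0, seed=5,
                   mutation_switch_generation=100)
    trace = optimize(sphere, None, unit_scaler(5), cfg).best_trace
    assert trace[1199] - trace[599] < 1e-4


def test_penalty_dominance():
    """With a large penalty weight no infeasible individual outranks a
    feasible one: the returned optimum is always feasible when one exists."""
    cfg = GAConfig(population_size=100, generations=100, t=1, seed=7,
                   penalty_weight=50.0, mutation_switch_generation=50)
    res = optimize(sphere, StepAdmet(0.9, 3), unit_scaler(3), cfg)
    assert res.feasible
    assert res.x_best[0] > 0.9


def test_admet_score_recoding():
    d = 3
    scaler = unit_scaler(d)

    class AllOnes:
        threshold = 0.5
        feature_names = scaler.feature_names

        def predict_proba(self, X):
            return np.full((np.atleast_2d(X).shape[0], 5), 0.9)

    class AllZeros(AllOnes):
        def predict_proba(self, X):
            return np.full((np.atleast_2d(X).shape[0], 5), 0.1)

    x = np.full(d, 0.5)
    # raw labels (1,1,1,1,1): Caco-2, CYP3A4, HOB favorable; hERG, MN toxic
    assert admet_score(AllOnes(), x, scaler)[0] == 3
    # raw labels (0,0,0,0,0): the two toxicity endpoints count as favorable
    assert admet_score(AllZeros(), x, scaler)[0] == 2


# ---------------------------------------------------------------------------
# Nearest-compound decoding


def test_match_nearest_hand_example():
    table = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 4.0]])
    scaler = MinMaxScaler(["a", "b"], np.zeros(2), np.ones(2))
    res = match_nearest(np.array([0.0, 0.0]), table, scaler, k=3)
    np.testing.assert_allclose(res.distances, [0.0, np.sqrt(2), 5.0])
    assert res.smiles[0] == "row_0"


def test_match_nearest_exact_row_is_first(small_dataset):
    table = small_dataset.descriptor_table
    names = table.descriptor_names[:10]
    sub = table.values[:, :10]
    scaler = fit_scaler(sub, names)
    x_hat = scaler.transform(sub[17:18])[0]
    res = match_nearest(x_hat, sub, scaler, k=3)
    assert res.smiles[0] == "row_17"
    assert res.distances[0] == pytest.approx(0.0, abs=1e-12)


def test_match_nearest_equals_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n, d = int(rng.integers(5, 40)), int(rng.integers(2, 8))
        table = rng.uniform(0, 10, size=(n, d))
        scaler = fit_scaler(table, [f"c{j}" for j in range(d)])
        x_hat = rng.uniform(0, 1, size=d)
        k = int(rng.integers(1, n + 1))
        res = match_nearest(x_hat, table, scaler, k=k)
        norm = scaler.transform(table)
        dist = np.sqrt(((norm - x_hat) ** 2).sum(axis=1))
        order = np.argsort(dist, kind="stable")[:k]
        np.testing.assert_allclose(res.distances, dist[order], atol=1e-12)
        assert res.smiles == [f"row_{i}" for i in order]


def test_match_nearest_rejects_oversized_k():
    scaler = MinMaxScaler(["a"], np.zeros(1), np.ones(1))
    with pytest.raises(ConfigError):
        match_nearest(np.array([0.5]), np.ones((2, 1)), scaler, k=3)
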
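"""Constrained genetic-algorithm inverse design over normalized descriptors.

The search space is [0,1]^d (min-max normalized descriptor values). Fitness
is the predicted pIC50 from the trained regressor, penalized when the sum of
favorability-recoded ADMET predictions falls below the threshold t:

    fitness(x) = f_hat(x) - penalty_weight * max(0, t - sum_k g_hat_k(x))

where each of the five binary ADMET predictions counts 1 when favorable:
Caco-2, CYP3A4 and HOB count their raw label, hERG and MN count the
*absence* of the label (1 codes cardiotoxic / genotoxic there, and summing
raw labels would reward toxicity). The GA is generational with elitism 1,
tournament selection, uniform crossover, per-gene Gaussian mutation clipped
to [0,1], and a scheduled mutation-rate drop once the search saturates.
Because descriptor vectors rarely decode to a synthesizable structure, the
optimum is interpreted through its nearest real compounds (Euclidean
distance in normalized space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admet import AdmetModel, predict_admet
from .data_model import ADMET_FAVORABLE, ConfigError, DescriptorTable, MinMaxScaler
from .regression import RegressionModel


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 500
    generations: int = 5000
    crossover_rate: float = 0.8
    mutation_rate_initial: float = 0.85
    mutation_rate_late: float = 0.5
    mutation_switch_generation: int = 2000
    mutation_sigma: float = 0.1
    tournament_size: int = 3
    t: int = 3
    penalty_weight: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate_initial,
                  self.mutation_rate_late):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.population_size % 2 or self.population_size < 4:
            raise ConfigError("population size must be even and >= 4")
        if not 0 <= self.t <= 5:
            raise ConfigError("ADMET threshold t must be in 0..5")
        if self.penalty_weight <= 0:
            raise ConfigError("penalty weight must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "GAConfig":
        """Reduced profile (pop 100, 300 generations) for quick runs."""
        params = dict(population_size=100, generations=300,
                      mutation_switch_generation=150)
        params.update(overrides)
        return cls(**params)


def admet_score(g_hat: AdmetModel, x_norm: np.ndarray, scaler: MinMaxScaler
                ) -> np.ndarray:
    """Favorability-recoded ADMET sum in 0..5 for each normalized row."""
    X = np.atleast_2d(np.asarray(x_norm, dtype=float))
    raw = scaler.inverse_transform(X)
    _, labels = predict_admet(g_hat, raw)
    fav = np.asarray(ADMET_FAVORABLE)
    return (labels == fav).sum(axis=1)


@dataclass
class OptimizationResult:
    x_best: np.ndarray             # normalized, in [0,1]^d
    x_best_raw: np.ndarray         # inverse-scaled descriptor values
    fitness: float                 # penalized fitness of x_best
    predicted_pic50: float
    admet_sum: int
    feasible: bool
    best_trace: np.ndarray         # best-so-far fitness per generation
    config: GAConfig
    feature_names: list[str]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "x_best_normalized": self.x_best.tolist(),
            "x_best_raw": self.x_best_raw.tolist(),
            "fitness": self.fitness,
            "predicted_pic50": self.predicted_pic50,
            "admet_sum": self.admet_sum,
            "feasible": self.feasible,
            "t": self.config.t,
            "generations": int(self.best_trace.size),
        }


def optimize(f_hat, g_hat: AdmetModel | None, scaler: MinMaxScaler,
             config: GAConfig = GAConfig()) -> OptimizationResult:
    """Run the constrained GA; deterministic given ``config.seed``.

    ``f_hat`` may be a trained :class:`RegressionModel` or any callable on a
    (pop, d) matrix of *normalized* rows (the latter is used by analytic
    surrogate tests, with the scaler as identity). ``g_hat=None`` disables
    the ADMET constraint (equivalent to t = 0).
    """
    d = len(scaler.feature_names)
    if isinstance(f_hat, RegressionModel):
        if g_hat is not None and f_hat.feature_names != g_hat.feature_names:
            raise ConfigError("f_hat and g_hat must share the same feature list")

        def predict_f(pop: np.ndarray) -> np.ndarray:
            return f_hat.predict(scaler.inverse_transform(pop))
    else:
        predict_f = f_hat

    def fitness_of(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = np.asarray(predict_f(pop), dtype=float)
        if g_hat is None or config.t == 0:
            score = np.full(pop.shape[0], 5)
        else:
            score = admet_score(g_hat, pop, scaler)
        shortfall = np.maximum(0, config.t - score)
        return f - config.penalty_weight * shortfall, f, score

    rng = np.random.default_rng(config.seed)
    pop = rng.random((config.population_size, d))
    fit, f_raw, score = fitness_of(pop)

    best_trace = np.empty(config.generations)
    best_idx = int(np.argmax(fit))
    best = (fit[best_idx], pop[best_idx].copy(), f_raw[best_idx], score[best_idx])

    for gen in range(config.generations):
        mut_rate = (config.mutation_rate_initial
                    if gen < config.mutation_switch_generation
                    else config.mutation_rate_late)
        # tournament selection
        k = config.tournament_size
        contenders = rng.integers(0, config.population_size,
                                  size=(config.population_size, k))
        winners = contenders[np.arange(config.population_size),
                             np.argmax(fit[contenders], axis=1)]
        parents = pop[winners]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        do_cx = rng.random(config.population_size // 2) < config.crossover_rate
        swap_mask = rng.random((config.population_size // 2, d)) < 0.5
        swap_mask &= do_cx[:, None]
        p1 = children[0::2]
        p2 = children[1::2]
        tmp = p1.copy()
        p1[swap_mask] = p2[swap_mask]
        p2[swap_mask] = tmp[swap_mask]
        # per-gene Gaussian mutation, clipped to the unit box
        mut_mask = rng.random(children.shape) < mut_rate
        children = children + mut_mask * rng.normal(0.0, config.mutation_sigma,
                                                    size=children.shape)
        np.clip(children, 0.0, 1.0, out=children)
        # elitism 1: the best-so-far individual replaces the first child
        children[0] = best[1]
        pop = children
        fit, f_raw, score = fitness_of(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best[0]:
            best = (fit[gen_best], pop[gen_best].copy(),
                    f_raw[gen_best], score[gen_best])
        best_trace[gen] = best[0]

    x_best = best[1]
    return OptimizationResult(
        x_best=x_best,
        x_best_raw=scaler.inverse_transform(x_best[None, :])[0],
        fitness=float(best[0]),
        predicted_pic50=float(best[2]),
        admet_sum=int(best[3]),
        feasible=bool(best[3] >= config.t),
        best_trace=best_trace,
        config=config,
        feature_names=list(scaler.feature_names),
    )


@dataclass
class MatchResult:
    smiles: list[str]
    distances: np.ndarray
    pic50: np.ndarray | None

    def to_frame(self) -> pd.DataFrame:
        data = {"SMILES": self.smiles, "distance": self.distances}
        if self.pic50 is not None:
            data["pIC50"] = self.pic50
        return pd.DataFrame(data)


def match_nearest(x_hat: np.ndarray, table: DescriptorTable | np.ndarray,
                  scaler: MinMaxScaler, k: int = 3,
                  activity=None, feature_names: list[str] | None = None,
                  ) -> MatchResult:
    """The k compounds nearest to x_hat by Euclidean distance in normalized
    space; ties broken by row order."""
    if isinstance(table, DescriptorTable):
        names = feature_names or scaler.feature_names
        cols = [table.descriptor_names.index(nm) for nm in names]
        values = table.values[:, cols]
        smiles = table.smiles
    else:
        values = np.asarray(table, dtype=float)
        smiles = [f"row_{i}" for i in range(values.shape[0])]
    if values.shape[0] == 0:
        raise ConfigError("descriptor table is empty")
    if k > values.shape[0]:
        raise ConfigError(f"k={k} exceeds table size {values.shape[0]}")
    norm_rows = scaler.transform(values, clip=False)
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    dist = np.sqrt(((norm_rows - x_hat) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    pic50 = None
    if activity is not None:
        pic50 = np.asarray(activity.pic50, dtype=float)[order]
    return MatchResult([smiles[i] for i in order], dist[order], pic50)
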
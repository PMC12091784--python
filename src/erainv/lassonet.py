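"""LassoNet: l1-penalized skip-layer feature selection with a hierarchy bound.

The model is a small feed-forward network with a linear skip connection:

    f(x) = theta . x + MLP(x),

trained by minimizing  L(theta, W) + lambda * ||theta||_1  subject to the
per-feature hierarchy constraint  ||W_j^(1)||_inf <= M * |theta_j|,
so a feature can reach the hidden layers only while its skip weight is
nonzero. Training follows the dense-to-sparse warm-started path: after every
gradient step the (theta_j, W_j^(1)) pairs are projected by the hierarchical
proximal operator, which solves

    min_{t, w} 1/2 (t - v)^2 + 1/2 ||w - u||^2 + lam |t|
    s.t. ||w||_inf <= M |t|

in closed form and yields exact zeros. The feature-level output is
lambda_drop(j): the smallest path penalty at which theta_j hits zero and
stays zero; group scores average lambda_drop over group members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ConfigError


# ---------------------------------------------------------------------------
# Hierarchical proximal operator


def hier_prox(theta: np.ndarray, W: np.ndarray, lam: float, M: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the hierarchy prox to every (theta_j, W_j) pair.

    ``theta``: (d,) skip weights; ``W``: (d, h) first-layer weights (row j =
    weights of feature j). Returns updated copies; the constraint
    ||W_j||_inf <= M |theta_j| holds exactly on the output.
    """
    theta = np.asarray(theta, dtype=float)
    W = np.asarray(W, dtype=float)
    d, h = W.shape
    absW = np.abs(W)
    s = -np.sort(-absW, axis=1)                      # sorted desc, (d, h)
    cum = np.concatenate([np.zeros((d, 1)), np.cumsum(s, axis=1)], axis=1)
    m = np.arange(h + 1)[None, :]
    soft = np.maximum(np.abs(theta)[:, None] + M * cum - lam, 0.0)
    w_m = (M / (1.0 + m * M * M)) * soft             # (d, h+1)

    # first m with s_m >= w_m >= s_{m+1}   (s_0 = +inf, s_{h+1} = 0)
    upper = np.concatenate([np.full((d, 1), np.inf), s], axis=1)
    lower = np.concatenate([s, np.zeros((d, 1))], axis=1)
    ok = (w_m <= upper) & (w_m >= lower)
    ok[:, -1] |= ~ok.any(axis=1)                     # numerical safety net
    m_star = np.argmax(ok, axis=1)
    w_star = w_m[np.arange(d), m_star]

    theta_new = np.sign(theta) * w_star / M
    # features with theta exactly 0 keep sign from W side irrelevant; sign(0)=0
    # would zero a positive w_star — but w_star>0 requires |theta|+Mcum>lam, and
    # if theta==0 the optimal t keeps sign free; choose +1.
    zero_t = (theta == 0) & (w_star > 0)
    theta_new[zero_t] = w_star[zero_t] / M
    # cap by M|theta_new| (not w_star) so the constraint holds exactly in floats
    W_new = np.sign(W) * np.minimum(absW, M * np.abs(theta_new)[:, None])
    return theta_new, W_new


# ---------------------------------------------------------------------------
# Network


class _Net:
    """Two-hidden-layer ReLU MLP with a linear skip layer, trained by Adam."""

    def __init__(self, d: int, hidden: tuple[int, int], seed: int):
        rng = np.random.default_rng(seed)
        h1, h2 = hidden
        self.W1 = rng.normal(0, np.sqrt(2.0 / d), (d, h1))
        self.b1 = np.zeros(h1)
        self.W2 = rng.normal(0, np.sqrt(2.0 / h1), (h1, h2))
        self.b2 = np.zeros(h2)
        self.w3 = rng.normal(0, np.sqrt(2.0 / h2), h2)
        self.b3 = 0.0
        self.theta = np.zeros(d)
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def params(self):
        return ["W1", "b1", "W2", "b2", "w3", "b3", "theta"]

    def forward(self, X: np.ndarray):
        A1 = X @ self.W1 + self.b1
        H1 = np.maximum(A1, 0.0)
        A2 = H1 @ self.W2 + self.b2
        H2 = np.maximum(A2, 0.0)
        out = H2 @ self.w3 + self.b3 + X @ self.theta
        return out, (A1, H1, A2, H2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        out = self.predict(X)
        return float(0.5 * np.mean((out - y) ** 2))

    def gradients(self, X: np.ndarray, y: np.ndarray):
        n = X.shape[0]
        out, (A1, H1, A2, H2) = self.forward(X)
        delta = (out - y) / n                     # dL/dout
        g = {
            "w3": H2.T @ delta,
            "b3": float(delta.sum()),
            "theta": X.T @ delta,
        }
        d2 = np.outer(delta, self.w3) * (A2 > 0)
        g["W2"] = H1.T @ d2
        g["b2"] = d2.sum(axis=0)
        d1 = (d2 @ self.W2.T) * (A1 > 0)
        g["W1"] = X.T @ d1
        g["b1"] = d1.sum(axis=0)
        return g

    def adam_step(self, grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        for name in self.params():
            gval = grads[name]
            p = getattr(self, name)
            m, v = self._adam.get(name, (np.zeros_like(np.asarray(gval, dtype=float)),
                                         np.zeros_like(np.asarray(gval, dtype=float))))
            m = beta1 * m + (1 - beta1) * np.asarray(gval)
            v = beta2 * v + (1 - beta2) * np.asarray(gval) ** 2
            self._adam[name] = (m, v)
            mhat = m / (1 - beta1 ** self._t)
            vhat = v / (1 - beta2 ** self._t)
            update = lr * mhat / (np.sqrt(vhat) + eps)
            setattr(self, name, p - update)
        self.b3 = float(self.b3)


# ---------------------------------------------------------------------------
# Path


@dataclass
class PathPoint:
    lam: float
    theta: np.ndarray
    first_layer: np.ndarray
    active_set: np.ndarray       # bool mask over features
    train_loss: float
    val_loss: float

    def hierarchy_violation(self, M: float) -> float:
        return float(np.max(np.maximum(
            0.0, np.abs(self.first_layer).max(axis=1) - M * np.abs(self.theta))))


@dataclass
class LassoNetPath:
    feature_names: list[str]
    M: float
    points: list[PathPoint]
    lambda_drop: np.ndarray      # per feature

    def support_sizes(self) -> np.ndarray:
        return np.array([p.active_set.sum() for p in self.points])


def lassonet_path(X, y, feature_names: list[str] | None = None,
                  hidden_sizes: tuple[int, int] = (64, 32), M: float = 10.0,
                  lam_grid: np.ndarray | None = None, n_lambdas: int = 50,
                  init_iters: int = 300, path_iters: int = 60,
                  lr: float = 2e-2, val_fraction: float = 0.1,
                  seed: int = 0, standardize: bool = True) -> LassoNetPath:
    """Train the dense-to-sparse LassoNet path.

    The default penalty grid is geometric with ``n_lambdas`` points, anchored
    at the skip-layer gradient magnitude of the dense fit, and is extended
    geometrically (up to twice over) if the support has not emptied, so that
    every feature receives a finite drop penalty whenever possible; features
    still active at the end of the extended grid are assigned one geometric
    step beyond it.
    """
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(d)]
    if M <= 0:
        raise ConfigError("hierarchy bound M must be positive")

    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
        y = (y - y.mean()) / max(y.std(), 1e-12)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xva, yva = X[train_idx], y[train_idx], X[val_idx], y[val_idx]

    net = _Net(d, hidden_sizes, seed)
    for _ in range(init_iters):
        net.adam_step(net.gradients(Xtr, ytr), lr)
        if not np.isfinite(net.loss(Xtr, ytr)):
            raise FloatingPointError("divergent dense training (loss is not finite)")

    if lam_grid is None:
        g = np.abs(net.gradients(Xtr, ytr)["theta"])
        lam0 = max(float(np.max(g)) * 0.02, 1e-8)
        ratio = (1e4) ** (1.0 / (n_lambdas - 1))
        lam_grid = lam0 * ratio ** np.arange(n_lambdas)
    else:
        lam_grid = np.asarray(lam_grid, dtype=float)
        if np.any(np.diff(lam_grid) <= 0):
            raise ConfigError("lam_grid must be strictly increasing")
        ratio = lam_grid[-1] / lam_grid[-2] if lam_grid.size > 1 else 2.0

    points: list[PathPoint] = []

    def run_lambda(lam: float) -> PathPoint:
        for _ in range(path_iters):
            net.adam_step(net.gradients(Xtr, ytr), lr)
            net.theta, net.W1 = hier_prox(net.theta, net.W1, lam * lr, M)
        train_loss = net.loss(Xtr, ytr)
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"divergent training at lambda={lam:g}")
        return PathPoint(
            lam=float(lam), theta=net.theta.copy(), first_layer=net.W1.copy(),
            active_set=net.theta != 0.0, train_loss=train_loss,
            val_loss=net.loss(Xva, yva),
        )

    for lam in lam_grid:
        points.append(run_lambda(float(lam)))

    extra = 0
    lam = float(lam_grid[-1])
    while points[-1].active_set.any() and extra < 2 * n_lambdas:
        lam *= float(ratio)
        points.append(run_lambda(lam))
        extra += 1

    # lambda_drop: smallest lambda with theta_j == 0 from there on
    active = np.stack([p.active_set for p in points])        # (n_points, d)
    lams = np.array([p.lam for p in points])
    beyond = lams[-1] * float(ratio)
    lambda_drop = np.full(d, beyond)
    for j in range(d):
        nz = np.flatnonzero(active[:, j])
        if nz.size == 0:
            lambda_drop[j] = lams[0]
        elif nz[-1] + 1 < len(points):
            lambda_drop[j] = lams[nz[-1] + 1]
        # else: survived the whole path -> one step beyond
    return LassoNetPath(list(feature_names), float(M), points, lambda_drop)


# ---------------------------------------------------------------------------
# Group scores


@dataclass
class GroupScores:
    """Group -> nonnegative score (mean member lambda_drop), ordered
    score desc then group name asc; keeps the per-descriptor drops and the
    group membership used to compute them."""

    group_names: list[str]
    scores: np.ndarray
    members: dict[str, list[str]]
    lambda_drop: dict[str, float]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        order = sorted(range(len(self.group_names)),
                       key=lambda i: (-self.scores[i], self.group_names[i]))
        self.group_names = [self.group_names[i] for i in order]
        self.scores = self.scores[order]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.group_names, self.scores))

    def top(self, k: int) -> list[str]:
        return self.group_names[:k]


def group_importance(path: LassoNetPath, group_map: dict[str, str],
                     top_members: int = 3) -> GroupScores:
    """Score each descriptor group by the mean lambda_drop of its
    ``top_members`` longest-surviving members.

    Scoring a group by its strongest members rather than a full-group mean
    keeps large families (descriptor taxonomies are heavily skewed) from
    drowning a few genuinely informative members among inert siblings.
    """
    if not path.points:
        raise ConfigError("empty LassoNet path")
    drops = dict(zip(path.feature_names, path.lambda_drop))
    members: dict[str, list[str]] = {}
    for name in path.feature_names:
        members.setdefault(group_map[name], []).append(name)
    for group, mem in members.items():
        if not mem:
            raise ConfigError(f"group {group!r} has no members")
    # a feature that never entered the support contributes the smallest grid
    # penalty; a group whose members were never active scores the path floor
    lam_floor = path.points[0].lam
    names = sorted(members)
    scores = []
    ever_active = {
        f: any(p.active_set[i] for p in path.points)
        for i, f in enumerate(path.feature_names)
    }
    for g in names:
        if not any(ever_active[f] for f in members[g]):
            scores.append(0.0)
        else:
            vals = sorted((drops[f] for f in members[g]), reverse=True)
            scores.append(float(np.mean(vals[:top_members])))
    return GroupScores(names, np.array(scores), members, drops)
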
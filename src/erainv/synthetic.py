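"""Synthetic compound datasets with known ground truth.

Emulates the statistical structure the pipeline assumes: a compounds x
descriptors real-valued matrix partitioned into named groups (within-group
correlation 0.5, between-group 0), a sparse nonlinear activity function over
a small informative subset (linear part plus one pairwise interaction and
one hinge term, so nonlinear learners genuinely beat linear ones), Gaussian
observation noise on pIC50, and five binary ADMET labels driven by logits
that partially reuse the activity-informative descriptors. Every quantity
needed to re-evaluate the ground truth is stored alongside the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    ADMET_PROPERTIES,
    ActivityTable,
    AdmetTable,
    ConfigError,
    DescriptorTable,
    load_tables,
    write_tables,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``noise_sd`` (pIC50 units) may be left ``None``, in which case it is set
    so that the signal variance fraction of observed pIC50 is
    ``signal_fraction`` (default 0.8, the regime where a boosted-tree
    regressor lands in the R^2 ~ 0.7-0.8 band seen on the real data).
    Informative descriptors are concentrated in ``n_signal_groups`` groups so
    group-level selection is distinguishable from singleton ranking.
    """

    n_compounds: int = 1500
    n_descriptors: int = 200
    n_groups: int = 20
    n_informative: int = 10
    n_signal_groups: int = 2
    signal_group_fraction: float = 0.75
    noise_sd: float | None = None
    signal_fraction: float = 0.8
    admet_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ConfigError("n_informative exceeds n_descriptors")
        if self.n_groups > self.n_descriptors:
            raise ConfigError("n_groups exceeds n_descriptors")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not 0 < self.n_signal_groups <= self.n_groups:
            raise ConfigError("n_signal_groups out of range")
        if not 0 <= self.admet_overlap <= 1:
            raise ConfigError("admet_overlap must be in [0, 1]")
        if not 0 < self.signal_group_fraction < 1:
            raise ConfigError("signal_group_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to re-evaluate the noiseless activity function."""

    informative_set: list[str]
    informative_idx: np.ndarray
    col_mean: np.ndarray          # standardization of informative columns
    col_sd: np.ndarray
    activity_coefficients: np.ndarray   # beta on standardized scale
    interaction_pair: tuple[int, int]   # positions within informative_idx
    interaction_coef: float
    hinge_feature: int                  # position within informative_idx
    hinge_cut: float
    hinge_coef: float
    intercept: float
    noise_sd: float
    admet_logit_features: list[list[int]]   # column indices per endpoint
    admet_logit_coefficients: list[list[float]]
    admet_intercepts: list[float]
    admet_col_mean: np.ndarray
    admet_col_sd: np.ndarray


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    descriptor_table: DescriptorTable
    activity: ActivityTable
    admet: AdmetTable
    truth: GroundTruth


def _true_activity_matrix(truth: GroundTruth, X: np.ndarray) -> np.ndarray:
    """Noiseless g(X) for a (n, d) matrix of raw descriptor values."""
    z = (X[:, truth.informative_idx] - truth.col_mean) / truth.col_sd
    g = truth.intercept + z @ truth.activity_coefficients
    a, b = truth.interaction_pair
    g = g + truth.interaction_coef * z[:, a] * z[:, b]
    g = g + truth.hinge_coef * np.maximum(0.0, z[:, truth.hinge_feature] - truth.hinge_cut)
    return g


def true_activity(dataset: SyntheticDataset, x: np.ndarray) -> float | np.ndarray:
    """Evaluate the stored ground-truth activity g(x) without noise."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != dataset.config.n_descriptors:
        raise ConfigError(
            f"expected {dataset.config.n_descriptors} descriptor values, got {X.shape[1]}"
        )
    g = _true_activity_matrix(dataset.truth, X)
    return float(g[0]) if single else g


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; identical config (incl. seed) -> identical output."""
    rng = np.random.default_rng(config.seed)
    n, d = config.n_compounds, config.n_descriptors

    # group structure: skewed sizes, as in real descriptor taxonomies where a
    # few families (e.g. electrotopological states) hold most of the columns.
    # The signal-bearing groups jointly hold signal_group_fraction of the
    # descriptors so that their correlated members populate the middle of the
    # importance ranking rather than leaving a sparse-signal cliff.
    n_sig = config.n_signal_groups
    n_noise_groups = config.n_groups - n_sig
    if n_noise_groups == 0:
        sig_total = d
    else:
        sig_total = min(max(int(round(config.signal_group_fraction * d)),
                            config.n_informative), d - n_noise_groups)
    sizes = np.zeros(config.n_groups, dtype=int)
    sizes[:n_sig] = sig_total // n_sig
    sizes[:sig_total % n_sig] += 1
    rest = d - sizes.sum()
    if n_noise_groups > 0:
        if rest < n_noise_groups:
            raise ConfigError("too many groups for the non-signal descriptors")
        sizes[n_sig:] = rest // n_noise_groups
        sizes[n_sig:n_sig + rest % n_noise_groups] += 1
    group_of = np.repeat(np.arange(config.n_groups), sizes)
    signal_groups = np.arange(n_sig)
    group_names = [f"group_{g:02d}" for g in range(config.n_groups)]
    desc_names = [f"desc_{j:04d}" for j in range(d)]
    group_map = {desc_names[j]: group_names[group_of[j]] for j in range(d)}

    # within-group correlation 0.5 via a shared group factor
    factors = rng.standard_normal((n, config.n_groups))
    Z = np.sqrt(0.5) * factors[:, group_of] + np.sqrt(0.5) * rng.standard_normal((n, d))
    # rescale to plausible positive descriptor ranges
    scale = rng.uniform(0.5, 5.0, size=d)
    X = scale * (Z + 4.0)

    per = np.full(n_sig, config.n_informative // n_sig)
    per[: config.n_informative % n_sig] += 1
    inf_idx: list[int] = []
    for g, k in zip(signal_groups, per):
        members = np.flatnonzero(group_of == g)
        if k > members.size:
            raise ConfigError("signal group too small for requested informative count")
        inf_idx.extend(rng.choice(members, size=k, replace=False).tolist())
    inf_idx = np.array(sorted(inf_idx))

    col_mean = X[:, inf_idx].mean(axis=0)
    col_sd = X[:, inf_idx].std(axis=0)
    z = (X[:, inf_idx] - col_mean) / col_sd

    # coherent effect direction per signal group (a descriptor family pushes
    # potency one way), so the shared group factor carries most of the signal
    # and correlated non-informative members remain informative proxies
    beta = rng.uniform(0.5, 1.5, size=config.n_informative)
    group_sign = {g: s for g, s in zip(signal_groups,
                                       rng.choice([-1.0, 1.0], size=n_sig))}
    beta *= np.array([group_sign[group_of[j]] for j in inf_idx])
    linear = z @ beta
    var_lin = linear.var()

    # nonlinear terms sized to ~30% of the linear variance (15% each)
    ia, ib = rng.choice(config.n_informative, size=2, replace=False)
    inter_raw = z[:, ia] * z[:, ib]
    gamma_int = np.sqrt(0.15 * var_lin) / max(inter_raw.std(), 1e-12)
    hinge_feat = int(rng.integers(config.n_informative))
    hinge_cut = float(rng.uniform(-0.5, 0.5))
    hinge_raw = np.maximum(0.0, z[:, hinge_feat] - hinge_cut)
    gamma_hinge = np.sqrt(0.15 * var_lin) / max(hinge_raw.std(), 1e-12)

    g_centered = linear + gamma_int * inter_raw + gamma_hinge * hinge_raw
    # map onto a realistic pIC50 scale: mean ~6.5, signal sd ~1.2
    g_sd = max(g_centered.std(), 1e-12)
    a_scale = 1.2 / g_sd
    intercept = 6.5 - a_scale * g_centered.mean()

    beta_s = beta * a_scale
    gamma_int_s = float(gamma_int * a_scale)
    gamma_hinge_s = float(gamma_hinge * a_scale)

    if config.noise_sd is None:
        sf = config.signal_fraction
        g_var = (a_scale * g_centered).var()
        noise_sd = float(np.sqrt(g_var * (1.0 - sf) / sf))
    else:
        noise_sd = float(config.noise_sd)

    truth = GroundTruth(
        informative_set=[desc_names[j] for j in inf_idx],
        informative_idx=inf_idx,
        col_mean=col_mean,
        col_sd=col_sd,
        activity_coefficients=beta_s,
        interaction_pair=(int(ia), int(ib)),
        interaction_coef=gamma_int_s,
        hinge_feature=hinge_feat,
        hinge_cut=hinge_cut,
        hinge_coef=gamma_hinge_s,
        intercept=float(intercept),
        noise_sd=noise_sd,
        admet_logit_features=[],
        admet_logit_coefficients=[],
        admet_intercepts=[],
        admet_col_mean=X.mean(axis=0),
        admet_col_sd=np.maximum(X.std(axis=0), 1e-12),
    )

    g_true = _true_activity_matrix(truth, X)
    pic50 = g_true + noise_sd * rng.standard_normal(n)
    ic50 = 10.0 ** (9.0 - pic50)

    # ADMET labels: logits over informative + fresh descriptors
    z_all = (X - truth.admet_col_mean) / truth.admet_col_sd
    n_per_label = 6
    n_reuse = int(round(config.admet_overlap * n_per_label))
    non_inf = np.setdiff1d(np.arange(d), inf_idx)
    Y = np.zeros((n, 5), dtype=int)
    for k in range(5):
        reuse = rng.choice(inf_idx, size=min(n_reuse, inf_idx.size), replace=False)
        fresh = rng.choice(non_inf, size=n_per_label - reuse.size, replace=False)
        cols = np.concatenate([reuse, fresh]).astype(int)
        w = rng.uniform(0.5, 1.5, size=cols.size) * rng.choice([-1.0, 1.0], size=cols.size)
        eta = z_all[:, cols] @ w
        eta *= 8.0 / max(eta.std(), 1e-12)   # strong signal: labels learnable
        noise = rng.logistic(0.0, 1.0, size=n)
        # resample the intercept until prevalence lands in [0.2, 0.8]
        for attempt in range(100):
            c = float(rng.normal(0.0, 2.0))
            y = (eta + c + noise > 0).astype(int)
            if 0.2 <= y.mean() <= 0.8:
                break
        else:
            raise ConfigError(
                f"could not achieve prevalence in [0.2, 0.8] for {ADMET_PROPERTIES[k]}"
            )
        Y[:, k] = y
        truth.admet_logit_features.append(cols.tolist())
        truth.admet_logit_coefficients.append(w.tolist())
        truth.admet_intercepts.append(c)

    smiles = [f"CMPD{i:05d}" for i in range(n)]
    table = DescriptorTable(smiles, desc_names, X, group_map)
    activity = ActivityTable(smiles, pic50, ic50)
    admet = AdmetTable(smiles, Y)
    return SyntheticDataset(config, table, activity, admet, truth)


def write_fixture(dataset: SyntheticDataset, directory: str | Path,
                  force: bool = False) -> dict[str, Path]:
    """Write the four CSVs plus a truth JSON; ``load_tables`` round-trips."""
    directory = Path(directory)
    paths = write_tables(dataset.descriptor_table, dataset.activity,
                         dataset.admet, directory, force=force)
    truth_path = directory / "truth.json"
    if truth_path.exists() and not force:
        raise FileExistsError(f"{truth_path} exists; pass force=True to overwrite")
    t = dataset.truth
    payload = {
        "informative_set": t.informative_set,
        "informative_idx": t.informative_idx.tolist(),
        "col_mean": t.col_mean.tolist(),
        "col_sd": t.col_sd.tolist(),
        "activity_coefficients": t.activity_coefficients.tolist(),
        "interaction_pair": list(t.interaction_pair),
        "interaction_coef": t.interaction_coef,
        "hinge_feature": t.hinge_feature,
        "hinge_cut": t.hinge_cut,
        "hinge_coef": t.hinge_coef,
        "intercept": t.intercept,
        "noise_sd": t.noise_sd,
        "admet_logit_features": t.admet_logit_features,
        "admet_logit_coefficients": t.admet_logit_coefficients,
        "admet_intercepts": t.admet_intercepts,
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    paths["truth"] = truth_path
    return paths


def load_fixture(directory: str | Path):
    """Reload a written fixture's tables (truth JSON is read separately)."""
    directory = Path(directory)
    return load_tables(directory / "descriptors.csv", directory / "activity.csv",
                       directory / "admet.csv", directory / "groups.csv")
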
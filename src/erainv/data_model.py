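"""Tabular containers, I/O, unit conversion, scaling and splitting.

The pipeline works on three row-aligned tables keyed by SMILES strings
(treated as opaque compound identifiers): a compounds x descriptors matrix
with a descriptor -> group map, an activity table (IC50 in nM and/or pIC50),
and a five-column binary ADMET label table (Caco-2, CYP3A4, hERG, HOB, MN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ADMET_PROPERTIES: tuple[str, ...] = ("Caco-2", "CYP3A4", "hERG", "HOB", "MN")

#: labels are coded so that 1 means permeable / metabolizable / cardiotoxic /
#: bioavailable / genotoxic respectively; the *favorable* outcome per column.
ADMET_FAVORABLE: tuple[int, ...] = (1, 1, 0, 1, 0)


class AlignmentError(ValueError):
    """SMILES keys do not line up across the input tables."""


class TableParseError(ValueError):
    """A cell could not be parsed; carries row/column coordinates."""


class ConfigError(ValueError):
    """Invalid configuration (ratios, shapes, ...)."""


# ---------------------------------------------------------------------------
# Containers


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix with named columns and a group map."""

    smiles: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    group_map: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("descriptor values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.smiles):
            raise ConfigError(
                f"row count {n} does not match number of SMILES {len(self.smiles)}"
            )
        if d != len(self.descriptor_names):
            raise ConfigError(
                f"column count {d} does not match descriptor names {len(self.descriptor_names)}"
            )
        if len(set(self.descriptor_names)) != d:
            raise ConfigError("duplicate descriptor names")
        missing = [c for c in self.descriptor_names if c not in self.group_map]
        if missing:
            raise ConfigError(f"descriptors missing from group map: {missing[:5]}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableParseError(
                f"non-finite descriptor value at row {i} column {self.descriptor_names[j]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.descriptor_names, copy=True)

    def groups(self) -> dict[str, list[str]]:
        """Group name -> member descriptor names (column order)."""
        out: dict[str, list[str]] = {}
        for name in self.descriptor_names:
            out.setdefault(self.group_map[name], []).append(name)
        return out


@dataclass
class ActivityTable:
    """Per-compound potency: IC50 (nM) and/or pIC50 = 9 - log10(IC50 nM)."""

    smiles: list[str]
    pic50: np.ndarray
    ic50_nM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pic50 = np.asarray(self.pic50, dtype=float)
        if self.pic50.shape != (len(self.smiles),):
            raise ConfigError("pic50 must be one value per compound")
        if self.ic50_nM is not None:
            self.ic50_nM = np.asarray(self.ic50_nM, dtype=float)
            if np.any(self.ic50_nM <= 0):
                raise ConfigError("IC50 values must be positive")
            expected = 9.0 - np.log10(self.ic50_nM)
            if np.max(np.abs(expected - self.pic50)) > 1e-9:
                raise ConfigError("pIC50 inconsistent with IC50 (9 - log10 nM)")


@dataclass
class AdmetTable:
    """Binary labels for the five ADMET endpoints, one row per compound."""

    smiles: list[str]
    y: np.ndarray  # (n, 5) in {0, 1}

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.shape != (len(self.smiles), len(ADMET_PROPERTIES)):
            raise ConfigError(
                f"ADMET labels must have shape (n, {len(ADMET_PROPERTIES)})"
            )
        if not np.isin(self.y, (0, 1)).all():
            raise ConfigError("ADMET labels must be strictly 0/1")
        self.y = self.y.astype(int)


# ---------------------------------------------------------------------------
# Unit conversion


def ic50_to_pic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in molar) = 9 - log10(IC50 in nM)."""
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50`, returning nM."""
    return 10.0 ** (9.0 - pic50)


# ---------------------------------------------------------------------------
# Min-max scaling


@dataclass
class MinMaxScaler:
    """Per-descriptor [0, 1] scaling learned from a reference (training) table.

    Constant columns map to 0; out-of-range values are clipped, so the GA
    search box [0,1]^d always decodes to descriptor values seen in training.
    """

    feature_names: list[str]
    minimum: np.ndarray
    maximum: np.ndarray

    @property
    def range_(self) -> np.ndarray:
        return self.maximum - self.minimum

    def transform(self, matrix: np.ndarray, clip: bool = True) -> np.ndarray:
        """Scale to [0,1]; with ``clip=False`` out-of-reference values keep
        their true scaled position (used for distances, not for GA decoding)."""
        x = np.asarray(matrix, dtype=float)
        rng = self.range_
        safe = np.where(rng > 0, rng, 1.0)
        out = (x - self.minimum) / safe
        out[..., rng == 0] = 0.0
        return np.clip(out, 0.0, 1.0) if clip else out

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        x = np.asarray(matrix, dtype=float)
        return self.minimum + x * self.range_


def fit_scaler(values: np.ndarray, feature_names: list[str],
               reference_rows: np.ndarray | None = None) -> MinMaxScaler:
    """Learn per-column min/max from ``reference_rows`` (default: all rows)."""
    values = np.asarray(values, dtype=float)
    ref = values if reference_rows is None else values[np.asarray(reference_rows)]
    if ref.shape[0] == 0:
        raise ConfigError("reference rows must be nonempty")
    return MinMaxScaler(
        feature_names=list(feature_names),
        minimum=ref.min(axis=0),
        maximum=ref.max(axis=0),
    )


def apply_scaler(scaler: MinMaxScaler, matrix: np.ndarray) -> np.ndarray:
    return scaler.transform(matrix)


# ---------------------------------------------------------------------------
# Splitting


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (must sum to 1) plus the permutation seed."""

    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios):
            raise ConfigError("ratios must be nonnegative")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError(f"ratios must sum to 1, got {sum(self.ratios)}")


def split_dataset(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, val, test) index arrays.

    |train| = floor(r_train * n), |val| = floor(r_val * n), test = remainder.
    The permutation is driven solely by ``spec.seed``.
    """
    if n < 3:
        raise ConfigError("need at least 3 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(spec.ratios[0] * n))
    n_val = int(math.floor(spec.ratios[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


# ---------------------------------------------------------------------------
# File I/O (comma-separated, header row, UTF-8, "." decimal)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, float_precision="round_trip")


def load_tables(descriptor_path: str | Path, activity_path: str | Path,
                admet_path: str | Path, group_map_path: str | Path,
                ) -> tuple[DescriptorTable, ActivityTable, AdmetTable]:
    """Load and row-align the three tables, keyed by SMILES.

    Row order follows the descriptor file. Missing/extra SMILES keys raise
    :class:`AlignmentError` naming the offenders; a non-numeric descriptor
    cell raises :class:`TableParseError` with its coordinates.
    """
    desc_df = _read_csv(descriptor_path)
    act_df = _read_csv(activity_path)
    admet_df = _read_csv(admet_path)
    group_df = _read_csv(group_map_path)

    if desc_df.columns[0] != "SMILES":
        raise TableParseError("descriptor file must start with a SMILES column")
    smiles = desc_df["SMILES"].astype(str).tolist()
    if len(set(smiles)) != len(smiles):
        raise AlignmentError("duplicate SMILES keys in descriptor file")

    names = [c for c in desc_df.columns if c != "SMILES"]
    raw = desc_df[names]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna().to_numpy()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise TableParseError(
            f"non-numeric descriptor cell {raw.iloc[i, j]!r} at row {i} "
            f"column {names[j]!r}"
        )

    group_map = dict(zip(group_df["descriptor"].astype(str),
                         group_df["group"].astype(str)))

    def _align(df: pd.DataFrame, label: str) -> pd.DataFrame:
        keys = df["SMILES"].astype(str)
        missing = sorted(set(smiles) - set(keys))
        extra = sorted(set(keys) - set(smiles))
        if missing or extra:
            raise AlignmentError(
                f"{label} file misaligned with descriptors; "
                f"missing={missing[:5]} extra={extra[:5]}"
            )
        return df.set_index(keys).loc[smiles]

    act = _align(act_df, "activity")
    adm = _align(admet_df, "ADMET")

    table = DescriptorTable(smiles, names, numeric.to_numpy(dtype=float), group_map)
    ic50 = act["IC50_nM"].to_numpy(dtype=float) if "IC50_nM" in act else None
    if "pIC50" in act:
        pic50 = act["pIC50"].to_numpy(dtype=float)
    elif ic50 is not None:
        pic50 = 9.0 - np.log10(ic50)
    else:
        raise TableParseError("activity file needs an IC50_nM or pIC50 column")
    activity = ActivityTable(smiles, pic50, ic50)
    admet = AdmetTable(smiles, adm[list(ADMET_PROPERTIES)].to_numpy())
    return table, activity, admet


def write_tables(table: DescriptorTable, activity: ActivityTable,
                 admet: AdmetTable, directory: str | Path,
                 force: bool = False) -> dict[str, Path]:
    """Write the four CSVs; floats use repr precision so reloads are bitwise equal."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "descriptors": directory / "descriptors.csv",
        "activity": directory / "activity.csv",
        "admet": directory / "admet.csv",
        "groups": directory / "groups.csv",
    }
    for p in paths.values():
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; pass force=True to overwrite")

    desc_df = pd.DataFrame(table.values, columns=table.descriptor_names)
    desc_df.insert(0, "SMILES", table.smiles)
    desc_df.to_csv(paths["descriptors"], index=False, float_format="%.17g")

    act_df = pd.DataFrame({"SMILES": activity.smiles})
    if activity.ic50_nM is not None:
        act_df["IC50_nM"] = activity.ic50_nM
    act_df["pIC50"] = activity.pic50
    act_df.to_csv(paths["activity"], index=False, float_format="%.17g")

    admet_df = pd.DataFrame(admet.y, columns=list(ADMET_PROPERTIES))
    admet_df.insert(0, "SMILES", admet.smiles)
    admet_df.to_csv(paths["admet"], index=False)

    pd.DataFrame({
        "descriptor": table.descriptor_names,
        "group": [table.group_map[c] for c in table.descriptor_names],
    }).to_csv(paths["groups"], index=False)
    return paths
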
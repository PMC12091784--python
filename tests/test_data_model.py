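import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erainv.data_model import (
    AlignmentError,
    ConfigError,
    SplitSpec,
    TableParseError,
    fit_scaler,
    ic50_to_pic50,
    load_tables,
    pic50_to_ic50,
    split_dataset,
    write_tables,
)
from erainv.synthetic import SyntheticConfig, generate


# ---------------------------------------------------------------------------
# IC50 <-> pIC50


@pytest.mark.parametrize("ic50,expected", [(1.0, 9.0), (1000.0, 6.0), (0.1, 10.0)])
def test_ic50_to_pic50_molar_convention(ic50, expected):
    assert ic50_to_pic50(ic50) == pytest.approx(expected, abs=1e-12)
    assert pic50_to_ic50(expected) == pytest.approx(ic50, rel=1e-12)


def test_ic50_nonpositive_rejected():
    with pytest.raises(ValueError):
        ic50_to_pic50(0.0)
    with pytest.raises(ValueError):
        ic50_to_pic50(-5.0)


# ---------------------------------------------------------------------------
# Loading and round trip


def _write_toy(tmp_path, activity_rows=None, descriptor_cell=None):
    smiles = ["CCO", "CCC", "c1ccccc1"]
    a_col = [1.0, descriptor_cell if descriptor_cell is not None else 2.0, 3.0]
    desc = pd.DataFrame({"SMILES": smiles, "a": a_col,
                         "b": [0.5, 0.25, 0.125]})
    act_smiles = activity_rows if activity_rows is not None else smiles
    act = pd.DataFrame({"SMILES": act_smiles,
                        "pIC50": [7.0 + i for i in range(len(act_smiles))]})
    admet = pd.DataFrame({"SMILES": smiles, "Caco-2": [1, 0, 1],
                          "CYP3A4": [0, 1, 1], "hERG": [0, 0, 1],
                          "HOB": [1, 1, 0], "MN": [0, 1, 0]})
    groups = pd.DataFrame({"descriptor": ["a", "b"], "group": ["G1", "G1"]})
    paths = {}
    for name, df in [("descriptors", desc), ("activity", act),
                     ("admet", admet), ("groups", groups)]:
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def test_load_tables_round_trip(tmp_path):
    paths = _write_toy(tmp_path)
    table, activity, admet = load_tables(paths["descriptors"], paths["activity"],
                                         paths["admet"], paths["groups"])
    assert table.smiles == ["CCO", "CCC", "c1ccccc1"]
    assert table.values.shape == (3, 2)
    assert activity.pic50.tolist() == [7.0, 8.0, 9.0]
    assert admet.y.shape == (3, 5)


def test_load_tables_missing_smiles_named(tmp_path):
    paths = _write_toy(tmp_path, activity_rows=["CCO", "CCC"])
    with pytest.raises(AlignmentError, match="c1ccccc1"):
        load_tables(paths["descriptors"], paths["activity"], paths["admet"],
                    paths["groups"])


def test_load_tables_non_numeric_cell_located(tmp_path):
    paths = _write_toy(tmp_path, descriptor_cell="NA")
    with pytest.raises(TableParseError, match="row 1.*'a'"):
        load_tables(paths["descriptors"], paths["activity"], paths["admet"],
                    paths["groups"])


def test_write_then_load_bitwise_equal(tmp_path):
    ds = generate(SyntheticConfig(n_compounds=20, n_descriptors=8, n_groups=2,
                                  n_informative=3, seed=3))
    paths = write_tables(ds.descriptor_table, ds.activity, ds.admet,
                         tmp_path / "fix")
    table, activity, admet = load_tables(paths["descriptors"], paths["activity"],
                                         paths["admet"], paths["groups"])
    np.testing.assert_array_equal(table.values, ds.descriptor_table.values)
    np.testing.assert_array_equal(activity.pic50, ds.activity.pic50)
    np.testing.assert_array_equal(admet.y, ds.admet.y)


# ---------------------------------------------------------------------------
# Scaler


def test_scaler_column_mapping():
    vals = np.array([[0.0, 4.0], [5.0, 4.0], [10.0, 4.0]])
    scaler = fit_scaler(vals, ["p", "q"])
    out = scaler.transform(vals)
    np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])
    # constant column maps to zero
    np.testing.assert_allclose(out[:, 1], [0.0, 0.0, 0.0])


def test_scaler_clips_out_of_range():
    scaler = fit_scaler(np.array([[0.0], [10.0]]), ["p"])
    assert scaler.transform(np.array([[12.0]]))[0, 0] == 1.0
    assert scaler.transform(np.array([[-3.0]]))[0, 0] == 0.0


def test_scaler_inverse_identity():
    rng = np.random.default_rng(0)
    vals = rng.uniform(-5, 5, size=(40, 6))
    scaler = fit_scaler(vals, [f"c{i}" for i in range(6)])
    back = scaler.inverse_transform(scaler.transform(vals))
    np.testing.assert_allclose(back, vals, atol=1e-9)


def test_scaler_empty_reference_rejected():
    with pytest.raises(ConfigError):
        fit_scaler(np.ones((3, 2)), ["a", "b"], reference_rows=np.array([], dtype=int))


# ---------------------------------------------------------------------------
# Splitting


def test_split_sizes_follow_floor_rule():
    tr, va, te = split_dataset(1974, SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (1381, 296, 297)


def test_split_deterministic():
    a = split_dataset(10, SplitSpec(seed=5))
    b = split_dataset(10, SplitSpec(seed=5))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


@pytest.mark.parametrize("n", list(range(3, 101)))
def test_split_partition_property(n):
    tr, va, te = split_dataset(n, SplitSpec(seed=1))
    assert len(tr) == int(np.floor(0.7 * n))
    assert len(va) == int(np.floor(0.15 * n))
    combined = np.concatenate([tr, va, te])
    assert sorted(combined.tolist()) == list(range(n))


def test_bad_ratios_rejected():
    with pytest.raises(ConfigError):
        SplitSpec(ratios=(0.7, 0.2, 0.2))


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.integers(min_value=3, max_value=400))
def test_split_partition_hypothesis(seed, n):
    tr, va, te = split_dataset(n, SplitSpec(seed=seed))
    parts = [set(tr.tolist()), set(va.tolist()), set(te.tolist())]
    assert parts[0] | parts[1] | parts[2] == set(range(n))
    assert sum(len(p) for p in parts) == n
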
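"""Sampling distributions, stratification, and unit normalisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dynamap.core import ParameterSpec
from dynamap.sampling import (
    classic_lhs,
    denormalize,
    denormalize_matrix,
    latin_hypercube,
    monte_carlo,
    normalize,
    normalize_matrix,
)

LIN = ParameterSpec("a", 0.0, 10.0)
LOG = ParameterSpec("b", 1e-3, 1.0, scale="log")
INT = ParameterSpec("n", 1, 12, scale="linear", integer=True)


def test_monte_carlo_empty_and_degenerate():
    assert monte_carlo([LIN], 0, seed=0).n_points == 0
    deg = ParameterSpec("c", 2.0, 2.0)
    ens = monte_carlo([deg], 25, seed=0)
    assert np.all(ens.matrix == 2.0)


def test_monte_carlo_log_uniform_decade_fraction():
    # log-uniform over three decades: 1/3 of the mass per decade
    ens = monte_carlo([LOG], 10_000, seed=0)
    frac = np.mean(ens.matrix[:, 0] <= 1e-2)
    assert frac == pytest.approx(1 / 3, abs=0.02)


@pytest.mark.parametrize("spec", [LIN, LOG])
def test_monte_carlo_marginal_is_uniform_in_sampling_scale(spec):
    ens = monte_carlo([spec], 10_000, seed=1)
    v = ens.matrix[:, 0]
    if spec.scale == "log":
        u = (np.log10(v) - np.log10(spec.low)) / (
            np.log10(spec.high) - np.log10(spec.low)
        )
    else:
        u = (v - spec.low) / (spec.high - spec.low)
    assert stats.kstest(u, "uniform").statistic < 0.02


def test_monte_carlo_integer_grid_uniform():
    ens = monte_carlo([INT], 12_000, seed=2)
    vals = ens.matrix[:, 0]
    assert set(vals) == set(float(i) for i in range(1, 13))
    counts = np.bincount(vals.astype(int))[1:]
    assert np.all(np.abs(counts / 12_000 - 1 / 12) < 0.02)


def test_same_seed_bit_identical_different_seed_not():
    a = monte_carlo([LIN, LOG, INT], 500, seed=9)
    b = monte_carlo([LIN, LOG, INT], 500, seed=9)
    c = monte_carlo([LIN, LOG, INT], 500, seed=10)
    assert a.matrix.tobytes() == b.matrix.tobytes()
    assert a.matrix.tobytes() != c.matrix.tobytes()


def test_points_within_spec_ranges():
    ens = monte_carlo([LIN, LOG, INT], 2000, seed=3)
    for j, spec in enumerate(ens.specs):
        col = ens.matrix[:, j]
        assert np.all((col >= spec.low) & (col <= spec.high))
        if spec.integer:
            assert np.all(col == np.round(col))


def test_lhs_factorial_design_size():
    # 5 segments for 5 parameters: the full factorial 5^5 = 3125 sets
    specs = [ParameterSpec(f"p{i}", 0.0, 1.0) for i in range(5)]
    ens = latin_hypercube(specs, 5, seed=0)
    assert ens.n_points == 5**5 == 3125


def test_lhs_single_segment_single_point():
    ens = latin_hypercube([LIN, LOG], 1, seed=4)
    assert ens.n_points == 1
    assert LIN.low <= ens.matrix[0, 0] <= LIN.high


def test_lhs_marginal_stratification_exact():
    # with s segments and d parameters, each parameter stratum holds
    # exactly s^(d-1) points
    specs = [
        ParameterSpec("x", 0.0, 8.0),
        ParameterSpec("y", 1e-2, 1e2, scale="log"),
        ParameterSpec("z", -4.0, 4.0),
    ]
    s = 4
    ens = latin_hypercube(specs, s, seed=5)
    assert ens.n_points == s**3
    for j, spec in enumerate(specs):
        v = ens.matrix[:, j]
        if spec.scale == "log":
            u = (np.log10(v) - np.log10(spec.low)) / (
                np.log10(spec.high) - np.log10(spec.low)
            )
        else:
            u = (v - spec.low) / (spec.high - spec.low)
        strata = np.clip((u * s).astype(int), 0, s - 1)
        counts = np.bincount(strata, minlength=s)
        assert list(counts) == [s**2] * s


def test_lhs_max_sets_truncation_and_cap():
    specs = [ParameterSpec(f"p{i}", 0.0, 1.0) for i in range(3)]
    ens = latin_hypercube(specs, 6, seed=0, max_sets=50)
    assert ens.n_points == 50
    with pytest.raises(ValueError, match="cap"):
        latin_hypercube([ParameterSpec(f"p{i}", 0.0, 1.0) for i in range(8)], 10)


def test_classic_lhs_stratifies_each_marginal():
    n = 64
    ens = classic_lhs([LIN, LOG], n, seed=6)
    assert ens.n_points == n
    for j, spec in enumerate(ens.specs):
        v = ens.matrix[:, j]
        if spec.scale == "log":
            u = (np.log10(v) - np.log10(spec.low)) / (
                np.log10(spec.high) - np.log10(spec.low)
            )
        else:
            u = (v - spec.low) / (spec.high - spec.low)
        strata = np.clip((u * n).astype(int), 0, n - 1)
        assert len(set(strata)) == n  # one point per stratum


def test_normalize_examples():
    specs = [LIN, LOG]
    u = normalize({"a": 5.0, "b": 1e-2}, specs)
    np.testing.assert_allclose(u, [0.5, 1 / 3])


def test_normalize_rejects_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        normalize({"a": 11.0}, [LIN])


def test_denormalize_corners_and_integer_rounding():
    specs = [LIN, LOG, INT]
    lows = denormalize(np.zeros(3), specs)
    highs = denormalize(np.ones(3), specs)
    assert [lows["a"], lows["b"], lows["n"]] == [0.0, 1e-3, 1.0]
    assert [highs["a"], highs["b"], highs["n"]] == [10.0, 1.0, 12.0]
    # u=0.5 on [1,12] -> 6.5 -> 7 under round-half-up
    assert denormalize(np.array([0.5]), [INT])["n"] == 7.0


def test_denormalize_rejects_out_of_unit():
    with pytest.raises(ValueError, match="outside"):
        denormalize(np.array([1.5]), [LIN])


@given(
    a=st.floats(0.0, 10.0),
    b=st.floats(min_value=1e-3, max_value=1.0),
)
def test_round_trip_denormalize_normalize(a, b):
    specs = [LIN, LOG]
    point = {"a": a, "b": b}
    u = normalize(point, specs)
    back = denormalize(u, specs)
    assert back["a"] == pytest.approx(a, rel=1e-12, abs=1e-12)
    assert back["b"] == pytest.approx(b, rel=1e-12)


def test_matrix_normalisation_round_trip():
    ens = monte_carlo([LIN, LOG, INT], 300, seed=8)
    unit = normalize_matrix(ens.matrix, ens.specs)
    assert unit.min() >= 0 and unit.max() <= 1
    back = denormalize_matrix(unit, ens.specs)
    np.testing.assert_allclose(back, ens.matrix, rtol=1e-12, atol=1e-12)


def test_duplicate_spec_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        monte_carlo([LIN, ParameterSpec("a", 0, 1)], 5)


def test_sample_ensemble_csv_round_trips_values(tmp_path):
    import csv as csv_mod
    import json

    ens = monte_carlo([LIN, LOG, INT], 30, seed=4)
    path = tmp_path / "samples.csv"
    ens.to_csv(path)
    with open(path) as fh:
        meta = json.loads(fh.readline().split(" ", 2)[2])
        rows = list(csv_mod.reader(fh))
    assert meta["seed"] == 4 and meta["method"] == "monte_carlo"
    assert rows[0] == ["a", "b", "n"]
    back = np.array([[float(v) for v in r] for r in rows[1:]])
    assert back.tobytes() == ens.matrix.tobytes()
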
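import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmtpp.diffstab import (
    DiffParams,
    differential_stability,
    fold_change,
    melting_profile,
    pchip_smooth,
    relative_abundance,
    s0_t_test,
    volcano_call,
)
from mmtpp.errors import ValidationError
from mmtpp.tables_io import (
    IntensityMatrix,
    ProteinRecord,
    SampleDesign,
    TransformState,
    parse_sample_id,
)
from oracles import pchip_oracle, pooled_t_oracle, s0_t_oracle

SIX = ["T_51_1", "T_51_2", "T_51_3", "C_51_1", "C_51_2", "C_51_3"]


def _matrix(values, sample_ids=SIX, state=TransformState.imputed, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    design = SampleDesign([parse_sample_id(s) for s in sample_ids])
    records = [ProteinRecord(pid) for pid in ids]
    return IntensityMatrix(
        records, design, pd.DataFrame(values, index=ids, columns=sample_ids), state
    )


def test_s0_t_identical_groups_is_null():
    t, p = s0_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], s0=0.1)
    assert t == 0.0 and p == 1.0


def test_s0_t_hand_example():
    """[2,3,4] vs [0,1,2]: sp = 1, t = 2 / (sqrt(2/3) + 0.1)."""
    t, p = s0_t_test([2, 3, 4], [0, 1, 2], s0=0.1)
    expected_t = 2.0 / (math.sqrt(2.0 / 3.0) + 0.1)
    assert abs(t - expected_t) < 1e-12
    assert abs(t - s0_t_oracle([2, 3, 4], [0, 1, 2], 0.1)) < 1e-12
    from scipy import stats
    assert abs(p - 2 * stats.t.sf(abs(expected_t), 4)) < 1e-12


def test_s0_zero_recovers_textbook_pooled_t():
    rng = np.random.default_rng(10)
    for _ in range(100):
        x = rng.normal(0, 1, 3)
        y = rng.normal(0.5, 1, 3)
        t, p = s0_t_test(x, y, s0=0.0)
        t_ref, p_ref = pooled_t_oracle(x, y)
        assert abs(t - t_ref) < 1e-9
        assert abs(p - p_ref) < 1e-9


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_s0_monotonicity_and_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 4)
    y = rng.normal(1, 1, 4)
    prev = np.inf
    for s0 in [0.0, 0.05, 0.1, 0.5, 2.0]:
        t, p = s0_t_test(x, y, s0)
        assert abs(t) <= prev + 1e-12
        prev = abs(t)
        t_sw, p_sw = s0_t_test(y, x, s0)
        assert abs(t + t_sw) < 1e-9
        assert abs(p - p_sw) < 1e-9


def test_fold_change_examples():
    assert fold_change([1, 2, 3], [1, 2, 3]) == 0.0
    assert abs(fold_change([2, 3, 4], [1, 2, 3]) - 1.0) < 1e-12
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=5), rng.normal(size=7)
    assert abs(fold_change(x, y) - (np.mean(x) - np.mean(y))) < 1e-12


@pytest.mark.parametrize(
    "fc,p,expected",
    [
        (2.0, 0.001, "stabilized"),
        (1.0, 0.001, "unchanged"),   # boundary is strict
        (-1.5, 0.04, "destabilized"),  # -log10(0.04) = 1.398 > 1.3
        (1.5, 0.05012, "unchanged"),   # -log10 just below 1.3
        (-2.0, 0.5, "unchanged"),
    ],
)
def test_volcano_call_thresholds(fc, p, expected):
    assert volcano_call(fc, p, DiffParams()) == expected


def test_differential_stability_identical_groups_unchanged():
    m = _matrix([[5, 6, 7, 5, 6, 7]])
    res = differential_stability(m)
    assert res.loc[0, "call"] == "unchanged"
    assert res.loc[0, "log2_fc"] == 0.0


def test_differential_stability_planted_shift_called():
    rng = np.random.default_rng(1)
    base = rng.normal(25, 0.2, size=(20, 6))
    base[0, :3] += 3.0  # planted stabilized protein
    res = differential_stability(_matrix(base))
    assert res.loc[res["protein_id"] == "P0", "call"].item() == "stabilized"
    assert (res.loc[res["protein_id"] != "P0", "call"] == "unchanged").mean() > 0.9


def test_differential_results_invariant_to_constant_shift_and_order():
    rng = np.random.default_rng(2)
    vals = rng.normal(25, 0.5, size=(10, 6))
    res1 = differential_stability(_matrix(vals))
    res2 = differential_stability(_matrix(vals + 7.5))
    pd.testing.assert_frame_equal(res1, res2)
    perm = rng.permutation(10)
    res3 = differential_stability(
        _matrix(vals[perm], ids=[f"P{i}" for i in perm])
    )
    merged = res1.merge(res3, on="protein_id", suffixes=("_a", "_b"))
    assert (merged["call_a"] == merged["call_b"]).all()
    np.testing.assert_allclose(merged["t_stat_a"], merged["t_stat_b"], atol=1e-12)


def test_pchip_knots_and_monotonicity():
    temps = np.array([37.0, 51.0, 56.0, 60.0, 64.0])
    vals = np.array([5.0, 4.0, 3.0, 1.0, 0.9])
    grid = np.linspace(37, 64, 500)
    sm = pchip_smooth(temps, vals, grid)
    at_knots = pchip_smooth(temps, vals, temps)
    np.testing.assert_allclose(at_knots, vals, atol=1e-12)
    assert (np.diff(sm) <= 1e-12).all()  # no overshoot on monotone data
    with pytest.raises(ValidationError):
        pchip_smooth([51.0, 51.0, 56.0], [1, 2, 3], grid)


def test_pchip_matches_independent_implementation():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = rng.integers(3, 9)
        x = np.sort(rng.uniform(30, 70, n))
        while np.any(np.diff(x) < 1e-3):
            x = np.sort(rng.uniform(30, 70, n))
        y = np.sort(rng.normal(size=n))[::-1].copy()  # monotone data
        grid = np.linspace(x[0], x[-1], 113)
        np.testing.assert_allclose(
            pchip_smooth(x, y, grid), pchip_oracle(x, y, grid), atol=1e-9
        )


def test_melting_profile_knots_and_linear_two_point_case():
    ids = ["T_37_1", "T_51_1", "C_37_1", "C_51_1"]
    m = _matrix([[25.0, 23.0, 25.0, 24.0]], sample_ids=ids,
                state=TransformState.normalized)
    curve = melting_profile(m, "P0", "treatment")
    np.testing.assert_allclose(curve.mean_log2, [25.0, 23.0])
    # PCHIP through two points is the straight segment
    expected = np.interp(curve.grid, [37.0, 51.0], [25.0, 23.0])
    np.testing.assert_allclose(curve.smoothed, expected, atol=1e-9)


def test_melting_profile_recovers_sigmoid_knots(tiny_dataset, tmp_path):
    """Replicate means lie inside the noise envelope of the true sigmoid."""
    from mmtpp.synth import melting_fraction
    from mmtpp.tables_io import read_protein_groups
    ds = tiny_dataset
    ds.protein_groups.to_csv(tmp_path / "pg.tsv", sep="\t", index=False)
    _, matrix = read_protein_groups(tmp_path / "pg.tsv")
    matrix = matrix.with_values(np.log2(matrix.values), TransformState.normalized)
    truth = ds.truth.set_index("protein_id")
    # pick an abundant non-binder observed everywhere
    pid = None
    for cand in truth.index[truth["base_log2"] > 26]:
        if not matrix.values.loc[cand].isna().any():
            pid = cand
            break
    assert pid is not None
    curve = melting_profile(matrix, pid, "control")
    row = truth.loc[pid]
    for T, mean in zip(curve.temperatures, curve.mean_log2):
        # scale/plateau unknown here; envelope spans extreme generator values
        fs = [
            melting_fraction(T, row.tm_C, s, p)
            for s in (1.0, 3.0)
            for p in (0.0, 0.2)
        ]
        lo = row.base_log2 + np.log2(min(fs)) - 0.8
        hi = row.base_log2 + np.log2(max(fs)) + 0.8
        assert lo - 1e-9 <= mean <= hi + 1e-9


def test_relative_abundance_reference_and_halving():
    ids = ["T_37_1", "T_51_1", "C_37_1", "C_51_1"]
    m = _matrix([[25.0, 24.0, 25.0, 25.0]], sample_ids=ids,
                state=TransformState.normalized)
    ra = relative_abundance(m, 37.0)
    t = ra[ra["arm"] == "treatment"].set_index("temperature_C")["rel_abundance"]
    assert abs(t[37.0] - 1.0) < 1e-12
    assert abs(t[51.0] - 0.5) < 1e-12
    c = ra[ra["arm"] == "control"].set_index("temperature_C")["rel_abundance"]
    assert abs(c[51.0] - 1.0) < 1e-12
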
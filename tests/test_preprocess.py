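import numpy as np
import pandas as pd
import pytest

from mmtpp.errors import TransformStateError, ValidationError
from mmtpp.preprocess import (
    PreprocessParams,
    filter_protein_groups,
    filter_unique_peptides,
    filter_valid_values,
    impute_downshifted_normal,
    impute_gaussian_downshift,
    log2_transform,
    mark_scaffold,
    normalize_to_scaffold,
)
from mmtpp.tables_io import (
    IntensityMatrix,
    ProteinRecord,
    SampleDesign,
    TransformState,
    parse_sample_id,
    read_protein_groups,
)
from conftest import write_pg_table

SIX = ["T_51_1", "T_51_2", "T_51_3", "C_51_1", "C_51_2", "C_51_3"]


def _matrix(values, ids=None, sample_ids=SIX, state=TransformState.raw, records=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    design = SampleDesign([parse_sample_id(s) for s in sample_ids])
    if records is None:
        records = [ProteinRecord(pid, unique_peptides={"": 3}) for pid in ids]
    df = pd.DataFrame(values, index=ids, columns=sample_ids)
    return IntensityMatrix(records, design, df, state)


def test_filter_protein_groups_drops_flagged_rows():
    records = [
        ProteinRecord("P1"),
        ProteinRecord("REV__X", is_reverse=True),
        ProteinRecord("CON__Y", is_contaminant=True),
        ProteinRecord("P4", is_site_only=True),
        ProteinRecord("P5"),
    ]
    m = _matrix(np.full((5, 6), 100.0), ids=[r.protein_id for r in records],
                records=records)
    out = filter_protein_groups(m)
    assert out.protein_ids == ["P1", "P5"]
    # no flags -> identity
    again = filter_protein_groups(out)
    assert again.protein_ids == out.protein_ids


def test_log2_transform_values_and_state():
    m = _matrix([[8.0, 1.0, 2500.0, 4.0, 4.0, 4.0]])
    out = log2_transform(m)
    assert out.state is TransformState.log2
    row = out.values.loc["P0"]
    assert row["T_51_1"] == 3.0
    assert row["T_51_2"] == 0.0
    assert abs(row["T_51_3"] - 11.287712379549449) < 1e-12


def test_raw_matrix_rejects_nonpositive_values():
    with pytest.raises(ValidationError):
        _matrix([[-1.0, 2, 2, 2, 2, 2]])


def test_normalize_to_scaffold_two_sample_example():
    """Scaffold [20, 21] -> shifts +0.5 / -0.5; scaffold means equalized."""
    two = ["T_51_1", "C_51_1"]
    records = [ProteinRecord("SCAF", is_scaffold=True), ProteinRecord("P1")]
    m = _matrix([[20.0, 21.0], [10.0, 10.0]], ids=["SCAF", "P1"],
                sample_ids=two, state=TransformState.log2, records=records)
    out = normalize_to_scaffold(m)
    assert out.state is TransformState.normalized
    np.testing.assert_allclose(out.values.loc["SCAF", two], [20.5, 20.5])
    np.testing.assert_allclose(out.values.loc["P1", two], [10.5, 9.5])
    # already-equal scaffold -> identity
    equal = pd.DataFrame(
        [[20.0, 20.0], [10.0, 11.0]], index=["SCAF", "P1"], columns=two
    )[m.values.columns]
    out2 = normalize_to_scaffold(m.with_values(equal, TransformState.log2))
    np.testing.assert_allclose(out2.values.loc["P1", two], [10.0, 11.0])


def test_normalize_preserves_within_sample_differences():
    rng = np.random.default_rng(0)
    vals = rng.normal(25, 2, size=(10, 6))
    records = [ProteinRecord("SCAF", is_scaffold=True)] + [
        ProteinRecord(f"P{i}") for i in range(9)
    ]
    m = _matrix(vals, ids=[r.protein_id for r in records],
                state=TransformState.log2, records=records)
    out = normalize_to_scaffold(m)
    before = np.diff(vals, axis=0)
    after = np.diff(out.values[SIX].to_numpy(), axis=0)
    np.testing.assert_allclose(before, after, atol=1e-12)


def test_normalize_missing_scaffold_requires_fallback():
    two = ["T_51_1", "C_51_1"]
    records = [ProteinRecord("SCAF", is_scaffold=True), ProteinRecord("P1")]
    m = _matrix([[np.nan, 21.0], [10.0, 10.0]], ids=["SCAF", "P1"],
                sample_ids=two, state=TransformState.log2, records=records)
    with pytest.raises(ValidationError):
        normalize_to_scaffold(m)
    with pytest.warns(UserWarning):
        out = normalize_to_scaffold(m, median_fallback=True)
    assert out.state is TransformState.normalized


def test_filter_valid_values_either_group_rule():
    vals = np.array(
        [
            [20, 21, 22, np.nan, np.nan, np.nan],  # 3 treat, 0 ctrl -> kept
            [20, 21, np.nan, 20, 21, np.nan],      # 2 vs 2 -> dropped
            [np.nan, np.nan, np.nan, 20, 21, 22],  # 0 vs 3 -> kept
        ]
    )
    m = _matrix(vals, state=TransformState.normalized)
    mask = filter_valid_values(m, 51.0, min_valid=3)
    assert mask.tolist() == [True, False, True]


def test_filter_valid_values_matches_brute_force_recount(tiny_dataset, tmp_path):
    ds = tiny_dataset
    ds.protein_groups.to_csv(tmp_path / "pg.tsv", sep="\t", index=False)
    _, matrix = read_protein_groups(tmp_path / "pg.tsv")
    matrix.state = TransformState.normalized  # filter only looks at missingness
    for t in matrix.design.temperatures:
        mask = filter_valid_values(matrix, t, min_valid=3)
        treat = matrix.design.sample_ids_at(t, "treatment")
        ctrl = matrix.design.sample_ids_at(t, "control")
        for i, pid in enumerate(matrix.protein_ids):
            n_t = sum(
                not np.isnan(matrix.values.loc[pid, c]) for c in treat
            )
            n_c = sum(
                not np.isnan(matrix.values.loc[pid, c]) for c in ctrl
            )
            assert mask[i] == (n_t >= 3 or n_c >= 3)


def test_filter_unique_peptides_rule_and_recount():
    records = [
        ProteinRecord("P1", unique_peptides={"": 2}),
        ProteinRecord("P2", unique_peptides={"": 1}),
        ProteinRecord("P3", unique_peptides={}),
        ProteinRecord("P4", unique_peptides={"A": 1, "B": 5}),
    ]
    with pytest.warns(UserWarning, match="unique-peptide"):
        mask = filter_unique_peptides(records, 2)
    assert mask.tolist() == [True, False, False, True]

    rng = np.random.default_rng(1)
    counts = 1 + rng.poisson(2.0, size=200)
    recs = [ProteinRecord(f"Q{i}", unique_peptides={"": int(c)}) for i, c in enumerate(counts)]
    mask = filter_unique_peptides(recs, 2)
    assert mask.sum() == int((counts >= 2).sum())


def test_impute_no_missing_is_identity_and_observed_never_altered():
    rng = np.random.default_rng(2)
    full = rng.normal(25, 2, size=(50, 6))
    out = impute_gaussian_downshift(full, rng=np.random.default_rng(0))
    np.testing.assert_array_equal(out, full)
    holey = full.copy()
    holey[rng.random(full.shape) < 0.3] = np.nan
    out = impute_gaussian_downshift(holey, rng=np.random.default_rng(0))
    obs = ~np.isnan(holey)
    np.testing.assert_array_equal(out[obs], holey[obs])
    assert not np.isnan(out).any()


def test_impute_moments_and_downshift_position():
    """Imputed draws match N(mu - 1.8 sd, (0.3 sd)^2) and sit below the mean."""
    rng = np.random.default_rng(3)
    n_missing = 20_000
    col = np.concatenate([rng.normal(25.0, 2.0, size=200), np.full(n_missing, np.nan)])
    values = col[:, None]
    obs = col[~np.isnan(col)]
    mu, sd = obs.mean(), obs.std(ddof=1)
    out = impute_gaussian_downshift(values, 1.8, 0.3, np.random.default_rng(4))
    imputed = out[np.isnan(values)]
    assert abs(imputed.mean() - (mu - 1.8 * sd)) < 0.03 * sd
    assert abs(imputed.std(ddof=1) - 0.3 * sd) < 0.03 * sd
    assert (imputed < mu).mean() >= 0.99


def test_impute_deterministic_under_seed():
    rng = np.random.default_rng(5)
    vals = rng.normal(25, 2, size=(40, 6))
    vals[rng.random(vals.shape) < 0.25] = np.nan
    a = impute_gaussian_downshift(vals, rng=np.random.default_rng(9))
    b = impute_gaussian_downshift(vals, rng=np.random.default_rng(9))
    np.testing.assert_array_equal(a, b)


def test_impute_requires_two_observed_per_column():
    vals = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 1.0]])
    with pytest.raises(ValidationError, match="fewer than 2"):
        impute_gaussian_downshift(vals)


def test_transform_state_order_is_enforced():
    m = _matrix(np.full((2, 6), 100.0))
    with pytest.raises(TransformStateError):
        normalize_to_scaffold(m)  # raw, not log2
    with pytest.raises(TransformStateError):
        filter_valid_values(m, 51.0)
    m2 = log2_transform(m)
    with pytest.raises(TransformStateError):
        log2_transform(m2)
    with pytest.raises(TransformStateError):
        impute_downshifted_normal(m2, PreprocessParams(), np.random.default_rng(0))


def test_mark_scaffold_by_pattern():
    records = [ProteinRecord("P1", gene_name="Abc1"),
               ProteinRecord("PEPTIDISC_SCAFFOLD", gene_name="NSPr")]
    n = mark_scaffold(records)
    assert n == 1
    assert records[1].is_scaffold and not records[0].is_scaffold
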
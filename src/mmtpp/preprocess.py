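"""Perseus-style preprocessing of label-free TPP intensity matrices.

The order of operations is fixed and enforced through the matrix transform
state:

1. ``filter_protein_groups`` — drop decoy, contaminant and site-only rows
   (scaffold rows are kept but flagged: they drive normalization and are
   excluded from testing);
2. ``log2_transform``;
3. ``normalize_to_scaffold`` — an additive per-sample shift in log2 space
   that equalizes the mean scaffold-peptide intensity across samples;
4. ``filter_valid_values`` — per temperature contrast, keep proteins with at
   least ``min_valid`` observed intensities in the treatment OR the control
   group;
5. ``impute_downshifted_normal`` — replace remaining missing values with
   draws from a normal distribution downshifted from each sample's observed
   mean, the standard treatment for missing-not-at-random dropout of
   low-abundance proteins.

Calling an operation out of order raises :class:`TransformStateError`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmtpp.errors import TransformStateError, ValidationError
from mmtpp.tables_io import IntensityMatrix, ProteinRecord, TransformState

__all__ = [
    "PreprocessParams",
    "mark_scaffold",
    "filter_protein_groups",
    "log2_transform",
    "normalize_to_scaffold",
    "filter_valid_values",
    "filter_unique_peptides",
    "impute_gaussian_downshift",
    "impute_downshifted_normal",
    "prepare_temperature_slice",
]

#: Default pattern matching Peptidisc scaffold-peptide entries by id or gene.
DEFAULT_SCAFFOLD_PATTERN = r"(?i)peptidisc|scaffold|\bNSPr?\b"


@dataclass
class PreprocessParams:
    """Tunable preprocessing parameters.

    min_valid
        Minimum observed intensities required in treatment or control at one
        temperature (default 3, i.e. a complete triplicate in one arm).
    min_unique_peptides
        Minimum unique peptides for a protein to be testable (default 2).
    impute_downshift, impute_width
        Location shift and width of the imputation distribution, in units of
        the per-sample standard deviation (defaults 1.8 and 0.3).
    """

    min_valid: int = 3
    min_unique_peptides: int = 2
    impute_downshift: float = 1.8
    impute_width: float = 0.3
    seed: int = 0
    scaffold_pattern: str = DEFAULT_SCAFFOLD_PATTERN
    median_fallback: bool = False

    def __post_init__(self) -> None:
        if self.min_valid < 1:
            raise ValidationError("min_valid must be >= 1")
        if self.impute_width <= 0:
            raise ValidationError("impute_width must be > 0")
        if self.impute_downshift < 0:
            raise ValidationError("impute_downshift must be >= 0")


def _require_state(matrix: IntensityMatrix, *allowed: TransformState) -> None:
    if matrix.state not in allowed:
        names = " or ".join(s.value for s in allowed)
        raise TransformStateError(
            f"operation requires matrix state {names}, got {matrix.state.value}"
        )


def mark_scaffold(records: list[ProteinRecord], pattern: str = DEFAULT_SCAFFOLD_PATTERN) -> int:
    """Flag scaffold rows in place by id/gene regex; returns the count."""
    rx = re.compile(pattern)
    n = 0
    for rec in records:
        hay = rec.protein_id + (" " + rec.gene_name if rec.gene_name else "")
        if rx.search(hay):
            rec.is_scaffold = True
            n += 1
    return n


def filter_protein_groups(matrix: IntensityMatrix) -> IntensityMatrix:
    """Remove decoy (reverse), contaminant and site-only rows.

    Scaffold rows survive this filter; they are needed for normalization and
    are dropped from differential testing later.
    """
    _require_state(matrix, TransformState.raw, TransformState.log2)
    keep = [
        not (r.is_reverse or r.is_contaminant or r.is_site_only)
        for r in matrix.records
    ]
    if not any(keep):
        warnings.warn("all protein groups removed by identification filters")
    return matrix.subset_rows(keep)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    _require_state(matrix, TransformState.raw)
    arr = matrix.values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=np.inf) <= 0:
        raise ValidationError("cannot log2-transform non-positive intensities")
    return matrix.with_values(np.log2(matrix.values), TransformState.log2)


def normalize_to_scaffold(
    matrix: IntensityMatrix, median_fallback: bool = False
) -> IntensityMatrix:
    """Equalize the mean scaffold intensity across samples.

    For each sample *j* every value is shifted by (global scaffold mean −
    scaffold mean in *j*); within-sample differences between proteins are
    unchanged.  If the scaffold is missing in some sample the function
    raises, unless ``median_fallback`` is set, in which case per-sample
    medians over all proteins are equalized instead (logged as a warning).
    """
    _require_state(matrix, TransformState.log2)
    scaffold_ids = [r.protein_id for r in matrix.records if r.is_scaffold]
    if scaffold_ids:
        scaffold = matrix.values.loc[scaffold_ids]
        per_sample = scaffold.mean(axis=0, skipna=True)
        if scaffold.isna().all(axis=0).any() or per_sample.isna().any():
            bad = per_sample.index[per_sample.isna()].tolist()
            if not median_fallback:
                raise ValidationError(
                    f"scaffold intensity missing in samples {bad}; "
                    "set median_fallback to normalize on per-sample medians"
                )
            scaffold_ids = []
    if not scaffold_ids:
        if not median_fallback:
            raise ValidationError(
                "no scaffold rows flagged; set median_fallback to normalize "
                "on per-sample medians"
            )
        warnings.warn("no usable scaffold; falling back to per-sample median equalization")
        per_sample = matrix.values.median(axis=0, skipna=True)
    shifts = per_sample.mean() - per_sample
    return matrix.with_values(matrix.values + shifts, TransformState.normalized)


def filter_valid_values(
    matrix: IntensityMatrix, temperature_C: float, min_valid: int = 3
) -> np.ndarray:
    """Row mask: >= min_valid observed values in treatment OR control at T."""
    _require_state(matrix, TransformState.normalized)
    treat = matrix.design.sample_ids_at(temperature_C, "treatment")
    ctrl = matrix.design.sample_ids_at(temperature_C, "control")
    if not treat or not ctrl:
        raise ValidationError(
            f"temperature {temperature_C:g} degC missing from one arm"
        )
    n_treat = matrix.values[treat].notna().sum(axis=1)
    n_ctrl = matrix.values[ctrl].notna().sum(axis=1)
    return ((n_treat >= min_valid) | (n_ctrl >= min_valid)).to_numpy()


def filter_unique_peptides(
    records: list[ProteinRecord], min_unique: int = 2
) -> np.ndarray:
    """Row mask: unique-peptide count >= min_unique in at least one group.

    Records without any unique-peptide count are dropped with a warning.
    """
    mask = np.empty(len(records), dtype=bool)
    n_unknown = 0
    for i, rec in enumerate(records):
        count = rec.max_unique_peptides()
        if count is None:
            mask[i] = False
            n_unknown += 1
        else:
            mask[i] = count >= min_unique
    if n_unknown:
        warnings.warn(
            f"{n_unknown} protein groups dropped: no unique-peptide counts"
        )
    return mask


def impute_gaussian_downshift(
    values: np.ndarray,
    downshift: float = 1.8,
    width: float = 0.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Impute NaNs column-wise from a downshifted normal distribution.

    For each column *j* with observed mean mu_j and standard deviation
    sigma_j, every missing cell is drawn from
    ``Normal(mu_j - downshift * sigma_j, (width * sigma_j)^2)``.  The RNG is
    consumed in row-major order over missing cells, so a fixed generator
    state reproduces the imputed matrix exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    values = np.asarray(values, dtype=float)
    out = values.copy()
    n_obs = (~np.isnan(values)).sum(axis=0)
    if (n_obs < 2).any():
        bad = np.nonzero(n_obs < 2)[0].tolist()
        raise ValidationError(
            f"columns {bad} have fewer than 2 observed values; sd undefined"
        )
    mu = np.nanmean(values, axis=0)
    sigma = np.nanstd(values, axis=0, ddof=1)
    missing = np.isnan(values)
    z = rng.standard_normal(int(missing.sum()))
    rows, cols = np.nonzero(missing)  # row-major order
    out[rows, cols] = mu[cols] - downshift * sigma[cols] + width * sigma[cols] * z
    return out


def impute_downshifted_normal(
    matrix: IntensityMatrix,
    params: PreprocessParams,
    rng: np.random.Generator,
) -> IntensityMatrix:
    """Matrix-level wrapper around :func:`impute_gaussian_downshift`."""
    _require_state(matrix, TransformState.normalized)
    imputed = impute_gaussian_downshift(
        matrix.values.to_numpy(dtype=float),
        downshift=params.impute_downshift,
        width=params.impute_width,
        rng=rng,
    )
    values = pd.DataFrame(
        imputed, index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix.with_values(values, TransformState.imputed)


def prepare_temperature_slice(
    matrix: IntensityMatrix,
    temperature_C: float,
    params: PreprocessParams,
    rng: np.random.Generator,
) -> IntensityMatrix:
    """Analysis-ready (imputed) submatrix for one temperature contrast.

    Applies the valid-value and unique-peptide filters, drops scaffold rows,
    restricts to the samples of this temperature, and imputes.  Rows in the
    returned matrix always carry at least ``min_valid`` real observations in
    one arm.
    """
    _require_state(matrix, TransformState.normalized)
    samples = matrix.design.sample_ids_at(temperature_C)
    sub = matrix.subset_samples(samples)
    valid = filter_valid_values(sub, temperature_C, params.min_valid)
    peptides = filter_unique_peptides(sub.records, params.min_unique_peptides)
    not_scaffold = np.array([not r.is_scaffold for r in sub.records])
    sub = sub.subset_rows(list(valid & peptides & not_scaffold))
    return impute_downshifted_normal(sub, params, rng)
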
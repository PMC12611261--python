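"""Per-temperature differential thermal-stability testing and melting profiles.

At each temperature the soluble-fraction log2 intensities of the treatment
(ligand) and control arms are compared with an s0-moderated two-sample
t-test in the SAM tradition:

    t = (mean_t - mean_c) / (s_p * sqrt(1/n_t + 1/n_c) + s0)

where ``s_p`` is the pooled (equal-variance) standard deviation and ``s0``
(default 0.1) damps the significance of tiny fold changes driven by tiny
variances.  Two-sided p-values are taken from the ordinary t distribution
with ``n_t + n_c - 2`` degrees of freedom evaluated at |t|; with ``s0 = 0``
this is exactly the textbook pooled two-sample t-test.

Volcano calling uses joint cutoffs with strict inequalities: a protein is
*stabilized* when ``log2_fc > fc_cut`` and ``-log10 p > logp_cut``
(defaults 1.0 and 1.3), *destabilized* for the mirrored fold-change cutoff,
otherwise *unchanged*.  No multiple-testing correction is applied here —
stability calls use fixed cutoffs; Benjamini-Hochberg correction lives in
the enrichment module.

Melting profiles are per-temperature replicate means +/- sd, smoothed with
monotonicity-preserving piecewise-cubic Hermite interpolation (PCHIP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from mmtpp.errors import TransformStateError, ValidationError
from mmtpp.tables_io import RESULT_COLUMNS, IntensityMatrix, SampleDesign, TransformState

__all__ = [
    "DiffParams",
    "MeltingCurve",
    "s0_t_test",
    "fold_change",
    "volcano_call",
    "differential_stability",
    "melting_profile",
    "pchip_smooth",
    "relative_abundance",
]

CALL_STABILIZED = "stabilized"
CALL_DESTABILIZED = "destabilized"
CALL_UNCHANGED = "unchanged"


@dataclass
class DiffParams:
    """Volcano-analysis parameters.

    s0       : variance-moderation constant (log2-intensity units).
    fc_cut   : |log2 fold change| that must be exceeded (strictly).
    logp_cut : -log10 p that must be exceeded (strictly); 1.3 ~ p = 0.05.
    """

    s0: float = 0.1
    fc_cut: float = 1.0
    logp_cut: float = 1.3

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")
        if self.fc_cut <= 0 or self.logp_cut <= 0:
            raise ValidationError("fc_cut and logp_cut must be > 0")


def s0_t_test(
    x_treat: np.ndarray, x_ctrl: np.ndarray, s0: float = 0.1
) -> tuple[float, float]:
    """Moderated two-sample t-test for one protein at one temperature.

    Returns ``(t, p)``; both groups need at least two values.  With a zero
    mean difference (e.g. identical groups) t is exactly 0 and p exactly 1.
    """
    t, p = _s0_t_test_rows(
        np.atleast_2d(np.asarray(x_treat, dtype=float)),
        np.atleast_2d(np.asarray(x_ctrl, dtype=float)),
        s0,
    )
    return float(t[0]), float(p[0])


def _s0_t_test_rows(
    X_treat: np.ndarray, X_ctrl: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized s0 t-test over rows (proteins)."""
    n_t, n_c = X_treat.shape[1], X_ctrl.shape[1]
    if n_t < 2 or n_c < 2:
        raise ValidationError(
            f"each group needs >= 2 replicates, got {n_t} and {n_c}"
        )
    diff = X_treat.mean(axis=1) - X_ctrl.mean(axis=1)
    var_t = X_treat.var(axis=1, ddof=1)
    var_c = X_ctrl.var(axis=1, ddof=1)
    sp = np.sqrt(((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2))
    denom = sp * math.sqrt(1.0 / n_t + 1.0 / n_c) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff == 0.0, 0.0, diff / denom)
    df = n_t + n_c - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def fold_change(x_treat: np.ndarray, x_ctrl: np.ndarray) -> float:
    """Mean difference treatment - control in log2 space."""
    x_treat = np.asarray(x_treat, dtype=float)
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    if x_treat.size == 0 or x_ctrl.size == 0:
        raise ValidationError("fold_change requires non-empty groups")
    return float(x_treat.mean() - x_ctrl.mean())


def volcano_call(log2_fc: float, p_value: float, params: DiffParams) -> str:
    """Classify one (fold change, p) pair; cutoffs are strict inequalities."""
    if not (np.isfinite(log2_fc) and np.isfinite(p_value)):
        raise ValidationError("volcano_call requires finite inputs")
    if -math.log10(p_value) > params.logp_cut:
        if log2_fc > params.fc_cut:
            return CALL_STABILIZED
        if log2_fc < -params.fc_cut:
            return CALL_DESTABILIZED
    return CALL_UNCHANGED


def differential_stability(
    matrix: IntensityMatrix, params: DiffParams = DiffParams()
) -> pd.DataFrame:
    """Volcano analysis of one imputed temperature slice.

    *matrix* must be in the imputed state and contain the samples of exactly
    one temperature in both arms.  Returns one row per protein with the
    columns of the standard results table, sorted by protein id.
    """
    if matrix.state is not TransformState.imputed:
        raise TransformStateError(
            f"differential_stability requires an imputed matrix, got {matrix.state.value}"
        )
    temps = matrix.design.temperatures
    if len(temps) != 1:
        raise ValidationError(
            f"expected samples of exactly one temperature, got {temps}"
        )
    temperature = temps[0]
    treat = matrix.design.sample_ids_at(temperature, "treatment")
    ctrl = matrix.design.sample_ids_at(temperature, "control")
    if not treat or not ctrl:
        raise ValidationError(f"temperature {temperature:g} degC missing an arm")
    X_t = matrix.values[treat].to_numpy(dtype=float)
    X_c = matrix.values[ctrl].to_numpy(dtype=float)
    t, p = _s0_t_test_rows(X_t, X_c, params.s0)
    fc = X_t.mean(axis=1) - X_c.mean(axis=1)
    neg_log10_p = -np.log10(p)
    calls = np.where(
        (neg_log10_p > params.logp_cut) & (fc > params.fc_cut),
        CALL_STABILIZED,
        np.where(
            (neg_log10_p > params.logp_cut) & (fc < -params.fc_cut),
            CALL_DESTABILIZED,
            CALL_UNCHANGED,
        ),
    )
    out = pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "temperature_C": temperature,
            "log2_fc": fc,
            "t_stat": t,
            "p_value": p,
            "neg_log10_p": neg_log10_p,
            "call": calls,
            "n_treat": len(treat),
            "n_ctrl": len(ctrl),
        },
        columns=RESULT_COLUMNS,
    )
    return out.sort_values("protein_id", kind="stable").reset_index(drop=True)


@dataclass
class MeltingCurve:
    """Replicate-mean melting profile of one protein in one arm."""

    protein_id: str
    arm: str
    temperatures: np.ndarray
    mean_log2: np.ndarray
    sd_log2: np.ndarray
    n_obs: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: np.array([]))
    smoothed: np.ndarray = field(default_factory=lambda: np.array([]))


def melting_profile(
    matrix: IntensityMatrix,
    protein_id: str,
    arm: str,
    grid_step: float = 0.1,
) -> MeltingCurve:
    """Mean +/- sd melting profile across the gradient, PCHIP-smoothed.

    Works on normalized (pre-imputation) data so imputed values never enter
    a melting curve; temperatures without any observation are dropped.
    """
    if matrix.state not in (TransformState.normalized, TransformState.log2):
        raise TransformStateError(
            "melting_profile expects log2/normalized (pre-imputation) data"
        )
    if protein_id not in matrix.values.index:
        raise ValidationError(f"protein {protein_id!r} not in matrix")
    temps, means, sds, ns = [], [], [], []
    for t in matrix.design.temperatures:
        cols = matrix.design.sample_ids_at(t, arm)
        if not cols:
            continue
        vals = matrix.values.loc[protein_id, cols].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        temps.append(t)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
        ns.append(vals.size)
    if len(temps) < 2:
        raise ValidationError(
            f"protein {protein_id!r}: needs observations at >= 2 temperatures in {arm}"
        )
    temps_arr = np.asarray(temps, dtype=float)
    grid = np.arange(temps_arr[0], temps_arr[-1] + grid_step / 2, grid_step)
    smoothed = pchip_smooth(temps_arr, np.asarray(means), grid)
    return MeltingCurve(
        protein_id=protein_id,
        arm=arm,
        temperatures=temps_arr,
        mean_log2=np.asarray(means),
        sd_log2=np.asarray(sds),
        n_obs=np.asarray(ns, dtype=int),
        grid=grid,
        smoothed=smoothed,
    )


def pchip_smooth(
    temps: np.ndarray, values: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Sample a shape-preserving cubic Hermite interpolant on a dense grid.

    The interpolant passes through every knot exactly and, by the
    Fritsch-Carlson construction, never overshoots between knots, so
    monotone data yield a monotone curve.
    """
    temps = np.asarray(temps, dtype=float)
    values = np.asarray(values, dtype=float)
    if temps.size < 2:
        raise ValidationError("pchip_smooth needs at least 2 knots")
    if np.any(np.diff(temps) <= 0):
        raise ValidationError("knot temperatures must be strictly increasing")
    return PchipInterpolator(temps, values)(np.asarray(grid, dtype=float))


def relative_abundance(
    matrix: IntensityMatrix, reference_temperature_C: float
) -> pd.DataFrame:
    """Per protein and arm, soluble abundance relative to a reference T.

    Returns a long table with columns protein_id, arm, temperature_C,
    rel_abundance where ``rel_abundance = 2^(mean_log2(T) -
    mean_log2(T_ref))``; the reference temperature itself maps to 1.
    Proteins unobserved at the reference temperature in an arm are omitted
    for that arm.
    """
    if matrix.state not in (TransformState.normalized, TransformState.log2):
        raise TransformStateError("relative_abundance expects pre-imputation data")
    if reference_temperature_C not in matrix.design.temperatures:
        raise ValidationError(
            f"reference temperature {reference_temperature_C:g} degC not in design"
        )
    rows = []
    for arm in sorted(matrix.design.arms):
        ref_cols = matrix.design.sample_ids_at(reference_temperature_C, arm)
        if not ref_cols:
            continue
        ref_mean = matrix.values[ref_cols].mean(axis=1, skipna=True)
        for t in matrix.design.temperatures:
            cols = matrix.design.sample_ids_at(t, arm)
            if not cols:
                continue
            mean_t = matrix.values[cols].mean(axis=1, skipna=True)
            ratio = np.power(2.0, mean_t - ref_mean)
            for pid, r in ratio.items():
                if np.isfinite(r):
                    rows.append((pid, arm, t, r))
    return pd.DataFrame(
        rows, columns=["protein_id", "arm", "temperature_C", "rel_abundance"]
    )
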
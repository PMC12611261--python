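"""Synthetic thermal-profiling experiments with known ground truth.

The generator emulates a membrane-mimetic TPP experiment end to end: a
proteome whose soluble fraction decays with temperature following two-state
denaturation, a treatment arm in which a subset of "binder" proteins shifts
its melting midpoint (Tm) up (stabilized) or down (destabilized), log-normal
replicate noise, intensity-dependent dropout (missing-not-at-random), a
constant scaffold-peptide row, decoy/contaminant/site-only rows exercising
the identification filters, unique-peptide counts, and an annotation table
with membrane classes and functional tags enriched in the binder classes.

The expected log2 intensity of protein *i* in arm *a* at temperature *T* is

    base_i + log2( (1 - plateau_i) / (1 + exp((T - Tm_ia) / scale_i)) + plateau_i )

with ``Tm_ia = Tm_i + dTm_i`` in the treatment arm for binders and ``Tm_i``
otherwise.  Each replicate measurement adds N(0, rep_noise_sd_log2) noise
and is then observed with probability ``logistic((value -
dropout_midpoint_log2) / dropout_slope)``.

Default parameters mirror the design of a Peptidisc membrane-library
experiment: triplicate arms, a 37 degC reference plus a 51-64 degC
gradient, and melting-point shifts of +/- 6 degC which drive log2 fold
differences past the volcano cutoff of 1 at intermediate temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from mmtpp.errors import ValidationError
from mmtpp.tables_io import (
    Annotation,
    AnnotationTable,
    Sample,
    SampleDesign,
    write_annotations,
    write_design,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "melting_fraction",
    "simulate_experiment",
    "write_dataset",
    "write_ground_truth",
    "read_ground_truth",
]

CLASS_STABILIZED = "stabilized_binder"
CLASS_DESTABILIZED = "destabilized_binder"
CLASS_NON_BINDER = "non_binder"

SCAFFOLD_ID = "PEPTIDISC_SCAFFOLD"
SCAFFOLD_GENE = "NSPr"

TRUTH_COLUMNS = ["protein_id", "class", "tm_C", "delta_tm_C", "base_log2", "tags"]


@dataclass
class SimConfig:
    """Generator configuration; defaults define the reference experiment."""

    n_proteins: int = 1000
    temperatures_C: tuple[float, ...] = (37.0, 51.0, 56.0, 60.0, 64.0)
    n_replicates: int = 3
    frac_stabilized: float = 0.05
    frac_destabilized: float = 0.02
    delta_tm_stabilized_C: float = 6.0
    delta_tm_destabilized_C: float = -6.0
    tm_mean_C: float = 54.0
    tm_sd_C: float = 4.0
    melt_scale_C: tuple[float, float] = (1.0, 3.0)
    plateau: tuple[float, float] = (0.0, 0.2)
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    rep_noise_sd_log2: float = 0.2
    dropout_midpoint_log2: float = 21.0
    dropout_slope: float = 1.5
    n_decoys: int = 50
    n_contaminants: int = 20
    n_site_only: int = 10
    scaffold_log2: float = 28.0
    scaffold_noise_sd: float = 0.05
    #: tag -> (probability in binders, probability in non-binders)
    tag_enrichment: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ATP binding": (0.60, 0.09)}
    )
    frac_membrane_binder: float = 0.9
    frac_membrane_nonbinder: float = 0.5
    frac_membrane_no_tms: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValidationError("n_proteins and n_replicates must be >= 1")
        if len(self.temperatures_C) == 0:
            raise ValidationError("at least one temperature required")
        temps = list(self.temperatures_C)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValidationError("temperatures must be strictly increasing")
        for frac in (self.frac_stabilized, self.frac_destabilized):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("class fractions must lie in [0, 1]")
        if self.frac_stabilized + self.frac_destabilized > 1.0:
            raise ValidationError("class fractions must sum to <= 1")
        for sd in (self.tm_sd_C, self.rep_noise_sd_log2, self.base_log2_sd):
            if sd <= 0:
                raise ValidationError("sd parameters must be > 0")


def melting_fraction(T: float, tm: float, scale: float, plateau: float = 0.0):
    """Soluble fraction remaining after heating to T (two-state model).

    ``f(T) = (1 - plateau) / (1 + exp((T - tm) / scale)) + plateau``;
    strictly decreasing in T, f -> 1 far below Tm and -> plateau far above,
    with ``f(tm) = (1 + plateau) / 2``.
    """
    if np.any(np.asarray(scale) <= 0):
        raise ValidationError("scale must be > 0")
    p = np.asarray(plateau, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValidationError("plateau must lie in [0, 1)")
    return (1.0 - p) * expit(-(np.asarray(T, dtype=float) - tm) / scale) + p


@dataclass
class SimulatedDataset:
    """All artifacts of one simulated experiment."""

    protein_groups: pd.DataFrame
    design: SampleDesign
    annotations: AnnotationTable
    truth: pd.DataFrame
    config: SimConfig


def _make_design(config: SimConfig) -> SampleDesign:
    samples = []
    for arm, letter in (("treatment", "T"), ("control", "C")):
        for t in config.temperatures_C:
            for r in range(1, config.n_replicates + 1):
                sid = f"{letter}_{t:g}_{r}"
                samples.append(Sample(sid, arm, float(t), r))
    return SampleDesign(samples)


def simulate_experiment(config: SimConfig) -> SimulatedDataset:
    """Generate one complete synthetic experiment.

    Returns the protein-groups table (MaxQuant dialect, linear intensities,
    0 = missing), the sample design, the annotation table, and the
    ground-truth table used by recovery benchmarks.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n = config.n_proteins

    # --- ground-truth protein parameters -------------------------------
    n_stab = round(config.frac_stabilized * n)
    n_dest = round(config.frac_destabilized * n)
    classes = np.array(
        [CLASS_STABILIZED] * n_stab
        + [CLASS_DESTABILIZED] * n_dest
        + [CLASS_NON_BINDER] * (n - n_stab - n_dest)
    )
    rng.shuffle(classes)
    tm = rng.normal(config.tm_mean_C, config.tm_sd_C, size=n)
    scale = rng.uniform(*config.melt_scale_C, size=n)
    plateau = rng.uniform(*config.plateau, size=n)
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    delta = np.where(
        classes == CLASS_STABILIZED,
        config.delta_tm_stabilized_C,
        np.where(classes == CLASS_DESTABILIZED, config.delta_tm_destabilized_C, 0.0),
    )
    ids = np.array([f"SIM{i + 1:05d}" for i in range(n)])
    genes = np.array([f"Sim{i + 1}" for i in range(n)])

    # --- tags and membrane annotation ----------------------------------
    is_binder = classes != CLASS_NON_BINDER
    tags: list[set[str]] = [set() for _ in range(n)]
    for tag, (p_binder, p_non) in config.tag_enrichment.items():
        p = np.where(is_binder, p_binder, p_non)
        has = rng.random(n) < p
        for i in np.nonzero(has)[0]:
            tags[i].add(tag)
    p_mem = np.where(
        is_binder, config.frac_membrane_binder, config.frac_membrane_nonbinder
    )
    is_membrane = rng.random(n) < p_mem
    no_tms = rng.random(n) < config.frac_membrane_no_tms
    tms = np.where(is_membrane & ~no_tms, 1 + rng.poisson(3.0, size=n), 0)

    entries: dict[str, Annotation] = {}
    for i in range(n):
        go = {"GO:0016020"} if is_membrane[i] else set()
        if "ATP binding" in tags[i]:
            go.add("GO:0005524")
        entries[ids[i]] = Annotation(
            go_terms=go, tms_count=int(tms[i]), tags=set(tags[i])
        )
    annotations = AnnotationTable(entries)

    # --- intensities -----------------------------------------------------
    sample_ids = design.sample_ids
    n_samples = len(sample_ids)
    log2_int = np.empty((n, n_samples))
    for j, s in enumerate(design.samples):
        tm_eff = tm + np.where(s.arm == "treatment", delta, 0.0)
        f = melting_fraction(s.temperature_C, tm_eff, scale, plateau)
        log2_int[:, j] = (
            base + np.log2(f) + rng.normal(0.0, config.rep_noise_sd_log2, size=n)
        )
    p_obs = expit(
        (log2_int - config.dropout_midpoint_log2) / config.dropout_slope
    )
    observed = rng.random((n, n_samples)) < p_obs
    linear = np.where(observed, np.power(2.0, log2_int), 0.0)

    uniq = 1 + rng.poisson(np.maximum(0.0, base - 20.0))

    rows: list[dict] = []
    for i in range(n):
        rows.append(
            _pg_row(ids[i], genes[i], linear[i], sample_ids, int(uniq[i]))
        )

    # scaffold: constant, always observed, high peptide count
    scaffold_vals = np.power(
        2.0,
        config.scaffold_log2
        + rng.normal(0.0, config.scaffold_noise_sd, size=n_samples),
    )
    rows.append(_pg_row(SCAFFOLD_ID, SCAFFOLD_GENE, scaffold_vals, sample_ids, 10))

    # decoy / contaminant / site-only rows: intensities from the same base
    # distribution so only the flags, not abundance, remove them
    def _extra_rows(count: int, prefix: str, flag_col: str | None):
        for k in range(count):
            b = rng.normal(config.base_log2_mean, config.base_log2_sd)
            t_ex = rng.normal(config.tm_mean_C, config.tm_sd_C)
            sc = rng.uniform(*config.melt_scale_C)
            vals = np.empty(n_samples)
            for j, s in enumerate(design.samples):
                f = melting_fraction(s.temperature_C, t_ex, sc, 0.1)
                v = b + math.log2(f) + rng.normal(0.0, config.rep_noise_sd_log2)
                obs = rng.random() < expit(
                    (v - config.dropout_midpoint_log2) / config.dropout_slope
                )
                vals[j] = 2.0**v if obs else 0.0
            row = _pg_row(f"{prefix}{k + 1:04d}", None, vals, sample_ids, 2)
            if flag_col:
                row[flag_col] = "+"
            yield row

    rows.extend(_extra_rows(config.n_decoys, "REV__SIMD", "Reverse"))
    rows.extend(_extra_rows(config.n_contaminants, "CON__SIMC", "Potential contaminant"))
    rows.extend(_extra_rows(config.n_site_only, "SITEONLY", "Only identified by site"))

    columns = (
        ["Protein IDs", "Gene names", "Reverse", "Potential contaminant",
         "Only identified by site", "Unique peptides"]
        + [f"LFQ intensity {s}" for s in sample_ids]
    )
    pg = pd.DataFrame(rows, columns=columns).fillna("")

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "class": classes,
            "tm_C": tm,
            "delta_tm_C": delta,
            "base_log2": base,
            "tags": [";".join(sorted(t)) for t in tags],
        },
        columns=TRUTH_COLUMNS,
    )
    return SimulatedDataset(pg, design, annotations, truth, config)


def _pg_row(
    pid: str,
    gene: str | None,
    linear_vals: np.ndarray,
    sample_ids: list[str],
    uniq: int,
) -> dict:
    row = {
        "Protein IDs": pid,
        "Gene names": gene or "",
        "Reverse": "",
        "Potential contaminant": "",
        "Only identified by site": "",
        "Unique peptides": uniq,
    }
    for sid, v in zip(sample_ids, linear_vals):
        row[f"LFQ intensity {sid}"] = 0 if v == 0.0 else f"{v:.6g}"
    return row


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write pg.tsv, design.tsv, annot.tsv and truth.tsv into out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": out_dir / "pg.tsv",
        "design": out_dir / "design.tsv",
        "annotations": out_dir / "annot.tsv",
        "truth": out_dir / "truth.tsv",
    }
    dataset.protein_groups.to_csv(paths["protein_groups"], sep="\t", index=False)
    write_design(dataset.design, paths["design"])
    write_annotations(dataset.annotations, paths["annotations"])
    write_ground_truth(dataset.truth, paths["truth"])
    return paths


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: ground-truth table missing columns {missing}")
    return df
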
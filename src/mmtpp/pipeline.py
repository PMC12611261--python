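"""End-to-end orchestration: from input tables to the results bundle.

One run chains the fixed preprocessing order, the per-temperature volcano
analysis, membrane classification, enrichment of the stabilized integral
membrane proteins, and the binder-fraction summary.  All randomness
(imputation) flows from a single seed recorded in the run manifest, and
every output is a deterministic function of (inputs, config, seed): rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from mmtpp import __version__
from mmtpp.annotate import (
    binder_fraction_summary,
    classify_proteins,
    enrich_terms,
    group_redundant_terms,
)
from mmtpp.diffstab import DiffParams, differential_stability
from mmtpp.errors import ValidationError
from mmtpp.preprocess import (
    PreprocessParams,
    filter_protein_groups,
    log2_transform,
    mark_scaffold,
    normalize_to_scaffold,
    prepare_temperature_slice,
)
from mmtpp.tables_io import (
    FLOAT_FORMAT,
    AnnotationTable,
    IntensityMatrix,
    ProteinGroupsDialect,
    read_annotations,
    read_design,
    read_protein_groups,
    write_results,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("mmtpp")


@dataclass
class RunConfig:
    """Authoritative configuration of one pipeline run."""

    protein_groups: str
    design: str | None = None
    annotations: str | None = None
    out_dir: str = "mmtpp_run"
    seed: int = 0
    intensity_prefix: str = "LFQ intensity "
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    diff: DiffParams = field(default_factory=DiffParams)
    enrichment_namespace: str = "both"
    binder_tag: str = "ATP binding"
    reference_temperature_C: float | None = None

    def to_dict(self) -> dict:
        # out_dir is where a run lands, not part of its scientific identity:
        # reruns into different directories must be byte-identical
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    results: pd.DataFrame
    classification: pd.DataFrame
    enrichment: pd.DataFrame
    binder_fractions: pd.DataFrame
    melting_profiles: pd.DataFrame
    manifest: dict
    out_dir: Path


def _melting_profile_table(matrix: IntensityMatrix) -> pd.DataFrame:
    """Knot statistics (mean, sd, n) per protein x arm x temperature."""
    rows = []
    temps = matrix.design.temperatures
    for arm in ("treatment", "control"):
        cols_by_t = {t: matrix.design.sample_ids_at(t, arm) for t in temps}
        for t, cols in cols_by_t.items():
            if not cols:
                continue
            block = matrix.values[cols]
            mean = block.mean(axis=1, skipna=True)
            sd = block.std(axis=1, ddof=1, skipna=True)
            n = block.notna().sum(axis=1)
            for pid in matrix.values.index:
                if n[pid] > 0:
                    rows.append(
                        (pid, arm, t, mean[pid], sd[pid] if n[pid] > 1 else 0.0, int(n[pid]))
                    )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "arm", "temperature_C", "mean_log2", "sd_log2", "n_obs"],
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the results bundle.

    Outputs written to ``config.out_dir``: ``differential_results.tsv``,
    one ``volcano_<T>.tsv`` per temperature, ``melting_profiles.tsv``,
    ``classification.tsv``, ``enrichment.tsv``, ``binder_fractions.tsv``
    and ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    dialect = ProteinGroupsDialect(intensity_prefix=config.intensity_prefix)
    design = read_design(config.design) if config.design else None
    records, matrix = read_protein_groups(
        config.protein_groups, dialect=dialect, design=design
    )
    matrix.design.require_both_arms()
    counts["input_rows"] = len(records)
    log.info("read %d protein groups x %d samples", *matrix.shape)

    n_scaffold = mark_scaffold(records, config.preprocess.scaffold_pattern)
    counts["scaffold_rows"] = n_scaffold
    matrix = filter_protein_groups(matrix)
    counts["after_id_filter"] = matrix.shape[0]
    log.info("identification filter: %d -> %d rows", counts["input_rows"], matrix.shape[0])

    matrix = log2_transform(matrix)
    matrix = normalize_to_scaffold(matrix, median_fallback=config.preprocess.median_fallback)

    annotations = (
        read_annotations(config.annotations)
        if config.annotations
        else AnnotationTable()
    )

    rng = np.random.default_rng(config.seed)
    per_temperature = []
    temps = matrix.design.temperatures
    ref_t = config.reference_temperature_C
    test_temps = [t for t in temps if ref_t is None or t != ref_t]
    for t in test_temps:
        slice_matrix = prepare_temperature_slice(matrix, t, config.preprocess, rng)
        res_t = differential_stability(slice_matrix, config.diff)
        counts[f"tested_at_{t:g}C"] = res_t.shape[0]
        log.info(
            "T=%g degC: %d proteins tested, %d called",
            t, res_t.shape[0], int((res_t["call"] != "unchanged").sum()),
        )
        write_results(res_t, out_dir / f"volcano_{t:g}C.tsv")
        per_temperature.append(res_t)
    results = pd.concat(per_temperature, ignore_index=True)
    write_results(results, out_dir / "differential_results.tsv")

    profiles = _melting_profile_table(matrix)
    profiles.to_csv(
        out_dir / "melting_profiles.tsv", sep="\t", index=False,
        float_format=FLOAT_FORMAT,
    )

    tested_ids = sorted(set(results["protein_id"]))
    classification = classify_proteins(tested_ids, annotations)
    classification.to_csv(out_dir / "classification.tsv", sep="\t", index=False)

    imp_ids = set(classification.loc[classification["class"] == "IMP", "protein_id"])
    stabilized = set(results.loc[results["call"] == "stabilized", "protein_id"])
    query = stabilized & imp_ids
    background = set(tested_ids)
    if query:
        enrichment = enrich_terms(
            query, background, annotations, namespace=config.enrichment_namespace
        )
        enrichment = group_redundant_terms(
            enrichment, query, annotations, namespace=config.enrichment_namespace
        )
    else:
        enrichment = pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "ease_p", "bh_q", "significant",
                     "grouped_with"]
        )
    enrichment.to_csv(
        out_dir / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    fractions = binder_fraction_summary(results, annotations, config.binder_tag)
    fractions.to_csv(
        out_dir / "binder_fractions.tsv", sep="\t", index=False,
        float_format=FLOAT_FORMAT,
    )

    counts["called_stabilized"] = int((results["call"] == "stabilized").sum())
    counts["called_destabilized"] = int((results["call"] == "destabilized").sum())
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "row_counts": counts,
        "outputs": [
            "differential_results.tsv",
            *[f"volcano_{t:g}C.tsv" for t in test_temps],
            "melting_profiles.tsv",
            "classification.tsv",
            "enrichment.tsv",
            "binder_fractions.tsv",
        ],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        results=results,
        classification=classification,
        enrichment=enrichment,
        binder_fractions=fractions,
        melting_profiles=profiles,
        manifest=manifest,
        out_dir=out_dir,
    )
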
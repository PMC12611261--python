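"""Readers and writers for every tabular format the pipeline touches.

The central input is a MaxQuant-style ``proteinGroups`` wide table: one row
per protein group, flag columns marking decoy / contaminant / site-only
identifications, per-group unique-peptide counts, and one intensity column
per sample (``LFQ intensity <sample>`` by default, ``iBAQ <sample>``
supported through the dialect).  Intensities of 0 (or empty cells) are the
MaxQuant convention for "not quantified" and become explicit missing values.

All tables are UTF-8, tab-delimited, with "." as the decimal separator.
Floats in result tables are written with 17 significant digits so that a
write/read round trip is exact to double precision.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mmtpp.errors import ValidationError

__all__ = [
    "TransformState",
    "ProteinGroupsDialect",
    "ProteinRecord",
    "Sample",
    "SampleDesign",
    "IntensityMatrix",
    "Annotation",
    "AnnotationTable",
    "read_protein_groups",
    "read_design",
    "read_annotations",
    "write_annotations",
    "write_design",
    "write_results",
    "read_results",
]

#: Column order of the differential-results table (stable public contract).
RESULT_COLUMNS = [
    "protein_id",
    "temperature_C",
    "log2_fc",
    "t_stat",
    "p_value",
    "neg_log10_p",
    "call",
    "n_treat",
    "n_ctrl",
]

FLOAT_FORMAT = "%.17g"

ARM_ALIASES = {
    "t": "treatment",
    "treat": "treatment",
    "treatment": "treatment",
    "c": "control",
    "ctrl": "control",
    "control": "control",
}


class TransformState(enum.Enum):
    """Position of an intensity matrix in the fixed preprocessing order."""

    raw = "raw"
    log2 = "log2"
    normalized = "normalized"
    imputed = "imputed"


@dataclass(frozen=True)
class ProteinGroupsDialect:
    """Column-name conventions of a proteinGroups-style table.

    The defaults match current MaxQuant output; ``intensity_prefix`` can be
    switched to ``"iBAQ "`` for iBAQ quantification, which is handled
    identically downstream.
    """

    intensity_prefix: str = "LFQ intensity "
    id_column: str = "Protein IDs"
    gene_column: str = "Gene names"
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"
    site_only_column: str = "Only identified by site"
    unique_peptides_prefix: str = "Unique peptides"
    decoy_prefix: str = "REV__"
    contaminant_prefix: str = "CON__"
    flag_value: str = "+"


@dataclass
class ProteinRecord:
    """One protein group: identifier, QC flags, and unique-peptide counts.

    ``unique_peptides`` maps a sample-group name to a count; the empty-string
    key holds the table-wide "Unique peptides" total when present.
    """

    protein_id: str
    gene_name: str | None = None
    is_reverse: bool = False
    is_contaminant: bool = False
    is_site_only: bool = False
    is_scaffold: bool = False
    unique_peptides: dict[str, int] = field(default_factory=dict)

    def max_unique_peptides(self) -> int | None:
        """Largest unique-peptide count over all groups, or None if unknown."""
        if not self.unique_peptides:
            return None
        return max(self.unique_peptides.values())


@dataclass(frozen=True, order=True)
class Sample:
    """One LC-MS/MS run: arm, temperature and replicate."""

    sample_id: str
    arm: str
    temperature_C: float
    replicate: int

    def __post_init__(self) -> None:
        if self.arm not in ("treatment", "control"):
            raise ValidationError(
                f"sample {self.sample_id!r}: arm must be 'treatment' or "
                f"'control', got {self.arm!r}"
            )
        if self.temperature_C < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: temperature must be >= 0 degC"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


class SampleDesign:
    """Validated set of samples covering a treatment/control gradient.

    Every (arm, temperature, replicate) triple must be unique.  Temperatures
    are exposed in ascending order.
    """

    def __init__(self, samples: Sequence[Sample]):
        if not samples:
            raise ValidationError("sample design is empty")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate sample_id {dup!r} in design")
        triples = [(s.arm, s.temperature_C, s.replicate) for s in samples]
        if len(set(triples)) != len(triples):
            dup = next(t for t in triples if triples.count(t) > 1)
            raise ValidationError(
                f"duplicate (arm, temperature, replicate) triple {dup} in design"
            )
        self.samples: tuple[Sample, ...] = tuple(
            sorted(samples, key=lambda s: (s.temperature_C, s.arm, s.replicate))
        )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def temperatures(self) -> list[float]:
        return sorted({s.temperature_C for s in self.samples})

    @property
    def arms(self) -> set[str]:
        return {s.arm for s in self.samples}

    def samples_at(self, temperature_C: float | None = None, arm: str | None = None) -> list[Sample]:
        out = []
        for s in self.samples:
            if temperature_C is not None and not math.isclose(s.temperature_C, temperature_C):
                continue
            if arm is not None and s.arm != arm:
                continue
            out.append(s)
        return out

    def sample_ids_at(self, temperature_C: float | None = None, arm: str | None = None) -> list[str]:
        return [s.sample_id for s in self.samples_at(temperature_C, arm)]

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        wanted = set(sample_ids)
        return SampleDesign([s for s in self.samples if s.sample_id in wanted])

    def require_both_arms(self) -> None:
        """Raise unless every temperature is present in both arms."""
        lonely = []
        for t in self.temperatures:
            arms = {s.arm for s in self.samples_at(t)}
            if arms != {"treatment", "control"}:
                lonely.append(t)
        if lonely:
            raise ValidationError(
                "temperatures present in only one arm: "
                + ", ".join(f"{t:g}" for t in lonely)
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleDesign) and self.samples == other.samples

    def __repr__(self) -> str:
        return (
            f"SampleDesign({len(self.samples)} samples, "
            f"temperatures={self.temperatures}, arms={sorted(self.arms)})"
        )


class IntensityMatrix:
    """Proteins x samples grid of intensities with explicit missingness.

    ``values`` is a DataFrame indexed by protein_id with one column per
    sample_id; missing cells are NaN.  ``state`` tracks progress through the
    fixed preprocessing order raw -> log2 -> normalized -> imputed.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        design: SampleDesign,
        values: pd.DataFrame,
        state: TransformState = TransformState.raw,
    ):
        if len(records) != values.shape[0]:
            raise ValidationError(
                f"{len(records)} records but {values.shape[0]} value rows"
            )
        if list(values.columns) != design.sample_ids:
            missing = set(design.sample_ids) - set(values.columns)
            extra = set(values.columns) - set(design.sample_ids)
            if missing or extra:
                raise ValidationError(
                    f"value columns do not match design (missing={sorted(missing)}, "
                    f"extra={sorted(extra)})"
                )
            values = values[design.sample_ids]
        rec_ids = [r.protein_id for r in records]
        if list(values.index) != rec_ids:
            raise ValidationError("value row index does not match record order")
        arr = values.to_numpy(dtype=float)
        finite_or_nan = np.isfinite(arr) | np.isnan(arr)
        if not finite_or_nan.all():
            raise ValidationError("intensity matrix contains non-finite values")
        if state is TransformState.raw and np.nanmin(arr, initial=np.inf) <= 0:
            raise ValidationError("raw intensities must be > 0 (0 means missing)")
        self.records = list(records)
        self.design = design
        self.values = values.astype(float)
        self.state = state

    @property
    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def record_for(self, protein_id: str) -> ProteinRecord:
        for r in self.records:
            if r.protein_id == protein_id:
                return r
        raise KeyError(protein_id)

    def subset_rows(self, keep: Sequence[bool] | Sequence[str]) -> "IntensityMatrix":
        """Row subset by boolean mask (record order) or by protein ids."""
        keep = list(keep)
        if len(keep) > 0 and isinstance(keep[0], (bool, np.bool_)):
            mask = np.asarray(keep, dtype=bool)
            if mask.shape[0] != len(self.records):
                raise ValidationError("row mask length does not match record count")
            records = [r for r, k in zip(self.records, mask) if k]
        else:
            wanted = set(keep)
            records = [r for r in self.records if r.protein_id in wanted]
        values = self.values.loc[[r.protein_id for r in records]]
        return IntensityMatrix(records, self.design, values, self.state)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        sub_design = self.design.subset(sample_ids)
        return IntensityMatrix(
            self.records, sub_design, self.values[sub_design.sample_ids], self.state
        )

    def with_values(self, values: pd.DataFrame, state: TransformState) -> "IntensityMatrix":
        return IntensityMatrix(self.records, self.design, values, state)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            list(self.records), self.design, self.values.copy(), self.state
        )

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __repr__(self) -> str:
        return (
            f"IntensityMatrix({self.shape[0]} proteins x {self.shape[1]} samples, "
            f"state={self.state.value}, missing={self.n_missing()})"
        )


@dataclass
class Annotation:
    """Per-protein annotation: GO terms, transmembrane-segment count, tags."""

    go_terms: set[str] = field(default_factory=set)
    tms_count: int | None = None
    tags: set[str] = field(default_factory=set)


class AnnotationTable:
    """protein_id -> Annotation lookup; absence means "no annotation"."""

    def __init__(self, entries: Mapping[str, Annotation] | None = None):
        self._entries: dict[str, Annotation] = dict(entries or {})
        for pid, ann in self._entries.items():
            if ann.tms_count is not None and ann.tms_count < 0:
                raise ValidationError(f"protein {pid!r}: negative TMS count")

    def get(self, protein_id: str) -> Annotation | None:
        return self._entries.get(protein_id)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def items(self):
        return self._entries.items()

    def proteins_with_tag(self, tag: str) -> set[str]:
        return {p for p, a in self._entries.items() if tag in a.tags}

    def terms_of(self, protein_id: str, namespace: str = "go") -> set[str]:
        """Annotation terms of one protein: 'go', 'tags' or 'both'."""
        ann = self._entries.get(protein_id)
        if ann is None:
            return set()
        if namespace == "go":
            return set(ann.go_terms)
        if namespace == "tags":
            return set(ann.tags)
        if namespace == "both":
            return set(ann.go_terms) | set(ann.tags)
        raise ValidationError(f"unknown annotation namespace {namespace!r}")


def _is_flagged(value: object, flag: str) -> bool:
    return isinstance(value, str) and value.strip() == flag


def read_protein_groups(
    path: str | Path,
    dialect: ProteinGroupsDialect = ProteinGroupsDialect(),
    design: SampleDesign | None = None,
) -> tuple[list[ProteinRecord], IntensityMatrix]:
    """Read a proteinGroups-style table into records plus a raw matrix.

    Intensity columns are located by ``dialect.intensity_prefix``; their
    suffixes become sample ids.  When *design* is omitted it is parsed from
    the sample ids via the ``<Arm>_<Temp>_<Rep>`` convention.  Zero or empty
    intensities become missing values; the count of missing cells therefore
    equals the count of zero/empty cells in the file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns.size == 0:
        raise ValidationError(f"{path}: missing header row")
    if dialect.id_column not in df.columns:
        raise ValidationError(
            f"{path}: missing required column {dialect.id_column!r}"
        )
    intensity_cols = [
        c for c in df.columns if c.startswith(dialect.intensity_prefix)
        and c != dialect.intensity_prefix.rstrip()
    ]
    if not intensity_cols:
        raise ValidationError(
            f"{path}: no intensity columns with prefix {dialect.intensity_prefix!r}"
        )
    sample_ids = [c[len(dialect.intensity_prefix):] for c in intensity_cols]

    ids = df[dialect.id_column].str.strip()
    if (ids == "").any():
        row = int(np.argmax((ids == "").to_numpy())) + 2  # 1-based + header
        raise ValidationError(f"{path}: empty protein id at file row {row}")
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate protein id {dup.iloc[0]!r}")

    # unique-peptide columns: bare total and/or per-group "<prefix> <group>"
    up_prefix = dialect.unique_peptides_prefix
    up_cols: dict[str, str] = {}
    for c in df.columns:
        if c == up_prefix:
            up_cols[""] = c
        elif c.startswith(up_prefix + " "):
            up_cols[c[len(up_prefix) + 1 :]] = c

    records: list[ProteinRecord] = []
    for i, pid in enumerate(ids):
        row = df.iloc[i]
        gene = row.get(dialect.gene_column, "") or None
        uniq: dict[str, int] = {}
        for group, col in up_cols.items():
            cell = row[col].strip()
            if cell != "":
                uniq[group] = int(float(cell))
        records.append(
            ProteinRecord(
                protein_id=pid,
                gene_name=gene,
                is_reverse=pid.startswith(dialect.decoy_prefix)
                or _is_flagged(row.get(dialect.reverse_column), dialect.flag_value),
                is_contaminant=pid.startswith(dialect.contaminant_prefix)
                or _is_flagged(row.get(dialect.contaminant_column), dialect.flag_value),
                is_site_only=_is_flagged(
                    row.get(dialect.site_only_column), dialect.flag_value
                ),
                unique_peptides=uniq,
            )
        )

    values = (
        df[intensity_cols]
        .replace("", "0")
        .astype(float)
        .set_axis(sample_ids, axis=1)
        .set_axis(list(ids), axis=0)
    )
    values = values.mask(values <= 0.0)  # 0 / empty -> missing

    if design is None:
        design = read_design(sample_ids=sample_ids)
    matrix = IntensityMatrix(records, design, values[design.sample_ids], TransformState.raw)
    return records, matrix


_SAMPLE_ID_RE = re.compile(r"^(?P<arm>[A-Za-z]+)_(?P<temp>\d+(?:\.\d+)?)_(?P<rep>\d+)$")


def parse_sample_id(sample_id: str) -> Sample:
    """Parse a ``<Arm>_<Temp>_<Rep>`` sample id (e.g. ``T_51_1``)."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise ValidationError(
            f"sample id {sample_id!r} does not follow the <Arm>_<Temp>_<Rep> convention"
        )
    arm = ARM_ALIASES.get(m.group("arm").lower())
    if arm is None:
        raise ValidationError(
            f"sample id {sample_id!r}: unknown arm {m.group('arm')!r} "
            f"(expected one of {sorted(set(ARM_ALIASES))})"
        )
    return Sample(sample_id, arm, float(m.group("temp")), int(m.group("rep")))


def read_design(
    path: str | Path | None = None,
    sample_ids: Sequence[str] | None = None,
    require_both_arms: bool = True,
) -> SampleDesign:
    """Build a SampleDesign from an explicit design file or from sample ids.

    The design file has four tab-separated columns: sample_id, arm,
    temperature_C, replicate.  An explicit file always overrides the naming
    convention.
    """
    if path is not None:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["sample_id", "arm", "temperature_C", "replicate"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: design file missing columns {missing}")
        samples = []
        for _, row in df.iterrows():
            arm = ARM_ALIASES.get(str(row["arm"]).strip().lower())
            if arm is None:
                raise ValidationError(
                    f"{path}: unknown arm {row['arm']!r} for sample {row['sample_id']!r}"
                )
            samples.append(
                Sample(
                    str(row["sample_id"]).strip(),
                    arm,
                    float(row["temperature_C"]),
                    int(float(row["replicate"])),
                )
            )
    elif sample_ids is not None:
        samples = [parse_sample_id(s) for s in sample_ids]
    else:
        raise ValidationError("read_design requires a path or sample_ids")
    design = SampleDesign(samples)
    if require_both_arms:
        design.require_both_arms()
    return design


def write_design(design: SampleDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design.samples],
            "arm": [s.arm for s in design.samples],
            "temperature_C": [s.temperature_C for s in design.samples],
            "replicate": [s.replicate for s in design.samples],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a protein annotation table.

    Expected columns: ``protein_id``, ``go_terms`` (semicolon-separated),
    ``tms_count`` (integer, empty for unknown), ``tags``
    (semicolon-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein_id", "go_terms", "tms_count", "tags"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: annotation table missing columns {missing}")
    entries: dict[str, Annotation] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"].strip()
        tms_cell = row["tms_count"].strip()
        tms = None if tms_cell == "" else int(float(tms_cell))
        if tms is not None and tms < 0:
            raise ValidationError(f"{path}: negative TMS count for {pid!r}")
        entries[pid] = Annotation(
            go_terms={t.strip() for t in row["go_terms"].split(";") if t.strip()},
            tms_count=tms,
            tags={t.strip() for t in row["tags"].split(";") if t.strip()},
        )
    return AnnotationTable(entries)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = []
    for pid, ann in sorted(table.items()):
        rows.append(
            {
                "protein_id": pid,
                "go_terms": ";".join(sorted(ann.go_terms)),
                "tms_count": "" if ann.tms_count is None else ann.tms_count,
                "tags": ";".join(sorted(ann.tags)),
            }
        )
    pd.DataFrame(rows, columns=["protein_id", "go_terms", "tms_count", "tags"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-results table (one row per protein x temperature).

    Column order is fixed; floats round-trip exactly through
    :func:`read_results`.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results table missing columns {missing}")
    results[RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: results table missing columns {missing}")
    return df
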
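"""Tabular I/O: curated QTL metadata tables, chromosome-length tables, BED output.

All coordinates are 0-based half-open internally.  BED output follows the BED
standard; chromosome-length tables accept the two leading columns of a FASTA
``.fai`` index.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "TRAIT_GROUPS",
    "POP_TYPES",
    "QTL_COLUMNS",
    "QTLRecord",
    "ChromosomeTable",
    "IngestResult",
    "RowError",
    "QTLSchemaError",
    "ChromTableError",
    "read_qtl_table",
    "write_qtl_table",
    "read_chrom_table",
    "write_chrom_table",
    "write_projected_bed",
    "read_projected_bed",
]

TRAIT_GROUPS = (
    "fruit",
    "flower",
    "vegetative_organ",
    "seed",
    "disease_resistance",
    "insect_resistance",
    "abiotic_stress",
)

POP_TYPES = ("F2", "RIL", "DH", "BC", "other")

#: canonical column order of the tab-separated QTL metadata table
QTL_COLUMNS = (
    "qtl_id",
    "study_ref",
    "trait_code",
    "trait_group",
    "linkage_group",
    "peak_cM",
    "ci_start_cM",
    "ci_end_cM",
    "lod",
    "pve_percent",
    "pop_type",
    "pop_size",
    "parents",
    "source_genome",
)

_REQUIRED_COLUMNS = (
    "qtl_id",
    "study_ref",
    "trait_code",
    "trait_group",
    "linkage_group",
    "ci_start_cM",
    "ci_end_cM",
)

_OPTIONAL_FLOAT = ("peak_cM", "lod", "pve_percent")
_OPTIONAL_INT = ("pop_size",)


class QTLSchemaError(ValueError):
    """The table header is missing a required column."""


class ChromTableError(ValueError):
    """A chromosome-length table is malformed or references an unknown name."""


class QTLRecord(BaseModel):
    """One published QTL together with its study metadata.

    Genetic-map coordinates are in centimorgans on the original study's map.
    ``lod``, ``pve_percent``, ``peak_cM`` and ``pop_size`` may be missing in
    literature tables and are never imputed here.
    """

    model_config = ConfigDict(frozen=True)

    qtl_id: str = Field(min_length=1)
    study_ref: str = Field(min_length=1)
    trait_code: str = Field(min_length=1)
    trait_group: Literal[TRAIT_GROUPS]  # type: ignore[valid-type]
    linkage_group: str = Field(min_length=1)
    peak_cM: Optional[float] = Field(default=None, ge=0)
    ci_start_cM: float = Field(ge=0)
    ci_end_cM: float = Field(ge=0)
    lod: Optional[float] = Field(default=None, gt=0)
    pve_percent: Optional[float] = Field(default=None, gt=0, le=100)
    pop_type: Literal[POP_TYPES] = "other"  # type: ignore[valid-type]
    pop_size: Optional[int] = Field(default=None, gt=0)
    parents: str = ""
    source_genome: str = ""

    @model_validator(mode="after")
    def _check_interval(self) -> "QTLRecord":
        if self.ci_start_cM > self.ci_end_cM:
            raise ValueError("interval reversed")
        if self.peak_cM is not None and not (
            self.ci_start_cM <= self.peak_cM <= self.ci_end_cM
        ):
            raise ValueError("peak outside interval")
        return self


@dataclass(frozen=True)
class RowError:
    """A rejected input row: 1-based data row number plus a reason."""

    row: int
    reason: str


@dataclass
class IngestResult:
    """Outcome of reading a QTL table: accepted records plus row diagnostics."""

    records: list[QTLRecord]
    rejected: list[RowError] = field(default_factory=list)

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejected)

    @property
    def group_counts(self) -> Counter:
        return Counter(r.trait_group for r in self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _clean(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    return value or None


def read_qtl_table(
    path,
    delimiter: str = "\t",
    column_map: Optional[Mapping[str, str]] = None,
) -> IngestResult:
    """Read and validate a delimited QTL metadata table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    delimiter
        Field separator (tab by default).
    column_map
        Optional mapping from the file's column names to the canonical
        ``QTL_COLUMNS`` names, for ingesting third-party layouts.

    Returns
    -------
    IngestResult
        Accepted records in file order plus per-row diagnostics for every
        rejected row; no row is silently dropped.

    Raises
    ------
    QTLSchemaError
        If a required column is absent from the header.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        if column_map:
            header = [column_map.get(c, c) for c in header]
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise QTLSchemaError(f"missing required column: {col}")
        records: list[QTLRecord] = []
        rejected: list[RowError] = []
        seen_ids: set[str] = set()
        for row_no, raw in enumerate(reader, start=1):
            if column_map:
                raw = {column_map.get(k, k): v for k, v in raw.items()}
            data = {k: _clean(raw.get(k)) for k in QTL_COLUMNS}
            if data["pop_type"] is None:
                data["pop_type"] = "other"
            for k in ("parents", "source_genome"):
                if data[k] is None:
                    data[k] = ""
            reason = _row_reason(data, seen_ids)
            if reason is not None:
                rejected.append(RowError(row_no, reason))
                continue
            try:
                rec = QTLRecord(**data)  # type: ignore[arg-type]
            except ValidationError as exc:
                rejected.append(RowError(row_no, _first_message(exc)))
                continue
            seen_ids.add(rec.qtl_id)
            records.append(rec)
    return IngestResult(records=records, rejected=rejected)


def _row_reason(data: dict, seen_ids: set[str]) -> Optional[str]:
    """Pre-validate a row so diagnostics use stable, readable reasons."""
    qtl_id = data.get("qtl_id")
    if not qtl_id:
        return "empty qtl_id"
    if qtl_id in seen_ids:
        return f"duplicate qtl_id: {qtl_id}"
    for col in ("ci_start_cM", "ci_end_cM"):
        if data.get(col) is None:
            return f"missing {col}"
        try:
            data[col] = float(data[col])
        except ValueError:
            return f"non-numeric {col}: {data[col]}"
    for col in _OPTIONAL_FLOAT:
        if data.get(col) is not None:
            try:
                data[col] = float(data[col])
            except ValueError:
                return f"non-numeric {col}: {data[col]}"
    for col in _OPTIONAL_INT:
        if data.get(col) is not None:
            try:
                data[col] = int(float(data[col]))
            except ValueError:
                return f"non-numeric {col}: {data[col]}"
    if data["ci_start_cM"] > data["ci_end_cM"]:
        return "interval reversed"
    return None


def _first_message(exc: ValidationError) -> str:
    err = exc.errors()[0]
    loc = ".".join(str(p) for p in err["loc"]) if err["loc"] else ""
    msg = err["msg"].removeprefix("Value error, ")
    return f"{loc}: {msg}" if loc else msg


def write_qtl_table(records: Iterable[QTLRecord], path, delimiter: str = "\t") -> None:
    """Write records in the canonical column order; missing values are empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(QTL_COLUMNS)
        for rec in records:
            row = []
            for col in QTL_COLUMNS:
                val = getattr(rec, col)
                row.append("" if val is None else str(val))
            writer.writerow(row)


@dataclass(frozen=True)
class ChromosomeTable:
    """Ordered chromosome-name -> length(bp) mapping for one assembly."""

    entries: dict  # insertion-ordered name -> int length

    def __post_init__(self):
        for name, length in self.entries.items():
            if length <= 0:
                raise ChromTableError(f"non-positive length for {name}: {length}")

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> int:
        try:
            return self.entries[name]
        except KeyError:
            raise ChromTableError(f"unknown chromosome: {name}") from None

    def __len__(self) -> int:
        return len(self.entries)

    def order(self, name: str) -> int:
        """Rank of a chromosome in table order (for stable sorting)."""
        try:
            return self.names.index(name)
        except ValueError:
            raise ChromTableError(f"unknown chromosome: {name}") from None

    def total_bp(self) -> int:
        return sum(self.entries.values())


def read_chrom_table(path) -> ChromosomeTable:
    """Read a chromosome-length table (first two columns of a ``.fai`` work)."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ChromTableError(f"line {line_no}: expected >=2 columns")
            name = parts[0]
            if name in entries:
                raise ChromTableError(f"line {line_no}: duplicate name {name}")
            try:
                length = int(parts[1])
            except ValueError:
                raise ChromTableError(
                    f"line {line_no}: non-integer length {parts[1]!r}"
                ) from None
            if length <= 0:
                raise ChromTableError(f"line {line_no}: non-positive length {length}")
            entries[name] = length
    return ChromosomeTable(entries=entries)


def write_chrom_table(chroms: ChromosomeTable, path) -> None:
    with open(path, "w") as fh:
        for name, length in chroms.entries.items():
            fh.write(f"{name}\t{length}\n")


_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand"


def write_projected_bed(
    records: Sequence,
    path,
    chroms: ChromosomeTable,
    lod_by_id: Optional[Mapping[str, float]] = None,
) -> None:
    """Write projected intervals as BED6.

    Name is the positional ``renamed_id`` when assigned, else the original
    ``qtl_id``; score is ``round(10 * LOD)`` (0 when LOD is missing).  Records
    are sorted by chromosome-table order then start.
    """
    lod_by_id = lod_by_id or {}
    rows = []
    for rec in records:
        if rec.chrom is None or rec.start_bp is None or rec.end_bp is None:
            raise ValueError(f"record {rec.qtl_id} has no coordinates")
        if rec.chrom not in chroms:
            raise ChromTableError(f"unknown chromosome: {rec.chrom}")
        lod = lod_by_id.get(rec.qtl_id)
        score = int(round(10 * lod)) if lod is not None else 0
        name = rec.renamed_id or rec.qtl_id
        rows.append((chroms.order(rec.chrom), rec.start_bp, rec.chrom, rec.end_bp, name, score))
    rows.sort(key=lambda r: (r[0], r[1], r[4]))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for _, start, chrom, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def read_projected_bed(path) -> list[tuple]:
    """Read BED6 lines back as ``(chrom, start, end, name, score, strand)``."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out
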
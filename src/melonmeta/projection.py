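"""Lift genetic-map QTL intervals onto a physical reference.

Each QTL is located by aligning the two 1-kb sequences flanking its mapping
interval against the target assembly.  Alignments arrive in PAF; query names
follow the convention ``<qtl_id>__L`` / ``<qtl_id>__R``.  The projected
interval is bounded by the flank edges that face the QTL: the end of the left
flank and the start of the right flank, after strand normalization.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .qtl_io import ChromosomeTable, ChromTableError, QTLRecord

__all__ = [
    "ProjectionStatus",
    "PafAlignment",
    "PafParseResult",
    "FlankPair",
    "ProjectedQTL",
    "parse_paf",
    "pair_flanks",
    "select_best_hit",
    "project_interval",
    "project_all",
    "quarter_filter",
    "rename_qtls",
    "chrom_number",
    "overlap_components",
    "status_counts",
]

LEFT_SUFFIX = "__L"
RIGHT_SUFFIX = "__R"


class ProjectionStatus(str, enum.Enum):
    PROJECTED = "projected"
    FAILED_FLANK_MISSING = "failed_flank_missing"
    FAILED_CROSS_CHROM = "failed_cross_chrom"
    FAILED_ORIENTATION = "failed_orientation"
    EXCLUDED_QUARTER_FILTER = "excluded_quarter_filter"


#: statuses whose records carry physical coordinates
_COORD_STATUSES = {
    ProjectionStatus.PROJECTED,
    ProjectionStatus.EXCLUDED_QUARTER_FILTER,
}


@dataclass(frozen=True)
class PafAlignment:
    """One PAF record (0-based half-open coordinates on both sequences)."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    aln_len: int
    mapq: int
    is_primary: bool = True


@dataclass
class PafParseResult:
    alignments: list[PafAlignment]
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self) -> int:
        return len(self.alignments)


def parse_paf(source: Union[str, Iterable[str]]) -> PafParseResult:
    """Parse PAF from a path or an iterable of lines.

    Mandatory columns 1-12 are parsed; the ``tp:A`` tag sets primary status
    (primary when absent).  Malformed lines are collected as ``(line_no,
    reason)`` pairs instead of raising, so one bad line cannot sink a run.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return parse_paf(list(fh))
    result = PafParseResult(alignments=[])
    for line_no, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            result.errors.append((line_no, f"expected >=12 columns, got {len(cols)}"))
            continue
        try:
            aln = PafAlignment(
                query_name=cols[0],
                query_len=int(cols[1]),
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                strand=cols[4],
                target_name=cols[5],
                target_len=int(cols[6]),
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                n_matches=int(cols[9]),
                aln_len=int(cols[10]),
                mapq=int(cols[11]),
                is_primary=_is_primary(cols[12:]),
            )
        except ValueError as exc:
            result.errors.append((line_no, f"bad field: {exc}"))
            continue
        reason = _validate_alignment(aln)
        if reason is not None:
            result.errors.append((line_no, reason))
            continue
        result.alignments.append(aln)
    return result


def _is_primary(tags: Sequence[str]) -> bool:
    for tag in tags:
        if tag.startswith("tp:A:"):
            return tag[5:] == "P"
    return True


def _validate_alignment(aln: PafAlignment) -> Optional[str]:
    if aln.strand not in "+-":
        return f"bad strand {aln.strand!r}"
    if not (0 <= aln.query_start < aln.query_end <= aln.query_len):
        return "query coordinates inverted or out of range"
    if not (0 <= aln.target_start < aln.target_end <= aln.target_len):
        return "target coordinates inverted or out of range"
    if not (0 <= aln.mapq <= 60):
        return f"mapq out of range: {aln.mapq}"
    if aln.n_matches > aln.aln_len:
        return "n_matches exceeds alignment length"
    return None


@dataclass
class FlankPair:
    """All alignments of one QTL's two flanks, partitioned by suffix."""

    qtl_id: str
    left_hits: list[PafAlignment] = field(default_factory=list)
    right_hits: list[PafAlignment] = field(default_factory=list)
    flank_len_bp: int = 1000


def pair_flanks(
    alignments: Iterable[PafAlignment], flank_len_bp: int = 1000
) -> dict[str, FlankPair]:
    """Group flank alignments per QTL by the ``__L`` / ``__R`` suffix.

    Queries without a recognised suffix are ignored (they cannot belong to a
    flank pair).
    """
    pairs: dict[str, FlankPair] = {}
    for aln in alignments:
        q = aln.query_name
        if q.endswith(LEFT_SUFFIX):
            qtl_id, side = q[: -len(LEFT_SUFFIX)], "L"
        elif q.endswith(RIGHT_SUFFIX):
            qtl_id, side = q[: -len(RIGHT_SUFFIX)], "R"
        else:
            continue
        pair = pairs.setdefault(qtl_id, FlankPair(qtl_id=qtl_id, flank_len_bp=flank_len_bp))
        (pair.left_hits if side == "L" else pair.right_hits).append(aln)
    return pairs


def select_best_hit(hits: Sequence[PafAlignment]) -> Optional[PafAlignment]:
    """Deterministic best-alignment policy.

    Primary hits beat secondary; then highest mapq, longest alignment, and
    finally lowest (target_name, target_start).  Returns None on empty input.
    """
    if not hits:
        return None
    return min(
        hits,
        key=lambda a: (not a.is_primary, -a.mapq, -a.aln_len, a.target_name, a.target_start),
    )


@dataclass
class ProjectedQTL:
    """A QTL lifted to physical coordinates, or a recorded projection failure."""

    qtl_id: str
    trait_code: str
    status: ProjectionStatus
    chrom: Optional[str] = None
    start_bp: Optional[int] = None
    end_bp: Optional[int] = None
    renamed_id: str = ""
    left_hit: Optional[PafAlignment] = None
    right_hit: Optional[PafAlignment] = None

    @property
    def length_bp(self) -> Optional[int]:
        if self.start_bp is None or self.end_bp is None:
            return None
        return self.end_bp - self.start_bp

    @property
    def midpoint_bp(self) -> Optional[float]:
        if self.start_bp is None or self.end_bp is None:
            return None
        return (self.start_bp + self.end_bp) / 2

    @property
    def is_retained(self) -> bool:
        return self.status is ProjectionStatus.PROJECTED


def project_interval(
    pair: FlankPair, chroms: ChromosomeTable, trait_code: str = ""
) -> ProjectedQTL:
    """Project one QTL interval from its best left/right flank alignments.

    Failure taxonomy: a missing flank, flanks on different chromosomes, and
    discordant strands or an empty interval after strand normalization each
    map to a distinct status so projection-rate summaries can be broken down
    by reason.
    """
    left = select_best_hit(pair.left_hits)
    right = select_best_hit(pair.right_hits)
    base = dict(qtl_id=pair.qtl_id, trait_code=trait_code, left_hit=left, right_hit=right)
    if left is None or right is None:
        return ProjectedQTL(status=ProjectionStatus.FAILED_FLANK_MISSING, **base)
    if left.target_name != right.target_name:
        return ProjectedQTL(status=ProjectionStatus.FAILED_CROSS_CHROM, **base)
    chrom = left.target_name
    chrom_len = chroms[chrom]  # raises ChromTableError if unknown
    if left.strand != right.strand:
        return ProjectedQTL(status=ProjectionStatus.FAILED_ORIENTATION, **base)
    # Inner edges face the QTL.  The genomically smaller hit plays the
    # outer-left role (a '-'-strand locus arrives with the flank roles
    # swapped), so after ordering the hits by position the interval runs from
    # the first hit's end to the second hit's start.
    first, second = sorted((left, right), key=lambda a: (a.target_start, a.target_end))
    start, end = first.target_end, second.target_start
    if start >= end:
        return ProjectedQTL(status=ProjectionStatus.FAILED_ORIENTATION, **base)
    start = max(0, start)
    end = min(chrom_len, end)
    if start >= end:
        return ProjectedQTL(status=ProjectionStatus.FAILED_ORIENTATION, **base)
    return ProjectedQTL(
        status=ProjectionStatus.PROJECTED, chrom=chrom, start_bp=start, end_bp=end, **base
    )


def project_all(
    qtl_records: Sequence[QTLRecord],
    alignments: Iterable[PafAlignment],
    chroms: ChromosomeTable,
    flank_len_bp: int = 1000,
) -> list[ProjectedQTL]:
    """Project every QTL; records with no flank alignments fail explicitly.

    The result has exactly one entry per input record, in input order.
    """
    pairs = pair_flanks(alignments, flank_len_bp=flank_len_bp)
    out = []
    for rec in qtl_records:
        pair = pairs.get(rec.qtl_id)
        if pair is None:
            out.append(
                ProjectedQTL(
                    qtl_id=rec.qtl_id,
                    trait_code=rec.trait_code,
                    status=ProjectionStatus.FAILED_FLANK_MISSING,
                )
            )
        else:
            out.append(project_interval(pair, chroms, trait_code=rec.trait_code))
    return out


def quarter_filter(
    records: Sequence[ProjectedQTL], chroms: ChromosomeTable
) -> list[ProjectedQTL]:
    """Flag projected intervals strictly larger than a quarter chromosome.

    Coordinates are never changed, only status; an interval of exactly one
    quarter is retained (strict "larger than").  Idempotent.
    """
    out = []
    for rec in records:
        if rec.status is ProjectionStatus.PROJECTED and rec.length_bp > chroms[rec.chrom] / 4:
            out.append(dataclasses.replace(rec, status=ProjectionStatus.EXCLUDED_QUARTER_FILTER))
        else:
            out.append(rec)
    return out


def chrom_number(chrom: str) -> str:
    """Trailing number of a chromosome name without zero padding ('chr08' -> '8')."""
    m = re.search(r"(\d+)$", chrom)
    return str(int(m.group(1))) if m else chrom


def overlap_components(
    intervals: Sequence[tuple[str, int, int]]
) -> list[list[str]]:
    """Single-linkage components of half-open intervals under intersection.

    ``intervals`` is a list of ``(id, start, end)``.  Touching intervals
    ([a,b) and [b,c)) do not intersect.  Output components are sorted by
    (min start, min end) and member ids are sorted within each component, so
    the result is invariant to input order.
    """
    items = sorted(intervals, key=lambda t: (t[1], t[2], t[0]))
    components: list[tuple[int, int, list[str]]] = []
    for id_, start, end in items:
        if components and start < components[-1][1]:
            cstart, cend, members = components[-1]
            components[-1] = (cstart, max(cend, end), members + [id_])
        else:
            components.append((start, end, [id_]))
    return [sorted(members) for _, _, members in components]


def rename_qtls(records: Sequence[ProjectedQTL]) -> list[ProjectedQTL]:
    """Assign positional names ``<trait><chrom#>.<rank>`` to retained QTLs.

    Within each (trait, chromosome), overlapping same-trait intervals form one
    locus (single linkage) and share one name; loci are ranked by ascending
    start.  Deterministic and invariant to input order.
    """
    by_group: dict[tuple[str, str], list[ProjectedQTL]] = {}
    for rec in records:
        if rec.status is ProjectionStatus.PROJECTED:
            by_group.setdefault((rec.trait_code, rec.chrom), []).append(rec)
    name_of: dict[str, str] = {}
    for (trait, chrom), members in by_group.items():
        comps = overlap_components([(m.qtl_id, m.start_bp, m.end_bp) for m in members])
        for rank, comp in enumerate(comps, start=1):
            name = f"{trait}{chrom_number(chrom)}.{rank}"
            for qtl_id in comp:
                name_of[qtl_id] = name
    return [
        dataclasses.replace(rec, renamed_id=name_of[rec.qtl_id])
        if rec.qtl_id in name_of
        else rec
        for rec in records
    ]


def status_counts(records: Iterable[ProjectedQTL]) -> dict[str, int]:
    counts: dict[str, int] = {s.value: 0 for s in ProjectionStatus}
    for rec in records:
        counts[rec.status.value] += 1
    return counts
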
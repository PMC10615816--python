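"""Landscape summaries of projected QTLs.

Per-chromosome counts and LOD/PVE means, hotspot (cluster) detection,
same-trait overlap grouping across studies, and cross-trait co-localization.
All operations take the retained projected records plus the original metadata
records for LOD/PVE/study lookups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .projection import ProjectedQTL, chrom_number, overlap_components
from .qtl_io import ChromosomeTable, QTLRecord

__all__ = [
    "ClusterRegion",
    "OverlapGroup",
    "ColocGroup",
    "chromosome_summary",
    "detect_clusters",
    "group_overlaps",
    "detect_colocalizations",
]

CLUSTER_WINDOW_BP = 5_000_000
CLUSTER_MIN_COUNT = 6  # "more than five"


@dataclass(frozen=True)
class ClusterRegion:
    """A hotspot: a window (<= 5 Mb before merging) holding > 5 QTL midpoints."""

    chrom: str
    window_start_bp: int
    window_end_bp: int
    member_ids: tuple[str, ...]
    trait_codes: frozenset[str]

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class OverlapGroup:
    """One same-trait locus supported by intersecting intervals from >=2 studies."""

    group_id: str
    trait_code: str
    chrom: str
    member_ids: tuple[str, ...]
    n_studies: int
    merged_start_bp: int
    merged_end_bp: int


@dataclass(frozen=True)
class ColocGroup:
    """Distinct-trait intervals sharing a nonempty common intersection."""

    chrom: str
    member_ids: tuple[str, ...]
    trait_codes: frozenset[str]
    intersection_start_bp: int
    intersection_end_bp: int


def _retained(records: Sequence[ProjectedQTL]) -> list[ProjectedQTL]:
    return [r for r in records if r.is_retained]


def chromosome_summary(
    records: Sequence[ProjectedQTL],
    qtl_by_id: Mapping[str, QTLRecord],
    chroms: Optional[ChromosomeTable] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome counts and LOD/PVE means over non-missing values.

    Returns the per-chromosome table (count, mean_pve, n_pve, mean_lod,
    n_lod; NaN means on empty denominators) and the same statistics computed
    globally, with denominators reported.
    """
    retained = _retained(records)
    rows: dict[str, dict] = {}
    if chroms is not None:
        for name in chroms.names:
            rows[name] = {"count": 0, "pve": [], "lod": []}
    for rec in retained:
        row = rows.setdefault(rec.chrom, {"count": 0, "pve": [], "lod": []})
        row["count"] += 1
        qtl = qtl_by_id[rec.qtl_id]
        if qtl.pve_percent is not None:
            row["pve"].append(qtl.pve_percent)
        if qtl.lod is not None:
            row["lod"].append(qtl.lod)

    def _mean(vals: list) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    table = pd.DataFrame(
        {
            "chrom": list(rows),
            "count": [r["count"] for r in rows.values()],
            "mean_pve": [_mean(r["pve"]) for r in rows.values()],
            "n_pve": [len(r["pve"]) for r in rows.values()],
            "mean_lod": [_mean(r["lod"]) for r in rows.values()],
            "n_lod": [len(r["lod"]) for r in rows.values()],
        }
    ).set_index("chrom")
    all_pve = [v for r in rows.values() for v in r["pve"]]
    all_lod = [v for r in rows.values() for v in r["lod"]]
    overall = {
        "count": len(retained),
        "mean_pve": _mean(all_pve),
        "n_pve": len(all_pve),
        "mean_lod": _mean(all_lod),
        "n_lod": len(all_lod),
    }
    return table, overall


def detect_clusters(
    records: Sequence[ProjectedQTL],
    window_bp: int = CLUSTER_WINDOW_BP,
    min_count: int = CLUSTER_MIN_COUNT,
) -> list[ClusterRegion]:
    """Find hotspot regions: windows of span <= ``window_bp`` holding
    >= ``min_count`` interval midpoints.

    Per chromosome the midpoints are sorted; every maximal run whose span fits
    the window seeds a candidate, and overlapping candidates merge into one
    region trimmed to its member extremes.  Output is sorted by (chromosome,
    start).
    """
    by_chrom: dict[str, list[ProjectedQTL]] = {}
    for rec in _retained(records):
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out: list[ClusterRegion] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda r: (r.midpoint_bp, r.qtl_id))
        mids = [r.midpoint_bp for r in members]
        n = len(mids)
        # candidate [mid[i], mid[j]] spans for maximal in-window runs
        candidates: list[tuple[float, float]] = []
        j = 0
        for i in range(n):
            j = max(j, i)
            while j + 1 < n and mids[j + 1] - mids[i] <= window_bp:
                j += 1
            if j - i + 1 >= min_count:
                candidates.append((mids[i], mids[j]))
        for lo, hi in _merge_spans(candidates):
            ids = tuple(r.qtl_id for r in members if lo <= r.midpoint_bp <= hi)
            traits = frozenset(r.trait_code for r in members if lo <= r.midpoint_bp <= hi)
            out.append(
                ClusterRegion(
                    chrom=chrom,
                    window_start_bp=int(lo),
                    window_end_bp=int(hi) + 1,
                    member_ids=ids,
                    trait_codes=traits,
                )
            )
    return out


def _merge_spans(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping/touching closed spans; input assumed start-sorted."""
    merged: list[list[float]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def group_overlaps(
    records: Sequence[ProjectedQTL],
    qtl_by_id: Mapping[str, QTLRecord],
) -> list[OverlapGroup]:
    """Same-trait loci replicated across studies.

    Within each (trait, chromosome) the intervals are grouped by single
    linkage under intersection; a group counts as an overlapped locus only
    when its members come from at least two distinct studies.  The merged
    extent is the union of member intervals.  Group ids reuse the positional
    naming scheme (``<trait><chrom#>.<rank>`` over all loci of that trait and
    chromosome), so they agree with renamed ids.
    """
    by_group: dict[tuple[str, str], list[ProjectedQTL]] = {}
    for rec in _retained(records):
        by_group.setdefault((rec.trait_code, rec.chrom), []).append(rec)
    out: list[OverlapGroup] = []
    for trait, chrom in sorted(by_group):
        members = by_group[(trait, chrom)]
        pos = {m.qtl_id: m for m in members}
        comps = overlap_components([(m.qtl_id, m.start_bp, m.end_bp) for m in members])
        for rank, comp in enumerate(comps, start=1):
            studies = {qtl_by_id[i].study_ref for i in comp}
            if len(studies) < 2:
                continue
            out.append(
                OverlapGroup(
                    group_id=f"{trait}{chrom_number(chrom)}.{rank}",
                    trait_code=trait,
                    chrom=chrom,
                    member_ids=tuple(comp),
                    n_studies=len(studies),
                    merged_start_bp=min(pos[i].start_bp for i in comp),
                    merged_end_bp=max(pos[i].end_bp for i in comp),
                )
            )
    return out


def detect_colocalizations(records: Sequence[ProjectedQTL]) -> list[ColocGroup]:
    """Maximal groups of intervals sharing a common point, spanning >=2 traits.

    Intersection semantics: a group is kept only while the common intersection
    of all members stays nonempty, and only inclusion-maximal groups are
    emitted (a chain A-B, B-C with empty A-and-C intersection yields two
    groups).  The reported interval is the common intersection.
    """
    by_chrom: dict[str, list[ProjectedQTL]] = {}
    for rec in _retained(records):
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out: list[ColocGroup] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda r: (r.start_bp, r.end_bp, r.qtl_id))
        # Any maximal common-point group is realised at some interval start.
        cand_sets: list[frozenset[str]] = []
        for rec in members:
            p = rec.start_bp
            covering = frozenset(
                m.qtl_id for m in members if m.start_bp <= p < m.end_bp
            )
            traits = {m.trait_code for m in members if m.qtl_id in covering}
            if len(covering) >= 2 and len(traits) >= 2:
                cand_sets.append(covering)
        maximal = _maximal_sets(cand_sets)
        pos = {m.qtl_id: m for m in members}
        groups = []
        for ids in maximal:
            start = max(pos[i].start_bp for i in ids)
            end = min(pos[i].end_bp for i in ids)
            groups.append(
                ColocGroup(
                    chrom=chrom,
                    member_ids=tuple(sorted(ids)),
                    trait_codes=frozenset(pos[i].trait_code for i in ids),
                    intersection_start_bp=start,
                    intersection_end_bp=end,
                )
            )
        out.extend(sorted(groups, key=lambda g: (g.intersection_start_bp, g.member_ids)))
    return out


def _maximal_sets(sets: list[frozenset]) -> list[frozenset]:
    uniq = sorted(set(sets), key=lambda s: (-len(s), sorted(s)))
    kept: list[frozenset] = []
    for s in uniq:
        if not any(s < k for k in kept):
            kept.append(s)
    return kept
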
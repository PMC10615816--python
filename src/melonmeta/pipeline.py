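"""Compose projection -> atlas -> consensus into one reproducible run.

A single config drives everything; the effective config is written into the
run directory, all tabular outputs are deterministic (sorted, no timestamps),
and the log carries the stage-level count ledger:
collected = projected + failed(all reasons); projected = retained + excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .atlas import (
    chromosome_summary,
    detect_clusters,
    detect_colocalizations,
    group_overlaps,
)
from .metaqtl import MetaConfig, run_metaqtl
from .projection import (
    ProjectionStatus,
    parse_paf,
    project_all,
    quarter_filter,
    rename_qtls,
    status_counts,
)
from .qtl_io import (
    read_chrom_table,
    read_qtl_table,
    write_projected_bed,
)

logger = logging.getLogger("melonmeta")

__all__ = ["RunConfig", "RunResult", "run_all", "write_report"]


class RunConfig(BaseModel):
    """Validated run parameters; round-trips losslessly through YAML."""

    qtl_table: str
    paf: str
    fai: str
    outdir: str
    flank_len: int = Field(default=1000, gt=0)
    quarter_filter: bool = True
    cluster_window: int = Field(default=5_000_000, gt=0)
    cluster_min_count: int = Field(default=6, ge=1)
    k_max: int = Field(default=5, ge=1)
    min_members: int = Field(default=2, ge=1)
    sd_min: float = Field(default=0.01, gt=0)
    seed: int = 17
    version: str = __version__

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class RunResult:
    outdir: Path
    counts: dict
    projected: list
    mqtls: list


def run_all(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and write every artifact under ``outdir``."""
    for key in ("qtl_table", "paf", "fai"):
        path = getattr(config, key)
        if not Path(path).is_file():
            raise FileNotFoundError(f"{key} not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())

    ingest = read_qtl_table(config.qtl_table)
    chroms = read_chrom_table(config.fai)
    paf = parse_paf(config.paf)
    logger.info(
        "ingest: %d accepted, %d rejected; paf: %d alignments, %d bad lines",
        len(ingest.records), len(ingest.rejected), len(paf.alignments), len(paf.errors),
    )

    projected = project_all(ingest.records, paf.alignments, chroms, config.flank_len)
    if config.quarter_filter:
        projected = quarter_filter(projected, chroms)
    projected = rename_qtls(projected)
    counts = status_counts(projected)
    counts["collected"] = len(ingest.records)
    counts["rejected_rows"] = len(ingest.rejected)
    retained = [r for r in projected if r.is_retained]
    qtl_by_id = {r.qtl_id: r for r in ingest.records}
    logger.info("projection: %s", counts)

    lod_by_id = {r.qtl_id: r.lod for r in ingest.records if r.lod is not None}
    with_coords = [
        r
        for r in projected
        if r.status in (ProjectionStatus.PROJECTED, ProjectionStatus.EXCLUDED_QUARTER_FILTER)
    ]
    write_projected_bed(with_coords, outdir / "projected.bed", chroms, lod_by_id)
    _write_status_tsv(projected, outdir / "status.tsv")

    summary, overall = chromosome_summary(retained, qtl_by_id, chroms)
    summary.to_csv(outdir / "summary.tsv", sep="\t", float_format="%.6g", na_rep="NA")
    clusters = detect_clusters(retained, config.cluster_window, config.cluster_min_count)
    _write_clusters_tsv(clusters, outdir / "clusters.tsv")
    overlaps = group_overlaps(retained, qtl_by_id)
    _write_overlaps_tsv(overlaps, outdir / "overlaps.tsv")
    colocs = detect_colocalizations(retained)
    _write_colocs_tsv(colocs, outdir / "colocalizations.tsv")

    meta_cfg = MetaConfig(
        k_max=config.k_max,
        min_members=config.min_members,
        sd_min_mb=config.sd_min,
        seed=config.seed,
    )
    mqtls, models = run_metaqtl(projected, qtl_by_id, chroms, meta_cfg)
    _write_mqtl_tsv(mqtls, models, outdir / "mqtl.tsv")
    _write_members_tsv(mqtls, outdir / "members.tsv")

    counts.update(
        {
            "retained": len(retained),
            "clusters": len(clusters),
            "overlap_groups": len(overlaps),
            "colocalizations": len(colocs),
            "mqtls": len(mqtls),
        }
    )
    write_report(counts, overall, outdir / "report.md")
    (outdir / "run_log.txt").write_text(
        "".join(f"{k}\t{v}\n" for k, v in sorted(counts.items()))
    )
    return RunResult(outdir=outdir, counts=counts, projected=projected, mqtls=mqtls)


def _write_status_tsv(projected, path) -> None:
    with open(path, "w") as fh:
        fh.write("qtl_id\ttrait_code\tstatus\tchrom\tstart_bp\tend_bp\trenamed_id\n")
        for r in projected:
            fh.write(
                f"{r.qtl_id}\t{r.trait_code}\t{r.status.value}\t"
                f"{r.chrom or ''}\t{'' if r.start_bp is None else r.start_bp}\t"
                f"{'' if r.end_bp is None else r.end_bp}\t{r.renamed_id}\n"
            )


def _write_clusters_tsv(clusters, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start_bp\twindow_end_bp\tn_members\ttraits\tmember_ids\n")
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.window_start_bp}\t{c.window_end_bp}\t{c.n_members}\t"
                f"{','.join(sorted(c.trait_codes))}\t{','.join(c.member_ids)}\n"
            )


def _write_overlaps_tsv(overlaps, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "group_id\ttrait_code\tchrom\tn_members\tn_studies\t"
            "merged_start_bp\tmerged_end_bp\tmember_ids\n"
        )
        for g in overlaps:
            fh.write(
                f"{g.group_id}\t{g.trait_code}\t{g.chrom}\t{len(g.member_ids)}\t"
                f"{g.n_studies}\t{g.merged_start_bp}\t{g.merged_end_bp}\t"
                f"{','.join(g.member_ids)}\n"
            )


def _write_colocs_tsv(colocs, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tintersection_start_bp\tintersection_end_bp\ttraits\tmember_ids\n")
        for g in colocs:
            fh.write(
                f"{g.chrom}\t{g.intersection_start_bp}\t{g.intersection_end_bp}\t"
                f"{','.join(sorted(g.trait_codes))}\t{','.join(g.member_ids)}\n"
            )


def _write_mqtl_tsv(mqtls, models, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mqtl_id\ttrait_code\tchrom\tn_members\tconsensus_position_mb\t"
            "consensus_sd_mb\tci95_start_mb\tci95_end_mb\tmodel_K\tmodel_aic\t"
            "singleton\taic_trace\n"
        )
        for m in mqtls:
            trace = models[(m.trait_code, m.chrom)].aic_trace
            trace_str = ";".join(f"K{k}:{a:.4f}" for k, a in trace)
            fh.write(
                f"{m.mqtl_id}\t{m.trait_code}\t{m.chrom}\t{len(m.member_ids)}\t"
                f"{m.consensus_position:.6f}\t{m.consensus_sd:.6f}\t"
                f"{m.ci95_start:.6f}\t{m.ci95_end:.6f}\t{m.model_K}\t"
                f"{m.model_aic:.6f}\t{int(m.singleton)}\t{trace_str}\n"
            )


def _write_members_tsv(mqtls, path) -> None:
    with open(path, "w") as fh:
        fh.write("mqtl_id\tqtl_id\n")
        for m in mqtls:
            for qtl_id in m.member_ids:
                fh.write(f"{m.mqtl_id}\t{qtl_id}\n")


def write_report(counts: dict, overall: dict, path) -> None:
    """Human-readable digest; every number also appears in a TSV output."""
    failed = (
        counts.get("failed_flank_missing", 0)
        + counts.get("failed_cross_chrom", 0)
        + counts.get("failed_orientation", 0)
    )
    lines = [
        "# Run summary",
        "",
        f"- QTLs collected: {counts.get('collected', 0)}",
        f"- projected: {counts.get('projected', 0) + counts.get('excluded_quarter_filter', 0)}",
        f"- failed projection: {failed}",
        f"- retained after quarter filter: {counts.get('retained', 0)}",
        f"- excluded by quarter filter: {counts.get('excluded_quarter_filter', 0)}",
        f"- mean PVE (n={overall.get('n_pve', 0)}): {overall.get('mean_pve', float('nan')):.2f}",
        f"- mean LOD (n={overall.get('n_lod', 0)}): {overall.get('mean_lod', float('nan')):.2f}",
        f"- cluster regions: {counts.get('clusters', 0)}",
        f"- overlapped same-trait loci: {counts.get('overlap_groups', 0)}",
        f"- cross-trait co-localizations: {counts.get('colocalizations', 0)}",
        f"- meta-QTLs: {counts.get('mqtls', 0)}",
        "",
    ]
    Path(path).write_text("\n".join(lines))
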
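"""Ground-truthed synthetic inputs for the full projection -> consensus chain.

Generates a toy assembly (index only, no bases), true consensus loci,
multi-study QTL tables with the statistical structure the mixture model
assumes, matching PAF flank placements, and recovery scoring of the emitted
meta-QTLs against the truth.

Noise model per simulated study x locus: the observed peak scatters normally
around the true position; the genetic CI width follows the classic
``c / (N * PVE%)`` population-size approximation (c = 530 by default) unless a
uniform physical width range is configured; LOD uses the standard
``-(N/2) log10(1 - pve)`` identity.  When no explicit positional noise sd is
configured, each observation's noise sd equals its own CI-implied sd, so the
generated data match the known-variance mixture assumption exactly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .metaqtl import MetaQTL, ci_to_sd
from .qtl_io import ChromosomeTable, QTLRecord

__all__ = [
    "TraitSpec",
    "StudyPlan",
    "SimConfig",
    "SyntheticLocus",
    "SyntheticTruth",
    "RecoveryReport",
    "simulate_truth",
    "simulate_studies",
    "emit_synthetic_paf",
    "score_recovery",
]

DEFAULT_CI_CONSTANT = 530.0  # backcross-style CI-width approximation constant
DEFAULT_BP_PER_CM = 250_000.0


@dataclass(frozen=True)
class TraitSpec:
    trait_code: str
    chrom: str
    n_loci: int
    trait_group: str = "fruit"


@dataclass(frozen=True)
class StudyPlan:
    study_ref: str
    pop_type: str
    pop_size: int
    detect_prob: float
    #: explicit positional noise sd; None = calibrated to each CI's own sd
    position_noise_sd_bp: Optional[float] = None


@dataclass
class SimConfig:
    """Knobs for the generator; defaults give a plausible 12-chromosome run."""

    n_chromosomes: int = 12
    chrom_length_range_bp: tuple[int, int] = (25_000_000, 40_000_000)
    chrom_lengths: Optional[dict[str, int]] = None  # overrides the range
    trait_specs: tuple[TraitSpec, ...] = (
        TraitSpec("FSI", "chr08", 2),
        TraitSpec("FW", "chr02", 1),
    )
    n_studies: int = 10
    pop_size_range: tuple[int, int] = (80, 250)
    pve_range: tuple[float, float] = (0.05, 0.30)  # fractions
    pve_jitter_sd: float = 0.1  # multiplicative log-normal jitter per study
    detect_prob: float = 1.0
    position_noise_sd_bp: Optional[float] = None  # None = calibrated
    min_separation_bp: int = 8_000_000
    edge_margin_bp: int = 3_000_000
    ci_constant_c: float = DEFAULT_CI_CONSTANT
    bp_per_cm: float = DEFAULT_BP_PER_CM
    #: None = formula widths; else draw physical CI widths uniform in this Mb range
    ci_width_range_mb: Optional[tuple[float, float]] = None
    flank_len_bp: int = 1000


@dataclass(frozen=True)
class SyntheticLocus:
    trait_code: str
    chrom: str
    position_bp: int
    effect_pve: float  # fraction in (0, 1)


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and score one synthetic run."""

    chrom_lengths: dict[str, int]
    true_loci: list[SyntheticLocus]
    study_plan: list[StudyPlan]
    seed: int
    config: SimConfig

    def chrom_table(self) -> ChromosomeTable:
        return ChromosomeTable(entries=dict(self.chrom_lengths))

    def to_json(self) -> str:
        payload = {
            "chrom_lengths": self.chrom_lengths,
            "true_loci": [dataclasses.asdict(l) for l in self.true_loci],
            "study_plan": [dataclasses.asdict(s) for s in self.study_plan],
            "seed": self.seed,
            "config": _config_dict(self.config),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        cfg = d["config"]
        cfg["trait_specs"] = tuple(TraitSpec(**t) for t in cfg["trait_specs"])
        for k in ("chrom_length_range_bp", "pop_size_range", "pve_range"):
            cfg[k] = tuple(cfg[k])
        if cfg.get("ci_width_range_mb") is not None:
            cfg["ci_width_range_mb"] = tuple(cfg["ci_width_range_mb"])
        return cls(
            chrom_lengths=dict(d["chrom_lengths"]),
            true_loci=[SyntheticLocus(**l) for l in d["true_loci"]],
            study_plan=[StudyPlan(**s) for s in d["study_plan"]],
            seed=d["seed"],
            config=SimConfig(**cfg),
        )


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["trait_specs"] = [dataclasses.asdict(t) for t in config.trait_specs]
    return d


def _study_rng(seed: int, study_ref: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(study_ref.encode())])


def simulate_truth(config: SimConfig, seed: int) -> SyntheticTruth:
    """Draw chromosome lengths, true loci, and a study plan; deterministic per seed.

    Loci of one trait on one chromosome are kept at least
    ``min_separation_bp`` apart (rejection sampling) so the planted K is
    identifiable; an infeasible request raises immediately.
    """
    rng = np.random.default_rng([seed, 0])
    if config.chrom_lengths is not None:
        lengths = dict(config.chrom_lengths)
    else:
        lo, hi = config.chrom_length_range_bp
        lengths = {
            f"chr{i + 1:02d}": int(rng.integers(lo, hi + 1))
            for i in range(config.n_chromosomes)
        }
    loci: list[SyntheticLocus] = []
    for spec in config.trait_specs:
        if spec.chrom not in lengths:
            raise ValueError(f"trait {spec.trait_code}: unknown chromosome {spec.chrom}")
        L = lengths[spec.chrom]
        usable = L - 2 * config.edge_margin_bp
        if usable <= 0 or (spec.n_loci - 1) * config.min_separation_bp > usable:
            raise ValueError(
                f"cannot place {spec.n_loci} loci {config.min_separation_bp} bp apart "
                f"on {spec.chrom} ({L} bp)"
            )
        positions = _place_separated(
            rng, spec.n_loci, config.edge_margin_bp, L - config.edge_margin_bp,
            config.min_separation_bp,
        )
        pve_lo, pve_hi = config.pve_range
        for pos in positions:
            loci.append(
                SyntheticLocus(
                    trait_code=spec.trait_code,
                    chrom=spec.chrom,
                    position_bp=int(pos),
                    effect_pve=float(rng.uniform(pve_lo, pve_hi)),
                )
            )
    plan = []
    pop_types = ("F2", "RIL", "DH", "BC")
    for i in range(config.n_studies):
        plan.append(
            StudyPlan(
                study_ref=f"study{i + 1:02d}",
                pop_type=pop_types[int(rng.integers(0, len(pop_types)))],
                pop_size=int(rng.integers(*config.pop_size_range)),
                detect_prob=config.detect_prob,
                position_noise_sd_bp=config.position_noise_sd_bp,
            )
        )
    return SyntheticTruth(
        chrom_lengths=lengths, true_loci=loci, study_plan=plan, seed=seed, config=config
    )


def _place_separated(
    rng: np.random.Generator, n: int, lo: int, hi: int, min_sep: int, max_tries: int = 20_000
) -> list[int]:
    for _ in range(max_tries):
        pos = sorted(int(p) for p in rng.uniform(lo, hi, size=n))
        if all(b - a >= min_sep for a, b in zip(pos, pos[1:])):
            return pos
    raise ValueError("could not satisfy minimum separation (region too crowded)")


def simulate_studies(truth: SyntheticTruth, seed: int) -> list[QTLRecord]:
    """Emit one QTL table row per detected study x locus combination.

    Genetic coordinates are the physical coordinates divided by the global
    cM<->bp rate, so the table and the PAF flank placements describe the same
    intervals.  Each study draws from its own sub-stream (stable hash of the
    study name), so adding a study never perturbs the others.
    """
    cfg = truth.config
    records: list[QTLRecord] = []
    trait_groups = {t.trait_code: t.trait_group for t in cfg.trait_specs}
    for study in truth.study_plan:
        rng = _study_rng(seed, study.study_ref)
        for i, locus in enumerate(truth.true_loci):
            if rng.uniform() >= study.detect_prob:
                continue
            L = truth.chrom_lengths[locus.chrom]
            pve = locus.effect_pve
            if cfg.pve_jitter_sd > 0:
                pve = float(np.clip(pve * np.exp(rng.normal(0.0, cfg.pve_jitter_sd)), 1e-3, 0.95))
            pve_percent = 100.0 * pve
            if cfg.ci_width_range_mb is not None:
                width_bp = rng.uniform(*cfg.ci_width_range_mb) * 1e6
            else:
                width_cm = cfg.ci_constant_c / (study.pop_size * pve_percent)
                width_bp = width_cm * cfg.bp_per_cm
            width_bp = float(min(width_bp, L - 2.0 * (cfg.flank_len_bp + 1)))
            claimed_sd_bp = width_bp / (2.0 * 1.96)
            noise_sd = (
                study.position_noise_sd_bp
                if study.position_noise_sd_bp is not None
                else claimed_sd_bp
            )
            peak = locus.position_bp + rng.normal(0.0, noise_sd) if noise_sd > 0 else float(
                locus.position_bp
            )
            half = width_bp / 2.0
            margin = cfg.flank_len_bp + 1
            peak = float(np.clip(peak, half + margin, L - half - margin))
            start_bp = int(round(peak - half))
            end_bp = int(round(peak + half))
            lod = -(study.pop_size / 2.0) * np.log10(1.0 - pve)
            records.append(
                QTLRecord(
                    qtl_id=f"{study.study_ref}_{locus.trait_code}_{locus.chrom}_{i}",
                    study_ref=study.study_ref,
                    trait_code=locus.trait_code,
                    trait_group=trait_groups.get(locus.trait_code, "fruit"),
                    linkage_group=locus.chrom,
                    peak_cM=peak / cfg.bp_per_cm,
                    ci_start_cM=start_bp / cfg.bp_per_cm,
                    ci_end_cM=end_bp / cfg.bp_per_cm,
                    lod=float(lod),
                    pve_percent=pve_percent,
                    pop_type=study.pop_type,
                    pop_size=study.pop_size,
                    parents="simP1 x simP2",
                    source_genome="sim_ref_v1",
                )
            )
    return records


def emit_synthetic_paf(
    truth: SyntheticTruth,
    records: Sequence[QTLRecord],
    flank_len: int = 1000,
    drop_right_flank: frozenset[str] | set[str] = frozenset(),
    cross_chrom: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[str], list[str]]:
    """Emit two primary PAF records per QTL, exactly flanking its interval.

    Corruption modes for failure-path testing: ``drop_right_flank`` omits the
    right flank of the named QTLs; ``cross_chrom`` sends their right flank to
    the next chromosome.  Returns (paf_lines, skipped_qtl_ids); a QTL whose
    interval leaves no room for a flank is skipped with a warning entry.
    """
    cfg = truth.config
    lines: list[str] = []
    skipped: list[str] = []
    names = list(truth.chrom_lengths)
    for rec in records:
        chrom = rec.linkage_group
        L = truth.chrom_lengths[chrom]
        start = int(round(rec.ci_start_cM * cfg.bp_per_cm))
        end = int(round(rec.ci_end_cM * cfg.bp_per_cm))
        if start - flank_len < 0 or end + flank_len > L:
            skipped.append(rec.qtl_id)
            continue
        lines.append(
            _paf_line(f"{rec.qtl_id}__L", flank_len, chrom, L, start - flank_len, start)
        )
        if rec.qtl_id in drop_right_flank:
            continue
        if rec.qtl_id in cross_chrom:
            other = names[(names.index(chrom) + 1) % len(names)]
            lines.append(
                _paf_line(
                    f"{rec.qtl_id}__R", flank_len, other, truth.chrom_lengths[other],
                    flank_len, 2 * flank_len,
                )
            )
        else:
            lines.append(
                _paf_line(f"{rec.qtl_id}__R", flank_len, chrom, L, end, end + flank_len)
            )
    return lines, skipped


def _paf_line(qname: str, flank_len: int, tname: str, tlen: int, ts: int, te: int) -> str:
    return "\t".join(
        str(v)
        for v in (
            qname, flank_len, 0, flank_len, "+", tname, tlen, ts, te,
            flank_len, flank_len, 60, "tp:A:P",
        )
    )


@dataclass
class RecoveryReport:
    """How well the emitted meta-QTLs recovered the planted truth."""

    k_true: dict[tuple[str, str], int]
    k_found: dict[tuple[str, str], int]
    position_rmse_mb: float  # NaN when nothing matched
    ci_coverage: float  # fraction of matched loci inside the MQTL ci95
    n_matched: int
    n_true_unmatched: int
    n_mqtl_unmatched: int
    matches: list[tuple[str, str, float]] = field(default_factory=list)


def score_recovery(
    truth: SyntheticTruth, mqtls: Sequence[MetaQTL], match_cap_mb: float = 2.0
) -> RecoveryReport:
    """Greedy nearest 1-to-1 matching of meta-QTLs to planted loci.

    Pairs are matched closest-first within ``match_cap_mb``; RMSE is over
    matched pairs, and coverage is the fraction of matched true loci lying
    inside the matched meta-QTL's 95% interval.  Deterministic.
    """
    true_by_group: dict[tuple[str, str], list[SyntheticLocus]] = {}
    for locus in truth.true_loci:
        true_by_group.setdefault((locus.trait_code, locus.chrom), []).append(locus)
    found_by_group: dict[tuple[str, str], list[MetaQTL]] = {}
    for m in mqtls:
        found_by_group.setdefault((m.trait_code, m.chrom), []).append(m)

    k_true = {g: len(v) for g, v in sorted(true_by_group.items())}
    k_found = {g: len(found_by_group.get(g, [])) for g in k_true}
    sq_errors: list[float] = []
    covered = 0
    matches: list[tuple[str, str, float]] = []
    n_true_unmatched = 0
    n_mqtl_unmatched = sum(
        len(v) for g, v in found_by_group.items() if g not in true_by_group
    )
    for group, loci in sorted(true_by_group.items()):
        cands = found_by_group.get(group, [])
        pairs = sorted(
            (
                (abs(m.consensus_position - locus.position_bp / 1e6), ti, mi)
                for ti, locus in enumerate(loci)
                for mi, m in enumerate(cands)
            ),
        )
        used_t: set[int] = set()
        used_m: set[int] = set()
        for dist, ti, mi in pairs:
            if dist > match_cap_mb or ti in used_t or mi in used_m:
                continue
            used_t.add(ti)
            used_m.add(mi)
            m = cands[mi]
            true_mb = loci[ti].position_bp / 1e6
            sq_errors.append((m.consensus_position - true_mb) ** 2)
            if m.ci95_start <= true_mb <= m.ci95_end:
                covered += 1
            matches.append((f"{group[0]}@{group[1]}:{loci[ti].position_bp}", m.mqtl_id, dist))
        n_true_unmatched += len(loci) - len(used_t)
        n_mqtl_unmatched += len(cands) - len(used_m)
    n_matched = len(sq_errors)
    return RecoveryReport(
        k_true=k_true,
        k_found=k_found,
        position_rmse_mb=float(np.sqrt(np.mean(sq_errors))) if sq_errors else float("nan"),
        ci_coverage=(covered / n_matched) if n_matched else 0.0,
        n_matched=n_matched,
        n_true_unmatched=n_true_unmatched,
        n_mqtl_unmatched=n_mqtl_unmatched,
        matches=matches,
    )
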
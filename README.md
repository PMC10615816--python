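# melonmeta

Integration of quantitative trait loci (QTLs) mapped in many independent
studies onto a single physical reference assembly, followed by consensus
("meta-QTL") analysis:

1. **Projection** — each QTL's genetic-map interval is located on the target
   assembly from alignments of its two 1-kb flanking sequences (PAF input,
   query names `<qtl_id>__L` / `<qtl_id>__R`). Projected intervals larger
   than a quarter of their chromosome are excluded; retained QTLs get
   positional names (`FSI8.1` = first FSI locus on chromosome 8, shared by
   all overlapping same-trait intervals).
2. **Atlas** — per-chromosome counts and mean LOD/PVE, hotspot detection
   (5-Mb windows holding more than five QTL midpoints), same-trait overlap
   grouping across studies (single linkage), and cross-trait co-localization
   (maximal groups with a nonempty common intersection).
3. **Consensus** — per trait × chromosome, observed positions are modeled as
   a K-component Gaussian mixture in which each observation keeps its own
   known variance (sd = CI width / 3.92, floored at 0.01 Mb); K is selected
   by AIC (`-2 logL + 2(2K-1)`, lowest wins, ties to smaller K); members are
   MAP-assigned and each component collapses to an inverse-variance-weighted
   consensus position with a ±1.96·sd interval.
4. **Synthetic data** — a seeded generator for genomes (index only), true
   loci, multi-study QTL tables with population-size-dependent CI widths and
   LODs, matching PAF flank placements (with corruption modes), and recovery
   scoring — so the entire pipeline is testable offline.

## CLI

```bash
# generate a ground-truthed synthetic input set
melonmeta simulate --seed 17 --out sim/

# full pipeline: project -> atlas -> consensus
melonmeta run-all --qtl-table sim/qtl_table.tsv --paf sim/flanks.paf \
                  --fai sim/genome.fai --out run/

# individual stages
melonmeta project --qtl-table T.tsv --paf A.paf --fai G.fai --out out/
melonmeta atlas   --qtl-table T.tsv --paf A.paf --fai G.fai --out out/
melonmeta meta    --qtl-table T.tsv --paf A.paf --fai G.fai --out out/ --seed 17

melonmeta report --run-dir run/
```

A run directory contains `projected.bed`, `status.tsv`, `summary.tsv`,
`clusters.tsv`, `overlaps.tsv`, `colocalizations.tsv`, `mqtl.tsv`,
`members.tsv`, `report.md`, the effective `config.yaml`, and a
`run_log.txt` count ledger (collected = projected + failed;
projected = retained + quarter-excluded). Reruns with the same config are
byte-identical.

## Input formats

- **QTL table** — TSV with header
  `qtl_id study_ref trait_code trait_group linkage_group peak_cM ci_start_cM
  ci_end_cM lod pve_percent pop_type pop_size parents source_genome`;
  optional numeric fields may be empty (averages skip them). A column-map
  option adapts third-party layouts.
- **Chromosome lengths** — the first two columns of a FASTA `.fai`.
- **Flank alignments** — standard PAF (0-based half-open); the `tp:A` tag
  marks primary alignments. Best hit per flank: primary > mapq > alignment
  length > lowest (target, start).

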
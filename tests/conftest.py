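from __future__ import annotations

import pytest

from melonmeta.projection import ProjectedQTL, ProjectionStatus
from melonmeta.qtl_io import ChromosomeTable, QTLRecord


@pytest.fixture
def chroms() -> ChromosomeTable:
    return ChromosomeTable(entries={"chrT": 40_000_000, "chrU": 30_000_000})


@pytest.fixture
def chroms12() -> ChromosomeTable:
    return ChromosomeTable(
        entries={f"chr{i:02d}": 30_000_000 + i * 1_000_000 for i in range(1, 13)}
    )


def make_proj(
    qtl_id: str,
    chrom: str = "chrT",
    start: int = 0,
    end: int = 1000,
    trait: str = "FSI",
    status: ProjectionStatus = ProjectionStatus.PROJECTED,
) -> ProjectedQTL:
    return ProjectedQTL(
        qtl_id=qtl_id,
        trait_code=trait,
        status=status,
        chrom=chrom,
        start_bp=start,
        end_bp=end,
    )


def make_qtl(
    qtl_id: str,
    study: str = "s1",
    trait: str = "FSI",
    group: str = "fruit",
    lod: float | None = 5.0,
    pve: float | None = 10.0,
    **kw,
) -> QTLRecord:
    defaults = dict(
        qtl_id=qtl_id,
        study_ref=study,
        trait_code=trait,
        trait_group=group,
        linkage_group="LG1",
        ci_start_cM=0.0,
        ci_end_cM=10.0,
        lod=lod,
        pve_percent=pve,
        pop_type="F2",
        parents="A x B",
        source_genome="ref1",
    )
    defaults.update(kw)
    return QTLRecord(**defaults)
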
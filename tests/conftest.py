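"""Shared fixtures: small deterministic genomes, record builders, and a
session-scoped default pipeline run reused by the heavier tests."""

from __future__ import annotations

import numpy as np
import pytest

from cas3audit.genome_io import AlignmentRecord
from cas3audit.pipeline import RunConfig, run_pipeline

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def make_record(
    name: str = "r",
    contig: str = "chr1",
    pos: int = 0,
    cigar: tuple[tuple[str, int], ...] = (("M", 100),),
    mapq: int = 60,
    strand: str = "+",
    paired: bool = False,
    proper: bool = False,
    unmapped: bool = False,
    secondary: bool = False,
    mate_pos: int = -1,
    tlen: int = 0,
) -> AlignmentRecord:
    return AlignmentRecord(
        query_name=name,
        contig=contig,
        pos=pos,
        cigar=cigar,
        mapq=mapq,
        strand=strand,
        is_paired=paired,
        is_proper_pair=proper,
        is_unmapped=unmapped,
        is_secondary=secondary,
        mate_contig=contig if paired else None,
        mate_pos=mate_pos,
        template_length=tlen,
    )


def make_pair(
    name: str,
    contig: str,
    left_pos: int,
    right_pos: int,
    read_len: int = 150,
    left_strand: str = "+",
    right_strand: str = "-",
) -> list[AlignmentRecord]:
    """An FR (unless overridden) read pair with the implied template length."""
    tlen = right_pos + read_len - left_pos
    common = dict(contig=contig, cigar=(("M", read_len),), paired=True)
    return [
        make_record(
            name=name, pos=left_pos, strand=left_strand,
            mate_pos=right_pos, tlen=tlen, **common,
        ),
        make_record(
            name=name, pos=right_pos, strand=right_strand,
            mate_pos=left_pos, tlen=-tlen, **common,
        ),
    ]


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full simulated pipeline run at seed 1 with all defaults."""
    outdir = tmp_path_factory.mktemp("run_seed1")
    report = run_pipeline(RunConfig(seed=1), outdir=outdir)
    return report, outdir
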
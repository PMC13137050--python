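"""Control-subtraction off-target scoring.

Cas3 mode scores each POT capture region as (treated split reads) minus
(no-crRNA control split reads); negative scores are retained for
diagnostics but never flagged. Cas9 benchmark mode computes windowed
adjusted indel percentages: the fraction of window-overlapping reads
carrying an insertion or deletion, minus the same fraction in a
no-guide control, clamped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import (
    DEFAULT_MAPQ_FLOOR,
    AlignmentRecord,
    GenomicInterval,
)
from .deletion_analysis import SplitReadEvidence
from .pot_enumeration import CaptureRegion

logger = logging.getLogger(__name__)

DEFAULT_FLAG_THRESHOLD = 5
DEFAULT_INDEL_HALFWIDTH = 20


@dataclass
class OffTargetScore:
    region: CaptureRegion
    treated_splits: int
    control_splits: int
    score: int  # treated - control; may be negative
    flagged: bool


@dataclass
class IndelQuantification:
    window: GenomicInterval
    test_covering: int
    test_edited: int
    control_covering: int
    control_edited: int
    test_indel_pct: float
    control_indel_pct: float
    adjusted_pct: float  # max(test - control, 0)


def _count_in_region(
    evidence: Sequence[SplitReadEvidence], region: GenomicInterval
) -> int:
    return sum(
        1
        for ev in evidence
        if ev.contig == region.contig and region.start <= ev.breakpoint < region.end
    )


def score_pot_sites(
    treated_evidence: Sequence[SplitReadEvidence],
    control_evidence: Sequence[SplitReadEvidence],
    capture_regions: Sequence[CaptureRegion],
    flag_threshold: int = DEFAULT_FLAG_THRESHOLD,
) -> list[OffTargetScore]:
    """One subtraction score per capture region.

    Overlapping capture regions each count the shared evidence (with a
    warning), matching per-region probe-panel accounting.
    """
    for i, a in enumerate(capture_regions):
        for b in capture_regions[i + 1 :]:
            if a.locus.overlaps(b.locus):
                logger.warning(
                    "capture regions %s and %s overlap; shared evidence is "
                    "counted in both",
                    a.locus,
                    b.locus,
                )
    out: list[OffTargetScore] = []
    for region in capture_regions:
        t = _count_in_region(treated_evidence, region.locus)
        c = _count_in_region(control_evidence, region.locus)
        score = t - c
        out.append(
            OffTargetScore(
                region=region,
                treated_splits=t,
                control_splits=c,
                score=score,
                flagged=score >= flag_threshold,
            )
        )
    return out


def _read_has_indel_in_window(
    rec: AlignmentRecord, win_start: int, win_end: int
) -> bool:
    ref = rec.pos
    for op, n in rec.cigar:
        if op == "D":
            if ref < win_end and win_start < ref + n:
                return True
            ref += n
        elif op == "M":
            ref += n
        elif op == "I":
            if win_start <= ref <= win_end:
                return True
        # S/H consume no reference
    return False


def adjusted_indel(
    test_records: Iterable[AlignmentRecord],
    control_records: Iterable[AlignmentRecord],
    cut_site: GenomicInterval,
    window_halfwidth: int = DEFAULT_INDEL_HALFWIDTH,
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
) -> IndelQuantification | None:
    """Windowed indel quantification around an expected Cas9 cut.

    A read counts as covering when its alignment overlaps the window
    [cut - halfwidth, cut + halfwidth), and as edited when any I or D
    CIGAR op falls inside it. Returns None when either sample has zero
    covering reads (the percentage is undefined).
    """
    point = cut_site.midpoint if len(cut_site) > 1 else cut_site.start
    win_start, win_end = point - window_halfwidth, point + window_halfwidth
    window = GenomicInterval(cut_site.contig, win_start, win_end)

    def tally(records: Iterable[AlignmentRecord]) -> tuple[int, int]:
        covering = edited = 0
        for rec in records:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.mapq < mapq_floor
                or rec.contig != cut_site.contig
            ):
                continue
            if rec.reference_end <= win_start or rec.pos >= win_end:
                continue
            covering += 1
            if _read_has_indel_in_window(rec, win_start, win_end):
                edited += 1
        return covering, edited

    t_cov, t_ed = tally(test_records)
    c_cov, c_ed = tally(control_records)
    if t_cov == 0 or c_cov == 0:
        logger.warning("no covering reads in window %s; indel pct undefined", window)
        return None
    t_pct = 100.0 * t_ed / t_cov
    c_pct = 100.0 * c_ed / c_cov
    return IndelQuantification(
        window=window,
        test_covering=t_cov,
        test_edited=t_ed,
        control_covering=c_cov,
        control_edited=c_ed,
        test_indel_pct=t_pct,
        control_indel_pct=c_pct,
        adjusted_pct=max(t_pct - c_pct, 0.0),
    )
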
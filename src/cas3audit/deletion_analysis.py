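"""Large-deletion calling from treated-vs-control alignment evidence.

The workflow mirrors capture-sequencing analysis of processive Cas3
degradation: soft-clip boundaries are extracted as split-read evidence and
counted in fixed-width bins across the capture region; bins where the
treated/control count ratio strictly exceeds the threshold (default 5) are
*cut points*; discordant read pairs anchored at a cut point are clustered
by their distal endpoint into individual deletion patterns; per-guide
extent summaries and neighboring-gene overlap fractions are derived from
the called patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import (
    DEFAULT_MAPQ_FLOOR,
    AlignmentRecord,
    GeneAnnotation,
    GenomicInterval,
)
from .util import percent_1dp

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLIP = 20
DEFAULT_BIN_WIDTH = 100
DEFAULT_RATIO_THRESHOLD = 5.0
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MERGE_TOL = 150


@dataclass(slots=True)
class SplitReadEvidence:
    query_name: str
    contig: str
    clip_side: str  # left | right
    breakpoint: int  # boundary between aligned and clipped segment
    clip_len: int


@dataclass(slots=True)
class DiscordantPair:
    query_name: str
    contig: str
    span: GenomicInterval  # leftmost mate end .. rightmost mate start
    template_length: int
    orientation: str  # FR | RF | FF | RR | interchrom


@dataclass
class BinCounts:
    bin: GenomicInterval
    treated_count: int
    control_count: int


@dataclass
class CutPoint:
    bin: GenomicInterval
    ratio: float
    treated_count: int

    @property
    def midpoint(self) -> int:
        return self.bin.midpoint


@dataclass
class DeletionPattern:
    del_interval: GenomicInterval
    left_bp: int
    right_bp: int
    n_supporting_pairs: int
    n_supporting_splits: int
    direction_5p_extent: int | None = None
    direction_3p_extent: int | None = None


@dataclass
class ExtentSummary:
    guide_id: str
    max_3p_extent: int
    max_5p_extent: int
    n_patterns: int


@dataclass
class GeneOverlapSummary:
    gene: str
    n_overlapping: int
    n_partial: int
    n_total: int
    fraction: float
    percent_1dp: float


def extract_split_reads(
    records: Iterable[AlignmentRecord],
    min_clip: int = DEFAULT_MIN_CLIP,
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
) -> list[SplitReadEvidence]:
    """Soft-clip boundary extraction from mapped primary records.

    One evidence item per qualifying soft clip (>= min_clip nt at either
    read end); the breakpoint is the reference coordinate at the clip
    boundary: ``pos`` for a left clip, the alignment's reference end for a
    right clip.
    """
    out: list[SplitReadEvidence] = []
    n_filtered = 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.mapq < mapq_floor:
            n_filtered += 1
            continue
        cigar = rec.cigar
        if not cigar:
            continue
        # leading hard clips precede any soft clip in a valid CIGAR
        i_first = 1 if cigar[0][0] == "H" and len(cigar) > 1 else 0
        i_last = len(cigar) - (2 if cigar[-1][0] == "H" and len(cigar) > 1 else 1)
        first, last = cigar[i_first], cigar[i_last]
        if first[0] == "S" and first[1] >= min_clip:
            out.append(
                SplitReadEvidence(
                    rec.query_name, rec.contig or "", "left", rec.pos, first[1]
                )
            )
        if last[0] == "S" and i_last != i_first and last[1] >= min_clip:
            out.append(
                SplitReadEvidence(
                    rec.query_name,
                    rec.contig or "",
                    "right",
                    rec.reference_end,
                    last[1],
                )
            )
    if n_filtered:
        logger.debug("split-read extraction skipped %d records", n_filtered)
    return out


def estimate_insert_stats(
    records: Iterable[AlignmentRecord],
) -> tuple[float, float]:
    """Mean and SD of |template length| over proper FR pairs."""
    tlens = [
        abs(rec.template_length)
        for rec in records
        if rec.is_paired and rec.is_proper_pair and rec.template_length > 0
    ]
    if not tlens:
        raise ValueError("no proper pairs to estimate insert size from")
    arr = np.asarray(tlens, dtype=float)
    return float(arr.mean()), float(arr.std())


def extract_discordant_pairs(
    records: Iterable[AlignmentRecord],
    tlen_threshold: float,
    mapq_floor: int = DEFAULT_MAPQ_FLOOR,
) -> list[DiscordantPair]:
    """Pairs with |template length| above threshold or non-FR orientation.

    Mates are joined by query name; pairs with a missing mate are dropped
    with a warning. The span runs from the leftmost mate's reference end
    to the rightmost mate's start (the unsequenced gap a deletion would
    inflate).
    """
    by_name: dict[str, AlignmentRecord] = {}
    pairs: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    for rec in records:
        if (
            not rec.is_paired
            or rec.is_unmapped
            or rec.is_secondary
            or rec.mapq < mapq_floor
        ):
            continue
        mate = by_name.pop(rec.query_name, None)
        if mate is None:
            by_name[rec.query_name] = rec
        else:
            pairs.append((mate, rec))
    if by_name:
        logger.warning("dropped %d reads with missing mates", len(by_name))

    out: list[DiscordantPair] = []
    for a, b in pairs:
        if a.contig != b.contig:
            orientation = "interchrom"
        else:
            left, right = (a, b) if a.pos <= b.pos else (b, a)
            orientation = {
                ("+", "-"): "FR",
                ("-", "+"): "RF",
                ("+", "+"): "FF",
                ("-", "-"): "RR",
            }[(left.strand, right.strand)]
        tlen = abs(a.template_length)
        if orientation == "FR" and tlen <= tlen_threshold:
            continue
        if orientation == "interchrom":
            continue  # deletions are intra-contig events
        span_start, span_end = left.reference_end, right.pos
        if span_start >= span_end:
            continue  # overlapping mates carry no gap information
        out.append(
            DiscordantPair(
                query_name=a.query_name,
                contig=a.contig or "",
                span=GenomicInterval(a.contig or "", span_start, span_end),
                template_length=a.template_length,
                orientation=orientation,
            )
        )
    return out


def bin_split_counts(
    evidence_treated: Sequence[SplitReadEvidence],
    evidence_control: Sequence[SplitReadEvidence],
    region: GenomicInterval,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> list[BinCounts]:
    """Tile the region with fixed-width bins and count breakpoints per bin.

    Conservation holds by construction: the bin counts of each sample sum
    to the number of in-region evidence items of that sample.
    """
    edges = list(range(region.start, region.end, bin_width)) + [region.end]
    n_bins = len(edges) - 1

    def counts(evidence: Sequence[SplitReadEvidence]) -> np.ndarray:
        c = np.zeros(n_bins, dtype=int)
        for ev in evidence:
            if ev.contig == region.contig and region.start <= ev.breakpoint < region.end:
                c[(ev.breakpoint - region.start) // bin_width] += 1
        return c

    treated, control = counts(evidence_treated), counts(evidence_control)
    return [
        BinCounts(
            bin=GenomicInterval(region.contig, edges[i], edges[i + 1]),
            treated_count=int(treated[i]),
            control_count=int(control[i]),
        )
        for i in range(n_bins)
    ]


def detect_cut_points(
    bins: Sequence[BinCounts],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[CutPoint]:
    """Bins where treated/max(control, 1) strictly exceeds the threshold.

    The ratio uses a pseudo-denominator of 1 when the control count is 0;
    a ratio exactly equal to the threshold does NOT qualify.
    """
    out: list[CutPoint] = []
    for b in bins:
        ratio = b.treated_count / max(b.control_count, 1)
        if ratio > ratio_threshold and b.treated_count >= min_support:
            out.append(CutPoint(bin=b.bin, ratio=ratio, treated_count=b.treated_count))
    return out


def _cluster_1d(values: list[int], tol: int) -> list[list[int]]:
    """Single-linkage clustering of sorted scalars: split where gap > tol."""
    order = sorted(range(len(values)), key=values.__getitem__)
    clusters: list[list[int]] = []
    for idx in order:
        if clusters and values[idx] - values[clusters[-1][-1]] <= tol:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return clusters


def infer_deletion_patterns(
    cut_points: Sequence[CutPoint],
    discordant_pairs: Sequence[DiscordantPair],
    splits: Sequence[SplitReadEvidence],
    merge_tol: int = DEFAULT_MERGE_TOL,
) -> list[DeletionPattern]:
    """Cluster cut-point-anchored discordant pairs into deletion patterns.

    For each cut point, pairs with one span endpoint within merge_tol of
    the cut-point bin midpoint are grouped by their far endpoint
    (single-linkage, merge_tol); each cluster yields one pattern whose
    breakpoints are the medians of the clustered inner mate boundaries.
    Patterns discovered from different cut points that agree on both
    breakpoints (within merge_tol) are de-duplicated, keeping the
    better-supported call.
    """
    candidates: list[DeletionPattern] = []
    for cp in cut_points:
        mid = cp.midpoint
        anchored_left = [
            p for p in discordant_pairs if abs(p.span.start - mid) <= merge_tol
        ]
        anchored_right = [
            p
            for p in discordant_pairs
            if abs(p.span.end - mid) <= merge_tol and p not in anchored_left
        ]
        for group, far_of in (
            (anchored_left, lambda p: p.span.end),
            (anchored_right, lambda p: p.span.start),
        ):
            if not group:
                continue
            far = [far_of(p) for p in group]
            for cluster in _cluster_1d(far, merge_tol):
                members = [group[i] for i in cluster]
                left_bp = int(median(p.span.start for p in members))
                right_bp = int(median(p.span.end for p in members))
                if left_bp >= right_bp:
                    continue
                n_splits = sum(
                    1
                    for s in splits
                    if abs(s.breakpoint - left_bp) <= merge_tol
                    or abs(s.breakpoint - right_bp) <= merge_tol
                )
                candidates.append(
                    DeletionPattern(
                        del_interval=GenomicInterval(
                            members[0].contig, left_bp, right_bp
                        ),
                        left_bp=left_bp,
                        right_bp=right_bp,
                        n_supporting_pairs=len(members),
                        n_supporting_splits=n_splits,
                    )
                )
        if not anchored_left and not anchored_right:
            logger.debug("cut point at %d has no supporting pairs", mid)

    # de-duplicate across cut points
    candidates.sort(
        key=lambda p: (-p.n_supporting_pairs, p.left_bp, p.right_bp)
    )
    kept: list[DeletionPattern] = []
    for pat in candidates:
        dup = any(
            abs(pat.left_bp - k.left_bp) <= merge_tol
            and abs(pat.right_bp - k.right_bp) <= merge_tol
            for k in kept
        )
        if not dup:
            kept.append(pat)
    kept.sort(key=lambda p: (p.left_bp, p.right_bp))
    return kept


def assign_extents(
    patterns: Sequence[DeletionPattern],
    pam_locus: GenomicInterval,
) -> None:
    """Annotate each pattern with strand-oriented 5'/3' extents from the PAM."""
    point = pam_locus.start if pam_locus.strand != "-" else pam_locus.end
    for pat in patterns:
        down = max(0, pat.right_bp - point)
        up = max(0, point - pat.left_bp)
        if pam_locus.strand == "-":
            down, up = up, down
        pat.direction_3p_extent = down
        pat.direction_5p_extent = up


def summarize_extents(
    patterns: Sequence[DeletionPattern],
    pam_locus: GenomicInterval,
    guide_id: str = "",
) -> ExtentSummary:
    """Maximum 5'/3' deletion extents relative to the PAM, plus the count."""
    assign_extents(patterns, pam_locus)
    if not patterns:
        return ExtentSummary(guide_id, 0, 0, 0)
    return ExtentSummary(
        guide_id=guide_id,
        max_3p_extent=max(p.direction_3p_extent or 0 for p in patterns),
        max_5p_extent=max(p.direction_5p_extent or 0 for p in patterns),
        n_patterns=len(patterns),
    )


def annotate_gene_overlap(
    patterns: Sequence[DeletionPattern],
    genes: Sequence[GeneAnnotation],
) -> list[GeneOverlapSummary]:
    """Per-gene fraction of deletion patterns overlapping the gene body.

    A pattern overlaps a gene iff its deleted interval intersects the gene
    body; the overlap is *partial* when the gene is not fully contained in
    the deletion. Percentages are half-up rounded to one decimal. An
    empty pattern set yields an explicit empty result (the fraction is
    undefined).
    """
    if not patterns:
        return []
    trees: dict[str, IntervalTree] = {}
    for i, pat in enumerate(patterns):
        trees.setdefault(pat.del_interval.contig, IntervalTree()).addi(
            pat.del_interval.start, pat.del_interval.end, i
        )
    out: list[GeneOverlapSummary] = []
    n_total = len(patterns)
    for gene in genes:
        body = gene.body
        tree = trees.get(body.contig)
        hits = tree.overlap(body.start, body.end) if tree is not None else set()
        n_overlapping = len(hits)
        n_partial = sum(
            1
            for h in hits
            if not (h.begin <= body.start and body.end <= h.end)
        )
        out.append(
            GeneOverlapSummary(
                gene=gene.name,
                n_overlapping=n_overlapping,
                n_partial=n_partial,
                n_total=n_total,
                fraction=n_overlapping / n_total,
                percent_1dp=percent_1dp(n_overlapping, n_total),
            )
        )
    return out
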
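"""In-silico crRNA screening for the Type I-E Cas3 system.

A candidate is a 3-nt AAG PAM followed (3' on the candidate strand) by a
32-nt protospacer. The screen applies four criteria: PAM present, spacer
GC content within [gc_min, gc_max] (bounds inclusive), target site
100-500 bp downstream of the target exon in the gene's transcription
direction, and genome uniqueness (no locus elsewhere matching
PAM+protospacer with <= design_mm_max mismatches and PAM exact, and no
exact match of PAM plus the 15-nt PAM-proximal seed).

"Downstream" distance is measured from the exon's transcription-direction
3' boundary to the PAM-proximal protospacer base, 0-based and inclusive of
both window bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _scan
from .genome_io import GenomicInterval, ReferenceGenome, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class DesignParams:
    pam: str = "AAG"
    spacer_len: int = 32
    gc_min: float = 0.30
    gc_max: float = 0.70
    window_min: int = 100
    window_max: int = 500
    design_mm_max: int = 3
    seed_len: int = 15

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.window_min >= self.window_max:
            raise ValueError("need window_min < window_max")
        if self.spacer_len <= self.seed_len:
            raise ValueError("need spacer_len > seed_len")

    @property
    def site_len(self) -> int:
        return len(self.pam) + self.spacer_len


@dataclass
class UniquenessHit:
    """An offending locus found by the uniqueness scan."""

    locus: GenomicInterval
    rule: str  # "mismatch" or "seed"
    n_mismatches: int


@dataclass
class CrRNACandidate:
    id: str
    target_gene: str
    locus: GenomicInterval  # PAM+protospacer footprint on the reference
    strand: str
    pam_seq: str
    spacer_seq: str
    gc: float
    distance_from_exon: int
    passes_uniqueness: bool | None = None
    rejection_reasons: list[str] = field(default_factory=list)
    uniqueness_hits: list[UniquenessHit] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        return not self.rejection_reasons and bool(self.passes_uniqueness)

    @property
    def site_seq(self) -> str:
        """PAM+spacer on the candidate strand."""
        return self.pam_seq + self.spacer_seq


def gc_content(seq: str) -> float:
    """Fraction of G+C over A/C/G/T sequence (errors on N or empty)."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"gc_content requires ACGT only, got {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _candidate_at(
    genome: ReferenceGenome,
    contig: str,
    q: int,
    strand: str,
    distance: int,
    gene: str,
    params: DesignParams,
) -> CrRNACandidate | None:
    """Build the candidate whose PAM-proximal protospacer base sits at q.

    Returns None when no PAM is present at the implied position (not a
    candidate at all); otherwise returns the candidate, with
    rejection_reasons populated for GC/N failures.
    """
    seq = genome.contigs[contig]
    plen, slen = len(params.pam), params.spacer_len
    if strand == "+":
        start = q - plen
        end = q + slen
        if start < 0 or end > len(seq):
            return None
        pam_seq = seq[start:q]
        spacer = seq[q:end]
    else:
        start = q - slen + 1
        end = q + plen + 1
        if start < 0 or end > len(seq):
            return None
        pam_seq = reverse_complement(seq[q + 1 : end])
        spacer = reverse_complement(seq[start : q + 1])
    if pam_seq != params.pam:
        return None
    reasons: list[str] = []
    gc = float("nan")
    if "N" in spacer:
        reasons.append("spacer_contains_N")
    else:
        gc = gc_content(spacer)
        if not (params.gc_min <= gc <= params.gc_max):
            reasons.append("gc_out_of_range")
    return CrRNACandidate(
        id=f"{gene}_{contig}_{start}_{strand}",
        target_gene=gene,
        locus=GenomicInterval(contig, start, end, strand),
        strand=strand,
        pam_seq=pam_seq,
        spacer_seq=spacer,
        gc=gc,
        distance_from_exon=distance,
        rejection_reasons=reasons,
    )


def scan_candidates(
    genome: ReferenceGenome,
    target_exon: GenomicInterval,
    params: DesignParams | None = None,
    gene: str = "",
    audit: bool = False,
) -> list[CrRNACandidate]:
    """Enumerate PAM-anchored candidates downstream of the target exon.

    Both strands are scanned. In audit mode candidates failing GC/N checks
    are also emitted, carrying their rejection_reasons; otherwise only
    clean candidates are returned (uniqueness is checked separately).
    """
    params = params or DesignParams()
    genome.check_interval(target_exon)
    if target_exon.strand == "-":
        sign, origin = -1, target_exon.start - 1
    else:
        sign, origin = 1, target_exon.end
    contig_len = len(genome.contigs[target_exon.contig])
    out: list[CrRNACandidate] = []
    for d in range(params.window_min, params.window_max + 1):
        q = origin + sign * d
        if not (0 <= q < contig_len):
            logger.warning(
                "design window truncated at contig edge (%s, distance %d)",
                target_exon.contig,
                d,
            )
            break
        for strand in ("+", "-"):
            cand = _candidate_at(
                genome, target_exon.contig, q, strand, d, gene, params
            )
            if cand is None:
                continue
            if cand.rejection_reasons and not audit:
                continue
            out.append(cand)
    out.sort(key=lambda c: (c.locus.start, c.strand))
    return out


def uniqueness_check(
    candidate: CrRNACandidate,
    genome: ReferenceGenome,
    params: DesignParams | None = None,
) -> tuple[bool, list[UniquenessHit]]:
    """Genome-uniqueness filter for one candidate.

    Fails iff (a) any locus other than the candidate's own matches
    PAM+protospacer with PAM exact and <= design_mm_max spacer mismatches
    on either strand, or (b) any other locus exactly matches PAM plus the
    PAM-proximal seed_len nt of the spacer. Returns (passes, hits).
    """
    params = params or DesignParams()
    site = _scan.encode(candidate.site_seq)
    seed = site[: len(params.pam) + params.seed_len]
    plen = len(params.pam)
    hits: list[UniquenessHit] = []
    own = (candidate.locus.contig, candidate.locus.start, candidate.strand)
    for contig, seq in genome.contigs.items():
        g = _scan.encode(seq)
        for strand in ("+", "-"):
            M = _scan.match_rows_oriented(g, site, strand)
            if M.shape[1] == 0:
                continue
            pam_ok = M[:plen].all(axis=0)
            mm = (~M[plen:]).sum(axis=0)
            for i in np.flatnonzero(pam_ok & (mm <= params.design_mm_max)):
                i = int(i)
                if (contig, i, strand) == own:
                    continue
                hits.append(
                    UniquenessHit(
                        GenomicInterval(contig, i, i + len(site), strand),
                        "mismatch",
                        int(mm[i]),
                    )
                )
            Ms = _scan.match_rows_oriented(g, seed, strand)
            if Ms.shape[1] == 0:
                continue
            for i in np.flatnonzero(Ms.all(axis=0)):
                i = int(i)
                # the seed footprint of the candidate's own site
                if strand == candidate.strand and contig == candidate.locus.contig:
                    own_start = (
                        candidate.locus.start
                        if strand == "+"
                        else candidate.locus.end - len(seed)
                    )
                    if i == own_start:
                        continue
                hits.append(
                    UniquenessHit(
                        GenomicInterval(contig, i, i + len(seed), strand), "seed", 0
                    )
                )
    return (not hits, hits)


def design_guides(
    genome: ReferenceGenome,
    target_exon: GenomicInterval,
    params: DesignParams | None = None,
    gene: str = "",
    audit: bool = False,
) -> list[CrRNACandidate]:
    """Full screen: window/PAM/GC scan followed by the uniqueness filter."""
    params = params or DesignParams()
    candidates = scan_candidates(genome, target_exon, params, gene=gene, audit=audit)
    for cand in candidates:
        if cand.rejection_reasons:
            cand.passes_uniqueness = None
            continue
        ok, hits = uniqueness_check(cand, genome, params)
        cand.passes_uniqueness = ok
        cand.uniqueness_hits = hits
        if not ok:
            cand.rejection_reasons.append("not_unique")
    return candidates
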
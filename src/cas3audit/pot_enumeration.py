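"""Genome-wide potential off-target (POT) enumeration and capture windows.

Cas3 mode: a locus is a POT site if it carries a contiguous exact match of
at least ``consec_min`` nt to PAM+spacer that overlaps at least one PAM
base (the *consecutive* rule), or an exact PAM with at most
``mm_max_cas3`` Hamming mismatches over the full 32-nt spacer (the
*mismatch-tolerant* rule). Cas9 mode: NGG PAM (N wildcard) 3' of a 20-nt
protospacer with at most ``mm_max_cas9`` mismatches.

Capture windows mirror targeted-capture probe design: +/-100 kbp around
the on-target PAM, and an asymmetric 9 kbp PAM-upstream / 1 kbp
PAM-downstream window around each POT site, following the site's strand
(Cas3 degradation is directional, so the window is anchored to the PAM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _scan
from .crrna_design import CrRNACandidate
from .genome_io import GenomicInterval, ReferenceGenome

logger = logging.getLogger(__name__)

ON_TARGET_FLANK = 100_000
POT_UPSTREAM = 9_000
POT_DOWNSTREAM = 1_000


@dataclass
class PotParams:
    mode: str = "cas3"
    consec_min: int = 16
    consec_max: int = 20  # recorded bound; runs longer than this still qualify
    mm_max_cas3: int = 7
    mm_max_cas9: int = 3
    cas9_pam: str = "NGG"
    pam_exact: bool = True  # mismatch-tolerant rule requires exact PAM
    consec_pam_full: bool = False  # require all PAM bases in the run, not >=1
    merge_offset: int = 10  # sites starting within this many bp are merged

    def __post_init__(self) -> None:
        if self.consec_min > self.consec_max:
            raise ValueError("need consec_min <= consec_max")
        if self.mm_max_cas3 < 0 or self.mm_max_cas9 < 0:
            raise ValueError("mismatch budgets must be >= 0")


@dataclass
class PotSite:
    locus: GenomicInterval
    strand: str
    rule: str  # consecutive | mismatch_tolerant | both
    longest_pam_anchored_run: int
    n_mismatches: int  # over the full spacer (PAM excluded)
    aligned_site_seq: str  # genomic sequence in guide orientation
    is_on_target: bool = False


@dataclass
class CaptureRegion:
    locus: GenomicInterval
    kind: str  # on_target | pot
    anchor: GenomicInterval


def _guide_site(guide: CrRNACandidate | str) -> tuple[str, GenomicInterval | None]:
    if isinstance(guide, str):
        return guide.upper(), None
    return guide.site_seq, guide.locus


def _pam_anchored_runs(M: np.ndarray, plen: int, pam_full: bool) -> np.ndarray:
    """Length of the longest exact run through the PAM, per genome position.

    Only runs containing the PAM-adjacent base (row plen-1) can reach a
    qualifying length, so the run through that row is the one measured.
    """
    m, n = M.shape
    anchor = plen - 1
    fwd = np.zeros(n, dtype=np.int32)
    alive = M[anchor].copy()
    fwd += alive
    for j in range(anchor + 1, m):
        alive &= M[j]
        fwd += alive
    back = np.zeros(n, dtype=np.int32)
    alive = M[anchor].copy()
    for j in range(anchor - 1, -1, -1):
        alive &= M[j]
        back += alive
    runs = np.where(M[anchor], fwd + back, 0)
    if pam_full:
        runs = np.where(back == anchor, runs, 0)
    return runs


def _merge_sites(sites: list[PotSite], merge_offset: int) -> list[PotSite]:
    """Collapse qualifying loci on the same strand starting <merge_offset bp
    apart into one physical site, keeping fewest mismatches then longest run."""
    if merge_offset <= 0:
        return sorted(sites, key=lambda s: (s.locus.contig, s.locus.start, s.strand))
    merged: list[PotSite] = []
    for site in sorted(
        sites, key=lambda s: (s.locus.contig, s.strand, s.locus.start)
    ):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.locus.contig == site.locus.contig
            and prev.strand == site.strand
            and site.locus.start - prev.locus.start < merge_offset
        ):
            best = min(
                (prev, site),
                key=lambda s: (s.n_mismatches, -s.longest_pam_anchored_run),
            )
            best.is_on_target = prev.is_on_target or site.is_on_target
            merged[-1] = best
        else:
            merged.append(site)
    merged.sort(key=lambda s: (s.locus.contig, s.locus.start, s.strand))
    return merged


def find_pot_sites_cas3(
    guide: CrRNACandidate | str,
    genome: ReferenceGenome,
    params: PotParams | None = None,
) -> list[PotSite]:
    """Enumerate Cas3 POT sites genome-wide for a PAM+32-nt guide.

    Both strands are scanned; the on-target locus is returned and flagged
    when the guide carries its genomic locus.
    """
    params = params or PotParams()
    site_seq, own_locus = _guide_site(guide)
    pat = _scan.encode(site_seq)
    plen = len(site_seq) - 32
    if plen < 1:
        raise ValueError("Cas3 guide must be PAM plus a 32-nt spacer")
    sites: list[PotSite] = []
    for contig, seq in genome.contigs.items():
        g = _scan.encode(seq)
        for strand in ("+", "-"):
            M = _scan.match_rows_oriented(g, pat, strand)
            if M.shape[1] == 0:
                continue
            pam_ok = M[:plen].all(axis=0)
            mm = (~M[plen:]).sum(axis=0).astype(np.int32)
            mm_rule = (mm <= params.mm_max_cas3) & (pam_ok if params.pam_exact else True)
            runs = _pam_anchored_runs(M, plen, params.consec_pam_full)
            consec_rule = runs >= params.consec_min
            for i in np.flatnonzero(mm_rule | consec_rule):
                i = int(i)
                rule = (
                    "both"
                    if mm_rule[i] and consec_rule[i]
                    else ("mismatch_tolerant" if mm_rule[i] else "consecutive")
                )
                locus = GenomicInterval(contig, i, i + len(pat), strand)
                raw = seq[i : i + len(pat)]
                aligned = raw if strand == "+" else _rc(raw)
                sites.append(
                    PotSite(
                        locus=locus,
                        strand=strand,
                        rule=rule,
                        longest_pam_anchored_run=int(runs[i]),
                        n_mismatches=int(mm[i]),
                        aligned_site_seq=aligned,
                        is_on_target=own_locus is not None
                        and locus.contig == own_locus.contig
                        and locus.start == own_locus.start
                        and strand == own_locus.strand,
                    )
                )
    return _merge_sites(sites, params.merge_offset)


def find_pot_sites_cas9(
    guide20: str,
    genome: ReferenceGenome,
    params: PotParams | None = None,
) -> list[PotSite]:
    """Enumerate Cas9 POT sites: 20-nt spacer + NGG PAM, <= mm_max_cas9
    spacer mismatches, both strands."""
    params = params or PotParams(mode="cas9")
    guide20 = guide20.upper()
    if len(guide20) != 20:
        raise ValueError("Cas9 guide must be 20 nt")
    pat = _scan.encode(guide20 + params.cas9_pam)
    wildcard = {20 + j for j, b in enumerate(params.cas9_pam) if b == "N"}
    sites: list[PotSite] = []
    for contig, seq in genome.contigs.items():
        g = _scan.encode(seq)
        for strand in ("+", "-"):
            M = _scan.match_rows_oriented(g, pat, strand, wildcard)
            if M.shape[1] == 0:
                continue
            pam_ok = M[20:].all(axis=0)
            mm = (~M[:20]).sum(axis=0).astype(np.int32)
            for i in np.flatnonzero(pam_ok & (mm <= params.mm_max_cas9)):
                i = int(i)
                raw = seq[i : i + len(pat)]
                sites.append(
                    PotSite(
                        locus=GenomicInterval(contig, i, i + len(pat), strand),
                        strand=strand,
                        rule="mismatch_tolerant",
                        longest_pam_anchored_run=0,
                        n_mismatches=int(mm[i]),
                        aligned_site_seq=raw if strand == "+" else _rc(raw),
                    )
                )
    return _merge_sites(sites, params.merge_offset)


def _rc(seq: str) -> str:
    from .genome_io import reverse_complement

    return reverse_complement(seq)


def _clip(start: int, end: int, contig_len: int, what: str) -> tuple[int, int]:
    if start < 0 or end > contig_len:
        logger.warning("%s capture window clipped at contig edge", what)
    return max(0, start), min(end, contig_len)


def pam_point(locus: GenomicInterval, strand: str) -> int:
    """Reference coordinate of the PAM's 5'-most base for a Cas3 site."""
    return locus.start if strand == "+" else locus.end


def build_capture_regions(
    anchors: list[PotSite] | list[GenomicInterval],
    genome: ReferenceGenome,
    kind: str,
) -> list[CaptureRegion]:
    """Capture windows around on-target loci (+/-100 kbp of the PAM) or POT
    sites (9 kbp PAM-upstream, 1 kbp PAM-downstream, strand-oriented)."""
    if kind not in ("on_target", "pot"):
        raise ValueError(f"unknown capture kind {kind!r}")
    regions: list[CaptureRegion] = []
    for anchor in anchors:
        locus = anchor.locus if isinstance(anchor, PotSite) else anchor
        strand = anchor.strand if isinstance(anchor, PotSite) else locus.strand
        genome.check_interval(locus)  # raises if anchor outside contig
        contig_len = len(genome.contigs[locus.contig])
        if kind == "on_target":
            point = pam_point(locus, strand)
            start, end = point - ON_TARGET_FLANK, point + ON_TARGET_FLANK
        elif strand == "-":
            start, end = locus.start - POT_DOWNSTREAM, locus.end + POT_UPSTREAM
        else:
            start, end = locus.start - POT_UPSTREAM, locus.end + POT_DOWNSTREAM
        start, end = _clip(start, end, contig_len, kind)
        regions.append(
            CaptureRegion(
                locus=GenomicInterval(locus.contig, start, end, strand),
                kind=kind,
                anchor=locus,
            )
        )
    return regions
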
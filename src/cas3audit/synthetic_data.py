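"""Synthetic genomes, deletion haplotypes and capture-sequencing reads.

The generator emulates the geometry of a directional-nuclease editing
experiment with known ground truth: a single-contig i.i.d. random genome
carrying a target gene flanked by neighbor genes; a planted AAG+32-nt
guide site a configurable distance downstream of the target exon; POT
sites planted at chosen spacer mismatch distances; per-cell haplotypes in
which a configurable fraction carry one one-sided deletion anchored at
the cut site (a long geometric 3' arm with probability
``direction_bias``, otherwise a short geometric 5'-direction deletion,
the anchor breakpoint jittered within +/-50 bp); and 2x150 bp paired-end
reads over the
capture regions in which breakpoint-crossing reads become soft-clipped
split reads and breakpoint-spanning fragments become discordant pairs
with inflated template lengths. A no-crRNA control library is simulated
from wild-type haplotypes only, and a small uniform soft-clip noise rate
is injected into both libraries.

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy.random.Generator`` streams, so every artifact (including the SAM
bytes) is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    GeneAnnotation,
    GenomicInterval,
    ReferenceGenome,
    reverse_complement,
)
from .pot_enumeration import CaptureRegion

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneSpec:
    name: str
    start: int
    end: int
    strand: str = "+"
    exon_spans: tuple[tuple[int, int], ...] | None = None


def default_gene_layout() -> list[GeneSpec]:
    """Target gene plus one neighbor on each flank, mirroring the
    TRAC/DAD1/ABHD4 geometry at reduced scale."""
    return [
        GeneSpec("TRAC", 190_000, 199_800, "+", ((190_000, 190_500), (199_300, 199_800))),
        GeneSpec("DAD1", 212_000, 224_000, "+"),
        GeneSpec("ABHD4", 175_000, 186_000, "-"),
    ]


@dataclass
class SimConfig:
    seed: int
    genome_len: int = 400_000
    contig: str = "chr_sim"
    gene_layout: list[GeneSpec] = field(default_factory=default_gene_layout)
    target_gene: str = "TRAC"
    guide_offset: int = 200  # bp from exon 3' end to PAM-proximal spacer base
    spacer_gc: float = 0.5
    n_cells: int = 200
    editing_rate: float = 0.6
    del_len_mean: int = 20_000
    del_len_max: int = 100_000
    direction_bias: float = 0.8
    small_ext_mean: int = 2_000
    breakpoint_jitter: int = 50
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 60
    depth: int = 200
    noise_clip_rate: float = 0.002
    noise_clip_min: int = 5
    noise_clip_max: int = 15
    pot_plants: list[tuple[int, int]] = field(
        default_factory=lambda: [(4, 1), (5, 1), (7, 1)]
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent nondeterminism)")
        for p in (self.editing_rate, self.direction_bias, self.noise_clip_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.genome_len, self.del_len_mean, self.read_len, self.depth) <= 0:
            raise ValueError("lengths and depth must be positive")


@dataclass
class PlantedPot:
    locus: GenomicInterval
    n_mismatches: int
    site_seq: str  # PAM+spacer in guide orientation


@dataclass
class PlantedDeletion:
    haplotype: int
    start: int
    end: int
    n_spanning_pairs: int | None = None  # filled in by simulate_reads


@dataclass
class GroundTruth:
    contig: str
    guide_locus: GenomicInterval | None = None
    guide_spacer: str = ""
    guide_pam: str = "AAG"
    cut_site: int = 0
    planted_pots: list[PlantedPot] = field(default_factory=list)
    deletions: list[PlantedDeletion] = field(default_factory=list)
    n_haplotypes: int = 0

    def true_max_extents(self) -> tuple[int, int]:
        """(max 3' extent, max 5' extent) of planted deletions from the PAM."""
        if self.guide_locus is None or not self.deletions:
            return (0, 0)
        point = (
            self.guide_locus.start
            if self.guide_locus.strand != "-"
            else self.guide_locus.end
        )
        d3 = max((max(0, d.end - point) for d in self.deletions), default=0)
        d5 = max((max(0, point - d.start) for d in self.deletions), default=0)
        if self.guide_locus.strand == "-":
            d3, d5 = d5, d3
        return (d3, d5)

    def gene_overlap_counts(self, genes: list[GeneAnnotation]) -> dict[str, int]:
        counts = {}
        for gene in genes:
            counts[gene.name] = sum(
                1
                for d in self.deletions
                if d.start < gene.body.end and gene.body.start < d.end
            )
        return counts

    def to_json(self, path: str | Path) -> None:
        doc = {
            "contig": self.contig,
            "guide_locus": asdict(self.guide_locus) if self.guide_locus else None,
            "guide_spacer": self.guide_spacer,
            "guide_pam": self.guide_pam,
            "cut_site": self.cut_site,
            "n_haplotypes": self.n_haplotypes,
            "planted_pots": [
                {
                    "locus": asdict(p.locus),
                    "n_mismatches": p.n_mismatches,
                    "site_seq": p.site_seq,
                }
                for p in self.planted_pots
            ],
            "deletions": [asdict(d) for d in self.deletions],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _random_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    n_gc = int(round(length * gc))
    letters = [rng.choice(["G", "C"]) for _ in range(n_gc)]
    letters += [rng.choice(["A", "T"]) for _ in range(length - n_gc)]
    return "".join(rng.permutation(letters))


def _mutate_spacer(
    rng: np.random.Generator, spacer: str, k: int, seed_len: int = 15
) -> str:
    """Copy of the spacer with exactly k substitutions, at least one of
    which falls in the PAM-proximal seed (so the planted POT cannot defeat
    the design-time seed-uniqueness filter)."""
    if k == 0:
        return spacer
    positions = set()
    positions.add(int(rng.integers(0, min(seed_len, len(spacer)))))
    while len(positions) < k:
        positions.add(int(rng.integers(0, len(spacer))))
    out = list(spacer)
    for pos in sorted(positions):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def make_genome(
    config: SimConfig,
) -> tuple[ReferenceGenome, list[GeneAnnotation], GroundTruth]:
    """Random genome with genes, one planted guide site and planted POTs."""
    rng = _rng(config, 1)
    codes = rng.integers(0, 4, config.genome_len, dtype=np.uint8)
    seq = bytearray(_BASES[codes].tobytes())

    genes: list[GeneAnnotation] = []
    target: GeneSpec | None = None
    for spec in config.gene_layout:
        if spec.end > config.genome_len:
            raise ValueError(f"gene {spec.name} overflows the genome layout")
        body = GenomicInterval(config.contig, spec.start, spec.end, spec.strand)
        exons = [
            GenomicInterval(config.contig, s, e, spec.strand)
            for s, e in (spec.exon_spans or ())
        ]
        genes.append(GeneAnnotation(spec.name, body, exons))
        if spec.name == config.target_gene:
            target = spec
    if target is None:
        raise ValueError(f"target gene {config.target_gene!r} not in layout")

    # plant the guide: AAG PAM + spacer, PAM-proximal spacer base at
    # guide_offset bp downstream of the target exon (transcription sense)
    spacer = _random_spacer(rng, 32, config.spacer_gc)
    pam = "AAG"
    exon3 = (
        (target.exon_spans or ((target.start, target.end),))[-1][1]
        if target.strand != "-"
        else (target.exon_spans or ((target.start, target.end),))[0][0]
    )
    if target.strand != "-":
        pam_start = exon3 + config.guide_offset - len(pam)
        site = pam + spacer
        guide_strand = "+"
    else:
        pam_start = exon3 - 1 - config.guide_offset - 31
        site = reverse_complement(pam + spacer)
        guide_strand = "-"
    if pam_start < 0 or pam_start + 35 > config.genome_len:
        raise ValueError("guide site overflows the genome layout")
    seq[pam_start : pam_start + 35] = site.encode()
    guide_locus = GenomicInterval(config.contig, pam_start, pam_start + 35, guide_strand)
    cut_site = pam_start if guide_strand == "+" else pam_start + 35

    truth = GroundTruth(
        contig=config.contig,
        guide_locus=guide_locus,
        guide_spacer=spacer,
        guide_pam=pam,
        cut_site=cut_site,
    )

    # plant POT copies away from the on-target capture window so that
    # their own 10-kb capture regions stay disjoint from it
    zones = [(15_000, 80_000), (315_000, 385_000)]
    zones = [
        (a, b) for a, b in zones if b + 10_000 < config.genome_len and a > 10_000
    ]
    occupied: list[tuple[int, int]] = []
    for k, count in config.pot_plants:
        for _ in range(count):
            for _attempt in range(100):
                zi = int(rng.integers(0, len(zones)))
                a, b = zones[zi]
                pos = int(rng.integers(a, b - 35))
                # spacing > 11 kb keeps the 10-kb POT capture windows disjoint
                if all(abs(pos - s) > 11_000 for s, _ in occupied):
                    break
            else:
                raise ValueError("could not place POT plant without overlap")
            occupied.append((pos, pos + 35))
            strand = "+" if rng.random() < 0.5 else "-"
            mut = _mutate_spacer(rng, spacer, k)
            planted = pam + mut
            insert = planted if strand == "+" else reverse_complement(planted)
            seq[pos : pos + 35] = insert.encode()
            truth.planted_pots.append(
                PlantedPot(
                    locus=GenomicInterval(config.contig, pos, pos + 35, strand),
                    n_mismatches=k,
                    site_seq=planted,
                )
            )

    genome = ReferenceGenome({config.contig: seq.decode()})
    return genome, genes, truth


def _draw_geometric(
    rng: np.random.Generator, mean: int, maximum: int | None = None
) -> int:
    val = int(rng.geometric(1.0 / mean))
    if maximum is not None:
        while val > maximum:
            val = int(rng.geometric(1.0 / mean))
    return val


def simulate_deletions(
    genome: ReferenceGenome, truth: GroundTruth, config: SimConfig
) -> list[tuple[int, int] | None]:
    """Draw one deletion (or none) per haplotype, anchored at the cut site.

    Returns the per-haplotype list (None = wild type) and records planted
    deletions in the ground truth.
    """
    rng = _rng(config, 2)
    contig_len = len(genome.contigs[truth.contig])
    cut = truth.cut_site
    haplotypes: list[tuple[int, int] | None] = []
    truth.n_haplotypes = config.n_cells
    for h in range(config.n_cells):
        if rng.random() >= config.editing_rate:
            haplotypes.append(None)
            continue
        for _attempt in range(100):
            anchor = cut + int(
                rng.integers(-config.breakpoint_jitter, config.breakpoint_jitter + 1)
            )
            # one-sided degradation: a long 3' arm with probability
            # direction_bias, otherwise a short 5'-direction deletion
            if rng.random() < config.direction_bias:
                l3 = _draw_geometric(rng, config.del_len_mean, config.del_len_max)
                l5 = 0
            else:
                l5 = _draw_geometric(rng, config.small_ext_mean, config.del_len_max)
                l3 = 0
            if truth.guide_locus is not None and truth.guide_locus.strand == "-":
                l3, l5 = l5, l3
            start, end = anchor - l5, anchor + l3
            if 0 <= start < end <= contig_len:
                break
            logger.debug("resampled out-of-contig deletion for haplotype %d", h)
        else:
            raise ValueError("could not place deletion inside the contig")
        haplotypes.append((start, end))
        truth.deletions.append(PlantedDeletion(haplotype=h, start=start, end=end))
    return haplotypes


def _sam_header(config: SimConfig) -> str:
    return (
        "@HD\tVN:1.6\tSO:unsorted\n"
        f"@SQ\tSN:{config.contig}\tLN:{config.genome_len}\n"
    )


def _simulate_library(
    rng: np.random.Generator,
    haplotypes: list[tuple[int, int] | None],
    regions: list[CaptureRegion],
    config: SimConfig,
    path: str | Path,
    prefix: str,
    support: dict[int, int] | None = None,
) -> None:
    """Sample paired-end fragments over the capture regions and write SAM.

    Fragments are assigned to haplotypes uniformly; reads crossing a
    deletion breakpoint are emitted with the longer segment aligned and
    the shorter soft-clipped, as a breakpoint-aware aligner would report
    them. ``support`` (haplotype index -> count) accumulates the number
    of fragments that cleanly span each haplotype's deletion.
    """
    rl = config.read_len
    proper_limit = config.insert_mean + 3 * config.insert_sd
    lines: list[str] = [_sam_header(config)]
    frag_no = 0
    for region in regions:
        rlen = len(region.locus)
        n_frag = int(round(config.depth * rlen / (2 * rl)))
        if n_frag == 0:
            logger.warning("zero fragments for region %s", region.locus)
            continue
        hap_idx = rng.integers(0, len(haplotypes), n_frag)
        flens = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, n_frag)),
            rl,
            None,
        ).astype(np.int64)
        starts_u = rng.random(n_frag)
        noise_u = rng.random(2 * n_frag)
        noise_c = rng.integers(
            config.noise_clip_min, config.noise_clip_max + 1, 2 * n_frag
        )
        noise_side = rng.integers(0, 2, 2 * n_frag)
        a0, b0 = region.locus.start, region.locus.end
        for i in range(n_frag):
            hap = int(hap_idx[i])
            d = haplotypes[hap]
            flen = int(flens[i])
            if d is not None:
                ds, de = d
                dlen = de - ds
                # haplotype coordinate = reference coordinate with the
                # deleted segment collapsed out
                hap_a = a0 if a0 <= ds else (ds if a0 < de else a0 - dlen)
                hap_b = b0 if b0 <= ds else (ds if b0 < de else b0 - dlen)
            else:
                ds = de = dlen = 0
                hap_a, hap_b = a0, b0
            span = hap_b - hap_a
            if span <= rl:
                continue
            f = min(flen, span)
            s = hap_a + int(starts_u[i] * (span - f + 1))
            e = s + f

            def place(u: int, v: int) -> tuple[int, str, int]:
                """Map a read [u, v) in haplotype coords to (ref pos, CIGAR,
                aligned ref length)."""
                if d is not None and u < ds < v:
                    a_len, b_len = ds - u, v - ds
                    if a_len >= b_len:
                        return u, f"{a_len}M{b_len}S", a_len
                    return de, f"{a_len}S{b_len}M", b_len
                pos = u if (d is None or u < ds) else u + dlen
                return pos, f"{v - u}M", v - u

            p1, c1, m1 = place(s, s + rl)
            p2, c2, m2 = place(e - rl, e)
            # uniform noise soft clips on otherwise clean reads
            for which in (0, 1):
                if noise_u[2 * i + which] < config.noise_clip_rate:
                    c = int(noise_c[2 * i + which])
                    if which == 0 and c1 == f"{rl}M":
                        if noise_side[2 * i] == 0:
                            c1 = f"{c}S{rl - c}M"
                            p1 += c
                            m1 -= c
                        else:
                            c1 = f"{rl - c}M{c}S"
                            m1 -= c
                    elif which == 1 and c2 == f"{rl}M":
                        if noise_side[2 * i + 1] == 0:
                            c2 = f"{c}S{rl - c}M"
                            p2 += c
                            m2 -= c
                        else:
                            c2 = f"{rl - c}M{c}S"
                            m2 -= c
            left_pos = min(p1, p2)
            right_end = max(p1 + m1, p2 + m2)
            tlen = right_end - left_pos
            proper = 2 if tlen <= proper_limit else 0
            f1 = 0x1 | 0x20 | 0x40 | proper
            f2 = 0x1 | 0x10 | 0x80 | proper
            name = f"{prefix}{frag_no}"
            frag_no += 1
            lines.append(
                f"{name}\t{f1}\t{config.contig}\t{p1 + 1}\t60\t{c1}\t=\t"
                f"{p2 + 1}\t{tlen}\t*\t*\n"
            )
            lines.append(
                f"{name}\t{f2}\t{config.contig}\t{p2 + 1}\t60\t{c2}\t=\t"
                f"{p1 + 1}\t{-tlen}\t*\t*\n"
            )
            if support is not None and d is not None and s + rl <= ds <= e - rl:
                support[hap] = support.get(hap, 0) + 1
    Path(path).write_text("".join(lines))


def simulate_reads(
    haplotypes: list[tuple[int, int] | None],
    capture_regions: list[CaptureRegion],
    genome: ReferenceGenome,
    config: SimConfig,
    truth: GroundTruth,
    treated_path: str | Path,
    control_path: str | Path,
) -> None:
    """Write treated and control SAM libraries and record per-deletion
    spanning-pair support in the ground truth.

    The control library is drawn from wild-type haplotypes only (the
    no-crRNA condition); both libraries share the noise model.
    """
    rng = _rng(config, 3)
    support: dict[int, int] = {}
    _simulate_library(
        rng, haplotypes, capture_regions, config, treated_path, "t", support
    )
    _simulate_library(rng, [None], capture_regions, config, control_path, "c")
    for d in truth.deletions:
        d.n_spanning_pairs = support.get(d.haplotype, 0)
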
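"""End-to-end orchestration: design -> POT -> simulate -> call -> score.

One structured config drives a reproducible run on a synthetic genome;
every stage's table is persisted as TSV (BED for intervals) alongside a
JSON report, and the report is recomputable from those intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import deletion_analysis as da
from . import offtarget_scoring as ots
from .crrna_design import CrRNACandidate, DesignParams, design_guides
from .genome_io import (
    GeneAnnotation,
    GenomicInterval,
    ReferenceGenome,
    read_alignments,
    write_bed,
    write_fasta,
)
from .pot_enumeration import (
    CaptureRegion,
    PotParams,
    PotSite,
    build_capture_regions,
    find_pot_sites_cas3,
)
from .synthetic_data import GroundTruth, SimConfig, make_genome, simulate_deletions, simulate_reads
from .util import percent_1dp, round_half_up

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class CallParams:
    bin_width: int = da.DEFAULT_BIN_WIDTH
    ratio_threshold: float = da.DEFAULT_RATIO_THRESHOLD
    min_support: int = da.DEFAULT_MIN_SUPPORT
    merge_tol: int = da.DEFAULT_MERGE_TOL
    min_clip: int = da.DEFAULT_MIN_CLIP
    mapq_floor: int = 20
    discordant_nsd: float = 3.0


@dataclass
class ScoringParams:
    flag_threshold: int = ots.DEFAULT_FLAG_THRESHOLD
    indel_window_halfwidth: int = ots.DEFAULT_INDEL_HALFWIDTH


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "cas3audit_run"
    design: DesignParams = field(default_factory=DesignParams)
    pot: PotParams = field(default_factory=PotParams)
    call: CallParams = field(default_factory=CallParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    sim: SimConfig | None = None
    # worked-example yield arithmetic inputs (fractions of cells)
    dko_frequency: float = 0.687
    viability: float = 0.421

    def resolved_sim(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        return SimConfig(seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        if doc["sim"] is None:
            doc["sim"] = dataclasses.asdict(self.resolved_sim())
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sim = doc.pop("sim", None)
        cfg = cls(
            seed=doc.get("seed", 1),
            outdir=doc.get("outdir", "cas3audit_run"),
            design=DesignParams(**doc.get("design", {})),
            pot=PotParams(**doc.get("pot", {})),
            call=CallParams(**doc.get("call", {})),
            scoring=ScoringParams(**doc.get("scoring", {})),
            dko_frequency=doc.get("dko_frequency", 0.687),
            viability=doc.get("viability", 0.421),
        )
        if sim is not None:
            layout = sim.pop("gene_layout", None)
            from .synthetic_data import GeneSpec

            if layout is not None:
                sim["gene_layout"] = [
                    GeneSpec(
                        g["name"],
                        g["start"],
                        g["end"],
                        g.get("strand", "+"),
                        tuple(tuple(x) for x in g["exon_spans"])
                        if g.get("exon_spans")
                        else None,
                    )
                    for g in layout
                ]
            sim["pot_plants"] = [tuple(p) for p in sim.get("pot_plants", [])]
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class RunReport:
    seed: int
    candidates: list[CrRNACandidate]
    guide: CrRNACandidate
    pot_sites: list[PotSite]
    capture_regions: list[CaptureRegion]
    cut_points: list[da.CutPoint]
    patterns: list[da.DeletionPattern]
    extents: da.ExtentSummary
    gene_overlaps: list[da.GeneOverlapSummary]
    scores: list[ots.OffTargetScore]
    effective_yield_pct: float
    truth: GroundTruth
    genome: ReferenceGenome
    genes: list[GeneAnnotation]


def effective_yield(dko_frequency: float, viability: float) -> float:
    """Edited-cell yield as a fraction of the initial cell input.

    Multiplies the knockout frequency among viable cells by the overall
    viability; report with :func:`effective_yield_percent` for the half-up
    one-decimal percentage convention.
    """
    for name, value in (("dko_frequency", dko_frequency), ("viability", viability)):
        if not (0 <= value <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return dko_frequency * viability


def effective_yield_percent(dko_frequency: float, viability: float) -> float:
    return round_half_up(100 * effective_yield(dko_frequency, viability), 1)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _write_tables(outdir: Path, report: RunReport, config: RunConfig) -> None:
    def tsv(name: str, rows: list[dict]) -> None:
        pd.DataFrame(rows).to_csv(outdir / name, sep="\t", index=False)

    tsv(
        "candidates.tsv",
        [
            {
                "id": c.id,
                "gene": c.target_gene,
                "contig": c.locus.contig,
                "start": c.locus.start,
                "end": c.locus.end,
                "strand": c.strand,
                "pam": c.pam_seq,
                "spacer": c.spacer_seq,
                "gc": round(c.gc, 4),
                "distance_from_exon": c.distance_from_exon,
                "passes_uniqueness": c.passes_uniqueness,
                "rejection_reasons": ";".join(c.rejection_reasons),
            }
            for c in report.candidates
        ],
    )
    tsv(
        "pot_sites.tsv",
        [
            {
                "contig": s.locus.contig,
                "start": s.locus.start,
                "end": s.locus.end,
                "strand": s.strand,
                "rule": s.rule,
                "longest_pam_anchored_run": s.longest_pam_anchored_run,
                "n_mismatches": s.n_mismatches,
                "is_on_target": s.is_on_target,
                "site_seq": s.aligned_site_seq,
            }
            for s in report.pot_sites
        ],
    )
    with open(outdir / "capture_regions.bed", "w") as fh:
        for r in report.capture_regions:
            fh.write(
                f"{r.locus.contig}\t{r.locus.start}\t{r.locus.end}\t{r.kind}\t0\t"
                f"{r.locus.strand}\n"
            )
    with open(outdir / "cut_points.bed", "w") as fh:
        for cp in report.cut_points:
            fh.write(
                f"{cp.bin.contig}\t{cp.bin.start}\t{cp.bin.end}\t"
                f"ratio={cp.ratio:.2f};treated={cp.treated_count}\t0\t.\n"
            )
    tsv(
        "patterns.tsv",
        [
            {
                "contig": p.del_interval.contig,
                "left_bp": p.left_bp,
                "right_bp": p.right_bp,
                "length": p.right_bp - p.left_bp,
                "n_supporting_pairs": p.n_supporting_pairs,
                "n_supporting_splits": p.n_supporting_splits,
                "extent_5p": p.direction_5p_extent,
                "extent_3p": p.direction_3p_extent,
            }
            for p in report.patterns
        ],
    )
    tsv(
        "extents.tsv",
        [
            {
                "guide": report.extents.guide_id,
                "max_3p_extent": report.extents.max_3p_extent,
                "max_5p_extent": report.extents.max_5p_extent,
                "n_patterns": report.extents.n_patterns,
            }
        ],
    )
    tsv(
        "gene_overlap.tsv",
        [
            {
                "gene": g.gene,
                "n_overlapping": g.n_overlapping,
                "n_partial": g.n_partial,
                "n_total": g.n_total,
                "percent": g.percent_1dp,
            }
            for g in report.gene_overlaps
        ],
    )
    tsv(
        "offtarget_scores.tsv",
        [
            {
                "contig": s.region.locus.contig,
                "start": s.region.locus.start,
                "end": s.region.locus.end,
                "kind": s.region.kind,
                "treated_splits": s.treated_splits,
                "control_splits": s.control_splits,
                "score": s.score,
                "flagged": s.flagged,
            }
            for s in report.scores
        ],
    )
    summary = {
        "seed": report.seed,
        "n_candidates": len(report.candidates),
        "guide_id": report.guide.id,
        "n_pot_sites": len(report.pot_sites),
        "n_cut_points": len(report.cut_points),
        "n_patterns": len(report.patterns),
        "max_3p_extent": report.extents.max_3p_extent,
        "max_5p_extent": report.extents.max_5p_extent,
        "gene_overlap_pct": {g.gene: g.percent_1dp for g in report.gene_overlaps},
        "n_flagged_offtargets": sum(
            1 for s in report.scores if s.flagged and s.region.kind == "pot"
        ),
        "on_target_flagged": any(
            s.flagged for s in report.scores if s.region.kind == "on_target"
        ),
        "effective_yield_pct": report.effective_yield_pct,
        "parameters": {
            "design": dataclasses.asdict(config.design),
            "pot": dataclasses.asdict(config.pot),
            "call": dataclasses.asdict(config.call),
            "scoring": dataclasses.asdict(config.scoring),
        },
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the full simulated workflow; deterministic given the seed."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.resolved_sim(), seed=config.seed)

    genome, genes, truth = _stage("make_genome")(make_genome)(sim)
    write_fasta(genome, outdir / "ref.fa")
    write_bed(genes, outdir / "genes.bed")

    target = next(g for g in genes if g.name == sim.target_gene)
    exon = target.three_prime_exon()
    candidates = _stage("design")(design_guides)(
        genome, exon, config.design, gene=target.name, audit=True
    )
    guide = next(
        (
            c
            for c in candidates
            if truth.guide_locus is not None
            and c.locus.start == truth.guide_locus.start
            and c.strand == truth.guide_locus.strand
        ),
        None,
    ) or next((c for c in candidates if c.passes), None)
    if guide is None:
        raise PipelineError("stage 'design': no passing crRNA candidate found")

    pot_sites = _stage("pot_enumeration")(find_pot_sites_cas3)(
        guide, genome, config.pot
    )
    on_target_regions = _stage("capture_regions")(build_capture_regions)(
        [guide.locus], genome, "on_target"
    )
    offtarget_sites = [s for s in pot_sites if not s.is_on_target]
    pot_regions = _stage("capture_regions")(build_capture_regions)(
        offtarget_sites, genome, "pot"
    )
    capture_regions = on_target_regions + pot_regions

    haplotypes = _stage("simulate_deletions")(simulate_deletions)(genome, truth, sim)
    treated_sam = outdir / "treated.sam"
    control_sam = outdir / "control.sam"
    _stage("simulate_reads")(simulate_reads)(
        haplotypes, capture_regions, genome, sim, truth, treated_sam, control_sam
    )
    truth.to_json(outdir / "truth.json")

    call = config.call
    treated = list(read_alignments(treated_sam))
    control = list(read_alignments(control_sam))
    treated_splits = da.extract_split_reads(treated, call.min_clip, call.mapq_floor)
    control_splits = da.extract_split_reads(control, call.min_clip, call.mapq_floor)
    mean, sd = da.estimate_insert_stats(treated)
    tlen_threshold = mean + call.discordant_nsd * sd
    pairs = da.extract_discordant_pairs(treated, tlen_threshold, call.mapq_floor)

    region = on_target_regions[0].locus
    bins = da.bin_split_counts(treated_splits, control_splits, region, call.bin_width)
    cut_points = da.detect_cut_points(bins, call.ratio_threshold, call.min_support)
    patterns = da.infer_deletion_patterns(
        cut_points, pairs, treated_splits, call.merge_tol
    )
    pam = GenomicInterval(
        guide.locus.contig, guide.locus.start, guide.locus.end, guide.strand
    )
    extents = da.summarize_extents(patterns, pam, guide_id=guide.id)
    neighbor_genes = [g for g in genes if g.name != sim.target_gene]
    gene_overlaps = da.annotate_gene_overlap(patterns, neighbor_genes)

    scores = ots.score_pot_sites(
        treated_splits, control_splits, capture_regions, config.scoring.flag_threshold
    )

    report = RunReport(
        seed=config.seed,
        candidates=candidates,
        guide=guide,
        pot_sites=pot_sites,
        capture_regions=capture_regions,
        cut_points=cut_points,
        patterns=patterns,
        extents=extents,
        gene_overlaps=gene_overlaps,
        scores=scores,
        effective_yield_pct=effective_yield_percent(
            config.dko_frequency, config.viability
        ),
        truth=truth,
        genome=genome,
        genes=genes,
    )
    _write_tables(outdir, report, config)
    return report
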
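# Methods

This note documents the models and procedures implemented in `cas3audit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Coordinates and evidence model

All intervals are 0-based half-open on named contigs; SAM input is
converted at the I/O boundary (by pysam) and BED is consumed natively, so
no downstream operation performs coordinate conversion. `N` bases never
match anything in any scan, on either side of a comparison — a
conservative choice that can only suppress candidate guides and POT
calls, never invent them. Alignment records below a mapping-quality floor
(default 20) are excluded from evidence extraction; the floor is exposed
in configuration since aligner defaults do not impose one.

## crRNA design screen

A Type I-E candidate is a 5′-AAG PAM followed by a 32-nt protospacer.
Four criteria, all configurable:

| parameter | default | meaning |
|---|---|---|
| `pam` | AAG | PAM on the candidate strand |
| `gc_min`, `gc_max` | 0.30, 0.70 | spacer GC bounds, **inclusive** ("between 30% and 70%" read inclusively) |
| `window_min`, `window_max` | 100, 500 bp | distance downstream of the target exon |
| `design_mm_max` | 3 | mismatch budget of the uniqueness scan |
| `seed_len` | 15 nt | PAM-proximal seed for the exact-seed uniqueness clause |

"Downstream of the target exon" is measured from the exon's
transcription-direction 3′ boundary to the PAM-proximal protospacer base,
0-based (the first downstream base is at distance 0) and inclusive of
both window bounds. Transcription-oriented measurement is the standard
reading where the anchor is otherwise ambiguous; both strands are scanned
inside the window.

Uniqueness is operationalized as **zero** offending loci: any other locus
matching PAM+protospacer with ≤ `design_mm_max` mismatches (PAM exact, on
either strand), or exactly matching PAM+seed, disqualifies the candidate.
No score threshold is used — the zero-hit reading is the strictest
self-consistent one. The seed clause requires an exact match because no
mismatch budget is defined for it.

## POT enumeration

Cas3 sites qualify under either of two rules, evaluated per genome
position and strand with a vectorized per-position match matrix:

- **consecutive**: a contiguous exact-match run of ≥ `consec_min`
  (default 16) nt to PAM+spacer that overlaps at least one PAM base. Since
  the PAM sits at the 5′ end of the 35-nt pattern, any qualifying run must
  pass through the PAM-adjacent position, which is the run the scanner
  measures. `consec_max` (20) is recorded but not an active bound: longer
  runs obviously still qualify, and the run length is reported.
  A stricter variant requiring all three PAM bases in the run is available
  (`consec_pam_full`).
- **mismatch-tolerant**: PAM exact and ≤ `mm_max_cas3` (default 7)
  Hamming mismatches over the 32-nt spacer. The PAM is excluded from the
  mismatch count because the companion rule names the PAM explicitly while
  this one is defined over the spacer; PAM exactness is the conservative
  reading and is configurable.

Cas9 mode: 20-nt spacer + NGG (N is a pattern wildcard that matches any
concrete base, but never a genomic N) with ≤ 3 spacer mismatches.

Qualifying loci on the same strand starting < 10 bp apart are merged into
one site, keeping fewest mismatches then longest run, to avoid
double-counting one physical site. Both scans are validated site-for-site
against an exhaustive plain-string checker on seeded random genomes.

Capture windows: ±100 kbp of the on-target PAM (the PAM's 5′-most
genomic coordinate); for POT sites, 9 kbp on the PAM-upstream side and
1 kbp downstream **in the site's strand orientation**, because the
asymmetric window only makes sense anchored to the directionality of
Cas3 degradation. Windows are clipped at contig edges with a warning.

## Deletion calling

- Split-read evidence: one item per soft clip ≥ `min_clip` (default
  20 nt, comparable to split-aligner minimums) at either read end; the
  breakpoint is the reference coordinate of the clip boundary.
- Discordant pairs: |template length| above the insert mean + 3 SD
  (estimated from proper pairs) or non-FR orientation — the standard
  structural-variant contract. The pair's span runs from the leftmost
  mate's end to the rightmost mate's start.
- Binning: fixed 100-bp tiling of the capture region. 100 bp resolves
  kilobase-scale deletions while keeping per-bin counts stable; the count
  of binned breakpoints is conserved by construction.
- Cut points: treated/max(control, 1) strictly > `ratio_threshold`
  (default 5; a ratio of exactly 5 does not qualify) **and** treated ≥
  `min_support` (default 3). The pseudo-denominator handles the
  zero-control case with minimal assumptions, and the support floor keeps
  the ratio rule from firing on 1-vs-0 noise.
- Pattern inference: for each cut point, pairs with one span endpoint
  within `merge_tol` (default 150 bp ≈ one read length, matching the
  breakpoint uncertainty of clipped alignments) of the bin midpoint are
  clustered by their far endpoint (single-linkage, same tolerance); each
  cluster becomes one pattern with breakpoints at the medians of the
  clustered inner mate boundaries. Patterns that agree on both breakpoints
  within `merge_tol` across cut points are de-duplicated, keeping the
  better-supported call. Because inner mate boundaries under-shoot the
  true junction by roughly half the inner gap (~50 bp at a 400 ± 60 bp
  insert), median breakpoints land well within the 150-bp tolerance.
- Extents are reported in strand-oriented 5′/3′ terms relative to the
  PAM's 5′-most coordinate. Gene overlap counts a pattern when its deleted
  interval intersects the gene body; *partial* is recorded when the gene
  is not fully contained. Percentages are half-up rounded to one decimal
  (`percent_1dp`), computed in decimal arithmetic to avoid binary-float
  ties.

## Off-target scoring

Cas3: score = treated − control split-read count over each POT capture
region; negative scores are retained as diagnostics but never flagged;
flagging requires score ≥ `flag_threshold` (default 5 — no numeric cutoff
is established in the field, so the threshold is configuration-surfaced).
Cas9 benchmark: a read is edited when any I/D CIGAR op overlaps a ±20 bp
window around the expected cut; adjusted % = max(test − control, 0). Zero
covering reads yield an explicit null result rather than a 0%.

## Synthetic data

The generator emulates the *geometry* of directional-nuclease capture
sequencing, not its biochemistry:

| parameter | default | emulates |
|---|---|---|
| `genome_len` | 400 kb, 1 contig | desk-scale stand-in for a target locus ±100 kb plus POT zones |
| gene layout | target + one neighbor per flank | TRAC flanked by DAD1/ABHD4-style neighbors |
| `n_cells` | 200 | independently edited haplotypes in one library |
| `editing_rate` | 0.6 | fraction of haplotypes carrying a deletion |
| deletion model | one-sided; 3′ arm ~ Geometric(mean 20 kb, truncated at 100 kb) with prob `direction_bias` = 0.8, else 5′ arm ~ Geometric(mean 2 kb); anchor jittered ±50 bp | long-range unidirectional degradation from the cut, with a minority of short reverse-direction events |
| reads | 2×150 bp, insert 400 ± 60 bp, 200× over capture regions | paired-end capture sequencing |
| noise | 0.2% of reads get a uniform 5–15 nt soft clip, both libraries | alignment-edge artifacts |
| `pot_plants` | one site each at 4, 5 and 7 spacer mismatches | POT sites at known mismatch distances |

Choices that warrant a word: the geometric length family was chosen for
its heavy right tail reaching the tens-of-kilobase maxima seen in real
directional-degradation data — no claim is made that it is the true Cas3
lesion distribution. Planted POT sites carry ≥ 4 mismatches by default
and always at least one mismatch inside the 15-nt seed, because a planted
site inside the design-time uniqueness budget would contradict the
premise that the guide passed the design screen. Fragments crossing a
deletion breakpoint are written with the longer segment aligned and the
shorter soft-clipped, as a breakpoint-aware aligner reports them; reads
whose clipped side is shorter than `min_clip` are (realistically) lost to
split-read extraction. Reads are emitted without base sequences (SEQ
`*`), since all downstream evidence is positional/CIGAR-based.

What the simulator does **not** model: substitution sequencing errors
(irrelevant to split/discordant evidence), PCR duplicates, capture-probe
efficiency bias, repetitive or low-complexity genomic context,
multi-deletion haplotypes, and inversions/translocations. Passing tests
therefore demonstrate correctness of the calling logic under idealized
mappability, not performance on real repetitive genomes.

At the default conditions the library covers each haplotype at roughly
1× (200× total / 200 haplotypes), so cut points — which pool split reads
across all haplotypes — are detected robustly, while only occasional
individual deletions accumulate ≥ 5 spanning pairs. Recovery statements
are therefore conditioned on that support level; the suite additionally
verifies 100% breakpoint recovery under a well-powered configuration
(5 fully edited haplotypes at the same depth, i.e. 40× per haplotype).

## Determinism and problem sizes

Every stochastic stage draws from `numpy.random.Generator` streams seeded
per stage from the run seed; identical configurations produce
byte-identical SAM, TSV and JSON outputs. The test suite runs the full
default workflow at seeds 1–10; oracle-equivalence checks use ten 25–30 kb
random genomes with planted near-misses, a size at which the exhaustive
per-position checker remains practical while still exercising both
strands, both rules and the merge logic. The acceptance script uses three
default-condition runs plus three well-powered runs for the recovery
measurement.

## Known limitations

- Uniqueness and POT scans are exact-Hamming; DNA/RNA-bulge off-target
  classes are out of scope.
- Pattern inference assumes deletions share a breakpoint near a detected
  cut point; a deletion whose both endpoints lie far from every cut point
  (e.g. from a mis-specified capture region) would be missed.
- The cut-point rule inherits the bin width: breakpoints straddling a bin
  boundary split their support across two bins (both are usually still
  detected, as in the worked example).
- `annotate_gene_overlap` reports per-gene fractions of *called* patterns;
  at low per-haplotype coverage the called set under-represents planted
  deletions without pair support, so fractions are estimates of the
  pattern population, not of all edited cells.
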
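"""POT scanning (Cas3 and Cas9) against exhaustive oracles, plus capture
window construction."""

import numpy as np
import pytest

from cas3audit.genome_io import GenomeIOError, GenomicInterval, ReferenceGenome, reverse_complement
from cas3audit.pot_enumeration import (
    PotParams,
    PotSite,
    build_capture_regions,
    find_pot_sites_cas3,
    find_pot_sites_cas9,
)

import oracles
from conftest import random_sequence

SPACER = "ACGTACGTACGTACGTACGTACGTACGTACGT"
SITE = "AAG" + SPACER
GUIDE20 = "ACGTACGTACGTACGTACGT"


def plant(seq, pos, insert):
    return seq[:pos] + insert + seq[pos + len(insert) :]


def mutate(site, positions):
    out = list(site)
    for p in positions:
        out[p] = "C" if out[p] != "C" else "A"
    return "".join(out)


class TestCas3:
    def test_exact_copy_reported_as_both(self):
        rng = np.random.default_rng(1)
        seq = plant(random_sequence(rng, 5000), 2000, SITE)
        sites = find_pot_sites_cas3(SITE, ReferenceGenome({"c": seq}))
        exact = [s for s in sites if s.locus.start == 2000 and s.strand == "+"]
        assert len(exact) == 1
        assert exact[0].rule == "both"
        assert exact[0].n_mismatches == 0
        assert exact[0].longest_pam_anchored_run == 35
        assert exact[0].aligned_site_seq == SITE

    def test_fails_both_rules_not_reported(self):
        # PAM exact, 8 spacer mismatches, longest PAM-anchored run 15
        # (first mismatch at spacer position 12 = site position 15)
        bad = mutate(SITE, [15, 17, 19, 21, 23, 25, 27, 29])
        rng = np.random.default_rng(2)
        seq = plant(random_sequence(rng, 5000), 2000, bad)
        sites = find_pot_sites_cas3(SITE, ReferenceGenome({"c": seq}))
        assert not any(s.locus.start == 2000 for s in sites)

    def test_seven_mismatches_reported_minus_strand(self):
        ok = mutate(SITE, [4, 8, 12, 16, 20, 24, 28])
        rng = np.random.default_rng(3)
        seq = plant(random_sequence(rng, 5000), 2000, reverse_complement(ok))
        sites = find_pot_sites_cas3(SITE, ReferenceGenome({"c": seq}))
        hit = [s for s in sites if s.locus.start == 2000]
        assert len(hit) == 1
        assert hit[0].strand == "-"
        assert hit[0].n_mismatches == 7
        assert hit[0].rule == "mismatch_tolerant"

    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_oracle_equivalence_random_genome(self, seed):
        rng = np.random.default_rng(seed)
        seq = plant(random_sequence(rng, 20_000), 9000, SITE)
        # sprinkle near-misses at known offsets
        seq = plant(seq, 1000, mutate(SITE, [5, 9, 13]))
        seq = plant(seq, 15_000, reverse_complement(mutate(SITE, [30, 31, 32, 33, 34])))
        params = PotParams(merge_offset=0)
        sites = find_pot_sites_cas3(SITE, ReferenceGenome({"c": seq}), params)
        got = {(s.locus.start, s.strand, s.rule) for s in sites}
        assert got == oracles.brute_force_pot_cas3(seq, SITE)

    def test_monotonicity_in_budgets(self):
        rng = np.random.default_rng(104)
        seq = plant(random_sequence(rng, 20_000), 9000, SITE)
        seq = plant(seq, 3000, mutate(SITE, [6, 10, 14, 18]))
        genome = ReferenceGenome({"c": seq})
        base = {
            (s.locus.start, s.strand)
            for s in find_pot_sites_cas3(SITE, genome, PotParams())
        }
        looser = {
            (s.locus.start, s.strand)
            for s in find_pot_sites_cas3(
                SITE, genome, PotParams(mm_max_cas3=9, consec_min=12)
            )
        }
        assert base <= looser


class TestCas9:
    def test_exact_planted_site(self):
        rng = np.random.default_rng(5)
        seq = plant(random_sequence(rng, 5000), 2500, GUIDE20 + "AGG")
        sites = find_pot_sites_cas9(GUIDE20, ReferenceGenome({"c": seq}))
        hit = [s for s in sites if s.locus.start == 2500 and s.strand == "+"]
        assert len(hit) == 1 and hit[0].n_mismatches == 0

    def test_four_mismatches_excluded(self):
        bad = mutate(GUIDE20, [2, 7, 11, 16]) + "TGG"
        rng = np.random.default_rng(6)
        seq = plant(random_sequence(rng, 5000), 2500, bad)
        sites = find_pot_sites_cas9(GUIDE20, ReferenceGenome({"c": seq}))
        assert not any(s.locus.start == 2500 for s in sites)

    @pytest.mark.parametrize("seed", [111, 112, 113])
    def test_oracle_equivalence_random_genome(self, seed):
        rng = np.random.default_rng(seed)
        seq = plant(random_sequence(rng, 20_000), 9000, GUIDE20 + "CGG")
        seq = plant(seq, 4000, mutate(GUIDE20, [3, 8]) + "GGG")
        params = PotParams(mode="cas9", merge_offset=0)
        sites = find_pot_sites_cas9(GUIDE20, ReferenceGenome({"c": seq}), params)
        got = {(s.locus.start, s.strand) for s in sites}
        assert got == oracles.brute_force_pot_cas9(seq, GUIDE20)


def test_merging_keeps_best_site():
    from cas3audit.pot_enumeration import _merge_sites

    def site(start, mm, run):
        return PotSite(
            locus=GenomicInterval("c", start, start + 35, "+"),
            strand="+",
            rule="mismatch_tolerant",
            longest_pam_anchored_run=run,
            n_mismatches=mm,
            aligned_site_seq="",
        )

    merged = _merge_sites([site(100, 5, 10), site(104, 2, 20), site(130, 3, 8)], 10)
    assert [(s.locus.start, s.n_mismatches) for s in merged] == [(104, 2), (130, 3)]


def test_linear_growth_of_random_pot_count():
    """On i.i.d. sequence the expected POT count is proportional to genome
    length (checked with a permissive consecutive-run rule so that counts
    are non-trivial)."""
    params = PotParams(consec_min=6, mm_max_cas3=0, merge_offset=0)

    def counts(length, seeds):
        vals = []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            genome = ReferenceGenome({"c": random_sequence(rng, length)})
            vals.append(len(find_pot_sites_cas3(SITE, genome, params)))
        return np.array(vals, dtype=float)

    seeds = range(300, 310)
    c1, c2 = counts(30_000, seeds), counts(60_000, seeds)
    diff = c2.mean() - 2 * c1.mean()
    sem = np.sqrt(c2.var(ddof=1) / 10 + 4 * c1.var(ddof=1) / 10)
    assert abs(diff) <= 3 * sem + 1e-9


class TestCaptureRegions:
    @pytest.fixture()
    def genome(self):
        rng = np.random.default_rng(7)
        return ReferenceGenome({"c": random_sequence(rng, 400_000)})

    def test_on_target_window(self, genome):
        locus = GenomicInterval("c", 150_000, 150_035, "+")
        (r,) = build_capture_regions([locus], genome, "on_target")
        assert (r.locus.start, r.locus.end) == (50_000, 250_000)

    def test_pot_window_plus_strand(self, genome):
        site = PotSite(
            locus=GenomicInterval("c", 20_000, 20_035, "+"),
            strand="+", rule="both", longest_pam_anchored_run=35,
            n_mismatches=0, aligned_site_seq="",
        )
        (r,) = build_capture_regions([site], genome, "pot")
        assert (r.locus.start, r.locus.end) == (11_000, 21_035)

    def test_pot_window_minus_strand_mirrored(self, genome):
        site = PotSite(
            locus=GenomicInterval("c", 20_000, 20_035, "-"),
            strand="-", rule="both", longest_pam_anchored_run=35,
            n_mismatches=0, aligned_site_seq="",
        )
        (r,) = build_capture_regions([site], genome, "pot")
        assert (r.locus.start, r.locus.end) == (19_000, 29_035)

    def test_clipped_at_contig_edge(self, genome):
        locus = GenomicInterval("c", 3000, 3035, "+")
        site = PotSite(
            locus=locus, strand="+", rule="both",
            longest_pam_anchored_run=35, n_mismatches=0, aligned_site_seq="",
        )
        (r,) = build_capture_regions([site], genome, "pot")
        assert r.locus.start == 0

    def test_anchor_outside_contig_errors(self, genome):
        with pytest.raises(GenomeIOError):
            build_capture_regions(
                [GenomicInterval("c", 500_000, 500_035, "+")], genome, "on_target"
            )
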
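"""Independent brute-force oracles used to validate the optimized scans.

Everything here is written as plain per-position string comparison with no
shared code with the package's vectorized implementations.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def hamming(a: str, b: str) -> int:
    """Mismatch count where N on either side always mismatches."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def site_on_strand(seq: str, pos: int, length: int, strand: str) -> str:
    window = seq[pos : pos + length]
    return window if strand == "+" else rc(window)


def brute_force_candidates(
    seq: str,
    exon_start: int,
    exon_end: int,
    exon_strand: str,
    pam: str = "AAG",
    spacer_len: int = 32,
    gc_min: float = 0.30,
    gc_max: float = 0.70,
    window_min: int = 100,
    window_max: int = 500,
) -> set[tuple[int, str]]:
    """All (site_start, strand) passing PAM/GC/window, scanning every position."""
    out = set()
    site_len = len(pam) + spacer_len
    for start in range(0, len(seq) - site_len + 1):
        for strand in ("+", "-"):
            site = site_on_strand(seq, start, site_len, strand)
            if site[: len(pam)] != pam or "N" in site:
                continue
            spacer = site[len(pam) :]
            gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
            if not (gc_min <= gc <= gc_max):
                continue
            # genomic coordinate of the PAM-proximal protospacer base
            q = start + len(pam) if strand == "+" else start + spacer_len - 1
            if exon_strand == "-":
                dist = (exon_start - 1) - q
            else:
                dist = q - exon_end
            if window_min <= dist <= window_max:
                out.add((start, strand))
    return out


def brute_force_uniqueness_hits(
    seq: str,
    site: str,
    own: tuple[int, str],
    mm_max: int = 3,
    pam_len: int = 3,
    seed_len: int = 15,
) -> list[tuple[int, str, str]]:
    """All offending (start, strand, rule) loci for the uniqueness filter."""
    hits = []
    m = len(site)
    seed = site[: pam_len + seed_len]
    for start in range(0, len(seq) - m + 1):
        for strand in ("+", "-"):
            window = site_on_strand(seq, start, m, strand)
            if (
                window[:pam_len] == site[:pam_len]
                and hamming(window[pam_len:], site[pam_len:]) <= mm_max
                and (start, strand) != own
            ):
                hits.append((start, strand, "mismatch"))
    for start in range(0, len(seq) - len(seed) + 1):
        for strand in ("+", "-"):
            window = site_on_strand(seq, start, len(seed), strand)
            own_seed_start = own[0] if own[1] == "+" else own[0] + m - len(seed)
            if window == seed and (start, strand) != (own_seed_start, own[1]):
                hits.append((start, strand, "seed"))
    return hits


def _pam_anchored_run(site: str, pattern: str, pam_len: int) -> int:
    """Longest exact-match run through the PAM-adjacent position."""
    match = [
        a == b and a != "N" and b != "N" for a, b in zip(site, pattern)
    ]
    anchor = pam_len - 1
    if not match[anchor]:
        return 0
    run = 1
    j = anchor - 1
    while j >= 0 and match[j]:
        run += 1
        j -= 1
    j = anchor + 1
    while j < len(match) and match[j]:
        run += 1
        j += 1
    return run


def brute_force_pot_cas3(
    seq: str,
    site: str,
    consec_min: int = 16,
    mm_max: int = 7,
    pam_len: int = 3,
) -> set[tuple[int, str, str]]:
    """All (start, strand, rule) Cas3 POT loci by exhaustive scanning."""
    out = set()
    m = len(site)
    for start in range(0, len(seq) - m + 1):
        for strand in ("+", "-"):
            window = site_on_strand(seq, start, m, strand)
            pam_ok = window[:pam_len] == site[:pam_len] and "N" not in window[:pam_len]
            mm = hamming(window[pam_len:], site[pam_len:])
            mm_rule = pam_ok and mm <= mm_max
            consec = _pam_anchored_run(window, site, pam_len) >= consec_min
            if mm_rule or consec:
                rule = (
                    "both"
                    if mm_rule and consec
                    else ("mismatch_tolerant" if mm_rule else "consecutive")
                )
                out.add((start, strand, rule))
    return out


def brute_force_pot_cas9(
    seq: str, guide20: str, mm_max: int = 3
) -> set[tuple[int, str]]:
    """All (start, strand) Cas9 POT loci (NGG PAM, N wildcard) by scanning."""
    out = set()
    m = 23
    for start in range(0, len(seq) - m + 1):
        for strand in ("+", "-"):
            window = site_on_strand(seq, start, m, strand)
            pam = window[20:]
            if pam[0] == "N" or pam[1:] != "GG":
                continue
            if hamming(window[:20], guide20) <= mm_max:
                out.add((start, strand))
    return out
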
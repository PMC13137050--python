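"""Vectorized per-position pattern matching over encoded genomes.

Bases are encoded A=0, C=1, G=2, T=3, N=4. An N never matches on either
side of a comparison; a *wildcard* pattern position (e.g. the N of an NGG
PAM) matches any concrete base but still not a genomic N.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i

_N = 4


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes."""
    arr = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return arr


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement in code space (A<->T, C<->G, N fixed)."""
    out = codes.copy()
    concrete = codes < _N
    out[concrete] = 3 - codes[concrete]
    return out


def match_matrix(
    gcodes: np.ndarray,
    pcodes: np.ndarray,
    wildcard: frozenset[int] | set[int] = frozenset(),
) -> np.ndarray:
    """Boolean matrix M[j, i]: does genome base i+j match pattern base j?

    One row per pattern position, one column per genome start position
    (there are ``len(gcodes) - len(pcodes) + 1`` valid starts).
    """
    m, n = len(pcodes), len(gcodes) - len(pcodes) + 1
    if n <= 0:
        return np.zeros((m, 0), dtype=bool)
    M = np.empty((m, n), dtype=bool)
    for j in range(m):
        g = gcodes[j : j + n]
        if j in wildcard:
            M[j] = g != _N
        else:
            M[j] = (g == pcodes[j]) & (pcodes[j] != _N) & (g != _N)
    return M


def match_rows_oriented(
    gcodes: np.ndarray,
    pcodes: np.ndarray,
    strand: str,
    wildcard: frozenset[int] | set[int] = frozenset(),
) -> np.ndarray:
    """Match matrix with rows in *pattern* order for either strand.

    A minus-strand site at [i, i+m) matches the pattern iff the reverse
    complement of the genomic slice equals the pattern; this is scanned as
    the forward comparison against the reverse-complemented pattern, then
    rows are flipped back into pattern order so that callers can treat PAM
    and spacer positions identically on both strands.
    """
    if strand == "+":
        return match_matrix(gcodes, pcodes, wildcard)
    m = len(pcodes)
    rc = complement_codes(pcodes)[::-1].copy()
    wc = {m - 1 - j for j in wildcard}
    return match_matrix(gcodes, rc, wc)[::-1]
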
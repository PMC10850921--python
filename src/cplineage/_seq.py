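"""Low-level DNA string utilities shared across modules.

Coordinates here are 0-based half-open unless a function says otherwise;
public modules expose 1-based inclusive coordinates matching the marker
tables.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def is_dna(seq: str, allow: str = "ACGTN") -> bool:
    return not set(seq) - set(allow)


def is_homopolymer(s: str) -> bool:
    return len(s) > 0 and len(set(s)) == 1


def run_left(s: str, i: int, base: str) -> int:
    """Length of the run of `base` ending just before index i (exclusive)."""
    n = 0
    j = i - 1
    while j >= 0 and s[j] == base:
        n += 1
        j -= 1
    return n


def run_right(s: str, i: int, base: str) -> int:
    """Length of the run of `base` starting at index i."""
    n = 0
    j = i
    while j < len(s) and s[j] == base:
        n += 1
        j += 1
    return n


def max_adjacent_run(s: str, start: int, end: int) -> int:
    """Longest homopolymer run immediately flanking the window [start, end)."""
    best = 0
    if start > 0:
        best = max(best, run_left(s, start, s[start - 1]))
    if end < len(s):
        best = max(best, run_right(s, end, s[end]))
    return best


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (contiguous) of a and b."""
    if not a or not b:
        return 0
    # small inputs only; O(|a||b|) DP
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def deletion_placements(longer: str, j: int, length: int) -> list[int]:
    """All start offsets j' such that deleting longer[j':j'+length] yields the
    same shorter string as deleting longer[j:j+length].

    An indel inside a repeat has several equivalent alignments; motif calls
    consider all of them.
    """
    out = [j]
    k = j
    while k - 1 >= 0 and longer[k - 1] == longer[k + length - 1]:
        k -= 1
        out.append(k)
    k = j
    while k + length < len(longer) and longer[k] == longer[k + length]:
        k += 1
        out.append(k)
    return sorted(out)


def left_normalize(longer: str, j: int, length: int) -> int:
    """Leftmost equivalent placement of the window [j, j+length) in `longer`."""
    while j - 1 >= 0 and longer[j - 1] == longer[j + length - 1]:
        j -= 1
    return j


def apply_anchored_variants(ref: str, variants) -> str:
    """Apply anchored (pos0, ref_allele, alt_allele) edits to `ref`.

    pos0 is the 0-based position of the anchor base; ref_allele/alt_allele are
    VCF-style (anchor base included, one a strict prefix of the other for pure
    indels; SNPs are single-base/single-base). Variants must not overlap.
    """
    edits = sorted(variants, key=lambda v: v[0], reverse=True)
    seq = ref
    for pos0, ra, aa in edits:
        if seq[pos0:pos0 + len(ra)] != ra:
            raise ValueError(
                f"reference mismatch at {pos0}: expected {ra!r}, "
                f"found {seq[pos0:pos0 + len(ra)]!r}"
            )
        seq = seq[:pos0] + aa + seq[pos0 + len(ra):]
    return seq
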
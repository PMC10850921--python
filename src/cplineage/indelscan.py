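"""Whole-plastome pairwise alignment, INDEL extraction and motif typing.

The module aligns complete chloroplast genomes end to end, turns gap runs
into anchored, left-normalized INDEL records, applies the read-screening
thresholds used for candidate variants (coverage > 200, allele fraction
> 60%), and classifies every INDEL's repeat structure into the four motif
classes used for cpINDEL markers: single-nucleotide repeat, tandem
duplication, SSR (microsatellite) and no-motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import (
    deletion_placements,
    is_dna,
    is_homopolymer,
    longest_common_substring,
    max_adjacent_run,
    apply_anchored_variants,
)

GAP = "-"

MOTIF_SNR = "single_nucleotide_repeat"
MOTIF_TANDEM = "tandem"
MOTIF_SSR = "ssr"
MOTIF_NONE = "no_motif"

#: locus-level precedence when several classes match. Calibrated on the
#: published cpINDEL panel: loci whose events sit in long mononucleotide
#: runs are conventionally reported as single-nucleotide repeats even when
#: a tandem or microsatellite structure is also present nearby.
MOTIF_PRECEDENCE = (MOTIF_SNR, MOTIF_SSR, MOTIF_TANDEM)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignParams:
    """Affine scoring for global DNA alignment.

    Defaults favour one long gap over scattered short ones, which is the
    right bias for discrete INDELs between near-identical plastomes.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    anchor_k: int = 21
    anchor_min_length: int = 5000  # below this, plain DP


@dataclass
class PairwiseAlignment:
    """A global end-to-end pairwise alignment with gap symbol '-'."""

    ref_id: str
    qry_id: str
    aligned_ref: str
    aligned_qry: str

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_qry):
            raise ValueError("aligned rows differ in length")
        for a, b in zip(self.aligned_ref, self.aligned_qry):
            if a == GAP and b == GAP:
                raise ValueError("column with gaps in both rows")

    @property
    def ref_seq(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def qry_seq(self) -> str:
        return self.aligned_qry.replace(GAP, "")

    def ref_positions(self) -> np.ndarray:
        """1-based ungapped reference coordinate per column (0 at gap columns
        before the first reference base)."""
        ref = np.frombuffer(self.aligned_ref.encode(), dtype="S1")
        return np.cumsum(ref != GAP.encode())

    def identity(self) -> float:
        same = sum(
            a == b
            for a, b in zip(self.aligned_ref, self.aligned_qry)
            if a != GAP and b != GAP
        )
        cols = sum(
            1
            for a, b in zip(self.aligned_ref, self.aligned_qry)
            if a != GAP and b != GAP
        )
        return same / cols if cols else 0.0


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # Biopython scores a length-L gap as open + (L-1)*extend; the intended
    # cost is open + L*extend.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _dp_align(a: str, b: str, params: AlignParams) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return GAP * len(b), b
    if not b:
        return a, GAP * len(a)
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    # Alignment.__str__ wraps long rows; rebuild from aligned coordinates
    ra, rb = [], []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        if sa > pa:
            ra.append(a[pa:sa])
            rb.append(GAP * (sa - pa))
        if sb > pb:
            ra.append(GAP * (sb - pb))
            rb.append(b[pb:sb])
        ra.append(a[sa:ea])
        rb.append(b[sb:eb])
        pa, pb = ea, eb
    if pa < len(a):
        ra.append(a[pa:])
        rb.append(GAP * (len(a) - pa))
    if pb < len(b):
        ra.append(GAP * (len(b) - pb))
        rb.append(b[pb:])
    return "".join(ra), "".join(rb)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def _chain_anchors(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Longest colinear chain (increasing in both coordinates) of anchor
    start pairs, then merged so consecutive anchors do not overlap."""
    if not pairs:
        return []
    pairs.sort()
    # longest increasing subsequence on the second coordinate (patience)
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for idx, (_, q) in enumerate(pairs):
        pos = bisect.bisect_left(tails, q)
        if pos == len(tails):
            tails.append(q)
            tails_idx.append(idx)
        else:
            tails[pos] = q
            tails_idx[pos] = idx
        prev[idx] = tails_idx[pos - 1] if pos > 0 else -1
    chain = []
    cur = tails_idx[-1]
    while cur != -1:
        chain.append(pairs[cur])
        cur = prev[cur]
    chain.reverse()
    # drop anchors that overlap their predecessor in either sequence
    merged: list[tuple[int, int]] = []
    for a, b in chain:
        if merged and (a < merged[-1][0] + k or b < merged[-1][1] + k):
            continue
        merged.append((a, b))
    return merged


def align_pair(
    a: str,
    b: str,
    params: AlignParams | None = None,
    ref_id: str = "ref",
    qry_id: str = "qry",
) -> PairwiseAlignment:
    """Global end-to-end alignment of two genome sequences.

    For long, near-identical inputs the sequences are anchored on unique
    shared k-mers chained colinearly; dynamic programming with the affine
    scoring of `params` is run between anchors, which yields the same
    alignment as full DP would on each inter-anchor segment.
    """
    params = params or AlignParams()
    for name, s in ((ref_id, a), (qry_id, b)):
        if not s:
            raise ValueError(f"empty sequence: {name}")
        if not is_dna(s):
            bad = sorted(set(s) - set("ACGTN"))
            raise ValueError(f"non-ACGTN characters in {name}: {bad}")

    if min(len(a), len(b)) < params.anchor_min_length:
        ra, rb = _dp_align(a, b, params)
        return PairwiseAlignment(ref_id, qry_id, ra, rb)

    k = params.anchor_k
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    shared = [(ka[m], kb[m]) for m in ka.keys() & kb.keys()]
    anchors = _chain_anchors(shared, k)
    if not anchors:
        ra, rb = _dp_align(a, b, params)
        return PairwiseAlignment(ref_id, qry_id, ra, rb)

    out_a: list[str] = []
    out_b: list[str] = []
    pa = pb = 0
    for sa, sb in anchors + [(len(a), len(b))]:
        seg_a, seg_b = a[pa:sa], b[pb:sb]
        if seg_a or seg_b:
            ra, rb = _dp_align(seg_a, seg_b, params)
            out_a.append(ra)
            out_b.append(rb)
        if sa < len(a):
            out_a.append(a[sa:sa + k])
            out_b.append(b[sb:sb + k])
            pa, pb = sa + k, sb + k
    return PairwiseAlignment(ref_id, qry_id, "".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# variant records


@dataclass(frozen=True)
class IndelVariant:
    """A reference-anchored, left-normalized insertion or deletion.

    ref_pos is the 1-based position of the anchor base (the last matching
    base before the event); ref_allele and alt_allele are VCF-style, so one
    is a strict prefix of the other and length = len(alt) - len(ref) is the
    signed event size.
    """

    ref_pos: int
    ref_allele: str
    alt_allele: str
    motif_class: frozenset = frozenset()
    primary_class: str | None = None
    coverage: int | None = None
    allele_fraction: float | None = None

    def __post_init__(self) -> None:
        ra, aa = self.ref_allele, self.alt_allele
        if len(ra) == len(aa):
            raise ValueError("not an indel: alleles have equal length")
        short, long_ = sorted((ra, aa), key=len)
        # suffix anchoring only for events at reference position 1, which
        # have no base before them (VCF convention)
        if not (long_.startswith(short)
                or (self.ref_pos == 1 and long_.endswith(short))):
            raise ValueError("one allele must be a strict prefix of the other")

    @property
    def length(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_insertion(self) -> bool:
        return self.length > 0

    @property
    def inserted_or_deleted(self) -> str:
        longer = self.alt_allele if self.is_insertion else self.ref_allele
        return longer[len(self.ref_allele if self.is_insertion else self.alt_allele):]


def normalize_indel(ref: str, pos0: int, ref_allele: str, alt_allele: str
                    ) -> tuple[int, str, str]:
    """Left-normalize an anchored indel against the reference (0-based pos)."""
    if len(ref_allele) == len(alt_allele):
        raise ValueError("not an indel")
    ins = len(alt_allele) > len(ref_allele)
    u = (alt_allele if ins else ref_allele)[1:]
    L = len(u)

    def shift_left(seq: str, j: int) -> int:
        # leftmost equivalent placement that still leaves an anchor base
        while j - 1 >= 1 and seq[j - 1] == seq[j + L - 1]:
            j -= 1
        return j

    if ins:
        # window in the longer sequence ref[:pos0+1] + u + ref[pos0+1:]
        longer = ref[:pos0 + 1] + u + ref[pos0 + 1:]
        j = shift_left(longer, pos0 + 1)
        anchor = j - 1
        new_u = longer[j:j + L]
        return anchor, ref[anchor], ref[anchor] + new_u
    j = shift_left(ref, pos0 + 1)
    anchor = j - 1
    return anchor, ref[anchor:anchor + L + 1], ref[anchor]


def extract_indels(aln: PairwiseAlignment) -> list[IndelVariant]:
    """Maximal gap runs of an alignment as left-normalized IndelVariants,
    sorted by reference position (1-based)."""
    ref, qry = aln.aligned_ref, aln.aligned_qry
    out: list[IndelVariant] = []
    ref_ungapped = aln.ref_seq
    rpos = -1  # 0-based index of last consumed reference base
    i = 0
    n = len(ref)
    while i < n:
        if ref[i] == GAP:  # insertion in query
            j = i
            while j < n and ref[j] == GAP:
                j += 1
            ins = qry[i:j]
            if rpos < 0:
                raise ValueError("insertion before first reference base")
            p0, ra, aa = normalize_indel(ref_ungapped, rpos, ref_ungapped[rpos],
                                         ref_ungapped[rpos] + ins)
            out.append(IndelVariant(p0 + 1, ra, aa))
            i = j
        elif qry[i] == GAP:  # deletion from query
            j = i
            while j < n and qry[j] == GAP:
                j += 1
            start = rpos + 1  # first deleted ref base, 0-based
            dele = ref[i:j]
            if start == 0:
                # deletion at the very start has no left anchor; anchor on the
                # base after the run instead (kept un-normalized)
                out.append(IndelVariant(1, dele + ref_ungapped[start + len(dele)],
                                        ref_ungapped[start + len(dele)]))
            else:
                p0, ra, aa = normalize_indel(
                    ref_ungapped, start - 1,
                    ref_ungapped[start - 1:start + len(dele)],
                    ref_ungapped[start - 1])
                out.append(IndelVariant(p0 + 1, ra, aa))
            rpos += len(dele)
            i = j
        else:
            rpos += 1
            i += 1
    return sorted(out, key=lambda v: v.ref_pos)


def extract_snps(aln: PairwiseAlignment) -> list[tuple[int, str, str]]:
    """Mismatch columns as (1-based ref position, ref base, query base)."""
    out = []
    rpos = 0
    for a, b in zip(aln.aligned_ref, aln.aligned_qry):
        if a != GAP:
            rpos += 1
            if b != GAP and a != b:
                out.append((rpos, a, b))
    return out


def apply_variants(ref: str, indels, snps=()) -> str:
    """Rebuild a query sequence from the reference plus extracted variants
    (round-trip check for extract_indels/extract_snps)."""
    edits = [(v.ref_pos - 1, v.ref_allele, v.alt_allele) for v in indels]
    edits += [(p - 1, a, b) for p, a, b in snps]
    return apply_anchored_variants(ref, edits)


# ---------------------------------------------------------------------------
# candidate filtering


@dataclass(frozen=True)
class FilterSpec:
    """Screen for NGS variant candidates: keep a candidate only with
    coverage strictly above min_coverage and allele fraction strictly above
    min_fraction."""

    min_coverage: int = 200
    min_fraction: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")


def filter_candidates(candidates: pd.DataFrame,
                      spec: FilterSpec | None = None) -> pd.DataFrame:
    """Retain rows with coverage > min_coverage and allele_fraction >
    min_fraction (both strict), preserving input order."""
    spec = spec or FilterSpec()
    for col in ("coverage", "allele_fraction"):
        if col not in candidates.columns:
            raise ValueError(f"candidate table lacks required column {col!r}")
        bad = candidates.index[candidates[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col} in row {bad[0]}")
    keep = (candidates["coverage"] > spec.min_coverage) & (
        candidates["allele_fraction"] > spec.min_fraction)
    return candidates.loc[keep]


# ---------------------------------------------------------------------------
# motif classification

#: a homopolymer allele of at least this length is a single-nucleotide
#: repeat on its own
SNR_MIN_ALLELE = 5
#: ... or any allele whose merged/adjacent mononucleotide run reaches this
SNR_MIN_RUN = 8
#: minimum shared substring with the adjacent window for a (partial) tandem
TANDEM_MIN_WORD = 4
#: microsatellite array: unit 2-6 nt with at least this many exact copies
SSR_MIN_COPIES = 3
SSR_UNIT_RANGE = (2, 6)
#: an event this close to (or overlapping) a microsatellite is SSR-class
SSR_MAX_DISTANCE = 10


def _is_snr(longer: str, j: int, L: int) -> bool:
    u = longer[j:j + L]
    if is_homopolymer(u):
        if L >= SNR_MIN_ALLELE:
            return True
        # merged run: allele plus flanking run(s) of the same base
        left = right = 0
        b = u[0]
        k = j - 1
        while k >= 0 and longer[k] == b:
            left += 1
            k -= 1
        k = j + L
        while k < len(longer) and longer[k] == b:
            right += 1
            k += 1
        return L + left + right >= SNR_MIN_RUN
    return max_adjacent_run(longer, j, j + L) >= SNR_MIN_RUN


def _is_tandem(longer: str, j: int, L: int) -> bool:
    u = longer[j:j + L]
    if L < 2 or is_homopolymer(u):
        return False
    left, right = longer[:j], longer[j + L:]
    if left.endswith(u) or right.startswith(u):
        return True
    thr = max(TANDEM_MIN_WORD, math.ceil(L / 2))
    if thr > L:
        return False
    if longest_common_substring(u, left[-L:]) >= thr:
        return True
    return longest_common_substring(u, right[:L]) >= thr


def microsatellite_arrays(s: str,
                          unit_range: tuple[int, int] = SSR_UNIT_RANGE,
                          min_copies: int = SSR_MIN_COPIES
                          ) -> list[tuple[int, int, int]]:
    """Exact tandem arrays of a non-homopolymer 2-6 nt unit with at least
    `min_copies` copies, as (start, end, unit_length) half-open windows."""
    out = []
    n = len(s)
    for p in range(unit_range[0], unit_range[1] + 1):
        i = 0
        while i + min_copies * p <= n:
            unit = s[i:i + p]
            if is_homopolymer(unit):
                i += 1
                continue
            k = i + p
            while s[k:k + p] == unit:
                k += p
            if (k - i) // p >= min_copies:
                out.append((i, k, p))
            i += 1
    return out


def _is_ssr(longer: str, j: int, L: int) -> bool:
    lo = max(0, j - SSR_MAX_DISTANCE - SSR_MIN_COPIES * SSR_UNIT_RANGE[1])
    hi = min(len(longer), j + L + SSR_MAX_DISTANCE
             + SSR_MIN_COPIES * SSR_UNIT_RANGE[1])
    for a, b, _p in microsatellite_arrays(longer[lo:hi]):
        a += lo
        b += lo
        gap = max(a - (j + L), j - b, 0)
        if gap <= SSR_MAX_DISTANCE:
            return True
    return False


def classify_gap(longer: str, j: int, L: int) -> frozenset:
    """Motif classes of a gap of length L at window [j, j+L) of the longer
    allele's sequence, considering every equivalent placement."""
    if L <= 0 or j < 0 or j + L > len(longer):
        raise ValueError("gap window outside the provided context")
    classes = set()
    for k in deletion_placements(longer, j, L):
        if _is_ssr(longer, k, L):
            classes.add(MOTIF_SSR)
        if _is_snr(longer, k, L):
            classes.add(MOTIF_SNR)
        if _is_tandem(longer, k, L):
            classes.add(MOTIF_TANDEM)
    return frozenset(classes)


def primary_class(classes: frozenset) -> str:
    for c in MOTIF_PRECEDENCE:
        if c in classes:
            return c
    return MOTIF_NONE


def classify_motif(v: IndelVariant, reference: str, window: int = 30
                   ) -> IndelVariant:
    """Classify an indel against its reference context (±window nt) and
    return a copy carrying motif_class / primary_class."""
    u = v.inserted_or_deleted
    if window < len(u):
        raise ValueError("context window shorter than the event")
    p0 = v.ref_pos - 1
    if v.is_insertion:
        lo = max(0, p0 + 1 - window)
        hi = min(len(reference), p0 + 1 + window)
        longer = reference[lo:p0 + 1] + u + reference[p0 + 1:hi]
        j = p0 + 1 - lo
    else:
        lo = max(0, p0 + 1 - window)
        hi = min(len(reference), p0 + 1 + len(u) + window)
        longer = reference[lo:hi]
        j = p0 + 1 - lo
    classes = classify_gap(longer, j, len(u))
    return IndelVariant(v.ref_pos, v.ref_allele, v.alt_allele,
                        motif_class=classes, primary_class=primary_class(classes),
                        coverage=v.coverage, allele_fraction=v.allele_fraction)


def classify_core_alignment(top: str, bottom: str) -> tuple[str, frozenset]:
    """Classify the variation shown by a marker's core-sequence alignment.

    `top` and `bottom` are gapped rows ('-' gaps); '//' separates segments
    of the same amplicon shown with intervening sequence omitted. Every gap
    run is classified in its segment context; the locus-level call is the
    union of event classes with the primary by precedence, or no_motif when
    no event shows structure.
    """
    classes: set = set()
    for seg_top, seg_bottom in zip(top.split("//"), bottom.split("//")):
        if len(seg_top) != len(seg_bottom):
            raise ValueError("core alignment rows differ in length")
        for row, other in ((seg_top, seg_bottom), (seg_bottom, seg_top)):
            i = 0
            while i < len(row):
                if row[i] == GAP:
                    j = i
                    while j < len(row) and row[j] == GAP:
                        j += 1
                    longer = other.replace(GAP, "")
                    start = len(other[:i].replace(GAP, ""))
                    classes |= classify_gap(longer, start, j - i)
                    i = j
                else:
                    i += 1
    return primary_class(frozenset(classes)), frozenset(classes)


def motif_census(variants) -> pd.Series:
    """Counts of indels per primary motif class, plus a 'multi_label' tally
    of events matching more than one class."""
    counts = {MOTIF_SNR: 0, MOTIF_TANDEM: 0, MOTIF_SSR: 0, MOTIF_NONE: 0,
              "multi_label": 0}
    for v in variants:
        cls = v.primary_class
        if cls is None:
            raise ValueError("variants must be classified first")
        counts[cls] += 1
        if len(v.motif_class) > 1:
            counts["multi_label"] += 1
    return pd.Series(counts)


# ---------------------------------------------------------------------------
# external formats


def indels_to_vcf(variants, chrom: str = "chloroplast") -> str:
    """Minimal VCF 4.2 text for a list of classified indels."""
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=MOTIF,Number=1,Type=String,Description="Primary motif class">',
             '##INFO=<ID=COV,Number=1,Type=Integer,Description="Read coverage">',
             '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for v in variants:
        info = []
        if v.primary_class:
            info.append(f"MOTIF={v.primary_class}")
        if v.coverage is not None:
            info.append(f"COV={v.coverage}")
        if v.allele_fraction is not None:
            info.append(f"AF={v.allele_fraction:.4f}")
        lines.append("\t".join([chrom, str(v.ref_pos), ".", v.ref_allele,
                                v.alt_allele, ".", ".", ";".join(info) or "."]))
    return "\n".join(lines) + "\n"
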
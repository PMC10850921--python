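"""PCR marker design, in-silico PCR and size-coded genotyping.

A marker is a primer pair flanking a discovered INDEL. Primer binding is
exact-match (no mismatch tolerance): amplification failures seen in the
wet lab are modelled by the undesignable / no-product paths rather than
by binding thermodynamics. Amplicon-length alleles at a locus are coded
as dense integers 1..k in ascending length order (code 1 = shortest) — a
convention, since published genotype tables rarely state their coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp
from .indelscan import IndelVariant

PRIMER_LEN_RANGE = (18, 27)
DEFAULT_AMPLICON_RANGE = (100, 300)
DEFAULT_MAX_PRODUCT = 2000
#: simple Wallace rule window: Tm = 2(A+T) + 4(G+C), primers paired within
TM_WINDOW_C = 5.0


class UndesignableError(ValueError):
    """No unique primer pair exists in the allowed window."""


class AmbiguousProductError(ValueError):
    """More than one possible PCR product."""

    def __init__(self, msg, sites):
        super().__init__(msg)
        self.sites = sites


@dataclass(frozen=True)
class MarkerDef:
    """A primer-pair locus on a reference genome.

    ref_start/ref_end are the 1-based inclusive amplicon bounds on the
    design reference (first base of the forward primer to last base of
    the reverse-primer binding site); expected_length is the amplicon
    length there.
    """

    locus: str
    fwd_primer: str
    rev_primer: str
    ref_start: int
    ref_end: int
    expected_length: int

    def __post_init__(self) -> None:
        if self.expected_length != self.ref_end - self.ref_start + 1:
            raise ValueError(
                f"{self.locus}: expected_length {self.expected_length} != "
                f"end - start + 1 = {self.ref_end - self.ref_start + 1}")
        for p in (self.fwd_primer, self.rev_primer):
            if not PRIMER_LEN_RANGE[0] <= len(p) <= PRIMER_LEN_RANGE[1]:
                raise ValueError(
                    f"{self.locus}: primer length {len(p)} outside "
                    f"{PRIMER_LEN_RANGE}")


@dataclass(frozen=True)
class GenotypeCall:
    """An accession's size-coded allele at one locus (None = no product)."""

    accession: str
    locus: str
    allele_code: int | None
    amplicon_length: int | None


def wallace_tm(primer: str) -> float:
    """Wallace 2AT+4GC rule melting temperature (deg C)."""
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def _count_occurrences(genome: str, site: str) -> int:
    n = start = 0
    while True:
        i = genome.find(site, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def design_primers(
    reference,
    v: IndelVariant,
    locus: str = "marker",
    primer_len: int = 20,
    amplicon_range: tuple[int, int] = DEFAULT_AMPLICON_RANGE,
    tm_window: float = TM_WINDOW_C,
) -> MarkerDef:
    """Design a unique primer pair bracketing a variant on the reference.

    Candidate forward primers end upstream of the event and reverse
    primers (as reverse complements of the + strand) start downstream;
    both must occur exactly once in the reference (either strand is
    checked via the + strand and its reverse complement together), their
    Wallace Tm must agree within `tm_window`, and the amplicon length
    must fall in `amplicon_range`. Raises UndesignableError when no such
    pair exists, the path that models real markers failing to amplify.
    """
    genome = reference.sequence if hasattr(reference, "sequence") else reference
    searchable = genome + "#" + revcomp(genome)

    event_start0 = v.ref_pos  # first base after the anchor, 0-based
    event_end0 = v.ref_pos - 1 + len(v.ref_allele)  # 0-based, exclusive
    lo_len, hi_len = amplicon_range

    fwd_candidates = []
    for start0 in range(max(0, event_start0 - (hi_len - primer_len)),
                        event_start0 - primer_len + 1):
        p = genome[start0:start0 + primer_len]
        if _count_occurrences(searchable, p) == 1:
            fwd_candidates.append((start0, p))

    rev_candidates = []
    for end0 in range(event_end0 + primer_len,
                      min(len(genome), event_end0 + hi_len) + 1):
        site = genome[end0 - primer_len:end0]
        p = revcomp(site)
        if _count_occurrences(searchable, p) == 1:
            rev_candidates.append((end0, p))

    for start0, fwd in fwd_candidates:
        for end0, rev in rev_candidates:
            length = end0 - start0
            if not lo_len <= length <= hi_len:
                continue
            if abs(wallace_tm(fwd) - wallace_tm(rev)) > tm_window:
                continue
            return MarkerDef(locus, fwd, rev, start0 + 1, end0, length)
    raise UndesignableError(
        f"{locus}: no unique primer pair with amplicon in {amplicon_range} "
        f"around position {v.ref_pos}")


def insilico_pcr(genome: str, m: MarkerDef,
                 max_product: int = DEFAULT_MAX_PRODUCT
                 ) -> tuple[str, int] | None:
    """Predict the PCR product of a marker on a template.

    A product is reported iff there is exactly one forward site with
    exactly one downstream reverse-complement reverse site within
    `max_product` nt (exact-match binding only). No binding, or a
    missing downstream partner, gives None (no product); several
    alternative products raise AmbiguousProductError.
    """
    fwd_sites = []
    start = 0
    while True:
        i = genome.find(m.fwd_primer, start)
        if i < 0:
            break
        fwd_sites.append(i)
        start = i + 1
    rev_site_seq = revcomp(m.rev_primer)
    rev_sites = []
    start = 0
    while True:
        i = genome.find(rev_site_seq, start)
        if i < 0:
            break
        rev_sites.append(i)
        start = i + 1

    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_site_seq)
            if end - f <= 0 or end - f > max_product:
                continue
            products.append((f, end))
    if not products:
        return None
    if len(products) > 1:
        raise AmbiguousProductError(
            f"{m.locus}: {len(products)} alternative products", products)
    f, end = products[0]
    seq = genome[f:end]
    return seq, len(seq)


def genotype_accessions(genomes: dict[str, str], markers,
                        max_product: int = DEFAULT_MAX_PRODUCT
                        ) -> pd.DataFrame:
    """Amplicon lengths for every accession x marker (NaN = no product)."""
    rows = {}
    for acc, seq in genomes.items():
        row = {}
        for m in markers:
            try:
                product = insilico_pcr(seq, m, max_product)
            except AmbiguousProductError:
                product = None
            row[m.locus] = product[1] if product else np.nan
        rows[acc] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "accession"
    return df


def call_genotypes(amplicons: pd.DataFrame) -> pd.DataFrame:
    """Integer allele codes from an accession x locus amplicon-length
    table: distinct lengths at a locus get codes 1, 2, ... in ascending
    length order; missing products stay missing. The coding does not
    depend on accession order.
    """
    if (amplicons.fillna(1) <= 0).any().any():
        raise ValueError("amplicon lengths must be positive")
    coded = {}
    for locus in amplicons.columns:
        lengths = sorted(set(amplicons[locus].dropna()))
        mapping = {length: code for code, length in enumerate(lengths, start=1)}
        coded[locus] = amplicons[locus].map(mapping)
    out = pd.DataFrame(coded, index=amplicons.index).astype("Int64")
    out.index.name = "accession"
    return out


def genotype_table_text(codes: pd.DataFrame) -> str:
    """Genotype matrix as TSV with '.' for missing calls."""
    df = codes.astype(object).where(codes.notna(), ".")
    return df.to_csv(sep="\t")
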
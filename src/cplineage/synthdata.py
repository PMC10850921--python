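"""Synthetic study data with known ground truth.

Everything the downstream pipeline consumes can be generated here:
quadripartite circular plastomes (LSC / IRa / SSC / IRb, the two inverted
repeats being exact reverse complements), lineages diverging along a known
taxon tree with planted SNPs and INDELs of the four motif classes,
pileup-style variant candidate tables with coverage and allele-fraction
noise, flow-cytometry peak pairs proportional to genome size, and
species-structured seed/volume morphometry with toy voxel masks.

All operations take one explicit integer seed and are reproducible
bit-for-bit for a given seed on one installation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import apply_anchored_variants, random_dna, revcomp
from .indelscan import (
    MOTIF_NONE,
    MOTIF_SNR,
    MOTIF_SSR,
    MOTIF_TANDEM,
    classify_gap,
    normalize_indel,
    primary_class,
)

REGION_NAMES = ("LSC", "IRa", "SSC", "IRb")

#: region lengths (nt) of the assembled domesticated-type plastome:
#: large single copy, inverted repeat, small single copy, inverted repeat
DEFAULT_REGION_LENGTHS = (88_684, 24_452, 18_414, 24_452)

#: rice internal standard 1C size (bp)
DEFAULT_INTERNAL_SIZE = 373_245_519


# ---------------------------------------------------------------------------
# reference genome


@dataclass
class CircularGenome:
    """An annotated quadripartite circular plastome.

    regions maps LSC/IRa/SSC/IRb to 1-based inclusive (start, end)
    intervals that partition the sequence; IRb is the reverse complement
    of IRa.
    """

    id: str
    sequence: str
    regions: dict[str, tuple[int, int]]
    circular: bool = True

    def validate(self, length_bounds: tuple[int, int] | None = None) -> None:
        covered = 0
        prev_end = 0
        for name in REGION_NAMES:
            start, end = self.regions[name]
            if start != prev_end + 1:
                raise ValueError(f"region {name} does not abut its predecessor")
            covered += end - start + 1
            prev_end = end
        if covered != len(self.sequence):
            raise ValueError("regions do not partition the sequence")
        ia, ib = self.regions["IRa"], self.regions["IRb"]
        if (ia[1] - ia[0]) != (ib[1] - ib[0]):
            raise ValueError("inverted repeats differ in length")
        if revcomp(self.region_seq("IRa")) != self.region_seq("IRb"):
            raise ValueError("IRb is not the reverse complement of IRa")
        if length_bounds is not None:
            lo, hi = length_bounds
            if not lo <= len(self.sequence) <= hi:
                raise ValueError(
                    f"genome length {len(self.sequence)} outside [{lo}, {hi}]")

    def region_seq(self, name: str) -> str:
        start, end = self.regions[name]
        return self.sequence[start - 1:end]

    def region_of(self, pos1: int) -> str:
        for name in REGION_NAMES:
            start, end = self.regions[name]
            if start <= pos1 <= end:
                return name
        raise ValueError(f"position {pos1} outside the genome")


def simulate_reference_genome(
    seed: int,
    region_lengths: tuple[int, int, int, int] = DEFAULT_REGION_LENGTHS,
    genome_id: str = "reference",
    length_bounds: tuple[int, int] | None = None,
) -> CircularGenome:
    """Random quadripartite plastome with the requested region lengths.

    The two IR lengths must be equal; the emitted genome is exactly
    sum(region_lengths) nt. Identical seeds give identical sequences.
    """
    lsc, ira, ssc, irb = region_lengths
    if ira != irb:
        raise ValueError(
            f"inverted repeats must have equal lengths (got {ira} and {irb})")
    if any(l <= 0 for l in region_lengths):
        raise ValueError("region lengths must be positive")
    if sum(region_lengths) < 1000:
        raise ValueError("total genome length must be at least 1 kb")
    rng = np.random.default_rng(seed)
    s_lsc = random_dna(rng, lsc)
    s_ira = random_dna(rng, ira)
    s_ssc = random_dna(rng, ssc)
    seq = s_lsc + s_ira + s_ssc + revcomp(s_ira)
    regions = {
        "LSC": (1, lsc),
        "IRa": (lsc + 1, lsc + ira),
        "SSC": (lsc + ira + 1, lsc + ira + ssc),
        "IRb": (lsc + ira + ssc + 1, lsc + ira + ssc + irb),
    }
    genome = CircularGenome(genome_id, seq, regions)
    genome.validate(length_bounds)
    return genome


# ---------------------------------------------------------------------------
# lineage simulation


@dataclass
class BranchSpec:
    """A branch of the generating taxon tree with per-branch mutation
    counts. Leaves are branches without children."""

    name: str
    n_snps: int = 0
    n_indels: int = 0
    children: list["BranchSpec"] = field(default_factory=list)

    def walk(self, path=()):
        yield self, path
        for child in self.children:
            yield from child.walk(path + (self.name,))

    def leaves(self):
        for node, _ in self.walk():
            if not node.children:
                yield node.name


def fig_tree(scale: int = 1, indels_per_branch: int = 0) -> BranchSpec:
    """A five-taxon tree shaped like the plastome phylogeny of the study
    system: bispinosa sister to natans, japonica next, then incisa, with a
    distant outgroup. SNP counts per branch are `scale` times a fixed
    profile."""
    return BranchSpec("root", 0, 0, [
        BranchSpec("outgroup", 40 * scale, indels_per_branch),
        BranchSpec("ingroup", 10 * scale, indels_per_branch, [
            BranchSpec("incisa", 12 * scale, indels_per_branch),
            BranchSpec("core", 6 * scale, indels_per_branch, [
                BranchSpec("japonica", 8 * scale, indels_per_branch),
                BranchSpec("nb", 4 * scale, indels_per_branch, [
                    BranchSpec("natans", 5 * scale, indels_per_branch),
                    BranchSpec("bispinosa", 5 * scale, indels_per_branch),
                ]),
            ]),
        ]),
    ])


@dataclass(frozen=True)
class PlantedVariant:
    """A planted edit in anchored VCF style on reference coordinates.

    pos0 is 0-based; for SNPs ref/alt are single bases. mirrored marks the
    IRb copy of an IRa edit.
    """

    branch: str
    pos0: int
    ref_allele: str
    alt_allele: str
    kind: str  # "snp" | "indel"
    motif_class: str | None = None
    mirrored: bool = False

    @property
    def pos1(self) -> int:
        return self.pos0 + 1


@dataclass
class LineageTruth:
    """Ground truth of a lineage simulation: the generating tree and every
    planted variant per branch, on reference coordinates."""

    tree: BranchSpec
    reference: CircularGenome
    variants: dict[str, list[PlantedVariant]]

    def leaf_variants(self, leaf: str, include_mirror: bool = True
                      ) -> list[PlantedVariant]:
        """All variants carried by a leaf (union over its root path)."""
        for node, path in self.tree.walk():
            if node.name == leaf and not node.children:
                branches = path + (leaf,)
                break
        else:
            raise KeyError(leaf)
        out = []
        for b in branches:
            for v in self.variants.get(b, []):
                if v.mirrored and not include_mirror:
                    continue
                out.append(v)
        return sorted(out, key=lambda v: v.pos0)

    def leaf_indels(self, leaf: str, include_mirror: bool = True):
        return [v for v in self.leaf_variants(leaf, include_mirror)
                if v.kind == "indel"]

    def newick(self) -> str:
        def fmt(node: BranchSpec) -> str:
            if not node.children:
                return node.name
            return "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
        return fmt(self.tree) + ";"


def _mirror_event(genome: CircularGenome, v: PlantedVariant) -> PlantedVariant:
    """The IRb copy of an IRa edit (positions mirrored, alleles
    reverse-complemented, re-anchored and left-normalized)."""
    a1, _a2 = genome.regions["IRa"]
    _b1, b2 = genome.regions["IRb"]
    ref = genome.sequence
    if v.kind == "snp":
        p1 = v.pos0 + 1  # 1-based
        q1 = b2 - (p1 - a1)
        return replace(v, pos0=q1 - 1, ref_allele=revcomp(v.ref_allele),
                       alt_allele=revcomp(v.alt_allele), mirrored=True)
    ins = len(v.alt_allele) > len(v.ref_allele)
    u = (v.alt_allele if ins else v.ref_allele)[1:]
    if ins:
        # insertion between pos1 and pos1+1 mirrors to an insertion between
        # mirror(pos1+1) and mirror(pos1)
        p1 = v.pos0 + 1
        q_anchor = b2 - (p1 + 1 - a1)  # 1-based anchor on IRb
        pos0, ra, aa = normalize_indel(ref, q_anchor - 1, ref[q_anchor - 1],
                                       ref[q_anchor - 1] + revcomp(u))
    else:
        last_del = v.pos0 + 1 + len(u)  # 1-based last deleted base
        q_first = b2 - (last_del - a1)  # 1-based first deleted base on IRb
        anchor0 = q_first - 2  # 0-based anchor before mirrored deletion
        pos0, ra, aa = normalize_indel(
            ref, anchor0, ref[anchor0:anchor0 + len(u) + 1], ref[anchor0])
    return replace(v, pos0=pos0, ref_allele=ra, alt_allele=aa, mirrored=True)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_snp(rng: np.random.Generator, base: str, kappa: float) -> str:
    """HKY-like base change: transition with probability kappa/(kappa+2)."""
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    tv = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
    return tv[int(rng.integers(0, 2))]


def _plant_indel(rng: np.random.Generator, ref: str, pos0: int, cls: str
                 ) -> tuple[str, str] | None:
    """Construct an anchored (ref_allele, alt_allele) insertion at pos0
    whose motif class is `cls`, or None if the local context does not
    allow it."""
    anchor = ref[pos0]
    ctx_lo, ctx_hi = max(0, pos0 - 40), min(len(ref), pos0 + 40)
    left, right = ref[ctx_lo:pos0 + 1], ref[pos0 + 1:ctx_hi]

    if cls == MOTIF_SNR:
        base = str(rng.choice(list("ACGT")))
        n = int(rng.integers(5, 9))
        u = base * n
    elif cls == MOTIF_TANDEM:
        k = int(rng.integers(6, 13))
        if pos0 - k + 1 < 0:
            return None
        u = ref[pos0 - k + 1:pos0 + 1]  # duplicate the adjacent k-mer
        if len(set(u)) == 1:
            return None
    elif cls == MOTIF_SSR:
        p = int(rng.integers(2, 6))
        unit = random_dna(rng, p)
        if len(set(unit)) == 1:
            return None
        copies = int(rng.integers(4, 7))
        u = unit * copies
    elif cls == MOTIF_NONE:
        u = random_dna(rng, int(rng.integers(5, 9)))
    else:
        raise ValueError(f"unknown motif class {cls!r}")

    # verify the planted event classifies as intended in its real context
    longer = left + u + right
    classes = classify_gap(longer, len(left), len(u))
    if primary_class(classes) != cls:
        return None
    return ref[pos0], anchor + u


def simulate_lineages(
    reference: CircularGenome,
    tree: BranchSpec,
    seed: int,
    motif_mix: dict[str, float] | None = None,
    margin: int = 200,
    min_indel_spacing: int = 300,
    ir_mirror: bool = True,
) -> tuple[dict[str, str], LineageTruth]:
    """Evolve leaf genomes from `reference` along `tree`.

    Each branch receives its requested number of SNPs and INDELs at
    unique, well-spaced reference positions outside `margin` nt of region
    boundaries (and outside IRb, where IRa edits are mirrored when
    ir_mirror is on). INDEL motif classes are drawn from `motif_mix`
    (default: uniform over the four classes); each planted INDEL is
    constructed so its intended class holds in context, and the default
    spacing leaves room for flanking PCR primers.

    Returns ({leaf name: sequence}, truth).
    """
    rng = np.random.default_rng(seed)
    ref = reference.sequence
    mix = motif_mix or {MOTIF_SNR: 0.25, MOTIF_TANDEM: 0.25,
                        MOTIF_SSR: 0.25, MOTIF_NONE: 0.25}
    classes = sorted(mix)
    weights = np.array([mix[c] for c in classes], dtype=float)
    weights /= weights.sum()

    # positions available for mutation: inside LSC/IRa/SSC away from
    # boundaries; IRb carries only mirrored copies
    allowed = np.zeros(len(ref), dtype=bool)
    for name in ("LSC", "IRa", "SSC"):
        start, end = reference.regions[name]
        lo, hi = start - 1 + margin, end - margin
        if hi > lo:
            allowed[lo:hi] = True

    total_indels = sum(n.n_indels for n, _ in tree.walk())
    n_avail = int(allowed.sum())
    if total_indels and n_avail // max(1, min_indel_spacing) < total_indels:
        raise ValueError(
            f"cannot place {total_indels} INDELs with spacing "
            f"{min_indel_spacing} in {n_avail} available positions")

    # indel_block enforces spacing between indels; occupied keeps any two
    # events (and their local context, which classification and alignment
    # normalization rely on) from interfering
    indel_block = np.zeros(len(ref), dtype=bool)
    occupied = np.zeros(len(ref), dtype=bool)
    PAD = 45  # context guard around planted indels

    def mark(arr: np.ndarray, pos0: int, radius: int) -> None:
        arr[max(0, pos0 - radius):min(len(ref), pos0 + radius + 1)] = True

    def window_free(arr: np.ndarray, pos0: int, radius: int) -> bool:
        return not arr[max(0, pos0 - radius):pos0 + radius + 1].any()

    variants: dict[str, list[PlantedVariant]] = {}
    candidates = np.flatnonzero(allowed)

    def free_candidates() -> np.ndarray:
        free = np.ones(len(candidates), dtype=bool)
        for arr, r in ((indel_block, min_indel_spacing), (occupied, PAD)):
            csum = np.concatenate([[0], np.cumsum(arr)])
            lo = np.maximum(candidates - r, 0)
            hi = np.minimum(candidates + r + 1, len(ref))
            free &= (csum[hi] - csum[lo]) == 0
        return candidates[free]

    def place_indel(node_name: str, cls: str) -> PlantedVariant | None:
        for attempt in range(400):
            pool = candidates if attempt < 50 else free_candidates()
            if len(pool) == 0:
                return None
            pos0 = int(rng.choice(pool))
            if not (window_free(indel_block, pos0, min_indel_spacing)
                    and window_free(occupied, pos0, PAD)):
                continue
            made = _plant_indel(rng, ref, pos0, cls)
            if made is None:
                continue
            ra, aa = made
            npos0, nra, naa = normalize_indel(ref, pos0, ra, aa)
            if not (window_free(indel_block, npos0, min_indel_spacing)
                    and window_free(occupied, npos0, PAD)):
                continue
            return PlantedVariant(node_name, npos0, nra, naa, "indel", cls)
        return None

    variants = {node.name: [] for node, _ in tree.walk()}

    # pass 1: all indels (they need clean, well-spaced context)
    for node, _path in tree.walk():
        for _ in range(node.n_indels):
            cls = str(rng.choice(classes, p=weights))
            v = place_indel(node.name, cls)
            if v is None:
                raise ValueError(
                    f"unable to place {node.n_indels} INDELs on branch "
                    f"{node.name}: not enough non-overlapping sites")
            variants[node.name].append(v)
            mark(indel_block, v.pos0, min_indel_spacing)
            mark(occupied, v.pos0, PAD + len(v.ref_allele))
            if ir_mirror and reference.region_of(v.pos0 + 1) == "IRa":
                m = _mirror_event(reference, v)
                variants[node.name].append(m)
                mark(indel_block, m.pos0, min_indel_spacing)
                mark(occupied, m.pos0, PAD + len(m.ref_allele))

    # pass 2: SNPs at any remaining free position
    for node, _path in tree.walk():
        placed = 0
        attempts = 0
        while placed < node.n_snps:
            attempts += 1
            if attempts > 200 * max(1, node.n_snps):
                raise ValueError(
                    f"unable to place {node.n_snps} SNPs on branch "
                    f"{node.name}: not enough free positions")
            pos0 = int(rng.choice(candidates))
            if not window_free(occupied, pos0, 1):
                continue
            base = ref[pos0]
            alt = _draw_snp(rng, base, kappa=2.0)
            v = PlantedVariant(node.name, pos0, base, alt, "snp")
            variants[node.name].append(v)
            mark(occupied, pos0, 1)
            if ir_mirror and reference.region_of(pos0 + 1) == "IRa":
                m = _mirror_event(reference, v)
                variants[node.name].append(m)
                mark(occupied, m.pos0, 1)
            placed += 1

    truth = LineageTruth(tree, reference, variants)
    genomes: dict[str, str] = {}
    for leaf in tree.leaves():
        edits = [(v.pos0, v.ref_allele, v.alt_allele)
                 for v in truth.leaf_variants(leaf)]
        genomes[leaf] = apply_anchored_variants(ref, edits)
    return genomes, truth


def true_alignment(reference: CircularGenome, truth: LineageTruth,
                   include_reference: bool = True) -> tuple[list[str], list[str]]:
    """Exact reference-coordinate alignment implied by the planted truth.

    Rows have the reference length: planted SNPs substitute bases, planted
    deletions become '-', and planted insertions (which occupy no
    reference column) are omitted. Returns (taxa, rows).
    """
    ref = reference.sequence
    taxa, rows = [], []
    if include_reference:
        taxa.append(reference.id)
        rows.append(ref)
    for leaf in truth.tree.leaves():
        row = list(ref)
        for v in truth.leaf_variants(leaf):
            if v.kind == "snp":
                row[v.pos0] = v.alt_allele
            elif len(v.ref_allele) > len(v.alt_allele):  # deletion
                for k in range(v.pos0 + 1, v.pos0 + len(v.ref_allele)):
                    row[k] = "-"
        taxa.append(leaf)
        rows.append("".join(row))
    return taxa, rows


# ---------------------------------------------------------------------------
# pileup-style variant candidates


def simulate_pileup_candidates(
    truth: LineageTruth,
    seed: int,
    coverage_mean: int = 300,
    frac_noise: float = 0.0,
    fp_rate: float = 0.0,
) -> pd.DataFrame:
    """Variant-candidate table as produced by read mapping: every planted
    variant with allele fraction near 1 (haploid plastome), plus false
    positives at `fp_rate` per reference position with fractions centred
    below 0.5.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    if not 0 <= fp_rate <= 1:
        raise ValueError("fp_rate must be a rate in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    for branch in sorted(truth.variants):
        for v in truth.variants[branch]:
            if v.pos0 in seen:
                continue
            seen.add(v.pos0)
            cov = max(1, int(rng.poisson(coverage_mean)))
            frac = float(np.clip(1.0 - abs(rng.normal(0.0, frac_noise)),
                                 0.0, 1.0)) if frac_noise > 0 else 1.0
            rows.append((truth.reference.id, v.pos1, v.ref_allele,
                         v.alt_allele, cov, frac, True))
    n_fp = int(rng.binomial(len(truth.reference.sequence), fp_rate)) \
        if fp_rate else 0
    if n_fp:
        for pos0 in sorted(rng.choice(len(truth.reference.sequence) - 1,
                                      size=n_fp, replace=False)):
            pos0 = int(pos0)
            if pos0 in seen:
                continue
            ref_b = truth.reference.sequence[pos0]
            alt = _draw_snp(rng, ref_b, kappa=1.0)
            cov = max(1, int(rng.poisson(coverage_mean)))
            frac = float(rng.uniform(0.0, 0.6))
            rows.append((truth.reference.id, pos0 + 1, ref_b, alt, cov,
                         frac, False))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "coverage", "allele_fraction", "is_true"])
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# flow-cytometry peaks


@dataclass(frozen=True)
class PeakSimParams:
    """Simulation settings for flow peak pairs with an internal standard."""

    true_1c_sizes: dict[str, float]
    internal_size: float = DEFAULT_INTERNAL_SIZE
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.true_1c_sizes.values()):
            raise ValueError("1C sizes must be positive")
        if self.internal_size <= 0:
            raise ValueError("internal_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_flow_peaks(params: PeakSimParams, n_reps: int = 1,
                        base_peak: float = 100.0) -> pd.DataFrame:
    """Flow peak pairs whose expected sample/internal ratio equals
    true_size/internal_size; jitter is multiplicative with sd noise_sd."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(params.seed)
    rows = []
    for taxon in sorted(params.true_1c_sizes):
        size = params.true_1c_sizes[taxon]
        for rep in range(n_reps):
            internal = base_peak * (1.0 + params.noise_sd * rng.standard_normal())
            peak = base_peak * (size / params.internal_size) * (
                1.0 + params.noise_sd * rng.standard_normal())
            rows.append((f"{taxon}_r{rep}", taxon, peak, internal,
                         params.internal_size))
    return pd.DataFrame(rows, columns=["sample_id", "site", "peak",
                                       "internal_peak", "internal_size"])


# ---------------------------------------------------------------------------
# seed / volume morphometry


#: per-taxon morphometry presets: seed height/width (mm), total capsule
#: volume (mm^3) and endosperm fraction, as (mean, sd). Total volumes put
#: the domesticated taxon at ~4.3x the tetraploid wild taxon with the wild
#: taxa ordered incisa < japonica <= natans < bispinosa; endosperm
#: fractions sit inside the observed 53-68.9% range, higher in japonica.
DEFAULT_MORPHO_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "T. incisa": {"height": (8.0, 1.0), "width": (14.0, 1.5),
                  "total_volume": (700.0, 90.0),
                  "endosperm_fraction": (0.62, 0.02)},
    "T. japonica": {"height": (12.0, 1.5), "width": (22.0, 2.0),
                    "total_volume": (2100.0, 250.0),
                    "endosperm_fraction": (0.67, 0.012)},
    "T. natans": {"height": (13.0, 1.5), "width": (25.0, 2.5),
                  "total_volume": (2400.0, 300.0),
                  "endosperm_fraction": (0.60, 0.02)},
    "T. bispinosa": {"height": (19.0, 2.0), "width": (38.0, 3.5),
                     "total_volume": (9030.0, 900.0),
                     "endosperm_fraction": (0.56, 0.02)},
}

#: observed range of endosperm/total volume ratios; preset draws stay inside
ENDOSPERM_FRACTION_RANGE = (0.53, 0.689)


def simulate_morphometry(
    n_per_taxon: dict[str, int],
    seed: int,
    presets: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-dimension and capsule/endosperm volume tables.

    Draws are normal per taxon; the endosperm fraction is truncated to the
    observed range so endosperm volume never exceeds total volume. Taxa
    with n == 0 are absent from the outputs.
    """
    presets = presets or DEFAULT_MORPHO_PRESETS
    rng = np.random.default_rng(seed)
    seed_rows, vol_rows = [], []
    for taxon in sorted(n_per_taxon):
        n = n_per_taxon[taxon]
        if n < 0:
            raise ValueError("n per taxon must be nonnegative")
        if n == 0:
            continue
        cfg = presets[taxon]
        for mean, _sd in cfg.values():
            if mean <= 0:
                raise ValueError("preset means must be positive")
        fm, fs = cfg["endosperm_fraction"]
        if not 0 < fm < 1:
            raise ValueError("endosperm fraction mean must be in (0, 1)")
        for i in range(n):
            h = _pos_normal(rng, *cfg["height"])
            w = _pos_normal(rng, *cfg["width"])
            total = _pos_normal(rng, *cfg["total_volume"])
            frac = fm if fs == 0 else _truncated_normal(
                rng, fm, fs, *ENDOSPERM_FRACTION_RANGE)
            endo = min(total, frac * total)
            sid = f"{taxon.replace(' ', '').replace('.', '')}_{i:03d}"
            seed_rows.append((sid, taxon, h, w))
            vol_rows.append((sid, taxon, total, endo))
    seeds = pd.DataFrame(seed_rows,
                         columns=["sample_id", "taxon", "height_mm", "width_mm"])
    vols = pd.DataFrame(vol_rows, columns=["sample_id", "taxon",
                                           "total_volume_mm3",
                                           "endosperm_volume_mm3"])
    return seeds, vols


def _pos_normal(rng, mean, sd):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("positive draw failed; check preset mean/sd")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated draw failed; check preset mean/sd")


def simulate_voxel_mask(endosperm_edge: int = 10, pericarp_thickness: int = 3
                        ) -> np.ndarray:
    """A toy CT label volume: a cubic endosperm (label 2) inside a cubic
    pericarp shell (label 1) on background 0."""
    if endosperm_edge < 1 or pericarp_thickness < 1:
        raise ValueError("edge and thickness must be >= 1")
    outer = endosperm_edge + 2 * pericarp_thickness
    grid = np.zeros((outer + 2,) * 3, dtype=np.int8)
    g0 = 1
    grid[g0:g0 + outer, g0:g0 + outer, g0:g0 + outer] = 1
    e0 = g0 + pericarp_thickness
    grid[e0:e0 + endosperm_edge, e0:e0 + endosperm_edge,
         e0:e0 + endosperm_edge] = 2
    return grid


def write_voxel_mask(path, mask: np.ndarray, voxel_edge_mm: float) -> None:
    """Raw integer grid with a sidecar header line
    (# dims=z,y,x voxel_edge_mm=... labels=...)."""
    with open(path, "w") as fh:
        z, y, x = mask.shape
        fh.write(f"# dims={z},{y},{x} voxel_edge_mm={voxel_edge_mm} "
                 "labels=0:background,1:pericarp,2:endosperm\n")
        for plane in mask:
            for row in plane:
                fh.write("".join(str(int(v)) for v in row) + "\n")


def read_voxel_mask(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(kv.split("=") for kv in header.lstrip("# ").split()
                      if "=" in kv)
        dims = tuple(int(d) for d in fields["dims"].split(","))
        voxel_edge = float(fields["voxel_edge_mm"])
        flat = [int(c) for line in fh for c in line.strip()]
    return np.array(flat, dtype=np.int8).reshape(dims), voxel_edge


# ---------------------------------------------------------------------------
# expanding a published-style genotype table


def expand_plastid_table(type_matrix: pd.DataFrame,
                         species: tuple[str, ...] | None = None
                         ) -> pd.DataFrame:
    """Per-accession genotype records from a plastid-type summary table.

    `type_matrix` has one row per (label, region) with locus code columns
    (cpINDEL*) and per-species accession-count columns; the output carries
    one row per accession with its species, region, source label and the
    full code vector. (label, region) pairs must be unique.
    """
    from .datasets import SPECIES

    species = species or SPECIES
    dup = type_matrix.duplicated(subset=["label", "region"])
    if dup.any():
        bad = type_matrix.loc[dup, ["label", "region"]].iloc[0].tolist()
        raise ValueError(f"duplicate (label, region) row: {bad}")
    loci = [c for c in type_matrix.columns if c.startswith("cpINDEL")]
    rows = []
    for _, r in type_matrix.iterrows():
        for sp in species:
            count = int(r[sp])
            if count < 0:
                raise ValueError("accession counts must be nonnegative")
            for i in range(count):
                acc = (f"{sp.replace(' ', '').replace('.', '')}"
                       f"_{r['label'].replace(' ', '')}_{r['region']}_{i:02d}")
                rows.append([acc, sp, r["region"], r["label"],
                             *[int(r[loc]) for loc in loci]])
    return pd.DataFrame(rows, columns=["accession", "species", "region",
                                       "source_label", *loci])


# ---------------------------------------------------------------------------
# external formats


def write_fasta(path, records: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="")
         for name, s in records.items()),
        path, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_truth(path, truth: LineageTruth) -> None:
    """Structured text: the tree in newick plus one line per planted
    variant."""
    with open(path, "w") as fh:
        fh.write(truth.newick() + "\n")
        fh.write("branch\tpos\tref\talt\tkind\tmotif\tmirrored\n")
        for branch in sorted(truth.variants):
            for v in truth.variants[branch]:
                fh.write(f"{branch}\t{v.pos1}\t{v.ref_allele}\t{v.alt_allele}"
                         f"\t{v.kind}\t{v.motif_class or '.'}\t{int(v.mirrored)}\n")
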
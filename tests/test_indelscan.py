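"""Alignment, INDEL extraction/normalization, candidate filtering and
motif classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cplineage import indelscan
from cplineage._seq import deletion_placements, random_dna
from cplineage.indelscan import (
    MOTIF_NONE,
    MOTIF_SNR,
    MOTIF_SSR,
    MOTIF_TANDEM,
    AlignParams,
    FilterSpec,
    IndelVariant,
    PairwiseAlignment,
    align_pair,
    classify_core_alignment,
    classify_gap,
    classify_motif,
    extract_indels,
    extract_snps,
    filter_candidates,
    motif_census,
    primary_class,
)

# ---------------------------------------------------------------------------
# alignment


def test_self_alignment_has_no_gaps():
    s = "ACGTACGTTGCA" * 10
    aln = align_pair(s, s)
    assert aln.aligned_ref == s
    assert aln.aligned_qry == s
    assert aln.identity() == 1.0


def test_small_forced_gap():
    # deleting one base from a short query forces a single gap column
    aln = align_pair("ACGTA", "ACTA")
    assert aln.aligned_ref == "ACGTA"
    assert aln.aligned_qry.count("-") == 1
    assert aln.aligned_qry.replace("-", "") == "ACTA"


def test_non_dna_characters_rejected():
    with pytest.raises(ValueError, match="non-ACGTN"):
        align_pair("ACGTX", "ACGT")


def test_alignment_roundtrip_recovers_inputs():
    rng = np.random.default_rng(3)
    a = random_dna(rng, 400)
    b = a[:100] + a[130:250] + "TTTTAC" + a[250:]
    aln = align_pair(a, b)
    assert aln.ref_seq == a
    assert aln.qry_seq == b
    assert not any(x == "-" and y == "-"
                   for x, y in zip(aln.aligned_ref, aln.aligned_qry))


def test_anchor_chain_matches_full_dp():
    """The k-mer anchored path must reproduce plain dynamic programming."""
    rng = np.random.default_rng(11)
    a = random_dna(rng, 6000)
    b = list(a)
    b[1500] = "A" if a[1500] != "A" else "C"
    del b[3000:3008]
    b = "".join(b[:4500]) + "GATTACA" + "".join(b[4500:])
    fast = align_pair(a, b, AlignParams(anchor_min_length=1000))
    slow = align_pair(a, b, AlignParams(anchor_min_length=10**9))
    assert (fast.aligned_ref, fast.aligned_qry) == \
        (slow.aligned_ref, slow.aligned_qry)


# ---------------------------------------------------------------------------
# extraction and normalization


def test_gapless_alignment_yields_no_indels():
    aln = PairwiseAlignment("r", "q", "ACGT", "ACTT")
    assert extract_indels(aln) == []
    assert extract_snps(aln) == [(3, "G", "T")]


def test_anchored_deletion_allele_convention():
    aln = PairwiseAlignment("r", "q", "ACGGGT", "AC---T")
    (v,) = extract_indels(aln)
    assert (v.ref_pos, v.ref_allele, v.alt_allele) == (2, "CGGG", "C")
    assert v.length == -3


def test_insertion_left_normalized_in_repeat():
    # extra AG inside an AG-run must be anchored at the run start
    ref = "TTAGAGAGCC"
    qry = "TTAGAGAGAGCC"
    aln = align_pair(ref, qry)
    (v,) = extract_indels(aln)
    assert v.ref_pos == 2
    assert v.alt_allele == v.ref_allele + "AG"


@given(st.integers(0, 2**31 - 1))
def test_normalization_idempotent_and_leftmost(seed):
    rng = np.random.default_rng(seed)
    ref = random_dna(rng, 80)
    j = int(rng.integers(1, 60))
    length = int(rng.integers(1, 8))
    pos0, ra, aa = indelscan.normalize_indel(
        ref, j - 1, ref[j - 1:j + length], ref[j - 1])
    again = indelscan.normalize_indel(ref, pos0, ra, aa)
    assert again == (pos0, ra, aa)
    # leftmost: no equivalent placement with an anchor base starts earlier
    placements = deletion_placements(ref, pos0 + 1, length)
    assert min(p for p in placements if p >= 1) == pos0 + 1


def test_roundtrip_reconstructs_query(lineage_sim, small_reference):
    genomes, _ = lineage_sim
    for leaf, seq in genomes.items():
        aln = align_pair(small_reference.sequence, seq,
                         ref_id="ref", qry_id=leaf)
        rebuilt = indelscan.apply_variants(
            small_reference.sequence, extract_indels(aln), extract_snps(aln))
        assert rebuilt == seq


def test_planted_indel_recovery_small(lineage_sim, small_reference):
    """Every planted INDEL (and its IR mirror) is recovered
    position-exactly; nothing else is called."""
    genomes, truth = lineage_sim
    for leaf, seq in genomes.items():
        aln = align_pair(small_reference.sequence, seq,
                         ref_id="ref", qry_id=leaf)
        found = {(v.ref_pos, v.ref_allele, v.alt_allele)
                 for v in extract_indels(aln)}
        planted = {(v.pos1, v.ref_allele, v.alt_allele)
                   for v in truth.leaf_indels(leaf)}
        assert found == planted


def test_planted_indel_recovery_full_length():
    """Recovery stays exact at the real plastome scale (~156 kb)."""
    from cplineage import synthdata

    ref = synthdata.simulate_reference_genome(5)
    tree = synthdata.fig_tree(scale=3, indels_per_branch=3)
    genomes, truth = synthdata.simulate_lineages(ref, tree, seed=55)
    leaf = "bispinosa"
    aln = align_pair(ref.sequence, genomes[leaf], ref_id=ref.id, qry_id=leaf)
    found = {(v.ref_pos, v.ref_allele, v.alt_allele)
             for v in extract_indels(aln)}
    planted = {(v.pos1, v.ref_allele, v.alt_allele)
               for v in truth.leaf_indels(leaf)}
    assert found == planted


# ---------------------------------------------------------------------------
# candidate filtering


def _cand(coverage, fraction):
    return pd.DataFrame({"coverage": coverage, "allele_fraction": fraction})


def test_filter_thresholds_are_strict():
    df = _cand([201, 200, 1000, 201], [0.61, 0.99, 0.60, 0.60])
    kept = filter_candidates(df, FilterSpec())
    assert kept.index.tolist() == [0]  # only coverage>200 AND fraction>0.60


def test_filter_missing_field_is_an_error():
    df = _cand([210, None], [0.7, 0.7])
    with pytest.raises(ValueError, match="coverage"):
        filter_candidates(df)


def test_filter_matches_bruteforce_scan():
    rng = np.random.default_rng(0)
    df = _cand(rng.integers(0, 400, 1000),
               np.round(rng.uniform(0, 1, 1000), 3))
    kept = filter_candidates(df, FilterSpec(200, 0.60))
    expected = [i for i in range(1000)
                if df.coverage[i] > 200 and df.allele_fraction[i] > 0.60]
    assert kept.index.tolist() == expected


@given(st.integers(0, 500), st.floats(0, 1))
def test_filter_monotone_in_thresholds(cov, frac):
    rng = np.random.default_rng(42)
    df = _cand(rng.integers(0, 400, 200), rng.uniform(0, 1, 200))
    base = filter_candidates(df, FilterSpec(200, 0.6))
    tighter = filter_candidates(
        df, FilterSpec(max(200, cov), max(0.6, min(frac, 1.0))))
    assert set(tighter.index) <= set(base.index)


def test_clean_synthetic_candidates_fully_retained(lineage_sim):
    from cplineage import synthdata

    _, truth = lineage_sim
    cand = synthdata.simulate_pileup_candidates(
        truth, seed=3, coverage_mean=300, frac_noise=0.02, fp_rate=0.0)
    kept = filter_candidates(cand)
    assert kept.is_true.all()
    assert len(kept) == len(cand)  # coverage_mean 300 >> 200, fractions ~1


# ---------------------------------------------------------------------------
# motif classification


PRINTED_TO_CLASS = {
    "Single nucleotide repeat": MOTIF_SNR,
    "Tandem": MOTIF_TANDEM,
    "SSR": MOTIF_SSR,
    "No motif": MOTIF_NONE,
}


def test_marker_panel_cores_classify_to_printed_motifs(marker_panel):
    """The 19 published core-sequence alignments reproduce the panel's
    motif annotations; the one complex locus is multi-label
    tandem + single-nucleotide repeat."""
    for _, row in marker_panel.iterrows():
        prim, classes = classify_core_alignment(row.core_top, row.core_bottom)
        if row.motif == "Tandem/Single nucleotide repeat":
            assert {MOTIF_TANDEM, MOTIF_SNR} <= classes, row.locus
        else:
            assert prim == PRINTED_TO_CLASS[row.motif], \
                f"{row.locus}: {prim} != printed {row.motif}"


def test_homopolymer_insertion_is_single_nucleotide_repeat():
    # 5-A insertion inside an A-run
    ref = "GGTCAAAATGCC"
    v = IndelVariant(ref_pos=6, ref_allele="A", alt_allele="AAAAAA")
    out = classify_motif(v, ref)
    assert out.primary_class == MOTIF_SNR


def test_classify_window_must_cover_event():
    ref = "GGTCAAAATGCC"
    v = IndelVariant(ref_pos=6, ref_allele="A", alt_allele="AAAAAAAAAA")
    with pytest.raises(ValueError, match="window"):
        classify_motif(v, ref, window=5)


def test_planted_motif_classes_recovered(lineage_sim, small_reference):
    """classify_motif recovers the generator's intended class for every
    planted INDEL."""
    _, truth = lineage_sim
    n = 0
    for branch, events in truth.variants.items():
        for v in events:
            if v.kind != "indel" or v.mirrored:
                continue
            iv = IndelVariant(v.pos1, v.ref_allele, v.alt_allele)
            out = classify_motif(iv, small_reference.sequence)
            assert out.primary_class == v.motif_class, (branch, v)
            n += 1
    assert n >= 10


def test_motif_census_counts_by_primary_class(marker_panel):
    variants = []
    for i, (_, row) in enumerate(marker_panel.iterrows(), 1):
        prim, classes = classify_core_alignment(row.core_top, row.core_bottom)
        variants.append(IndelVariant(100 * i, "AT", "A",
                                     motif_class=classes, primary_class=prim))
    census = motif_census(variants)
    assert census[MOTIF_SNR] == 11  # ten SNR rows + the complex locus
    assert census[MOTIF_TANDEM] == 4
    assert census[MOTIF_SSR] == 1
    assert census[MOTIF_NONE] == 3
    assert census["multi_label"] >= 1
    assert motif_census([]).drop("multi_label").sum() == 0


# --- independent brute-force scanner ---------------------------------------


def _oracle_placements(longer, j, L):
    target = longer[:j] + longer[j + L:]
    return [k for k in range(len(longer) - L + 1)
            if longer[:k] + longer[k + L:] == target]


def _oracle_snr(longer, j, L):
    u = longer[j:j + L]
    if len(set(u)) == 1:
        if L >= indelscan.SNR_MIN_ALLELE:
            return True
        total = L
        k = j - 1
        while k >= 0 and longer[k] == u[0]:
            total += 1
            k -= 1
        k = j + L
        while k < len(longer) and longer[k] == u[0]:
            total += 1
            k += 1
        return total >= indelscan.SNR_MIN_RUN
    for side in (longer[:j][::-1], longer[j + L:]):
        if side:
            run = 1
            while run < len(side) and side[run] == side[0]:
                run += 1
            if run >= indelscan.SNR_MIN_RUN:
                return True
    return False


def _oracle_tandem(longer, j, L):
    u = longer[j:j + L]
    if L < 2 or len(set(u)) == 1:
        return False
    left, right = longer[:j], longer[j + L:]
    if left.endswith(u) or right.startswith(u):
        return True
    thr = max(indelscan.TANDEM_MIN_WORD, -(-L // 2))
    if thr > L:
        return False
    subs = {u[a:a + n] for n in range(thr, L + 1)
            for a in range(L - n + 1)}
    lw, rw = left[-L:], right[:L]
    return any(s in lw or s in rw for s in subs)


def _oracle_ssr(longer, j, L):
    for p in range(2, 7):
        for i in range(len(longer) - 3 * p + 1):
            unit = longer[i:i + p]
            if len(set(unit)) == 1:
                continue
            copies = 1
            while longer[i + copies * p:i + (copies + 1) * p] == unit:
                copies += 1
            if copies < 3:
                continue
            a, b = i, i + copies * p
            gap = max(a - (j + L), j - b, 0)
            if gap <= indelscan.SSR_MAX_DISTANCE:
                return True
    return False


def _oracle_classify(longer, j, L):
    classes = set()
    for k in _oracle_placements(longer, j, L):
        if _oracle_snr(longer, k, L):
            classes.add(MOTIF_SNR)
        if _oracle_tandem(longer, k, L):
            classes.add(MOTIF_TANDEM)
        if _oracle_ssr(longer, k, L):
            classes.add(MOTIF_SSR)
    return frozenset(classes)


def test_classifier_agrees_with_bruteforce_scanner():
    """classify_gap matches an exhaustive scanner (all placements, all
    unit sizes and offsets) on 1,000 random events."""
    rng = np.random.default_rng(17)
    for _ in range(1000):
        # biased alphabet so runs and repeats actually occur
        probs = rng.dirichlet([0.7] * 4)
        n = int(rng.integers(20, 70))
        longer = "".join(np.array(list("ACGT"))[
            rng.choice(4, size=n, p=probs)])
        L = int(rng.integers(1, 10))
        j = int(rng.integers(0, n - L + 1))
        assert classify_gap(longer, j, L) == _oracle_classify(longer, j, L), \
            (longer, j, L)


def test_primary_class_precedence():
    assert primary_class(frozenset()) == MOTIF_NONE
    assert primary_class(frozenset({MOTIF_TANDEM, MOTIF_SNR})) == MOTIF_SNR
    assert primary_class(frozenset({MOTIF_TANDEM, MOTIF_SSR})) == MOTIF_SSR


# ---------------------------------------------------------------------------
# VCF output


def test_vcf_output_contains_classified_indels():
    v = classify_motif(IndelVariant(2, "CGGG", "C"), "ACGGGTTT")
    text = indelscan.indels_to_vcf([v], chrom="cp")
    assert "##fileformat=VCFv4.2" in text
    assert "cp\t2\t.\tCGGG\tC" in text
    assert "MOTIF=" in text
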
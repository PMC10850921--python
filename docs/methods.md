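# Methods

## Scope and data model

The package analyses maternal lineages of water chestnuts from complete
chloroplast genomes and derived PCR markers, estimates nuclear genome
size/ploidy from flow-cytometry peak pairs, and summarizes seed
morphometry. The sequencing, cytometry and CT data of the original study
are not public; the package therefore ships (a) the published summary
tables it can recompute from — the 19-locus cpINDEL marker panel with core
variation alignments and amplicon coordinates on the KY705084 frame, the
nine-locus genotype matrix of 79 accessions, and the flow-cytometry peak
table with the rice internal standard (1C = 373,245,519 bp) — and (b) a
synthetic generator that produces sequence-level inputs with known truth.
The core alignment of cpINDEL1 is not available in machine-readable form;
a constructed, representative single-nucleotide-repeat core stands in and
is flagged `core_source = synthetic` in the packaged table.

## Synthetic plastomes and lineages

`synthdata.simulate_reference_genome` draws a uniform-random quadripartite
genome LSC + IRa + SSC + IRb with IRb the exact reverse complement of IRa;
defaults (88,684 / 24,452 / 18,414 / 24,452 nt) mirror the assembled
domesticated-type plastome, and smaller regions are accepted for
desk-scale runs. `simulate_lineages` evolves leaves along a user tree with
per-branch SNP and INDEL counts:

* SNPs follow an HKY-like scheme, transition probability κ/(κ+2) with
  κ = 2 and uniform base frequencies, so forcing equal rates downstream has
  an exact Jukes–Cantor limit to test against.
* Each planted INDEL is *constructed* to carry an intended motif class —
  a homopolymer insertion of 5–8 nt (single-nucleotide repeat), a
  duplication of the adjacent 6–12-mer (tandem), an inserted 2–5 nt unit
  array of 4–6 copies (SSR), or a random 5–8-mer verified to show no
  structure — and is re-verified in context at planting time, so the
  classifier has a labelled truth set.
* Mutations stay `margin` nt (default 200) away from region boundaries;
  edits falling in IRa are mirrored into IRb (positions reflected, alleles
  reverse-complemented, re-normalized), preserving the quadripartite
  invariant. Planted INDELs keep ≥ 300 nt spacing (default) so flanking
  primers fit; all positions are disjoint, which makes the truth record a
  unique, position-exact key for recovery tests.
* One integer seed per operation; identical seeds reproduce outputs
  byte-for-byte (numpy `default_rng`).

Placement uses rejection sampling with a deterministic fallback that
enumerates all positions whose exclusion windows are free; dense requests
fail loudly rather than degrade. Note the random-parking bound: at spacing
*s* a region of length *L* fits only about 0.75·L/(2s) randomly placed
INDELs, so small toy genomes should request few INDELs per branch.

`true_alignment` emits the reference-coordinate alignment implied by the
truth directly (SNPs substituted, deletions as gaps, insertions dropped);
replicated power studies use it instead of re-aligning hundreds of genome
pairs, which exercises the estimator rather than the aligner.

What the generator does **not** emulate: read-level errors, assembly
artifacts, rate heterogeneity along the genome, recombination (absent in
plastomes), homoplasy from recurrent slippage at the same locus, and
cytometry debris/gating. Passing tests therefore demonstrate correctness
of the algorithms under clean, well-separated variation — not robustness
to raw-data pathologies upstream of these interfaces.

## Alignment and INDEL extraction

`align_pair` is global and end-to-end: unique shared 21-mers are chained
colinearly (longest increasing subsequence), and the segments between
anchors are aligned by affine-gap dynamic programming
(Bio.Align.PairwiseAligner; match +1, mismatch −2, gap −10 − 0.5·L). The
gap penalty deliberately favours one long gap over scattered short ones,
matching the discrete INDELs that separate near-identical plastomes.
Inputs below 5 kb skip anchoring; the anchored path reproduces full
dynamic programming on every inter-anchor segment (tested). Gap runs
become VCF-style anchored events, left-normalized against the reference;
normalization stops at position 2 so an anchor base always exists, and the
rare event at position 1 is suffix-anchored (VCF convention). Candidate
screening keeps rows with coverage > 200 **and** allele fraction > 0.60,
both strict.

## Motif classification

A single gap has several equivalent alignments inside repeats, so every
classification considers all equivalent placements of the event window in
the longer allele. The classes, calibrated so that all 19 published marker
cores reproduce their annotated motif column exactly:

* **single_nucleotide_repeat** — the allele is a homopolymer of ≥ 5 nt, or
  a shorter homopolymer whose merged run (allele + flanking same-base
  runs) reaches ≥ 8 nt, or any allele that directly abuts a mononucleotide
  run of ≥ 8 nt. The published panel contains a plain 5-T insertion with
  no adjacent run and several non-homopolymer events at long T-runs, which
  rules out a homopolymer-allele-only definition.
* **tandem** — non-homopolymer allele of ≥ 2 nt that equals the
  immediately adjacent sequence (full-copy duplication/contraction) or
  shares a common substring of ≥ max(4, ⌈|allele|/2⌉) with the adjacent
  window of its own length (partial duplication; the published tandem loci
  include 16 nt deletions that only begin with a copy of the adjacent
  9-mer).
* **ssr** — an exact tandem array of a non-homopolymer 2–6 nt unit with
  ≥ 3 copies overlaps or lies within 10 nt of the event. Requiring the
  allele to be a whole number of units would reject the panel's own SSR
  locus, whose events are 4 and 5 nt at a 5-mer/3-mer array.
* **no_motif** — none of the above.

Several classes can hold at once; the locus-level primary class uses the
precedence **snr > ssr > tandem**, which is how the published panel labels
loci whose run-adjacent events also sit in AT-rich repeat structure. An
independent brute-force scanner (all placements, all unit sizes and
offsets) agrees with the classifier on 1,000 random events in the test
suite.

## Markers and genotyping

Primer design scans the variant flanks for 20-mers (18–27 accepted) that
occur exactly once in the genome counting both strands, pairs them within
an amplicon window of 100–300 nt (spanning the published 135–250 nt
panel), and requires Wallace-rule (2AT+4GC) melting temperatures within
5 °C. No unique pair → `UndesignableError`, the path that models the five
published markers that failed to amplify. In-silico PCR uses exact-match
binding with a 2 kb product cap; zero or ambiguous products give no call.
Allele codes rank distinct amplicon lengths ascending (code 1 = shortest)
— published genotype tables do not state their coding order, so this is a
documented convention, and everything downstream depends only on code
identity, not values.

## Plastid types

Accessions sharing an identical allele-code vector over the marker panel
form one type; accessions with any missing panel call are excluded and
reported (the published matrix prints complete vectors only). Labels are
T01, T02, … in lexicographic vector order, independent of row order; an
alias map can restore published names. The published lineage tally keeps
collection regions apart — two row pairs of the printed matrix share a
vector across regions, and the printed "12 lineages" counts those rows
separately — so `stratify_by=("region",)` reproduces the printed partition
(12 lineages, largest domesticated type 25, *T. natans* marginal 10),
while the default un-stratified grouping yields the 9 distinct vectors,
with type W spanning Japan and China as one type. Both conventions are
first-class and tested.

## Distances and trees

Distances are TN93-family (two transition classes, one transversion
class, empirical base frequencies pooled over all sequences) with the two
transition/transversion rate ratios shared across pairs. All pairwise
distances and the two shared ratios are fitted jointly by maximizing the
composite (summed pairwise) multinomial log-likelihood with L-BFGS-B
(gradient tolerance 1e-8, log-parameterized, initialized from per-pair
closed-form TN93). Columns are dropped pair by pair (pairwise deletion);
per-pair usable-site counts and the union count are both reported, since
"usable positions" is ambiguous between the two. Saturated pairs get an
infinite, flagged distance with a diagnostic instead of silent NaN. With
`force_equal_rates` the per-pair maximum is the Jukes–Cantor closed form
and is evaluated analytically — the model-nesting tests assert equality to
1e-10.

Neighbor joining follows Saitou–Nei; Q-criterion ties break toward the
lowest index pair in current node order, and a negative branch length is
clamped to zero with the deficit moved to its sister so path lengths are
preserved where possible. On additive matrices the tree is exact (path
distances reproduce the input to 1e-9, tested against brute-force quartet
enumeration and the scikit-bio implementation as an independent oracle).
Outgroup rooting bisects the outgroup's pendant branch.

Variable-site counts ignore gaps and N: "all-variable" needs ≥ 2 distinct
bases among rows present; "parsimony-informative" needs ≥ 2 bases each in
≥ 2 rows. Both are exposed because "informative variations" is not defined
precisely by the source material.

## Cytometry and morphometry

Genome size is the internal-standard ratio formula; linearity of
fluorescence in DNA content with a single co-processed standard is
assumed, exactly as in the published table, and the estimate is invariant
to the arbitrary fluorescence units. Ploidy is 2·round(size/baseline)
(half up), with the baseline either fixed or the median of samples
flagged diploid; a ratio below 0.25 is rejected as an implausible
standard. Published peaks carry two decimals, so reproduction is checked
at 0.01% relative, not to the integer.

Seed summaries use sample SD (n−1); singleton groups report SD 0 with an
explicit flag. CT volumes come from labelled voxel masks (background /
pericarp / endosperm): endosperm volume is the endosperm voxel count times
voxel_edge³, total volume adds the pericarp ("total" = pericarp +
endosperm is a documented convention; the source phrasing is loose).
Interspecific ratios are ratios of group means — per-seed pairings do not
exist, and the aggregate ranges reported for domesticated-versus-wild
comparisons (total 4.2–4.5, endosperm 3.3–3.7) are ratios of group-level
quantities.

Morphometry presets place the taxa at incisa < japonica ≤ natans <
bispinosa in seed size, the domesticated total volume at 4.3× the
tetraploid wild taxon, and endosperm fractions truncated to the observed
53–68.9% band with the higher fractions in *T. japonica*. With those
presets the simulated endosperm-volume ratio lands near
4.3 × (0.56/0.67) ≈ 3.6, inside the reported 3.3–3.7 band.

## Problem sizes and numerical choices

Full-length (156 kb) simulation plus anchored alignment runs in about one
second and is exercised once per suite; the 100-replicate topology power
study uses ~10 kb genomes with branch SNP counts scaled to moderate
divergence and truth-derived alignments, a size at which the recovery rate
criterion (≥ 95%) is comfortably met while the study stays cheap to rerun.
Monte-Carlo acceptance checks (flow-peak recovery at 1% noise, JC-limit
agreement at d = 0.05 over 100 kb, morphometry ratios) use 3-SE bands
around generator truth. Optimization tolerances: L-BFGS-B gtol 1e-8 for
the composite likelihood; NJ arithmetic is plain float64 with no
tolerance beyond the 1e-9 additivity check in tests.

## Known limitations

* The pseudo-MSA is reference-projected pairwise alignment: insertions
  relative to the reference are dropped, which is adequate for
  ~99.9%-identical plastomes but loses insertion columns a full MSA would
  keep; distances use substitutions only.
* Primer binding is exact-match; mismatch tolerance and thermodynamic
  dimer/hairpin screening are out of scope, so wet-lab failure modes are
  modelled only by the undesignable/no-product paths.
* Events spanning the circular origin are out of scope; genomes are
  linearized at the LSC start (no published marker spans the origin).
* Motif-class thresholds are calibrated to one published 19-locus panel;
  other genomes may need different run-length or copy-number floors.
* The composite-likelihood fit shares rate ratios across pairs but not
  among-site rate variation; saturated or extremely divergent pairs are
  flagged rather than rescued.
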
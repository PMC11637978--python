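# Methods

`mitoribo` is a desk-scale re-implementation of the quantitative analyses
surrounding an LRPPRC–SLIRP mitochondrial translation study: spike-in
calibrated translation-efficiency (TE) estimation from mitoribosome
profiling with matched RNAseq, protected-fragment length profiling, a
helicase signature-motif screen, Dollo-parsimony ortholog-origin inference,
neighbor joining, and pLDDT-guided rigid-segment partitioning.  A seeded
synthetic-data generator stands in for deposited raw sequencing data, so
every analysis runs from scratch with no downloads.

## The simulated profiling design

The generator emulates a mixed-species design: human (target) and mouse
(spike-in) cell lysates combined 95:5 and sequenced as ribosome-protected
fragments (RPF) and matched RNA libraries, for a knockout (KO) versus rescue
contrast.

**Annotation.** Thirteen target features named after the human mtDNA-encoded
coding sequences, with realistic CDS lengths (207 nt for `MT-ATP8` up to
1,812 nt for `MT-ND5`), laid out non-overlapping on a single toy reference
with 50 nt intergenic gaps; `MT-ND6` is the only light-strand feature.
Three spike-in features (700–1,500 nt) represent the second organism.

**Sampling weights.** Every feature carries an absolute weight.  Target
transcript *f* weighs `abundance × rna_fold × te_fold × length_nt`, with
molar abundance 1 for every transcript by default, `rna_fold` applied only
in the KO condition, and `te_fold` applied only to KO RPF libraries
(footprint density is proportional to abundance times translation
efficiency).  The spike-in class has a *fixed* weight calibrated so that its
read share equals `spike_read_fraction` (default 0.05) in the rescue
condition.  Reads are multinomial over these weights.

This anchored mixing is the load-bearing modeling decision.  Because the
spike-in weight does not move with the knockout, the spike-in behaves as a
physical spike-in does: when KO depletes the mitochondrial transcriptome the
spike-in share of reads rises, and ratios of spike-normalized quantities
recover the programmed fold changes exactly in expectation.  Renormalizing
target weights among themselves while pinning the spike share per read
would, by contrast, make absolute fold recovery impossible (any
depth-or-spike normalization would then see only compositional changes of
roughly two-fold magnitude for this preset).

**Default KO preset.** Heavy-strand transcripts are reduced 1.6–3.8-fold,
strongest for the cytochrome c oxidase class and assigned deterministically:

| transcript | fold reduction | transcript | fold reduction |
|---|---|---|---|
| MT-CO1 | 3.8 | MT-ND4 | 2.0 |
| MT-CO2 | 3.4 | MT-ND2 | 1.9 |
| MT-CO3 | 3.0 | MT-ATP8 | 1.8 |
| MT-CYB | 2.6 | MT-ND4L | 1.7 |
| MT-ND5 | 2.4 | MT-ND1 | 1.6 |
| MT-ATP6 | 2.2 | MT-ND3, MT-ND6 | 1.0 (stable) |

All reductions sit strictly inside the observed 1.5–4-fold range, with the
extremes (1.6, 3.8) attained, so that fold changes recovered from finite
libraries respect the printed bounds with margin.  TE multipliers:
`MT-CO1 = MT-CO2 = 0.4` (a 2.5-fold reduction, clearing the more-than-two-fold
bound with margin), `MT-ND6 = 2.5`, all others 1.  The non-extreme
per-transcript values are implementation choices, not measured ground truth.

**Read geometry.** RPF lengths follow a discretized normal truncated to
[20, 45] nt — mean 33 nt (rescue) versus 31 nt (KO), SD 2 nt — creating the
qualitative shortening of protected fragments in KO; only the 2 nt mean
difference, not its absolute placement, is asserted anywhere.  RNA fragment
lengths are uniform on [50, 150] nt.  Start positions are uniform such that
the aligned span fits inside the feature.  With probability 0.1 a 1–5 nt
soft clip is attached on a random side; soft clips carry no information and
exist so the removal step has something to remove.  No nucleotide sequences,
alignment errors or library-prep biases are modeled — which is precisely why
parameter recovery here validates the *pipeline arithmetic*, not robustness
to real-data artifacts.

**Whole-cell RNAseq emulation.** Depth (CPM) normalization can only recover
per-transcript abundance folds when the library is dominated by an invariant
mass — in a real whole-cell library, the nuclear transcriptome.  The
generator emulates this by letting the invariant feature class carry 95% of
baseline reads (`WHOLE_CELL_BACKGROUND_FRACTION = 0.95`, a realistic order
for the non-mitochondrial share of a polyA library); the residual
compositional bias factor is `0.95 + 0.05·m ≈ 0.974` (where `m ≈ 0.47` is
the length-weighted mean KO fold), so a programmed 1.6-fold reduction is
recovered as ≈1.56-fold and a 3.8-fold as ≈3.70-fold.

**Determinism.** Every generator output is a pure function of its arguments
including the seed; the four-library contrast forks per-library seeds by
stable offsets so adding a library never perturbs existing ones.

## Counting and normalization

Soft clips are removed first: a read's reference span is the sum of its
M/D/N CIGAR runs from its 1-based position, and its protected-fragment
length is the number of aligned query bases (M/I runs), matching
query-length semantics for length histograms.  A read is assigned to the
unique feature overlapping its span by ≥1 nt; multi-feature overlaps are
ambiguous, intergenic reads unassigned, both excluded from counts but
tallied so `assigned + ambiguous + unassigned` equals the stream size.
Counting is unstranded (no strand rule is part of the emulated design, and
per-feature totals for single-feature mito transcripts are insensitive to
it).

The spike-in factor is the raw sum of spike-assigned reads — no per-million
rescaling, since every downstream contrast is a ratio in which the scale
cancels.  RPK is `count / (length_nt/1000)`; TE is spike-normalized RPF RPK
over spike-normalized RNA RPK per condition; contrasts are `log2(KO/rescue)`.
The pseudocount defaults to 0 with explicit undefined flags (NaN) instead of
a silent epsilon: mitochondrial transcripts are deeply covered, and hiding
zeros would mask simulation bugs.  By construction
`log2fc_synthesis = log2fc_rna + log2fc_te` exactly wherever all three are
defined.  When several libraries share an assay and condition their
normalized RPK values are averaged before TE is formed.

## Motif screen

Nineteen helicase consensus motifs (8 DDX, 8 DHX including a duplicate
`SAT`, 3 others) are compiled to exact-length regular expressions: `x`
matches any of the 20 residues; all other letters match case-insensitively
(lowercase letters such as the `g` in `RgxD` are ordinary residues — treating
them as wildcards would silently weaken the screen).  Matching allows
overlaps, reports 1-based positions, and the report asserts no positive
helicase classification (no threshold of matching families is defined for
such a call); the verdict "no helicase signature" is issued only for zero
hits.

## Dollo parsimony and neighbor joining

Under Dollo parsimony (one gain, unlimited losses) the loss-minimizing
single-gain placement on a rooted tree is the MRCA of all species possessing
the protein; losses are the maximal subtrees below the origin containing no
present species.  Tests verify minimality against exhaustive enumeration
over all loss-subtree subsets on trees up to 8 leaves.  Uncertain
presence cells (the tentative Trichoplax SLIRP call) are resolved by a
policy flag — `as-absent` (default, the conservative reading of a tentative
ortholog), `as-present`, or `both`.  The nine-species fixture tree encodes
the conventional ladder Bilateria ⊂ Eumetazoa ⊂ Metazoa with choanoflagellate,
filasterean, fungal and alphaproteobacterial outgroups; the Metazoa-root origin
of LRPPRC/mS31 is invariant to the unresolved placozoan/sponge branching.

Neighbor joining is the classical Q-criterion algorithm, exact on additive
matrices.  Determinism choices: ties on Q go to the lexicographically
smallest label pair (clusters keyed by smallest member leaf), and negative
branch lengths are clamped to zero with the deficit moved to the sister
branch.  An independent cross-check against scikit-bio's NJ runs in the test
suite; the in-package implementation is what the pipeline uses.

## Mobility segmentation

Per-residue pLDDT is converted to a mobility proxy `m = 100 − pLDDT` (the
simplest transform honoring the inverse confidence–mobility relation;
configurable).  The chain is partitioned into exactly N contiguous segments
minimizing total SSR of a per-segment polynomial (default order 2: a rigid
body produces a smoothly varying equivalent mobility along the chain that a
quadratic captures; a full 3-D TLS tensor fit is deliberately out of scope —
the reusable part is the exact partitioning).  Interval SSRs come from
prefix sums of polynomial moments with the abscissa scaled to [−1, 1] for
conditioning (fit SSR is invariant under affine reparametrization); the DP
over precomputed interval costs is exact, ties broken toward the earliest
boundary, and is verified against brute-force enumeration for short
profiles.  `min_len` defaults to 5 residues (and is raised to order+1 when
needed) to forbid degenerate one-residue segments.  Leading/trailing ranges
(for example a mitochondrion-targeting sequence at residues 1–59) can be
trimmed; interior trims are rejected because they would break contiguity.
The residual-versus-N curve is non-increasing by construction, and on
synthetic profiles with well-separated segment means (≥5× the noise SD) its
largest relative drop sits at the true segment count, with breakpoints
recovered within ±10 residues across seeds.

## Problem sizes and numerical conventions

Library sizes are chosen to make the statistical claims crisp at interactive
runtimes: 10^6 reads for read-composition and whole-cell abundance checks
(binomial 3-SD half-width ≈ 0.065 percentage points on the 95% share),
2×10^5 reads per library for TE recovery (shared spike-count fluctuations
correlate per-transcript TE estimates within a run; the median across seeds
1–5 recovers programmed folds within 10%).  All tables are TSV; SAM output
carries a minimal `@HD`/`@SQ` header; only CIGAR ops M/I/D/S/N are accepted
(H/P/=/X are rejected as out of scope for transcriptome alignments).
Annotation coordinates are 0-based half-open (BED convention), SAM positions
1-based; the conversion happens exactly once, inside counting.

## Known limitations

* The generator validates pipeline arithmetic, not robustness to mapping
  errors, PCR duplicates, multi-mappers or library-prep bias — none of which
  are modeled (duplicate removal and junction handling are treated as
  upstream concerns).
* TE contrasts carry no replicate model or significance testing; published
  differential-expression machinery is intentionally out of scope.
* The whole-cell emulation collapses the entire non-mitochondrial
  transcriptome into an invariant class; real nuclear expression changes
  would propagate into CPM folds.
* Segmentation replaces the 3-D TLS tensor model with a 1-D polynomial fit,
  so exact boundary agreement with a full TLS analysis of a real predicted
  structure is not guaranteed; on a real pLDDT profile the method is a
  change-point analysis of confidence, nothing more.
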
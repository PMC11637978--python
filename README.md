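# mitoribo

A desk-scale pipeline for the quantitative analyses behind an
LRPPRC–SLIRP-dependent mitochondrial translation study: spike-in calibrated
translation efficiency (TE) from mitoribosome profiling with matched RNAseq,
protected-fragment length profiling, a helicase signature-motif screen,
Dollo-parsimony ortholog-origin inference with neighbor joining, and exact
rigid-segment partitioning of per-residue pLDDT mobility profiles.  A seeded
synthetic-data generator emulates the study's mixed-species (95:5
human:mouse) knockout-versus-rescue sequencing design, so the whole pipeline
builds, runs and tests itself with no external data.

Who it is for: anyone who wants a small, fully tested reference
implementation of these analyses — the normalization chain, the parsimony
and tree algorithms, and the change-point segmentation — on data whose
ground truth is programmable.

## The statistics at the core

For transcript *f*, with counts `c` summed across coding features after
soft-clip removal:

```
RPK_f   = c_f / (L_f / 1000)                  feature-length normalization
S_lib   = Σ_spike c                           spike-in scale factor (raw sum)
norm_f  = RPK_f / S_lib                       spike-in normalization
TE_f    = norm_f(RPF) / norm_f(RNA)           translation efficiency
log2FC  = log2( X_f(KO) / X_f(rescue) )       for X ∈ {RNA, TE, synthesis}
CPM_f   = c_f / Σc × 10^6                     read-depth normalization
```

with the exact decomposition `log2FC_synthesis = log2FC_RNA + log2FC_TE`.
Dollo parsimony places a protein's origin at the MRCA of the species
possessing it and counts the maximal ortholog-free subtrees below as losses.
Segmentation minimizes total per-segment polynomial SSR of the mobility
proxy `100 − pLDDT` over all partitions into N contiguous runs, by exact
dynamic programming.

## Worked example

```bash
python analysis/02_te_analysis.py --seed 1
```

simulates the four matched libraries (RPF/RNA × rescue/KO, 200,000 reads
each), counts, normalizes and prints:

```
COX1 TE reduced 2.46-fold, COX2 2.53-fold (both > 2-fold);
ND6 TE increased 2.54-fold (> 2-fold); other transcripts near unity.
```

i.e. the knockout's programmed transcript-specific translation effects
(COX1/COX2 multiplier 0.4, ND6 2.5) are recovered from raw simulated reads
through the full counting-and-normalization chain.  The other drivers follow
the same pattern:

| script | what it shows |
|---|---|
| `analysis/01_simulate_libraries.py` | emits SAM libraries under the 95:5 mixing design |
| `analysis/03_fragment_lengths.py` | KO protected fragments 2 nt shorter than rescue |
| `analysis/04_rna_abundance.py` | heavy-strand RNA reductions recovered inside 1.5–4-fold |
| `analysis/05_helicase_motifs.py` | 19-motif screen; recovers planted motifs, zero hits on clean sequences |
| `analysis/06_ortholog_origins.py` | LRPPRC/mS31 origin at the Metazoa root, zero losses |
| `analysis/07_segment_mobility.py` | N=4 rigid segments of a synthetic 1394-residue profile, residual curve |

Each writes its tables under `results/`.  The same functionality is exposed
as subcommands of the `mitoribo` CLI (`simulate`, `count`, `lengths`, `te`,
`motifscan`, `dollo`, `nj`, `segment`, `run-all`); `run-all` produces a
checksum manifest, so identical configs yield byte-identical manifests.

To screen a real protein (for example an LRPPRC FASTA exported from UniProt
P42704) for helicase motifs: `mitoribo motifscan --fasta lrpprc.fa --out
hits.tsv` — the expected result is zero matches.

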
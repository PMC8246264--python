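# splicekit

Analyses for a zebrafish *mbnl* loss-of-function model of myotonic
dystrophy: cassette-exon mis-splicing, MBNL-binding-motif (YGCY) positional
enrichment, cross-species exon orthology, genotype clustering, swim-test
kinematics, and the shared statistics layer — with a synthetic-data module
so every stage runs end-to-end without any sequencing download.

MBNL-family RNA-binding proteins control alternative splicing by binding
YGCY elements (Y ∈ {C, U}) around cassette exons; their functional loss —
the core lesion of myotonic dystrophy — produces direction-consistent
mis-splicing across tissues and species. The package implements the
computational side of a multi-mutant zebrafish study of this biology:

- **PSI arithmetic and filtering** (`splice_events`): percent spliced in
  from RT-PCR band intensities, PSI = inc/(inc+exc)×100; ΔPSI =
  mean(mutant) − mean(WT); mis-splicing at FDR < 0.10; regulation classes
  at FDR < 0.05 and |ΔPSI| > 0.2; a consensus set of cassette exons
  significant in ≥ 4 of 7 mutant lines; the |log₂FC| ≥ 1, FDR < 0.05
  differential-expression filter.
- **Motif enrichment** (`motif_enrichment`): YGCY frequency versus
  composition-matched control 4-mers (equal A+T base count and CG
  dinucleotide count) in five windows per cassette exon — the exon, 250 nt
  of intron on either side of it, and 250 nt of intron adjacent to the
  flanking constitutive exons — reported as
  log₂(enrichment in regulated / enrichment in non-regulated exons).
- **Exon orthology** (`ortholog_map`): an exon pair is orthologous iff the
  host genes are ≥ 75% identical (global protein alignment), the exons share
  a transcription-order index in at least one transcript pair, and a
  translated Smith–Waterman alignment scores E < 0.05
  (E = K·m·n·e^(−λS), BLOSUM62 gapped constants K = 0.041, λ = 0.267);
  concordance of ΔPSI across species is Spearman's ρ.
- **Clustering** (`cluster_analysis`): top-800 most variable cassette
  events, gap statistic for the cluster count, K-means partition of fish.
- **Swim kinematics** (`behavior_kinematics`): total distance, percent time
  active (pauses = ≥ 20 consecutive frames with no between-frame speed
  > 1.5 cm/s), active-swimming speed, fastest 100-frame window speed, and a
  0–100 vertical position index in an 18 × 25.4 × 7.6 cm novel tank.
- **Statistics** (`stats_core`): one-way ANOVA + Tukey HSD with a compact
  letter display, unpaired t-test, Spearman ρ, Benjamini–Hochberg FDR,
  chi-square Mendelian-ratio fit, and ΔΔC_T relative expression normalized
  to *eef1a1l1*.
- **Synthetic data** (`synthetic_data`): generators for multi-genotype PSI
  tables with planted direction-consistent mis-splicing, gene sequences with
  controlled per-window YGCY densities, and active/pause swim trajectories —
  each a pure function of its seed, each returning the ground truth needed
  to score the downstream analysis.

## Worked example

`analysis/` holds the numbered pipeline drivers. After
`python analysis/01_simulate_study.py --seed 1` (seven mutant lines with
graded planted |ΔPSI| from 0.15 to 0.51, three replicates each, 800 cassette
events), `python analysis/02_splicing_filters.py` prints:

```
consensus set (>=4 of 7 lines): 76 cassette exons

recovery of planted events (recall rises with planted |ΔPSI|):
          planted  called  recovered  recall
line0         200      68         64   0.320
line3         200     169        160   0.800
line6         200     208        194   0.970
```

Weakly mis-spliced lines (planted |ΔPSI| ≈ 0.15) are mostly invisible at
FDR < 0.10 with three replicates, while strong effects are nearly always
recovered — the consensus set therefore concentrates on robustly shifted
exons. `analysis/04_motif_enrichment.py` then reproduces the positional
signature of direct MBNL regulation on sequences with motifs planted
accordingly:

```
region                                    mbnl_activated  mbnl_repressed
cassette_exon                                       0.01            8.15
intron_3prime_of_cassette                           8.92           -0.00
intron_5prime_of_cassette                           0.03            8.95
```

Positive log₂ cells sit exactly where motifs were planted: downstream
intron for Mbnl-activated exons, upstream intron and exon body for
Mbnl-repressed exons; all other cells are ≈ 0.

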
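# Methods

## Conventions

Inclusion levels (PSI) are kept on the 0–1 scale throughout; the ×100
percent scale is display formatting only (the RT-PCR band formula returns
percent because that is its natural output). All genomic coordinates are
0-based half-open internally; GFF3 input (1-based closed) is converted on
read, BED12 and rMATS SE coordinates pass through unchanged. Exons are
indexed in transcription order: exon 0 is the 5′-most exon on the coding
strand, the rightmost block of a minus-strand transcript. One coordinate
convention and one exon-order convention eliminate the off-by-one drift
that otherwise accumulates between BED- and GFF-derived structures.

## Splicing filters

Mis-splicing significance is FDR < 0.10 (strict), regulation classes
require FDR < 0.05 and |ΔPSI| > 0.2 (both strict), and the
differential-expression filter is |log₂FC| ≥ 1.0 (inclusive) with
FDR < 0.05. The fold-change bound is the one threshold whose printed form
does not state an inequality direction; it is taken inclusive and is
configurable. ΔPSI is the mutant-minus-WT difference of replicate means.
An exon whose inclusion rises on Mbnl loss is *Mbnl-repressed* (the protein
normally suppresses it); one whose inclusion falls is *Mbnl-activated*.
Events with missing replicate PSI are dropped from variance and magnitude
computations, never imputed. Event-type tallies do not deduplicate
overlapping events across types.

## Motif enrichment

Two 4-mer presets ship: the canonical YGCY expansion
{TGCT, TGCC, CGCT, CGCC} (default) and a published variant list
{GCTT, CGCT, TGCT, GCGC} that departs from the strict YGCY pattern; both
are selectable and neither is silently corrected to the other.

Controls for a motif are all 4-mers with the same A+T base count and the
same CG-dinucleotide count (overlapping positions 1–2, 2–3, 3–4), minus the
entire analysis motif set — excluding all motifs, not just the query,
prevents the control mean from absorbing signal. Occurrences are counted at
every offset (overlaps included); windows containing N at a position never
match there.

The five windows per cassette exon are the exon body, the last/first 250 nt
of the upstream/downstream intron (adjacent to the cassette), and the
first/last 250 nt of the same introns adjacent to the flanking constitutive
exons. Short introns are truncated: when the two windows claiming one
intron would overlap, each is cut at the intron midpoint, with the
cassette-adjacent window taking the extra base on odd lengths. Minus-strand
windows are extracted from mirrored genomic intervals and
reverse-complemented, so "5′/3′" always means transcriptional direction.

Enrichment pools counts across a window set (pooled occurrences over pooled
nucleotides) rather than averaging per exon; the motif side of the ratio is
the mean per-motif count so that equal motif and control densities give a
ratio of exactly 1. A pseudocount of 1 occurrence (configurable) on the
motif mean and on each control count keeps the log₂ heatmap finite at zero
counts. Non-regulated exons default to tested cassette exons with FDR > 0.5
and |ΔPSI| < 0.05; both cutoffs are configurable.

## Exon orthology

Gene conservation is global percent identity — identical aligned pairs over
alignment columns — under BLOSUM62 with affine gaps (open 11, extend 1);
`X` never counts as a match. The measure is deliberately simple and
documented because alternatives (coverage-weighted identity, CDS nucleotide
identity) are equally defensible; the threshold (75%, inclusive) and the
criterion itself can be toggled.

The translated search is an in-package Smith–Waterman over all pairings of
the three forward-frame translations per side (exon sequences arrive
coding-strand oriented; a flag adds reverse frames), BLOSUM62, gaps 11/1.
The e-value is the gapped Karlin–Altschul closed form E = K·m·n·e^(−λS)
with K = 0.041 and λ = 0.267, where m and n are the total translated
residues over the searched frames — the search space reflects every frame
pairing actually examined. When a database size in nucleotides is supplied,
n becomes db_size/3. These e-values are internally consistent rather than
calibrated to any external database, which is sufficient for thresholding
at 0.05 (strict). On random 120-nt pairs the null e-value falls below 0.05
in well under 5% of draws, so the threshold behaves conservatively.

The exon-position criterion is existential: two exons match if any
transcript of gene A and any transcript of gene B assign them the same
1-based transcription-order index.

## Clustering

The most variable cassette events are selected by across-sample PSI
variance with lexicographic event-id tie-breaks (deterministic selection);
only events with complete PSI coverage are eligible. PSI columns share the
[0,1] scale, so no standardization is applied by default (a flag exists).

The gap statistic uses the PCA-aligned bounding-box uniform reference
(Tibshirani's recommended variant), Gap(k) = mean_ref[log W*] − log W with
W the pooled within-cluster sum of squares, s_k inflated by √(1 + 1/B), and
the usual smallest-k selection rule Gap(k) ≥ Gap(k+1) − s_{k+1}. Reference
draws are a pure function of the seed. Identical samples short-circuit to
k = 1 rather than taking log 0.

K-means is Lloyd's algorithm with k-means++ seeding, best of 25 restarts
(ties go to the earliest restart), and the within-cluster objective is
asserted non-increasing at every iteration; emptied clusters are reseeded
on the farthest point. Cluster ids are canonicalized by first appearance so
that permuting samples permutes assignments identically. The study both
reports the gap-selected k and forces the two-center partition; on data
with graded effect sizes across many genotypes the two can legitimately
disagree, so the pipeline returns both.

## Swim kinematics

Between-frame speed is Euclidean displacement × fps. A pause is a maximal
run of ≥ 20 consecutive speeds (2 s at the 10 fps default) none of which
exceeds 1.5 cm/s — a speed of exactly 1.5 stays inside a run, per the
stated wording. Fastest speed is the best mean over 100 consecutive frames
(50- and 30-frame windows, and the mean of the 30 fastest non-overlapping
1-s bins, are available as robustness variants; non-overlapping bins were
chosen for determinism). The vertical index is the frame-mean of
100 × height/depth with the 18 cm tank depth as default calibration;
image-convention input (y down) is flipped at read time.

Dropped tracking frames make the spanning speed undefined: undefined
speeds terminate pause runs, are excluded from speed means, invalidate
fastest-speed windows containing them, and contribute no distance. This is
the conservative choice — no motion is invented across a gap. No smoothing
is applied to tracked positions.

## Statistics

"Ordinary" one-way ANOVA is the equal-variance fixed-effects decomposition
(a Welch-type variant is behind a flag); all-groups-identical input returns
F = 0, p = 1 rather than NaN. Tukey HSD uses the studentized-range
distribution with the Tukey–Kramer correction for unbalanced groups (via
scipy, which evaluates the distribution numerically). The compact letter
display uses the insert-and-absorb algorithm at α = 0.05; its defining
property — two groups share a letter iff their adjusted p ≥ α — is enforced
by round-trip tests. Benjamini–Hochberg q-values follow the step-up
definition with monotonicity enforcement. ΔΔC_T fold changes are
2^(−ΔΔC_T) after per-sample reference-gene normalization and calibrator
centering. Reporting supports both mean±s.d. and mean±s.e.m.; the choice is
explicit, never defaulted.

## Synthetic data

The splicing generator draws a latent baseline PSI uniform on [0.05, 0.95]
per event, adds logit-normal replicate noise (sd 0.3, a typical
biological-replicate scale), and observes binomial inclusion reads over a
Poisson junction total (mean 100 by default; 150–500 in the scripted
studies). Planted events shift the latent PSI by |ΔPSI| ~ N(δ, 0.1) in one
direction shared across all mutant genotypes — mis-splicing from a common
regulatory lesion is direction-consistent — and baselines that cannot
accommodate a drawn delta are resampled rather than clipping the effect.
Defaults mirror the study design: three biological replicates per genotype,
seven mutant lines in the scripted study. Significance on synthetic tables
is a two-sample t-test on empirical-logit PSI with BH correction across
events; this stands in for the upstream caller's likelihood model — the
table schema is identical either way, and it is the filtering and
summarization downstream of the caller that this package implements and
tests.

The sequence generator writes one gene per contig on a random strand,
background bases i.i.d. (25% each by default, configurable because the
controls are composition-matched), with every analysis-motif occurrence
scrubbed from the background so planted counts are exact; motifs are then
planted without overlap at Poisson counts around density × length/100 per
window. The trajectory generator integrates piecewise-constant segment
speeds with a persistent noisy heading, reflecting the heading before each
step so per-frame displacement equals speed/fps exactly even at walls;
positional jitter is added after integration and never alters ground-truth
mode labels.

What the generators do not emulate: read-level sequencing artifacts,
junction-mapping ambiguity, isoform interdependence among events,
covariance between exons of one gene, tracker detection noise beyond
Gaussian jitter, and fish behavior beyond piecewise-constant speeds.
Passing tests therefore demonstrate the correctness of the filtering,
counting, alignment and segmentation logic under the stated statistical
structure — not robustness to upstream artifacts those tools must handle.

## Problem sizes

The test suite and acceptance script scale simulations to desk-size:
200–800 events per splicing table, 60–200 exons per motif class (25–50
seeds for null calibration), 200 random pairs for the orthology null,
100 seeds × 30 samples for gap-statistic selection, 3,000-frame
trajectories, and 10,000 replicates for type-I calibration. These sizes
give the property checks comfortable statistical resolution while keeping
a full run to a few minutes.
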
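# Methods

## Labeling model and the stability score

The pipeline assumes constant transcription during the labeling pulse
and first-order decay — the simplest model under which the
labeled/unlabeled split is informative about decay. For synthesis rate
*s* (transcripts/h), decay rate *k* (1/h) and pulse length *t* (hours,
default 1.0), steady state gives total = *s/k*, labeled =
*(s/k)(1 − e^{−kt})*, unlabeled (FT) = *(s/k)e^{−kt}*; conservation
(total = labeled + FT) is exact by construction. The stability score
SS = log₂(FT/4sU) is then log₂(e^{−kt}/(1 − e^{−kt})), strictly
decreasing in *k*. SS is a relative stability readout, not a half-life
estimate; if transcription changes during the pulse, newly made and
pre-existing pools come from different regimes and SS is biased — the
model deliberately does not attempt to correct for that.

A pseudocount (default 1 normalized-count unit, disable with
`pseudocount=0`) keeps SS finite when one pool has no reads; the ≥ 5
read expression filter limits its influence. SS is computed per
replicate and replicates are averaged afterwards (rather than averaging
abundances first); differential stability across conditions is a
one-way fixed-effects ANOVA on the replicate SS values, reported with
raw p (default decision threshold) and BH q alongside. Degenerate
inputs: all-equal replicate values return (F = 0, p = 1); zero
within-group variance with real between-group spread returns
(F = ∞, p = 0).

## Normalization

Counts are filtered (max over samples ≥ 5 reads; a strict > 5 variant
is available) and normalized by the median-of-ratios method: per-sample
factors are medians of count/geometric-mean ratios over rows with no
zeros, then rescaled to geometric mean 1 so normalization is
idempotent; an error instructs fallback to library-size scaling when no
all-positive row exists. Factors are estimated within fraction type
(total/4sU/FT) by default because the three library types have grossly
different compositions; a global mode exists.

SS, RE and ΔSS are computed on these size-factor-normalized abundances,
not on per-million-rescaled values. Rescaling each sample to its own
per-million total would divide by a sample-specific denominator that
moves with the very composition changes under study, shifting every
unaffected transcript's SS in the affected condition; in a perturbation
study this inflated the ANOVA false-positive rate from ~5% to up to
13%. Normalizing raw RPM by median-of-ratios (the procedural
description this pipeline follows) is algebraically identical to
count/size-factor, since median-ratio factors absorb any per-column
scaling. An `rpm` table (per-million of the normalized total) is still
produced for reporting.

## Synthetic data

The generator emulates the study design it stands in for: three
conditions ("cell lines") × {total, 4sU, FT} × 2 replicates; 1–3 PASs
per 3′-most exon (defaults 43/37/20%, putting ~57% of genes in the
APA-pair analysis); intronic PASs in 25% of genes; half-lives
log-normal with median 4 h and log-sd 0.8 (a typical mammalian mRNA
range, ~0.5–30 h); per-gene synthesis rates log-normal (log-sd 1.0)
split across isoforms by a Dirichlet draw; distal isoforms modestly
less stable than proximal (median k ratio 1.3 per step) and intronic
isoforms less stable than their genes (median ratio 2.0) — the
directional defaults matching the biology the analyses are meant to
detect; decay-rate scalings per gene type (lncRNA 2.5×, pseudogene
1.8×) so gene-type stability comparisons have signal. Per-condition
decay columns (`k_<condition>`) start equal and are perturbed directly
by the validation studies.

Counts are multinomial per library with Poisson library sizes around
the configured depth (log-normal jitter, sd 0.05). An optional
symmetric cross-contamination parameter mixes the labeled and unlabeled
pools (default 0; the fractionation efficiency of a real pulldown is
not calibrated).

Reads are single-end, fixed length (50 nt aligned), emitted as minimal
valid SAM using the antisense 3′-end-seq convention: the read is
sequenced from the transcript 3′ end, so its 5′ end carries the
reverse-complemented poly(A) tail as a soft clip of Ts (in read
orientation) and its first aligned base sits on the cleavage site. A
plus-strand transcript therefore yields a reverse-strand record with a
trailing stored clip of As; a minus-strand transcript a forward record
with a leading T clip. The few bases a tail clip would occupy beyond
each cleavage site are kept free of templated adenosines so genuine
tail Ts are unambiguously non-genomic; internal-priming-like noise is
modeled instead by decoy reads (random positions, 0–1 clipped Ts) and a
configurable fraction of sub-threshold mapping qualities. Sequencing
errors, PCR duplicates and quality strings are out of scope.

What the generator does **not** emulate: alignment artifacts, templated
A-stretch internal priming, 3′-end microheterogeneity correlated with
sequence context, batch effects, or fraction-specific biases beyond
library size. Passing tests therefore demonstrate correctness of the
analysis logic under the stated model, not robustness to every real
artifact.

## PAS discovery

A read is a PAS read iff mapping quality ≥ 10, aligned length ≥ 23 nt
(defensive; trimming happens upstream) and the number of consecutive Ts
at the start of its read-orientation 5′ soft clip that do not match the
reference when laid back on the genome is ≥ 2. A clip T matching its
templated base (the complement rule applies for reverse-strand records,
so a genomic A-run downstream of a plus-strand site makes the Ts
genomic) terminates the run; positions beyond the contig are treated as
non-genomic. The cleavage site is the position of the read base
adjacent to the clip; the site strand is opposite the alignment strand.

Cleavage sites are clustered within 24 nt by greedy summit absorption:
repeatedly take the unassigned site with the highest total count (ties:
smaller coordinate) and absorb unassigned same-chrom/strand sites
within the window. The cluster's reported position is the summit (a
convention; the most distal member would be an alternative). Clusters
are assigned to the strand-matched gene containing the summit; with
same-strand overlap (possible in user-supplied annotation, never in
generated annotation) the gene with the closest 3′ end wins, with a
warning. Region classes: TPA (3′-most exon), IPA (intron, host
recorded), other_exonic, intergenic; no downstream extension is
applied, so a summit past the annotated gene end is intergenic.

Coordinates are 0-based half-open internally; BED output is 0-based,
GTF is converted from/to 1-based on IO.

## APA analytics

Per gene, the two 3′-most-exon clusters with the highest combined
total-fraction expression across conditions are selected (tie: the more
proximal), labeled pPAS/dPAS by strand-aware order;
aUTR size is the genomic distance between the two summits (no splicing
within the 3′UTR assumed). RE = log₂(dPAS/pPAS) per sample; RED is the
RE difference between samples or conditions (positive = lengthening).
Usage shifts between two conditions use a 2×2 Fisher exact test on
pooled raw counts with BH FDR, calling lengthened/shortened when
p < 0.05 and the absolute dPAS relative-abundance difference exceeds
0.05 (the threshold is applied to the absolute value). Isoform
stability differences per condition use Fisher on
[pPAS, dPAS] × [4sU, FT] pooled counts, FDR < 0.05, with the sign of
ΔSS = SS(dPAS) − SS(pPAS) giving direction (red = dPAS more stable,
blue = pPAS more stable); replicates are pooled rather than modeled — a
generalized linear isoform-usage model was deliberately traded for a
fully specified exact test. IPA events compare each intronic cluster
with the gene's most abundant TPA cluster (`tpa_ref="sum"` compares
against the summed TPA signal instead) and are binned by host-intron
size and consumed MaxEnt-style splice-site scores; bins with missing
scores are skipped with a warning.

Quintile binning is rank-based with stable tie-breaking: bin sizes
differ by at most one, bins are ordered by the variable, and the
response distribution in bin 1 vs bin 5 is compared by a two-sided
rank-sum test (exact null for small untied samples).

## Feature regression and motifs

Features are computed on the sense strand: GC/U content of the mature
transcript, 3′-most exon, 3′UTR (annotation anchor to the most distal
PAS) and aUTR (pPAS→dPAS interval); mature-transcript and region sizes;
junction density = junctions per kb of mature transcript; 3′UTR PAS
count from observed clusters (annotated positions as fallback).
Individual R² is the squared Pearson correlation with the response
(identical to the one-variable least-squares R²); features are sorted
by it, and cumulative R² at rank *j* is the OLS R² on the top-*j*
features, z-scored for conditioning (R² itself is scale-invariant).
Constant features score 0 and are excluded from the cumulative fit;
rows with missing values are dropped.

Hexamer enrichment counts overlapping occurrences pooled across
sequences (a per-sequence presence/absence mode is available), tests
each hexamer with a 2×2 Fisher exact ([this hexamer, all others] ×
[fg, bg]) and BH q; the top 10 enriched hexamers (odds ratio > 1,
q < 0.05) are stacked ungapped into a 4×6 position-frequency matrix
(offset alignment of hexamers is out of scope).

## Structure scoring

Sequences are scanned in 100-nt windows with 50-nt steps; only full
windows are kept, and a sequence shorter than 100 nt gets a single
full-length window so short 3′UTRs are not discarded. The window count
is 1 for L < 100, else ⌊(L − 100)/50⌋ + 1. The per-sequence score is
the median window MFE; failed windows are skipped with a warning.

The default engine is a Nussinov-style maximum-base-pairing dynamic
program (GC/AU/GU pairs, minimum hairpin loop 3, −1 per pair): a
surrogate pseudo-energy that ranks pairing potential but is **not**
thermodynamic. An adapter shells out to ViennaRNA's `RNAfold` for
kcal/mol values when it is installed; the engines' rank agreement is
checked on a panel of composition-varied sequences (uniform-random
sequences of equal composition have almost no pairability spread to
rank, so the smoke-test panel draws base compositions from a
Dirichlet). Partition functions, pseudoknots and pairing-probability
output are out of scope.

Per-position probing signal is summarized by the Gini index
G = Σᵢⱼ|xᵢ − xⱼ| / (2n²x̄) per 100/50 window (the same windowing as the
MFE scan, chosen for internal consistency — a declared convention),
median per region; all-zero windows are skipped and an all-zero region
is missing.

## Validation studies and problem sizes

The studies behind `scripts/acceptance.py` and the acceptance tests
run at desk scale: SS-vs-half-life recovery on 500 genes at 2×10⁵
reads/sample (Spearman ≥ 0.9 expected); PAS round trip on 60 genes at
2×10⁴ (exact recovery; decoy precision 1.0 with 30% decoys);
clustering vs an independent re-implementation on 1000 random ≤12-site
instances; ANOVA power/FPR at the package's default experiment size
(200 genes at 2×10⁵ reads/sample, i.e. ~10³ reads/gene/sample — the
per-gene coverage regime of real 3′-end-seq libraries; at 5× more genes
per read the small-sample ANOVA's gene-level power drops to ~0.7–0.85),
with genes represented by their most expressed PAS isoform; APA/IPA
directionality on 300 genes with 4× (dPAS) and 3× (IPA) decay-rate
perturbations; Fisher/rank-sum vs full enumeration on 500/50 random
instances; regression recovery (0.8·zGC − 0.4·zU + ε, n = 2000, 100
replicates); and a full-pipeline double run compared byte-for-byte.

## Known limitations

- SS is biased when transcription changes during the pulse; no
  correction is attempted.
- The exact-test route ignores replicate-level overdispersion
  (replicates are pooled), so its p-values are optimistic for genes
  with real biological replicate variance.
- The surrogate folding engine saturates on pairing-rich sequences and
  carries no stacking or loop energetics; use the RNAfold adapter for
  thermodynamic values.
- The small-sample ANOVA (two replicates per condition) runs slightly
  above its nominal level for low-count transcripts, whose log-ratio
  noise is heavy-tailed.
- Gene assignment has no 3′-end extension; sites just downstream of an
  annotated gene end are intergenic.
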
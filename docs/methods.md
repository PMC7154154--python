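# Methods

This note records the models, conventions and numerical choices behind
`varepi`, and what the synthetic benchmark does and does not establish.

## Coordinates and site overlap

VCF and GTF coordinates are 1-based inclusive; BED/narrowPeak are 0-based
half-open.  Internal arithmetic is 1-based; a variant's BED interval is
`(pos-1, pos-1+|ref|)`.  Indels are VCF-style (anchor base shared between
ref and alt) and are located by their anchor position for region
classification and state calling.

Peak overlap at a variant site compares the variant's position directly
against the half-open peak interval (`start <= pos < end`), so a site at
the exclusive end coordinate of a peak is outside it.  The 4-kb peak-count
profiles use the same frame, which makes them exactly translation
invariant.

## Region classification

Each variant receives one category by fixed precedence: `exonic > UTR5 >
UTR3 > intronic > ncRNA_intronic > upstream > downstream > intergenic`.
Within one transcript, an exon base annotated as UTR is UTR; across
transcripts the highest-precedence label wins.  "Upstream"/"downstream"
are the 1-kb (configurable `flank`) bands beyond the TSS/TES in gene
orientation.  Splicing and exonic-consequence subcategories are collapsed
into `exonic`; introns of noncoding-biotype transcripts are
`ncRNA_intronic`.  Gene assignment is nearest TSS by absolute distance,
ties to the lexicographically smaller gene id (deterministic and logged);
the signed distance is negative upstream of the TSS in gene orientation.
Fold enrichment for category c is `(n_c/N)/(L_c/L)`, with `L_c` measured
by painting the genome base-by-base with the same precedence; the ratio is
invariant under rescaling all lengths.  TSS-distance profiles default to
±2500 bp in 50-bp bins; bin width is not a published constant and is
configurable.

## Epigenetic state model

Activating marks (H3K4me3 for promoters, H3K27ac for enhancers) give
states A/I per condition; repressive signals (H3K27me3, DNA methylation)
give In/T, where "T" is implemented as the permissive complement of
"inhibited".  A switch class is the rendered pair, e.g. `A->A`, `I->A`.
A variant is *epigenetically stable* when its H3K4me3 or H3K27ac class is
`A->A`; a variant qualifying under both marks counts once and is flagged
(`via="both"`), with H3K4me3 recorded as the primary mark.  Repressive
stability is not required by default (the expected In/T switch counts are
zero in this design) but can be enforced with
`require_repressive_stable`.  DNA methylation input is accepted either as
region BEDs or as per-CpG levels, converted with a default of mean
methylation ≥ 0.5 over 200-bp windows, adjacent methylated windows merged.

## Differential expression

Expression is analysed as log2(TPM+1); the +1 pseudocount handles zeros.
The per-gene test is Student's pooled-variance two-sample t
(df = n1+n2−2).  The common-variance assumption matches the linear-model
variance structure that limma-style analyses rely on; with 3–5 replicates
it is decisively more powerful than Welch's t, whose effective df collapses
toward min(n)−1 when the two sample variances draw apart by chance (at
n = 3, σ = 0.3 and a 4-fold effect, measured sensitivity is ~0.97 pooled
vs ~0.79 Welch).  Welch remains available (`equal_var=False`).
Benjamini–Hochberg adjustment runs across tested genes (all-zero genes are
excluded from the family and reported `ns`; with a single replicate
calling is fold-change-only and loudly logged).  Calling presets:
`default` = |FC| > 2 and FDR < 0.05; `strict` = |FC| ≥ 4 and raw
p ≤ 1e-5.  Fold change is computed on the log2(TPM+1) scale.  Percentages
in overlap summaries are rounded half-up to two decimals, matching printed
tables.  The paired target-shift test takes one observation per target
gene — the difference of per-condition mean log2(TPM+1) — into a standard
paired t-test.

## Motif model

A PFM column with counts `c` becomes probabilities
`p = (c + 0.5)/(colsum + 2)` and natural-log weights `ln(p/bg)` with a
flat background by default (optionally estimated from the supplied
genome).  Scanning scores every offset on both strands (reverse-complement
weights for −); the best hit takes the maximum score, ties resolved to the
smaller offset then the + strand, with scores within 1e-9 treated as tied
(vectorized summation-order noise).  Bases outside ACGT score 0
(background-neutral).  Absolute score conventions differ between published
motif tools, so absolute thresholds transfer only qualitatively; the
shipped defaults are score ≥ 10 for a strong hit, TPM ≥ 3 for the TF
presence gate, |count difference| ≥ 10 for differential TFs, 150-bp
windows (half-width 75) for cohort counting and 12-bp windows (half-width
6) for candidate rescoring.  The two-condition scan scores the
reference-allele window for the stem condition and the alternate-allele
window for the induced condition, since the two genomes differ only at the
called variants.  Deletion alt windows are re-padded from the genome to
the nominal width in cohort counting (flagged) so per-allele counts are
comparable; candidate rescoring uses the unpadded spliced windows.  The
allele delta is `score_alt − score_ref`, antisymmetric under allele swap.

## Candidate selection

Candidates are the intersection of epigenetically stable variants with
variants whose nearest-TSS gene is called DE.  The pipeline's default DE
preset is `default`, not `strict`: the strict raw-p ≤ 1e-5 criterion is
unattainable at small replicate counts (a pooled t with df ≤ 8 would need
|t| beyond any realistic effect), so strict is reserved for deeply
replicated designs and remains a config/CLI choice.  For each candidate,
every expressed TF (gate evaluated in the induced condition, where a
gained site would act) is rescored over the 12-bp windows and retained iff
the alternate-allele score reaches the cutoff — the gate is deliberately
on the alternate allele only, because the question is which TFs *can*
bind the induced genome.  An enhancer-stable candidate may sit in any
region category; no promoter/enhancer–region consistency constraint is
imposed.

## Synthetic data: what it emulates

The generator produces a 500-kb single-contig genome (GC 0.41), 50
non-overlapping multi-exon genes (~20% noncoding, both strands, short
TSS-adjacent exons so first introns start near the TSS), 1000 variants
(~55% indels of length 1–5, echoing observed indel/SNV ratios) placed by
region-category weights with intronic enrichment, SNV alleles drawn from a
C>T-dominated 12-way spectrum (G>C rarest), peaks realizing a per-mark
switch plan of 46 promoter-stable + 20 enhancer-stable variants (disjoint)
plus 18/12 and 30/30 switching classes and background peaks, and a
lognormal TPM table: baseline log2(TPM+1) means ~ Normal(3,2) truncated at
0 (DE genes Uniform(4,6) so down-shifts stay positive), replicate noise
σ = 0.3 in log2, planted effects ±2 log2 (4-fold), 20% of genes DE.

Five replicates per condition is the bundle default.  This is a designed
positive control: at a 4-fold effect and σ = 0.3, n = 5 is the smallest
replicate count at which the pooled t detects every planted gene after BH
correction with negligible failure probability, so end-to-end recovery of
the planted causal set is a property of the method, not of a lucky seed.
(The DE sensitivity benchmark is still run at n = 3, where the bar is
sensitivity ≥ 0.9 rather than 1.0.)

Six causal variants (five promoter-stable, one enhancer-stable, echoing
the usual preponderance of promoter-mark candidates) are planted by
writing a motif consensus into a first intron within 900 bp of the TSS,
with the middle motif column carrying the weakest base as the reference
allele and the consensus base as the alternate: by construction
score_alt ≥ 10 > score_ref under the shipped library, the construction is
verified by rescoring at generation time, and the variant's nearest TSS is
its gene's.  Only motifs whose maximum score sits within one broken
column of the cutoff (the width-9/10 sharp toy motifs) can realize this
relation.  Unforced stable classes are only assigned to variants whose
nearest gene is not planted DE, so planted recovery is exact by design.
The ten toy PFMs (widths 6–15, fixed internal seed) stand in for a motif
database; TF genes 1–7 are given expression above the TPM ≥ 3 gate in
both conditions, 8–10 below it.

What passing these tests does **not** show: real peak calls have noisy
boundaries and replicate disagreement; real expression has mean–variance
dependence, batch effects and outliers that a common-variance t does not
model; real motif databases contain correlated, degenerate motifs; real
variants cluster and fall in repeats.  The benchmark validates the
bookkeeping, thresholds and integration logic, not robustness to those
data pathologies.

## Determinism and degenerate inputs

All generator randomness flows through one `numpy` Generator seeded per
run; bundles and pipeline reports are byte-identical across re-runs.
Multiallelic VCF records are rejected loudly rather than split; non-PASS
records are dropped with a count.  Zero-variance genes with equal means
get p = 1, with unequal means p = 0.  Sequences shorter than a motif score
−inf in allele deltas and are skipped in best-hit scanning.  Windows
truncated at contig edges are flagged.  Chromosome-name dialects
("chr5"/"5") are normalized by a configurable prefix helper at the I/O
boundary.

## Scope decisions

Enrichment and spectrum statistics are computed pooled over the variants
supplied in one VCF; per-cell-line-pair analysis is obtained by running
per-pair VCFs separately (the `pair_id` field tags provenance but does not
partition any statistic).  Variant callers' tumor/normal pairing semantics
are likewise left to the caller: any biallelic VCF is accepted.

## Known limitations

Protein-consequence annotation, structural variants, differential peak
calling, liftOver between assemblies, and external target-set or pathway
databases are out of scope; target lists are user-supplied files.  The
nearest-TSS gene assignment ignores 3D contacts and eQTL evidence; the
motif model is mononucleotide (no shape or dinucleotide terms); TF
name–gene mapping is an explicit user table with no fuzzy matching.
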
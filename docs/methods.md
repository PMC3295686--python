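# Methods

## The measurement being modelled

MBD/MBP-seq captures methylated genomic fragments with a methyl-CpG-binding
protein and sequences the captured fraction. The signal is therefore a read
*density* enrichment over methylated intervals, on top of a background of
non-specifically captured fragments; there is no paired input library in the
design this package targets, so each sample is called against its own
background.

## Window counting

Reads are assigned to windows by their 5′-most genomic coordinate (start for
`+` reads, end − 1 for `-` reads), not by interval overlap. On a
non-overlapping tiling this makes the window counts a partition of the read
set — total counts are conserved, which is both easy to reason about and
directly testable — and it keeps a fragment from inflating two adjacent
windows. Windows tile each chromosome from coordinate 0 with a configurable
stride; the default stride is one third of the window (100 bp for the 300 bp
default), trading sub-window peak resolution against a threefold increase in
windows. The final partial window of a chromosome is kept.

## Background model

The null hypothesis is that a window's count comes from non-specific
background. Low-coverage windows — counts at or below the 0.90 quantile of
all window counts (configurable) — are taken as background-dominated, and a
negative binomial NB(μ, k), Var = μ + μ²/k, is fitted to them by method of
moments: μ is the sample mean, k = μ²/(s² − μ). Method of moments is closed
form and well behaved on the upper-truncated sample the quantile filter
produces; a maximum-likelihood refinement was considered and rejected as it
buys little at 10⁴–10⁵ windows while being sensitive to the truncation.
When the background sample shows no overdispersion (s² ≤ μ) the model
degrades to Poisson(μ); when every background window is empty the model is
flagged degenerate with μ = 0, and scanning against it calls any window
holding at least one read (documented behaviour, exercised in tests). The
null is fitted genome-wide; chromosomes are assumed to share one background
capture rate.

## Empirical FDR

For each count value *c* observed on the track the statistic

FDR(c) = P_null(C ≥ c) / (fraction of windows with count ≥ c)

estimates the fraction of windows at or above *c* that the background alone
would produce. Upper-tail fractions are used in both numerator and
denominator: a per-count form (point mass over point fraction) is exposed
behind a flag, but the tail form is the default because per-count observed
fractions of rare high counts are noisy (a single window at count 50 gives a
denominator of 1/n, and every higher count is untabulated). Values are
clipped to [0, 1] and then regularised by a cumulative minimum over
ascending counts, making the table non-increasing in *c*; the
regularisation never increases a value, so calls at any threshold are
preserved or extended when the threshold is raised. Counts never observed
are not tabulated — the statistic is defined relative to the observed
track. Windows with FDR(c) ≤ α are candidates; α defaults to 1% and the
window to 300 bp, the settings used for this assay class.

## Merging and strand refinement

Candidate windows overlapping by ≥ 1 bp merge into peaks (book-ended
windows also merge when the stride equals the window, where overlap cannot
occur). A peak's read count is recounted as the number of read 5′ ends in
the merged span, and its FDR is the minimum over its windows.

Captured fragments are double-stranded, so around a true methylated site
forward-read 5′ ends pile up on the left and reverse-read 5′ ends on the
right. Each peak is scored by a one-sided Wilcoxon rank-sum test of
"forward positions lie left of reverse positions": the statistic is the
midrank sum of forward positions in the pooled sample, and for n + m ≤ 20
the p-value is the exact permutation probability P(W ≤ W_obs), computed by
a dynamic program over doubled midranks (ties are therefore handled exactly,
and the p-value matches full enumeration of all C(n+m, n) assignments).
Beyond 20 observations a normal approximation with tie-corrected variance
and continuity correction is used. Peaks with fewer than two reads on
either strand get p = 1. By default the p-value is recorded and no peak is
dropped — the refinement step annotates rather than filters, since any
filter threshold here would be an invention; an explicit
`require_orientation` flag enables dropping at a chosen α.

## Differential calls

With one pooled library per condition, presence/absence is the only
defensible contrast: a treated-only peak is a hypermethylation call, a
control-only peak a hypomethylation call, overlapping peaks are shared
(threshold ≥ 1 bp overlap by default, configurable; shared peaks record
their largest-overlap partner and are reported, not discarded). The
normalized difference (a − b)/(a + b) on counts-per-million in the peak
span, with reads counted by 5′ coordinate for consistency with peak
counting, summarises the quantitative contrast in [−1, 1]; it is 0 with a
degenerate flag when neither sample has reads in the span. A global summary
counts hyper/hypo/shared (shared pairs counted once, via the treated side)
and flags global hypomethylation when hypo calls outnumber hyper calls.

## Feature annotation

Deliberately wide, strand-aware definitions: promoter = 20 kbp upstream of
the TSS, 3′-flank = 20 kbp downstream of the TTS, gene body = the
transcribed span (exons and introns, unioned over a gene's transcripts),
intergenic = none of these. The 20 kbp promoter is unusual relative to the
conventional 1–2 kbp but is retained as this assay class's convention for
capturing distal regulatory methylation; it is configurable. Because these
regions can overlap between neighbouring genes, a peak is classified by the
largest overlap with each class's merged interval union, ties broken
gene_body > promoter > 3′-flank (the transcribed unit is the most concrete
annotation). The nearest gene is the gene whose TSS is closest to the peak
midpoint, distance signed in the gene's orientation (negative upstream);
TSS-distance ties resolve to the lexicographically smallest gene id for
determinism.

## Gene-set enrichment

Focus genes (nearest genes of calls filtered by feature class and label;
intergenic excluded unless requested) are tested per set with a
right-tailed Fisher's exact test — the hypergeometric tail
P(X ≥ overlap) with the draw being the focus list and the urn the gene
universe — computed in exact rational arithmetic and only converted to
float at the end. The universe defaults to all genes of the supplied gene
model rather than the union of the sets, since the annotated genome is the
sampling frame that produced the focus list. Raw p-values are reported
alongside Benjamini–Hochberg adjusted values.

## Synthetic data generator

The generator produces what the pipeline consumes, with the statistical
structure the model assumes and nothing more:

- a multi-chromosome genome with planted, non-overlapping methylated
  intervals (lengths uniform in a configurable range, default 500–2000 bp;
  an optional minimum inter-region gap keeps regions resolvable at window
  scale);
- a two-condition contrast in which the treated condition retains a
  uniformly chosen subset of the control's intervals
  (`fraction_retained_in_treated`), emulating global hypomethylation;
- fragments placed uniformly over the genome, lengths uniform on 50–350 bp
  (the sonication range of standard fragment libraries; truncated at
  chromosome ends), strands uniform;
- capture as per-fragment acceptance: probability 1 for fragments
  intersecting a methylated interval of the condition, 1/enrichment_factor
  otherwise, so the expected read-density ratio inside/outside methylated
  regions is exactly the enrichment factor. Rejection sampling emits
  exactly the requested read count.

Defaults used throughout the tests: enrichment factor 8 (typical of MBD
capture at high CpG density), background mean of roughly 4–8 reads per
300 bp window, 40–100 planted regions of about 1 kb, retained fraction 0.6
for the hypomethylation contrast. Not modelled: base-level sequence and CpG
density (capture efficiency in reality scales with CpG count), sequencing
error, mappability, duplicate reads, between-animal variance (conditions
are single pooled samples, as in the pooled-library design this mirrors),
and GC bias. Passing tests therefore demonstrate the statistical machinery
— null fitting, FDR calibration, recovery, directionality — under the
model's own assumptions, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run on genomes of 2–10 Mb with
4×10⁴–1.5×10⁵ reads per sample and 10⁴–10⁵ windows — sizes at which every
quantity of interest (tail fractions, moment estimates, recovery rates) is
already stable, chosen as the package's standard desk-scale study
conditions. Quantiles use numpy's default linear interpolation; the sample
variance uses ddof = 1. FDR ratios at counts with zero observed fraction
cannot occur (only observed counts are tabulated). The Wilcoxon exact path
switches to the normal approximation above n + m = 20; at the boundary the
two agree to about 10⁻². BED scores are −10·log₁₀(FDR) capped at 1000.

## Known limitations

- The empirical FDR is a ratio estimator; on tracks with very few windows
  (< ~100) its denominator is coarse and the table is conservative.
- Peaks inherit window granularity: boundaries are window-start aligned and
  can overhang a true region by up to one window on each side; two regions
  closer than the window smear merge into one peak.
- With `require_orientation`, low-coverage true peaks (< 2 reads per
  strand) are dropped by construction.
- The differential contrast is presence/absence; it does not model count
  uncertainty across conditions (no replicates exist in the targeted
  design), so shared peaks with large normalized differences are reported
  but not tested.
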
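# Methods

This note documents the statistical model, the parameter choices and the
known limitations of each analysis stage. All claims here are either
mathematical properties of the model or statements verified by the test
suite on simulated data; no empirical performance numbers beyond those are
claimed.

## Mixture model

All read-level quantities derive from one admixture model. A sample with
tumor purity ρ contains tumor cells of average ploidy τ mixed with diploid
normal cells, so its average copy number is D = 2(1−ρ) + ρτ. For a locus
with tumor total copy number q:

- **logR** (depth ratio, log2): `log2((2(1−ρ) + ρq) / D)`
- **BAF** at a heterozygous SNP with b tumor copies of the B allele:
  `((1−ρ) + ρb) / (2(1−ρ) + ρq)`
- **VAF** of a somatic mutation on m of the q copies, present in a fraction
  CCF of tumor cells: `ρ·m·CCF / (2(1−ρ) + ρq)`

Alt counts are treated as binomial at the observed depth; per-bin logR noise
is Gaussian.

### Identifiability

logR alone cannot distinguish (ρ, q per segment) from (ρ/2, 2q−2): the
transformed profile reproduces every logR value exactly, for all segments
simultaneously. The degeneracy is broken only by allele-resolved evidence on
odd-copy segments — most effectively SNVs inside single-copy (LOH) regions,
whose VAF ρ/(2−ρ) is not reproducible by any multiplicity at purity ρ/2.
The simulator therefore places the first five truncal mutations of each
tumor inside that tumor's 3p LOH region (modelling biallelic inactivation of
a tumor suppressor: the second hit sits on the retained allele), and the
purity fit admits SNVs as evidence. Without such variants, reported purities
can be off by a factor of two with identical likelihoods.

## Variant validation

Two rules per (variant, region) cell:

- depth < 50× → **inconclusive** (cannot confirm or refute; stays in the
  attempted denominator of the validation rate but is never a failure);
- otherwise VAF ≥ 1% → **validated**, else **failed**.

The VAF boundary is inclusive ("at least 1% of reads"); the depth boundary is
strict (exactly 50× is evaluable). Rates are reported as percentages rounded
half-up to one decimal. Somatic rows validated in no region are dropped from
the mutation matrix; variants validated in the matched normal are labelled
germline and excluded from somatic analyses.

The optional sequencing-artifact classifier is a forward-stepwise logistic
regression: candidate features enter one at a time when a likelihood-ratio
test (χ², 1 df) against the current model reaches p < 0.05; constant
features are pre-excluded; with no selected features the model predicts the
training prevalence. A call is kept when the fitted artifact probability is
below 0.5.

## Clonality and phylogeny

Regions sharing at least one validated somatic mutation are connected;
connected components define clonally independent tumors. Within a tumor,
mutations with identical region-presence patterns collapse into clones, and
clones are ordered by strict containment of their region sets. This is a
two-state perfect phylogeny: any two presence sets must be nested or
disjoint, and a violating pair raises an error naming both mutations. When
no mutation covers every region, a mutation-free virtual root is added.
A tree is *linear* when every clone has at most one child, else *branched*.

ITB index = (mean per-region count of non-ubiquitous mutations) / (number of
ubiquitous mutations), over somatic SNV/indel rows by default (CNA rows can
be included by flag), rounded half-up to two decimals. Undefined (error)
when no mutation is ubiquitous.

## Copy-number segmentation

Preprocessing per sample, in order:

1. **GC correction**: LOESS of logR on GC fraction (span 0.3), trend
   subtracted, original median restored; skipped with a warning when GC is
   constant.
2. **Quantile normalization** across the patient's samples (each column
   mapped onto the mean order-statistic profile). This equalizes
   distributions so shared breakpoints are comparable, but it *mixes
   amplitudes* between samples whose aberrant genome fractions differ. The
   pipeline therefore segments on quantile-normalized tracks and then
   re-measures per-sample segment means on GC-corrected, Winsorized,
   non-normalized tracks before the purity fit.
3. **Winsorization**: each bin is clamped to a running median (window 5)
   ± k·MAD of the residuals (k = 2.5). The sliding window preserves genuine
   multi-bin segments; a whole-chromosome window would clip them.

Segmentation minimises, per chromosome and jointly over all S samples,

```
Σ_samples Σ_bins (logR − segment mean)² + γ · (number of breakpoints)
```

with breakpoints shared across samples, solved exactly by an O(n²·S)
dynamic program. Ties break toward fewer segments. The solution is the
global optimum of the penalized least-squares objective; the test suite
verifies this against exhaustive enumeration on small instances.

**Choosing γ.** γ is on the summed-SSE scale, so it must match the data
scale. `SegmentationConfig` defaults to the published genome-wide setting
(γ = 1000), appropriate for exome-scale bin counts. On the simulator's
miniature genome (300 bins, logR noise 0.1) the pipeline default is γ = 2
for a 16-sample joint fit (real shared events gain ≳ 2.7 summed SSE, noise
splits ≲ 0.5), and single-sample analyses use γ ≈ 0.4. The rule of thumb:
γ should lie between the SSE gain of the smallest real event (amplitude
δ², times bins, times samples carrying it) and the typical spurious gain
(~σ² per sample).

## Purity and ploidy

Grid search: ρ ∈ [0.05, 1.00] step 0.01; τ ∈ 2·DI ± 0.5 step 0.05, where DI
is the flow-cytometric DNA index (prior ploidy 2·DI). For each (ρ, τ) the
log-likelihood sums:

- per segment: a Gaussian mixture of the observed mean logR over integer
  q ∈ [0, 8], with SD = σ_logR/√n_bins. The per-segment SD already shrinks
  with n_bins, so each segment enters the sum once — weighting again by
  n_bins would count the bin evidence twice (information ∝ n²) and let a
  small centering fluctuation on a long segment overwhelm all SNV evidence.
- per admitted SNV (VAF > 5% and depth > 50): a mixture of the observed VAF
  over integer multiplicity m ∈ [1, q̂] on the segment's best-fitting q̂,
  with binomial-approximation SD.

The top five models per sample are kept (ranked by likelihood). Across
samples, one model per sample is selected by minimising pairwise L1
distances between expected modal copy-number profiles and shared-SNV
multiplicities, plus λ times the sum of likelihood ranks (λ = 1 by
default); solved exhaustively up to 10⁶ combinations, else by cross-entropy
search. CCF posteriors use a binomial likelihood on a grid over [0, 1.5] —
extending above 1 so that sampling noise cannot truncate a clonal variant's
posterior mass below 0.95 — and a variant is clonal iff Pr(CCF < 0.95) < 0.5.

## Allelic imbalance

Heterozygous SNPs: 3-component Gaussian mixture (hom-ref / het / hom-alt) on
normal-sample BAFs; SNPs assigned to the middle component with posterior
> 0.9 and tumor coverage strictly > 40× are kept (hard window [0.3, 0.7]
fallback with a warning if the fit fails). Mirrored BAF = max(BAF, 1−BAF).
Purity adjustment inverts the BAF mixture equation for the minor-allele copy
count (clamped to [0, q] against sampling noise) and returns (q−nB)/q; the
inversion is exact on noise-free input.

Per segment, a two-sided paired Wilcoxon signed-rank test on per-SNP
(tumor − normal) mirrored BAFs (zero differences dropped; an unpaired
Mann-Whitney variant is available), Bonferroni-corrected across segments at
α = 0.05. Segments with fewer than five SNPs are reported non-significant
with a reason. Type-I error at α = 0.05 is verified within binomial noise
on 1,000 null simulations.

**3p breakpoints.** The per-region breakpoint is the start of the first
chromosome-3 segment without significant imbalance (the end of the LOH
prefix) — a model-free call that does not depend on the purity fit. The
per-tumor consensus pools each segment's p-values across the tumor's
regions with Fisher's method before the same prefix rule, so a single
low-purity biopsy cannot truncate the call. A region conflicts with its
tumor only when its own imbalance extends more than 1 Mb *beyond* the
consensus; a shorter per-region call is treated as a power issue.

## Pipeline

Stage order: simulate/load → variant validation → clonality/phylogeny →
segmentation → purity/ploidy → allelic imbalance → report. Each stage is
wrapped so a failure aborts with the stage name; a missing input file aborts
with the name of the stage that consumes it. All randomness flows from one
seed; reports serialise to JSON byte-identically for a fixed config.
Thresholds actually applied are logged. Plotting failures are never
pipeline errors.

Recovery tolerances verified end to end on the simulated 4-tumor patient
(20 regions, purities 0.3–0.9, one genome-doubled tumor with DNA index
1.82): tumor partition, topologies and 3p breakpoint labels exact; purity
within 0.05 and ploidy within 0.1 of truth for every region.

## Limitations

- The copy-number model assumes clonal integer copy numbers per segment;
  subclonal copy-number events are not modelled.
- Purity is unidentifiable from logR alone (see Identifiability); samples
  without admitted SNVs on odd-copy segments can select a half-purity
  model.
- The perfect-phylogeny construction assumes noise-free presence calls;
  a single miscalled cell can raise a compatibility error. No error
  correction or probabilistic tree inference is attempted.
- The exact segmentation DP is O(n²) per chromosome and intended for bin
  counts up to a few thousand, not genome-wide 1-kb grids.
- Quantile normalization assumes the samples share most of their logR
  distribution; with very different aberrant fractions the re-measurement
  step mitigates but does not remove the bias.
- The ITB index depends on the set of validated mutations; inconclusive
  cells (depth < 50×) are excluded rather than imputed.
- The simulator's genome is miniature (three 10-Mb chromosomes) and its
  clone trees are small (one or two subclones); it is a correctness
  harness, not a realistic cancer-genome generator.
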
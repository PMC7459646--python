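# Methods

## Data model and coordinates

Methylation calls are per-sample records of (chromosome, position,
strand, coverage, methylated count) at CpG sites, read and written in
the Bismark coverage dialect (1-based inclusive, with a redundant
percent-methylation column that is cross-checked against the counts on
input). All interval arithmetic is done internally on 0-based half-open
coordinates; GFF3 and coverage files are converted at I/O and round-trip
losslessly. A CpG site is indexed by the position of its plus-strand C.

## Coverage filtering and uniting

Per sample, a site is kept iff `coverage > 10` and
`coverage <= percentile(coverage, 99.9)`. Both cuts are evaluated on
the sample's raw coverage distribution (the upper percentile is not
recomputed after the lower cut); the percentile uses linear
interpolation and the upper cut is strict, so a constant-coverage sample
loses nothing to it. Uniting intersects sites across **all** samples of
the groups being compared — no per-group minimum relaxation — so every
retained site has counts in every sample.

## Region model

One canonical isoform per gene: the longest mRNA, ties broken by the
lexicographically smallest transcript id. An mRNA without exons is
rejected. Isoform overlap **across** genes is not resolved by deleting
genes; collisions are settled per CpG by label precedence.

Promoter tiers are anchored at the TSS and extend upstream along the
annotated strand: P250 spans 1–250 bp, P1K 251–1000 bp, P6K
1001–6000 bp from the TSS; flanks combine 6001–10,000 bp upstream with
10 kb downstream of the mRNA 3′ end. For minus-strand genes "upstream"
runs rightward in genome coordinates. Tiers are clipped at chromosome
ends and are never truncated at neighbouring genes — a site claimed by
several genes gets the highest-precedence label under
`exon > intron > P250 > P1K > P6K > flanks > intergenic`, with the
lexicographically smallest gene id on ties within one label. The label
set always partitions any site set, which the tests verify against a
brute-force all-overlaps oracle, together with idempotence and
invariance under genome mirroring.

## Per-CpG test

Counts are pooled within groups (coverage-weighted), and the two-group
binomial logistic regression is fitted in closed form: with a single
two-level factor the ML fitted probabilities are exactly the pooled
group proportions, so the deviance LRT equals the 2×2 G-test on the
pooled table and is computed vectorised over sites
(`2·Σ O·log(O/E)` in likelihood form, with `0·log 0 = 0`). p-values
come from the χ² distribution with 1 df. The closed form is exact at
boundary proportions (0% or 100%), so no continuity correction or
separation fallback is needed; the identity with an iteratively fitted
GLM is asserted in the tests against statsmodels. Δ is the difference
of pooled group percentages (treatment − control); a replicate-averaged
alternative would weight samples equally rather than reads — the pooled
form matches the uniting semantics and is the package's convention.

No overdispersion correction is applied by default: the test assumes
binomial sampling within groups. This mirrors the standard
logistic-regression treatment of RRBS counts and is a documented
limitation (below).

## SLIM q-values

The null proportion π₀ is estimated from the p-value ECDF by a sliding
linear model: the ECDF is evaluated on a λ-grid of 100 bins; ten
overlapping windows of width (1−0.1)/2 slide across [0.1, 1]; an OLS
line is fitted in each window and the smallest slope — the flattest,
most null-pure stretch, where the alternative component's CDF has
exhausted its mass — is taken as π₀, clipped to [0, 1]. q-values are
then `q₍ᵢ₎ = π₀·m·p₍ᵢ₎/rankᵢ` with maximal ranks under ties, made
monotone non-decreasing in p by a right-to-left running minimum and
clipped to [0, 1]. Because π₀ ≤ 1, SLIM q-values are bounded above by
Benjamini–Hochberg values, which the tests assert. With fewer than 10
p-values the ECDF is too coarse for the sliding fit and the function
falls back to Benjamini–Hochberg with a warning.

On 10,000 uniform p-values the estimator lands at π₀ ≈ 0.99; on null
binomial data at coverage ≈ 30 it sits near 0.94 — mild conservatism
from the discreteness of count-based p-values, acceptable for an FDR
procedure (it can only make q-values smaller, and the realized null DMC
rate stays far below target because of the 20-point difference filter).

## DMC / DMG calling

DMC ⇔ `q < 0.01` and `|Δ| ≥ 20` percentage points; hyper if Δ > 0,
hypo if Δ < 0. Swapping treatment and control negates every Δ and
exchanges hyper with hypo while leaving p and q unchanged (tested).
A gene is a DMG iff it has at least one DMC labelled exon, intron,
P250, P1K or P6K; flank DMCs are tallied per region but never create a
DMG by themselves, and intergenic DMCs map to no gene. Contrasts are
oriented with the earlier group as control — for groups (NC, SS, SO)
the contrasts are SS:NC, SO:NC and SO:SS.

## Global patterns

Embeddings and clustering operate on the percent-methylation matrix of
united sites (not logits — percent scale is the package's reporting
convention throughout). Variance selection keeps sites with
across-sample variance strictly above the chosen percentile (default
95; percentile 0 means every varying site). t-SNE runs with perplexity
2 — appropriate for ~12 samples — seeded and with PCA initialisation
for determinism, and requires perplexity < (n−1)/3. PCA returns the
first two component scores; Ward linkage uses Euclidean distances on
samples; correlations are Pearson.

## Enrichment

* **ORA** — hypergeometric upper tail `P(X ≥ k)` of the DMG/pathway
  overlap. The universe is the set of genes with at least one united
  CpG in the scope (only assayed genes can be called), configurable by
  passing a different universe; pathways with no member in the universe
  are skipped.
* **Wilcoxon** — per pathway, a signed-rank test of per-site paired
  differences of the two group means. Pairing is per CpG site. Zero
  differences are dropped (the test is undefined on them); pathways
  with fewer than 5 usable sites are reported NA and excluded from the
  BH family.
* **KS-boot** — observed statistic D = sup-norm distance between the
  ECDF of the pathway's per-site Δ values and the ECDF of all Δ values
  in the region scope; the null is built from 1000 size-matched
  with-replacement draws from the background, and
  `p = (1 + #{D_boot ≥ D_obs}) / (n_iter + 1)` — the add-one estimator
  never returns 0 and attains a minimum of 1/1001 at the default
  iteration count. Deterministic under seed.

Each test runs for every region label plus "all", and p-values are BH
adjusted across pathways within each (test, scope) family.

## Synthetic data generator

The generator emulates the target study design: groups (NC, SS, SO) ×
4 replicates; toy chromosomes (default 2 × 100 kb) with genes of
1.5–3.5 kb, 2–5 exons, uniform random strand, and a ~35% chance of a
second overlapping isoform; CpG sites are actual CG dinucleotides of
the simulated sequence. Counts follow a beta-binomial hierarchy:

* baseline per-site methylation π ~ Beta(0.8, 0.8) — mildly bimodal, as
  CpG methylomes are;
* per-sample coverage ~ NegBin(mean 30, size 8), matching typical RRBS
  depth and spread; zero-coverage sites are absent from that sample's
  calls, as in real coverage files;
* methylated count ~ Binomial(coverage, p) with p either π exactly
  (`rho = 0`) or Beta-distributed around π with intra-class correlation
  `rho`.

`within_group_overdispersion` (rho) **defaults to 0**, i.e. the
binomial model the per-site test assumes. This is deliberate: the
planted-truth benchmarks measure the procedure's intrinsic operating
characteristics (sensitivity, FDR, null calibration), which requires
simulating under the test's null. Real replicate methylomes show
extra-binomial variation; setting rho > 0 reproduces it and shows the
known behaviour of uncorrected logistic-regression tests — inflated
statistics and anticonservative p-values (at rho = 0.01, coverage 30,
the SLIM π₀ estimate on null data drops to ≈ 0.84). That robustness
experiment is available but is not the default validation condition.

Planted effects: `n_effect_sites` sites (default 300) are chosen
uniformly; each affects one treatment group or, with equal probability,
all of them; shifts are ±`effect_size` points (default 30), half hyper
and half hypo, with upward shifts assigned to the lower-baseline half
of the chosen sites so that clipping to [0, 1] rarely erodes the
planted difference. The truth table records the realized post-clipping
shift per site. The generator writes standard formats (FASTA, GFF3,
Bismark coverage, TSV) and is byte-reproducible under its seed.

What the simulation does **not** emulate: strand-specific calls (calls
are emitted destranded at the plus-strand C; the analysis layer keeps a
strand field and handles either convention), non-CpG methylation,
bisulfite conversion failure, SNP interference, mappability structure
and digestion-site enrichment of RRBS coverage. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
stated sampling model, not robustness to those artefacts.

## Validation problem sizes

The test-suite and acceptance-script benchmarks use 10,000 CpGs for
calibration and recovery runs (4 vs 4 samples, coverage 30; 5 seeds for
null calibration, 500 planted effects for recovery), 20 random genomes
× 10,000 sites for the annotation oracle, 500 null pathways of size 30
against a 5,000-site background for KS-boot calibration, and a
40–60 kb single-chromosome design for end-to-end determinism — sizes at
which every Monte-Carlo band asserted in the tests is comfortably
resolved.

## Known limitations

* The binomial LRT is anticonservative under within-group
  overdispersion; no beta-binomial or overdispersion-corrected test is
  currently implemented.
* The SLIM π₀ estimator inherits mild conservatism from discrete
  p-values at low coverage.
* Promoters of neighbouring genes are not truncated against each other;
  precedence resolves collisions per CpG only.
* ORA ignores ontology-graph structure; the pathway table is taken as
  given.
* DMR segmentation, tiling-window analyses and covariate adjustment are
  out of scope.
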
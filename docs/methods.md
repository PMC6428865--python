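# Methods

## The interaction model

Counts `Y_gj` for gene `g` in library `j` are modeled as negative binomial
(NB2), `Var(Y) = μ + α μ²`, with log link over the 2×2 assay × condition
design:

    log μ_gj = log s_j + β0 + β_A A_j + β_C C_j + β_I A_j C_j

`A_j` indicates a ribosome-footprint (RPF) library and `C_j` the
knock-down condition. The interaction `β_I` is the translational-
efficiency change: the part of the RPF fold change not explained by the
mRNA fold change. One GLM is fitted per gene by iteratively reweighted
least squares (working weights `μ/(1+αμ)`, convergence when the largest
coefficient step falls below 1e-8, at most 100 iterations, non-convergence
always flagged and propagated as missing — never silent). Standard errors
come from the Fisher information `XᵀWX`; the test on `β_I` is a Wald z
with a normal reference, and FDR is Benjamini–Hochberg across all tested
genes. Size factors are median-of-ratios, computed once on the combined
mRNA+RPF matrix so that a single normalization underlies the single fitted
model; genes containing any zero are excluded from the reference set.

### Dispersion estimation

Dispersion is estimated once per gene from all samples jointly, with no
information borrowed across genes (no empirical-Bayes shrinkage): the
within-cell residual sum of squares is pooled across the four design
cells, giving `s²` on `df = Σ_c (n_c − 1)` degrees of freedom, and

    α̂ = max(1e-8, (s²·df/(df−2) − m̄) / m̄²)

with `m̄` the overall size-factor-normalized mean. Two points deserve
explanation:

* **Residual (within-cell) pooling.** Pooling the raw normalized counts
  across cells instead would fold genuine between-condition effects into
  `α̂`, inflating the variance estimate exactly for the regulated genes the
  test exists to find — a self-masking estimator. Residual pooling keeps
  `α̂` unbiased whether or not the gene is regulated.
* **The `df/(df−2)` factor.** With duplicate libraries `df = 4`, and a
  4-df variance estimate is noisy: `E[1/s²] = df/((df−2)σ²)`, so plugging
  the raw `s²` into the Wald denominator biases `|z|` upward and inflates
  the type-I error (~0.11 at a nominal 0.05 in our null simulations). The
  analytic inverse-chi-square correction removes that bias; with it the
  null rejection rate at p < 0.05 is 0.040–0.057 across seeds and across
  (mean, dispersion) regimes. The factor tends to 1 as replication grows.

### What per-gene estimation cannot give you

With duplicates and per-gene dispersion, far-tail p-values remain
anticonservative (the estimator's left tail occasionally produces very
large z), so the *realized* FDR among BH-significant genes exceeds the
nominal level when effects are present, and power is bounded: at
dispersion α the interaction z cannot exceed ≈ `|ln FC| / √(2α)` with
duplicate libraries regardless of counting depth (≈1.55 for a two-fold TE
change at α = 0.1 — about 33% power at p < 0.05 even with α known
exactly). Production differential-expression engines escape this bound
only by sharing dispersion information across genes; this package
deliberately keeps the estimator transparent and per-gene, and its
recovery guarantees should be read with that bound in mind. At α = 0.02 —
a typical gene-wise dispersion for technical duplicates in yeast — the
same test reaches ~35–40% sensitivity at FDR < 0.05 with essentially
perfect directional accuracy among detections.

## Classification

A gene is significant iff `fdr < 0.05` (strict inequality). Direction:
`delta_te < 0` is "activated by the factor" (its efficiency falls upon
knock-down), `delta_te > 0` "repressed". mRNA status: buffered iff
`|log2fc_mrna| < 0.433` (strict, so exactly 0.433 is not buffered);
otherwise decreased/increased by sign. The threshold is `log2(1.35)`
rounded to three digits — a ±35% abundance band. The label set covers all
six sign combinations even though typically only five are occupied;
classification is total, and missing statistics map to `not_regulated`.
Because the mRNA log2FC standard error with duplicate libraries is ≈0.46
log2 units at α = 0.1, the buffered/decreased/increased status of a
*detected* gene is itself noisy; the direction (activated vs repressed) is
driven by the same statistic that triggered detection and is essentially
never confused between the two sides.

## Positional profiles

**Footprint metagene.** The first 15 codons of every gene are masked
(cycloheximide-induced pile-up region); genes with fewer than 40 retained
codons are excluded (counted in the log). Per codon the signal is
observed/expected, where the expectation assumes uniform codon usage:
`expected_j = library_total_j / total retained codons`, both totals over
the *whole analysis set* supplied, not the plotted group. This choice
keeps values comparable across libraries while preserving between-gene and
between-condition level differences — a level shift between conditions is
precisely the readout that distinguishes an initiation defect (uniform
shift) from an elongation stall (slope change). Knock-down values are
divided per gene by that gene's linear mRNA fold change before averaging
(the correction is per-gene, applied before any aggregation). Codon
positions map to 100 equal-width relative bins; replicates are averaged
first, then genes; `n_genes` is recorded per bin. The profile is exactly
invariant to rescaling any library by a constant and to gene order.

**Structure metagene.** Per-nucleotide structure scores (PARS-style:
higher = more double-stranded) are aligned to the first CDS nucleotide
(TIS = position 0). Each gene contributes upstream positions only as far
as its 5ʹUTR extends (up to 100 nt) and downstream only as far as its CDS
extends (up to 300 nt); means skip missing values, mirroring `na.rm=TRUE`
semantics, and the per-position gene count is reported. Region means
(5ʹUTR/CDS/3ʹUTR) skip missing values; a zero-length region yields
missing. Group feature comparisons report mean and median (both, since
box-plot centers are medians while captions often say "mean") with a
two-sided Wilcoxon–Mann–Whitney test against the unregulated background.

**Rank test.** Exact by full enumeration of label assignments when
n1+n2 ≤ 12 (valid under ties, since the U statistic uses midranks);
otherwise a normal approximation with midrank tie correction and a 0.5
continuity correction (always applied — conservative at moderate n).

## Run-on rate calculus

`SR = nTR / cell_volume` and `HL = RA / SR`, all in arbitrary units with
no calibration to minutes. `HL·SR = RA` holds exactly on synthetic
records by construction. Group comparisons take per-gene `log2(t30/t0)`
for SR and HL and test each class against the `not_regulated` background
with the two-sided rank test; genes missing a condition or carrying
non-positive rates are excluded with a logged count. Shut-off decay
series are fitted by ordinary least squares of `ln(level)` on time
(`t½ = ln 2 / |slope|`; a non-negative slope is flagged as infinite
half-life, not an error). Polysome gradients use the conventional 26
fractions grouped as free (1–5), subunits (6–11), monosomes (12–15),
light (16–21) and heavy polysomes (22–26).

## The synthetic-data generator

The generator emulates the knock-down experiment end to end; its defaults
are the study conditions the pipeline is tested under.

* **Classes.** Seven classes with default proportions
  activated buffered/decreased/increased = 0.050/0.015/0.010, repressed
  = 0.050/0.040/0.010, not_regulated = 0.825. The split is a free choice
  (only the activated/repressed totals of such screens are typically
  reported); it makes activated genes mostly mRNA-buffered and repressed
  genes split between buffered and decreased, echoing the three large
  occupied subgroups, with the `*_increased` classes representable but
  rare.
* **Effects.** `delta_te = −1` (activated) or `+1` (repressed) log2
  units; mRNA log2FC ~ N(0, 0.15) clipped to ±0.35 for buffered classes,
  ≈ ∓0.85 for decreased/increased, N(0, 0.10) for unregulated genes.
  Base means are 100 + lognormal(median 200, σ=1) counts; dispersion
  defaults to α = 0.1 for every gene — a deliberately noisy regime (see
  the power discussion above).
* **Gene models.** Region lengths are log-normal per class,
  parameterized by median and log-scale spread (0.40–0.45); the medians
  encode the known feature contrasts — activated genes long and
  structured (5ʹUTR 80 nt, CDS 1555.5 nt vs background 52/1113 nt),
  repressed genes short (44/753 and 35.5/600 nt), a longer 3ʹUTR
  (128 nt) only for the repressed-buffered class. CDS lengths are
  rounded to positive multiples of 3.
* **Structure profiles.** Per-nucleotide score = class region baseline
  (5ʹUTR 0.16 activated / 0.06 background / 0.03
  repressed-decreased; CDS 0.32–0.35 regulated vs 0.25 background)
  + a class TIS-window term on [−100, +50] (activated +0.15, others 0)
  − a dip of 0.30 on [−20, 0] for every class *except* the activated one
  (unregulated transcripts keep an accessible initiation site; activated
  ones do not), + i.i.d. N(0, 0.2) noise.
* **Counts.** NB draws with the mRNA mean at t30 multiplied by
  `2^log2fc_mrna` and the RPF mean additionally by `2^delta_te`; codon
  coverage is multinomial over codons given the gene's footprint count,
  uniform by default with an optional geometric 5ʹ ramp. Membrane
  annotation probability is 0.50 for activated classes vs 0.25 elsewhere
  (a two-fold enrichment by construction); membrane genes are split
  evenly between SRP-dependent and -independent.
* **Run-on records.** Baseline SR and HL are log-normal (σ=0.7); at t30
  the activated class applies SR × 0.5 and HL × 2 with multiplicative
  log-normal noise (σ=0.1); `RA = SR·HL` exactly by construction.
* **Seeding.** One master seed; each generator derives its stream from
  the master seed plus a CRC of its component name, so adding a
  generator never perturbs the others, and identical seeds give
  byte-identical artifacts.

**What the generator does not emulate:** positional biases beyond the
optional 5ʹ ramp (no codon-specific dwell times, no real pausing), ragged
library-specific GC or length biases, correlated dispersion across genes,
partially degraded or uncapped transcript pools, and any sequence-level
features (only lengths and score profiles exist). Passing tests therefore
demonstrate correctness of the estimators and contracts under a clean NB
generative model, not robustness to every artifact of real libraries.

## Numerical and design choices

* IRLS initialization from OLS on `log(y+0.5)`; linear predictors clipped
  to ±30 to prevent overflow; all-zero genes flagged degenerate with
  missing p.
* BH q-values propagate missing p-values and count only tested genes in
  m; ties at exactly the FDR cut-off are non-significant.
* The hypergeometric upper tail is summed in log space (no underflow for
  p ≥ 1e-300).
* GFF3 gene models are read through `gffutils` (features
  five_prime_UTR/CDS/three_prime_UTR grouped by Parent, 1-based inclusive
  spans summed per region); lengths are orientation-free, so minus-strand
  genes need no special casing. All other dialects (counts + sample
  metadata, per-nucleotide scores, codon coverage, truth, rates) are
  strict TSV readers that report the offending line and never coerce
  malformed input. Internal coordinates are 0-based half-open.
* Floating-point output uses 6 significant digits everywhere, making
  artifacts byte-stable across runs; the run log (timestamps) is the only
  non-reproducible file a pipeline run writes.
* The pipeline CLI exposes simulate / te-test / classify / metagene /
  pars / rates / analyze / report over one YAML config; flags override
  config values; each bundle carries a manifest with the seed and a hash
  of the generating parameters (output directory excluded — it is where,
  not what).

## Problem sizes

Simulation-backed checks use 2,000 genes with duplicate libraries (the
calibration, recovery, and rate analyses) and an 800-gene analysis set
with 40-gene groups for the metagene contract; these sizes put Monte-Carlo
error well inside the asserted tolerances while keeping any single check
in the seconds range.
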
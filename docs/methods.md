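# Methods

This note documents the statistical model, the synthetic-data
generator, the numerical choices and the known limitations of the
package, in that order.

## Differential-expression engine

Counts K_gj for gene g in sample j are modelled as negative binomial
with mean s_j·μ_{g,group(j)} and dispersion α_g, in the standard RNA-seq
parameterisation Var = μ + α·μ².

**Normalisation.** Size factors s_j are median-of-ratios: the median
over genes of K_gj divided by the gene's geometric-mean reference, then
rescaled to geometric mean 1.  By default the reference is the grand
pseudo-reference over all samples; the pipeline's `build_triplet`
instead anchors the per-gene geometric mean to the species-N samples.
The reason is quantitative: when a large fraction of genes is divergent
between the species *and* one group's reads map poorly to the reference
in use (the cross-species mapping situation this design creates), the
ratio distribution of that group's columns loses the symmetric-majority
structure median-of-ratios relies on — zero-driven exclusion of genes
removes mass asymmetrically and the group's median ratio is biased by
~0.15 log₂ under the generator's default conditions, inflating
HIL-vs-B false positives several-fold.  The species-N profile is the
natural anchor because the design's own premise is that most genes in a
HIL behave like the background parent, and it restored nominal error
rates in the null simulations shipped in the test suite.

**Dispersion.** Per-gene method-of-moments on normalised counts,
α̂_raw = max(0, (s² − μ̄)/μ̄²) pooled over groups with ≥2 replicates
(replicate-weighted), computed once across all four groups so every
contrast shares one α per gene.  Genes with α̂_raw > 0 are blended 50/50
with a trend α_tr(μ) fitted by log-linear regression of α̂_raw on log
mean; genes with α̂_raw = 0 (no observed excess variance) stay at the
floor of 10⁻⁸ rather than being pulled up to the trend — a constant
gene reports (numerically) zero dispersion.  The trend is capped at 10
and requires ≥10 positive-raw genes, falling back to the median
otherwise.

**Testing.** Group means are plug-in averages of normalised counts;
log₂FC = log₂((μ̂_A + ε)/(μ̂_B + ε)) with ε = 0.5 / median
size-factor-corrected library size guarding zeros.  The standard error
comes from Var(μ̂) = (μ Σ 1/s_j + n α μ²)/n² per group via the delta
method, the Wald statistic is referred to the normal distribution, and
BH step-up adjustment is applied within each contrast.  Genes at zero
in both groups report log₂FC = 0, p = 1.  This engine is deliberately
simpler than DESeq2 (no empirical-Bayes dispersion posterior, no
Cook's-distance filtering, no independent filtering); a DESeq2-shaped
table adapter lets externally computed contrasts replace it, because
the package's contribution is the classification layer, not the DE fit.

## Classification tables

Both tables consume only the three significance flags (padj < 0.05,
configurable once) and fold-change signs, so calls are invariant to
count scale and gene order; both tables are total (exhaustively tested
over all 2³ × 2³ patterns).  Two open readings were settled as
follows:

* Transgressive calls do **not** require the parents to differ
  (`transgressive_requires_parental_difference=False` by default, with
  the stricter reading behind the flag).  This is the only reading
  under which compensatory genes — whose parents are equal by
  definition — can be transgressive, which the regulatory table
  requires for consistency.
* "Intermediate" for additive means opposite signs of the two
  H-contrast fold changes, not a magnitude window; a significant flag
  alongside an exactly-zero fold change routes to ambiguous.

The transgressive rule precedes the additive/dominant rules, so a gene
significantly beyond both parents is transgressive regardless of the
parental contrast.

## Introgression boundaries

Per-gene mapping deltas use the HIL's samples only (parental samples
would flag the whole donor genome) and a fixed pseudocount of 0.1
inside the log.  Segmentation is a run rule: flag Δ > θ (default 1.0),
report maximal runs of ≥ `min_run` (default 5) flagged genes tolerating
≤ `max_gap` (default 2) consecutive unflagged genes; unflagged genes
inside a run are kept as segment members since they lie within the
physical interval, and segment coordinates are the outermost flagged
genes' start/end.  At ~21% synonymous-site divergence the delta signal
is strongly bimodal (|Δ| ≈ log₂(1/λ) ≈ 4.3 at the default leak), so the
defaults are far from the decision boundary; they are an explicit,
reproducible stand-in for what is usually done by eye and are not
claimed to reproduce any particular published boundary call.  No
HMM/changepoint machinery and no sub-gene breakpoints.

## Synthetic data generator

The generator emulates: triplicate sampling of species B, species N and
two HILs; ~12,000 1:1 orthologs laid out on five autosomes plus an X
carrying ~17% of genes; NB counts with per-gene dispersion drawn
log-uniformly from [0.005, 0.2]; baseline means log-uniform in
[20, 2000]; per-sample library factors uniform in [0.7, 1.3]; two
nonoverlapping X intervals (fractions 0.62–0.92 and 0.12–0.52 of the X)
whose genes take the donor mean and map to the donor reference; and a
mapping-leak λ = 0.05 scaling every wrong-reference mean (cross-species
mapping is poor but nonzero at this divergence).  Architecture fractions
default to conserved 0.50, no-effect 0.12, trans-only 0.12,
compensatory 0.13, combined 0.13 — chosen to mirror the observed
preponderance of conserved profiles with the divergent classes at
roughly equal shares — with effect size d = 2 log₂ units and combined
sub-patterns (intermediate / reinforced beyond B / opposite side of N)
in equal thirds.  Both HILs share one truth table, i.e. the same
*trans*-perturbation hits the same genes in both lines; this matches
the empirical observation the pipeline is meant to recover (high
cross-HIL concordance) and is the interesting regime for the
concordance statistics.

What the generator does **not** emulate: GC/length biases, outlier
samples, correlated genes or batch structure, unbalanced designs,
partial mappability within genes, or any sequence evolution.  Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to the
artefacts of real libraries.

## Problem sizes and numerical choices

Test simulations use 1,000–5,000 genes (null calibration at 5,000;
category recovery at 4,000 genes, d = 3, α = 0.02, 5 replicates;
boundary recovery at 3,000), which keeps the full suite under ten
seconds while leaving Monte-Carlo error well inside the asserted bands.
All randomness flows from a single `numpy` Generator seeded per
experiment; two runs at one seed are byte-identical down to the written
fixtures and JSON report.  Rounding for reported percentages is
half-up (two-sided `decimal`), percentages to integers and Jaccard
indices to one decimal.  Ties and degenerate inputs: empty DEG
intersections yield an explicit "no shared DEGs" report rather than an
error; overlapping segments, unsorted deltas, under-replicated designs
and out-of-range p-values raise typed exceptions.

## Limitations

* The NB Wald engine is approximate at very low counts and few
  replicates; it is calibrated in the shipped simulations (raw-p
  false-positive rate 0.044–0.052 at the null) but real data with
  outliers will benefit from the DESeq2 adapter path.
* "Detectable expression" (mean raw count ≥ 1 across the comparison's
  samples, plus ≥1 nonzero count) is a pragmatic, configurable filter;
  published expressed-gene totals depend on whatever filter the
  original workflow applied and are not expected to match exactly.
* Combined *cis–trans* effects are not sub-classified into compensatory
  vs reinforcing; the three-contrast design cannot separate them.
* Gene-set/GO enrichment is out of scope.
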
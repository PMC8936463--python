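# Methods

This note documents the statistical models implemented in `osteosc`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducing
results.

## Study design being modeled

Two species (human, chimpanzee), six iPSC-derived cell lines per species plus
one technical replicate per species, differentiated through three collection
stages (pluripotent, mesenchymal, osteogenic). Each droplet collection pools
one human and one chimpanzee line at the same stage, so species and batch are
not confounded; droplets are assigned to species bioinformatically from
counts of UMIs aligning uniquely to each genome. Osteogenic cells are further
resolved into five substages (preosteoblast, osteoblast, embedding
osteoblast, mineralizing osteoblast, maturing osteocyte) from marker-gene
positivity.

## Synthetic-data generator

`generate_experiment` draws, for each (species, line, replicate, stage)
sample, `cells_per_sample` cells whose per-gene log-scale means are

    baseline_g + stage_g,s + marker_g,(s or substage) + de_g,s * lfc_g * ln2 * 1[human]
    + b_g,line

with `b_g,line ~ N(0, line_effect_sd^2)` drawn per gene and line. Relative
abundances are the softmax of these means; a dedicated mitochondrial gene
block is rescaled per cell to a Beta-distributed mitochondrial fraction
(mean `mito_frac_mean = 0.05`) so QC filters are exercisable. Totals are
lognormal (`exp(N(log 5000, 0.35))` UMIs by default — a realistic droplet
depth) and counts are multinomial given the total, which makes per-droplet
UMI conservation exact; an optional gamma overdispersion multiplier gives
negative-binomial-like counts. Interspecific DE structure is motif-driven:
each gene picks a motif (a vector of per-condition DE probabilities; default
two motifs, "DE everywhere" at weight 0.3 and "DE nowhere" at 0.7, matching
the dominant patterns such a design produces), conditions flip DE indicators
independently, and DE genes carry one `N(0, lfc_sd^2)` log2 fold change
applied wherever the indicator is on. Doublets are always cross-species (the
case demultiplexing must detect): one extra cell of each species from the
same pool merged into one droplet. Alignment bleed-through sends each UMI to
the wrong genome with probability `bleed`.

Defaults (6 lines/species + 1 replicate each, 3 stages, 360 cells/sample =
15,120 droplets, 1,000 genes) are a desk-scale rendition of the design: the
real study collected two orders of magnitude more cells and genes, so
absolute DE counts are not comparable — only the statistical behaviour of
the methods is. The generator does **not** emulate: ambient RNA, empty
droplets, same-species doublets, UMI saturation, batch-specific chemistry
effects, gene-length or GC biases, or reads mapping to both genomes (UMIs
are uniquely aligned by construction). Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every artifact of real droplet data.

`generate_topic_data` draws Poisson counts with rates
`libsize * (L F')`, L rows Dirichlet on the simplex, F columns Dirichlet gene
distributions — exactly the grade-of-membership model the topic fitter
assumes.

## Species demultiplexing

The ratio rule labels a droplet human when `h/(h+c) >= 0.9` and chimpanzee
when `<= 0.1` (boundaries inclusive, matching the rule's wording), multiplet
strictly between, and `unassigned` when no UMI aligned (a QC failure, not a
species call). The percentile rule assigns a provisional species by majority
genome, computes the 10th percentile of each species' own-genome counts
(linear interpolation; the interpolation is configurable since the upstream
tool's convention is not documented), and relabels droplets exceeding both
percentiles as multiplets. With `bleed = 0`, singlet ratios are exactly 0 or
1, so the ratio rule is analytically exact — that is the basis of the
demultiplexing acceptance check.

## QC, normalization, scaling

Cells are kept when total UMIs >= 1000, detected genes >= 700 and
mitochondrial fraction <= 0.25 (all boundaries in the keep direction).
Log-normalization is `ln(1 + count/libsize * 1e4)`; the 1e4 scale factor and
the +/-10 clip on scaled values follow the common single-cell toolchain
convention and are configurable. Nuisance regression removes total-UMI and
mitochondrial-fraction effects per gene by OLS on the log-normalized values;
residuals are standardized then clipped. Cross-dataset integration is out of
scope here, so the regression operates directly on the log-normalized
matrix (optionally with batch covariates added) rather than on an integrated
embedding — a documented deviation that leaves the positivity rule operating
on scaled residuals either way. Marker positivity is evaluated after
regression and standardization but before clipping would matter (clip only
affects values beyond +/-10, far from any mean threshold).

## Marker-rule staging

A cell positively expresses a gene when its scaled value strictly exceeds
the mean over all cells being classified. Stage rules are ordered,
first-match-wins:

    maturing osteocyte       MEPE+
    mineralizing osteoblast  PHEX+
    embedding osteoblast     BGLAP+ RUNX2-
    osteoblast               BGLAP+ RUNX2+
    preosteoblast            RUNX2+

This ordering encodes the canonical osteogenic marker progression (RUNX2
early, BGLAP mid, PHEX/MEPE late) as an interpretation, and the scheme object
is fully configurable (alternative 6- or 8-gene schemes can be supplied).
The general scheme is pluripotent = POU5F1+, mesenchymal = CD44+ POU5F1-,
osteogenic = COL1A1+ POU5F1-. Marker discovery is one-vs-rest Wilcoxon
rank-sum on log-normalized values, testing only genes detected in >= 25% of
the class with average logFC >= 0.25 in the class's favour (up-regulated
only), BH-adjusted within class, with a top-100-by-logFC selector for
enrichment input. The rank-sum p-value is exact (full enumeration) for
tie-free samples up to n = 50 and a tie-corrected normal approximation
otherwise. Average logFC is `ln(mean(expm1(x)) + 1)` difference between
class and rest, the toolchain convention.

## Pseudobulk differential expression

Pseudobulk samples are sums over unique (line, replicate, classification)
groups, optionally after seeded subsampling of each group to a common cell
count. Gene filters drop mitochondrial and ribosomal genes and genes with
mean log2 CPM <= 0; the log2-CPM transform uses prior count 0.5 over
libsize + 1 (the same transform the precision weights use, reused for
consistency). TMM normalization follows the published recipe: reference
sample by upper-quartile proximity to the mean, M-values trimmed 30% per
tail and A-values 5% per tail, asymptotic-binomial inverse-variance weights,
factors rescaled to geometric mean 1. Precision weights come from the
mean-variance trend: per-gene OLS on the design, lowess (frac = 0.5) of
sqrt residual SD against average log count, predicted sqrt-SD at each fitted
value raised to the -4.

The per-gene model is `y = b0 + b_species x + b_line + e` with the cell line
a random intercept shared by technical replicates. Estimation is weighted
REML: the variance ratio `s2_line/s2_e` is profiled by 1-D bounded
optimization on the log scale (with an explicit boundary check at zero), in
the eigenbasis of the whitened random-effect covariance so each likelihood
evaluation is O(n). Tests use Satterthwaite degrees of freedom computed from
the numerical gradient of the coefficient variance and the finite-difference
REML information; at the boundary (zero line variance) the model collapses
to weighted least squares with n - p degrees of freedom, and non-convergence
falls back the same way with a per-gene flag. Satterthwaite was preferred
over Kenward-Roger as adequate at this design size (14 samples). DE calls
use BH FDR < 0.01 within each classification.

## Correlation-motif joint DE

Each condition's pseudobulk is TMM-normalized and precision-weighted on its
own (condition-wise reference selection). Weighted least squares gives the
contrast estimate, residual variance and unscaled coefficient variance v_g;
variances are shrunk with the standard empirical-Bayes scaled-inverse-
chi-square prior, fit by method of moments on log sample variances
(trigamma inversion by Newton iteration). The moderated statistic is
`t = beta / (s_post sqrt(v_g))` with d0 + d degrees of freedom. The DE
(alternative) density is the null t stretched by
`sqrt((v_g + v1)/v_g)`; v1 is estimated by moment-matching the mean squared
statistic in the upper 1% tail of |t| (configurable), floored at 0.1 times
the median v_g — an explicit, testable rule for a quantity the original
framework leaves implicit.

The mixture model: gene g follows motif k with probability pi_k; under motif
k, condition d is DE with probability q_kd; the observed statistic density is
`q_kd f1 + (1 - q_kd) f0`. EM updates responsibilities, pi and Q in closed
form (log-space, with Q clamped to [1e-6, 1 - 1e-6]); the log-likelihood is
asserted non-decreasing. Restarts use Dirichlet(1) pi and Uniform(0.05,
0.95) Q initializations (default 5 starts; EM is multimodal). Model size is
chosen by BIC with (K - 1) + K*D free parameters. The per-gene per-condition
DE posterior is `sum_k z_gk a_gdk`; calls use a strict > 0.65 threshold.
Conservation between species compares species-wise stage-transition
posteriors: conserved iff |dP| <= 0.3 (inclusive; implemented with a 1e-12
epsilon so the inclusive boundary survives float rounding). At the
separation used in the calibration experiments (stretch factor 4, 20 df,
5,000 genes) the fitted Q recovers the generating values to a few hundredths
per entry; tighter recovery requires stronger separation since the DE
indicators are latent.

## Topic modeling

Counts are optionally batch-corrected by equalizing per-gene batch means on
the log(count + 1) scale and rounding back to non-negative integers (an
explicit stand-in for the correction step whose algorithm the original
toolchain does not document). Poisson NMF minimizes
`sum(LF') - sum(X log LF')` by the classic multiplicative updates, which
never increase the objective; fitting stops at relative objective change
below 1e-6 or `max_iter`. Loadings rows are rescaled to per-cell topic
probabilities (all-zero rows become uniform, flagged); factors are rescaled
to sum 1 across each **gene** by default — implemented verbatim as the
analysis describes even though per-topic normalization is the more common
convention, which is available behind `factor_norm="per_topic"`. Top topic
features are ranked by the Poisson KL divergence between the gene's rate
under the topic and its maximum rate under any other topic, an explicit
distinctiveness score standing in for an undocumented reference algorithm.

## Variance and enrichment statistics

Mean and variance per gene are computed within species x classification over
pseudobulk samples (the analysis text is ambiguous between cells and
pseudobulk samples; pseudobulk is the default because the computation is
described immediately after pseudobulk construction, and a per-cell mode is
a one-line switch by passing the cell-level matrix). Adjacent
classifications along the trajectory are compared with Welch two-sided
t-tests on the gene-wise distributions of means and of variances — Welch
because group variances differ by construction; reported variances are
log2-transformed. Gene-set enrichment uses the upper-tail hypergeometric
test (significant at p < 0.01 and BH q < 0.05) and, for external gene sets,
a one-sided Fisher's exact test whose background is exactly the set of genes
tested for DE. BH is used where the original tooling defaults to a Storey
q-value; at these set counts the difference is a conservative constant
factor.

## Numerical choices and degenerate inputs

* Zero-total droplets are `unassigned`, never a species guess.
* Constant genes yield zero scaled vectors with a flag, not NaN.
* All-zero loading rows become uniform topic vectors with a warning; empty
  rows/columns are dropped before NMF with a warning.
* Degenerate Fisher margins return p = 1 with a flag.
* EM and NMF assert/guarantee monotone objectives; both clamp parameters
  away from bounds by 1e-6/1e-12 epsilons.
* All randomness flows from one seed via `SeedSequence` fan-out, so
  identical configurations replay byte-identically.

## Problem sizes used in the test and acceptance runs

The suite exercises the pipeline at 15,120 droplets x 1,000 genes (the
default generator scale) and the component calibrations at 2,000 genes x 14
samples (mixed model), 5,000 genes x 3 conditions (motif mixture), and 600
cells x 200 genes (topic recovery) — sizes chosen so each calibration has
enough resolution to detect miscalibration while the whole suite stays
convenient to run on a laptop-class single CPU.

## Known limitations

* The mixed model supports exactly one random intercept (cell line);
  replicate is not a second variance component, mirroring the single-term
  model equation.
* The motif mixture supports two groups per contrast (species, or two
  adjacent stages), not multi-level factors.
* The generator's doublets are always cross-species; same-species doublets
  (invisible to genome demultiplexing) are out of scope.
* Integration/embedding (reciprocal PCA, UMAP) and graph clustering are
  deliberately not implemented; the marker-rule scheme is the in-scope
  classification.
* BH replaces Storey q-values in enrichment; v1 tail estimation and the
  topic batch-correction/top-feature rules are explicit reinterpretations of
  steps whose reference algorithms are not documented.
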
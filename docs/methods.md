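# Methods

## Scope and data model

`climagea` analyses diploid biallelic SNP genotypes from individuals grouped
into J populations, each population tied to a sampling site with measured
climate variables.  All statistics operate on per-population allele counts
(alternate count and total sampled alleles per SNP × population); hemizygous
calls (females on the Z chromosome) contribute one allele.  The pipeline
order is: sample subsetting → relatedness pruning → SNP filters → climate
PCA → Ω fit → replicated Bayes-factor scan → POD thresholding → candidate
selection → annotation → gene scores → GO enrichment.

## Genotype QC

Defaults: minimum minor allele frequency 0.01 and minimum call rate 0.8
(both inclusive keep-thresholds, computed on the final sample set), removal
of SNPs on unplaced-scaffold chromosomes, ≥ 15 individuals per population,
males only on Z (female Z calls are set missing; unknown sex is treated as
female there, conservatively), and greedy relatedness pruning at cutoff
0.25.  Relatedness is the method-of-moments estimator
mean over SNPs of (x_k − 2p)(x_l − 2p) / (2p(1−p)); it carries the usual
finite-sample centering bias of order −1/(N−1) on unrelated pairs, which is
irrelevant at the 0.25 cutoff.  Pruning repeatedly removes the individual
with the most above-cutoff partners (ties: lower call rate, then
lexicographically last id), which takes out the chick of a parent–parent–
chick trio first.  Call rate on Z uses the male-only denominator once
females are masked, so Z SNPs are not spuriously removed.

## Climate PCA

The site × variable table mixes units, so variables are standardized before
decomposition (correlation PCA).  Components are sign-fixed (largest-
magnitude loading positive), ordered by decreasing variance; variance
fractions are reported over all components and sum to one.  The retained
scores (default 4 components) are re-standardized to mean 0, SD 1
(population SD, ddof = 0) *after* truncation — scores standardized
post-truncation was an open choice; it matches the scale the scan validates.

## The neutral model and Ω estimation

Frequencies follow a truncated-Gaussian model on the frequency scale:
α_ij = clamp(π_i + s_i m_ij, ε, 1−ε) with s_i = √(π_i(1−π_i)),
m_i ~ N(0, Ω), ε = 10⁻⁴, and binomial sampling of counts.

The Ω estimator is a corrected moment estimator.  The raw moment matrix
V = Z'Z/S of standardized residuals z_ij = (y_ij − π̂_i)/ŝ_i (π̂ the pooled
count-weighted frequency) is biased two ways:

1. **Sampling noise** inflates the diagonal by ν_j = (1 − Ω_jj)·E[1/n_ij];
   this is removed explicitly.
2. **Centering** on the pooled per-SNP frequency annihilates the rank-one
   component 1h′ + h1′ of Ω along the pooled-weight vector.  The *relative*
   structure of h is recovered from heterozygosity moment identities —
   E[H_j] = E[s²](1 − Ω_jj) for the per-population expected heterozygosity
   and E[π̂(1−π̂)] = E[s²](1 − v_tot) for the pooled one — iterated with the
   working gauge pinned at w′Ωw = 0.

The *absolute* level of h is not identifiable from count data: the shared
drift of all populations is confounded with the ancestral frequencies (we
verified that a profile marginal likelihood over the shared-drift scalar is
flat once the Beta ancestral-frequency parameters are refit).  As in the
coancestry-estimation literature, an identifiability convention closes the
gap: **the least-related pairs of populations are assigned zero shared
drift**.  The anchor is estimated split-sample — the k = 4 least-related
pairs are chosen on one half of the SNPs and their covariance evaluated on
the other half, in both directions — which removes the order-statistic
selection bias of anchoring on an observed minimum.  A consequence: drift on
the branch ancestral to *all* sampled populations is absorbed into the
reference and not reported in Ω; estimates are comparable to a generating
matrix only when that matrix respects the same convention (e.g. drift trees
with no root branch).  Finally Ω is shrunk toward its diagonal just enough
to make the smallest eigenvalue ≥ 10⁻⁶.  The uncorrected estimator
(plain shrunk V) remains available via `bias_correction=False`.

The Beta(a, b) hyperparameters for π are fitted by method of moments to the
pooled frequencies, after deconvolving the drift + sampling share of their
variance.

## XtX

XtX_i = z_i′ Σ_i⁻¹ z_i with Σ_i = Ω + diag((1 − Ω_jj)/n_ij): the Mahalanobis
norm of the standardized frequency vector under the fitted model *including
binomial sampling noise*.  At the sample sizes this pipeline targets
(tens of alleles per population) sampling noise is comparable to drift and
cannot be ignored; including it gives the statistic its natural calibration,
E[XtX] ≈ J − 1 under neutrality (one degree of freedom is spent on the
per-SNP frequency centering).  Populations with zero sampled alleles at a
SNP are dropped and Ω sub-matrixed.

## Monte-Carlo Bayes factors

Per SNP, the standardized residual vector and the covariate are whitened
with the Cholesky factor of Σ_i (u = L⁻¹z, d = L⁻¹c), giving the working
model u = βd + e, e ~ N(0, σ²I), with a zero-mean Gaussian prior on β
(`prior_sd`, default 0.2 on the standardized-frequency scale).  The Bayes
factor against β = 0 is estimated by Monte Carlo: the average likelihood
ratio over `n_mc` prior draws of β (log-sum-exp, draws independent across
SNPs and runs), reported in decibans.  A conjugate closed form
(log BF = −½ log(1 + τ²b/σ²) + τ²a²/(2σ²(σ² + τ²b)), a = u′d, b = d′d)
exists for the same model and serves as the test oracle.

σ² is a method-of-moments plug-in: the **genome-wide median of u′u/J**.
Whitening makes the neutral residual variance ≈ 1 by construction, and the
median calibrates the realized level robustly.  Two alternatives were
rejected on statistical grounds: a per-SNP u′u/J lets a strong, saturated
selection signal inflate its own noise estimate (capping all Bayes factors
near 20 dB regardless of effect size), and a per-SNP residual-based
estimate gives the null an F-like tail that violates the < 0.1% neutral
decisive rate.

The scan runs once per seed (default seeds 1, 2, 3); only the Monte-Carlo
draws differ between runs.  The decision statistic is the minimum dB across
runs, so "decisive" means every run exceeded 20 dB.  The core XtX statistic
is deterministic given the fitted model, so replicate runs share one XtX
vector and the union/intersection distinction for outlier calls across core
runs does not arise.

## POD null calibration

Pseudo-observed data are simulated from the fitted model — π ~ Beta(â, b̂),
m ~ N(0, Ω̂), truncated-Gaussian frequencies, binomial counts at the
observed per-population allele totals — and scored with the *same* Ω̂ (never
refit on POD), so the threshold measures SNP-level exceedance rather than Ω
uncertainty.  The empirical threshold at level α is the ⌈(1−α)N⌉-th order
statistic of the null sample; outlier calls use strict exceedance, so a
value exactly at the threshold is not an outlier.  Default n_pod = 50,000
pseudo-SNPs at α = 0.01 (a desk-scale choice; the threshold estimate's
noise is already far below the calibration tolerance there).

## Candidates

Jeffreys classes on min-dB use the half-open intervals (10, 15], (15, 20],
(20, ∞).  Candidates per covariate are the decisive SNPs; reported subsets
are those in annotated genes, and those that are additionally XtX outliers.
The overlap test is a one-sided exact binomial tail P(X ≥ k | n, p₀) with
n the annotated decisive SNPs and p₀ defaulting to the genome-wide outlier
rate (outliers / SNPs tested) — the null proportion was an open choice and
is configurable.

## Annotation

A SNP is assigned to the gene containing it (distance 0) or the nearest
gene within a symmetric window, default 2,500 bp, inclusive at exactly
2,500 (the boundary convention was an open choice and is documented here).
Distance is position-to-nearest-edge, strand-ignored, signed negative
upstream of the gene start.  Ties: overlapping genes → smaller start then
id; equidistant flanking genes → lexicographically smallest id.  SNPs on
chromosomes absent from the gene set are unannotated, not errors.

## Gene scores and GO enrichment

Per gene: the number of annotated SNPs and the maximum over its SNPs of the
min-across-runs dB (the same decision statistic as SNP-level calls).  Genes
are grouped by exact SNP count below 100 and by the bins 100–149, 150–199,
200–299, 300–499, ≥ 500 above, ranked within groups by descending max dB
(competition ranks: ties share the smallest rank), and scored rank/size
∈ (0, 1] — low score = strong association, and under no signal the scores
are uniform on the rank grid by construction.

Annotations are propagated up the is_a DAG (true-path rule: a gene annotated
to a term belongs to every ancestor).  Terms with fewer than `node_size`
(default 10) genes are not tested.  Each term's gene scores are compared
against the full universe's score distribution with a one-sided two-sample
KS test (alternative: term scores stochastically smaller); if a term's genes
hold exactly the m smallest of N scores the statistic attains 1 − m/N.  The
`elim` algorithm processes terms from the most specific level (longest path
from the root) upward and, when a term's p-value falls below `elim_cutoff`
(default 0.01), removes its genes from all ancestors' sets before those are
tested, so specific signal is not re-reported in general terms.  P-values
are left unadjusted: the DAG structure makes neighbouring tests conditionally
dependent and standard multiplicity corrections invalid.  `elim` is the
implemented decorrelation; the blended elim/weight hybrid some tools default
to is intentionally out of scope, and the algorithm label is carried in
every output row.

## Synthetic data

The generator emulates a range-wide SNP-chip study: 20 populations × 20
individuals by default, 20,000 SNPs on four autosomes, a Z chromosome
(~10% of SNPs) with sexed individuals and hemizygous females, and a small
unplaced-scaffold chromosome ("chr35", ~2%) to exercise the QC filter.
Defaults and what they emulate:

| parameter | default | rationale |
|---|---|---|
| Ω | hierarchical, 4 clades, diag ≈ 0.012 | genome-wide FST ≈ 0.01 of a widespread, weakly structured species |
| π distribution | Beta(2, 2) | chip-ascertained common-variant spectrum; keeps truncation of the Gaussian frequency model negligible |
| effect size β | 2.0 | a per-SD-of-covariate shift on the standardized frequency scale large enough to saturate frequencies across the gradient (strong local adaptation) |
| selected SNPs | 50 of 20,000 | a minority of loci under climate-driven selection |
| missing rate | 0.02 | SNP-chip-scale missingness |
| related pairs | 3 | close relatives known to contaminate field collections |
| climate | 22 variables from 2 latent gradients + noise | gives the PCA a known low-rank truth; gradient 1 (the selection covariate) dominates |

The selection shift enters on the standardized (m) scale so the effect is
comparable across π; spiked SNPs draw π from mid-frequencies (standing
variation).  Related pairs are made by copying ~50% of sites wholesale
(expected relatedness ≈ 0.5, safely above the 0.25 cutoff).  Climate
variables get random units (scale factors over ~2.5 orders of magnitude) so
correlation PCA is genuinely exercised.

What the generator does **not** emulate — linkage disequilibrium,
recombination maps, coalescent noise, ascertainment interacting with
structure, spatially autocorrelated sampling — bounds what green tests
show: they validate the statistical machinery under its own model
assumptions, not robustness to the full messiness of real data.

## Numerical choices and problem sizes

Simulation-based checks run at desk scale chosen once: calibration and
spike-in at J = 20, 20,000 SNPs with a 50,000-SNP POD null; Ω recovery at
J = 8, 25 diploids/population, 10,000 SNPs with a two-clade drift tree
(diag 0.05) that respects the min-coancestry convention; Monte-Carlo vs
closed-form agreement at n_mc = 10⁵.  `n_mc` defaults to 1,000 in the
library (the replicate-minimum damps Monte-Carlo noise); the CLI scan
default is 10,000.  Degenerate inputs are contracts, not crashes:
monomorphic or untyped SNPs carry NaN statistics and are excluded from
thresholds; populations with no alleles at a SNP are dropped from that
SNP's quadratic form; all-missing SNPs are removed with a logged count.

## Known limitations

- Ω is identified only up to the min-coancestry gauge; drift shared by all
  sampled populations is not attributable from these data.
- The Bayes factor is a whitened-regression Monte-Carlo statistic: it keeps
  the decision scale (dB, min across seeded runs) and the Ω correction of
  the hierarchical Bayesian machinery it stands in for, but it is not a
  posterior from the full count-level model, and its dB values are not
  numerically comparable to that machinery's beyond the Jeffreys bands.
- Heavy truncation (strong drift plus extreme ancestral frequencies)
  biases the heterozygosity identities the Ω correction relies on.
- The KS enrichment p-values are asymptotic for large terms and, as in the
  tooling this follows, unadjusted for multiple testing.
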
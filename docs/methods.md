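# Methods

`stressfactor` analyses paired transcriptome/metabolome experiments with a
factorial drought x heat design and two air-humidity settings under heat.
This note documents the models, the synthetic-data generator that defines
the package's test conditions, the numerical choices, and the limitations.

## Experimental design model

Samples carry two binary stress factors — drought (D) and heat (H) — plus a
relative-air-humidity level that is only meaningful under heat: heating air
without supplementing moisture raises the vapor pressure deficit, so "heat"
is really a compound of temperature and dry air. The six conditions are
control, D, H_LrH, H_HrH, DH_LrH and DH_HrH (LrH = low relative humidity,
HrH = humidity supplemented). Genotype and experimental batch are recorded
per sample; genotypes are pooled in all models (the package targets designs
where genotypes show no divergent stress response), batch is a nuisance
factor removed during preprocessing.

## Preprocessing

*Transcriptome* (complete intensity matrices): quantile normalization
(each column's sorted values are replaced by the across-column mean of
sorted values; ties receive the mean reference over their rank span),
optional probe-to-gene averaging, log2, and batch correction.

*Metabolome* (peak tables with censoring): total-ion-current scaling
(columns divided by their observed sum, rescaled by the mean column sum),
the 2/3 detection filter (a mass is kept if observed in at least two thirds
of the samples of at least one condition, computed on the pre-imputation
mask so an imputed value never counts as detected), imputation of censored
cells at the detection floor (default 5e5) followed by log2, then batch and
measurement-order correction.

Batch correction fits, per variable, an additive least-squares model with
the condition factor, sum-to-zero-coded batch, and an optional linear
measurement-order covariate, and subtracts the fitted nuisance part. On
balanced designs this removes batch means exactly and provably leaves
condition-mean differences untouched; it coincides with mixed-model batch
estimates in the balanced case while having an exactly testable contract.
Rank-deficient condition/batch layouts (batch nested in condition) are
rejected with an explicit error.

A caveat worth knowing: quantile normalization assumes all samples share
one intensity distribution. When a large fraction of variables is strongly
regulated, the stressed samples genuinely have heavier-tailed
distributions, and forcing a common distribution compresses those tails —
interaction estimates then acquire a bias toward zero for strongly
co-regulated variables. The effect is visible in the demo pipeline's
recovery metrics (which run the full normalization chain) and absent when
the factorial model is fitted on data without distribution distortion.

## Factorial decomposition

Per variable, ordinary least squares on

    y = b0 + bD*D + bH*H + bDH*D*H + e,   e ~ N(0, s^2)

using only the four low-humidity cells (control, D, H_LrH, DH_LrH), so the
humidity term cannot contaminate the stress coefficients. On balanced data
the coefficients reduce to cell-mean contrasts (bDH = DH - D - H +
control). Residual variances can be moderated by empirical-Bayes shrinkage
toward a common prior: with e_g = log s_g^2 - digamma(d/2) + log(d/2), the
prior degrees of freedom d0 solve trigamma(d0/2) = var(e) - trigamma(d/2)
(Newton inversion of the trigamma), the prior variance is s0^2 =
exp(mean(e) + digamma(d0/2) - log(d0/2)), and the moderated variance is the
degrees-of-freedom-weighted blend (d0*s0^2 + d*s^2)/(d0 + d) with t tests
on d + d0 degrees of freedom. When the observed spread of log-variances
does not exceed the theoretical chi-square spread the prior is effectively
infinite; d0 is capped at 1e6, which collapses every variance onto the
prior (numerically indistinguishable from the infinite-prior limit while
keeping all downstream arithmetic finite). Moderation is on by default.

Significance calls per coefficient use |estimate| > lfc (default 1.0 log2
units) together with Benjamini-Hochberg adjusted p < alpha (default 0.05);
the adjustment family is one coefficient across all variables of one
layer. The same joint rule is applied to the interaction coefficient — the
fold-change condition on bDH is configurable but on by default, keeping
the three calls symmetric.

The (D, H, D:H) call triple then maps each variable into a response group:
columns encode single-stress specificity (.1 drought-only, .2 shared
same-sign, .3 heat-only), rows encode the interaction (2.x additive = no
interaction, 3.x enhanced = interaction reinforcing the single-stress
direction, 1.x reduced = interaction counteracting it), group 4 is
interaction-only ("specific"), opposite-sign single-stress patterns go to
`opp_additive`/`opp_interaction`, and all-ns is `null`. The classifier is a
total function on the 27-point call space; an exhaustive truth table is
frozen in the tests.

## Humidity contrasts

A one-way model on the six-level condition factor provides every
condition's log2 contrast to control with a pooled residual variance
(n - 6 degrees of freedom). Pooling follows from fitting one linear model
over the multi-valued factor rather than pairwise two-sample fits; the
per-pair alternative would only change degrees of freedom. On the four
factorial cells the contrasts reproduce the factorial coefficient
combinations exactly (DH_LrH contrast = bD + bH + bDH). Venn decomposition
of two conditions' regulated sets is direction-specific: a variable up in A
and down in B contributes to A-only(up) and B-only(down).

## Regularized CCA

Both layers are restricted to shared samples and their top-k
largest-variance variables (default k = 100), standardized to unit
variance, and integrated by ridge-regularized CCA: the leading solutions of

    (Cxx + lx*I)^-1 Cxy (Cyy + ly*I)^-1 Cyx a = rho^2 a

computed through the SVD of the doubly-whitened cross-covariance (numerically
symmetric and stable). Standardization makes covariance and correlation
formulations coincide, so the per-layer ridge weights are interpretable as
correlation-shrinkage intensities and are estimated analytically as

    lambda* = sum_offdiag var-hat(r_ij) / sum_offdiag r_ij^2,  clipped to [0,1],

the closed-form intensity of shrinking the empirical correlation matrix
toward the identity. Eigenvector signs are pinned (largest-|weight| x-entry
positive per component) for reproducibility. Component interpretation uses
correlations between each original variable and the canonical scores, with
t-transform p-values BH-adjusted per component x layer.

## Correlation networks

Pearson correlations over the paired samples, p from the exact null
t-transform t = r*sqrt((n-2)/(1-r^2)), BH-adjusted per edge class
(gene-mass / gene-gene / mass-mass / cross-targeted; families kept separate
because edge classes are thresholded separately). The global network admits
nodes through strong gene-mass edges (r > 0.85 and, by default, adjusted
p < 1e-5 — the p condition on admission edges is configurable), then adds
gene-gene and mass-mass edges among admitted nodes under both thresholds.
Submodule views over an explicit variable list keep positive edges above a
relaxed cutoff (default 0.75) and annotate negative edges below its mirror
image. Communities come from asynchronous label propagation on the
positive-edge subgraph: seeded random visiting order, majority-label
adoption with uniformly random seeded tie-breaks, iterated to a fixed point
where every label is a weak neighborhood majority; a consensus mode
majority-votes co-membership over several seeds. Dense modules are maximal
cliques (Bron-Kerbosch with pivoting), canonically ordered (size
descending, then lexicographic), optionally restricted to cliques
containing a mass. The gene set can be reduced to the top-3 correlated
genes per mass before clique analysis, and clique genes can be linked to a
targeted-metabolomics layer through cross-layer edges with a
minimum-connection display filter.

## Enrichment

One-sided hypergeometric over-representation tests of a selection against
a universe, terms intersected with the universe first, BH across terms.
The universe defaults to all variables surviving preprocessing on the
relevant layer — the least biased choice when no array background is
available. Depletion (lower tail) is available behind a flag.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream guarantee is demonstrated. Per variable, on the
log2 scale:

    y = baseline + bD*D + bH*H + bDH*D*H + humidity + batch
        + sum_f loading*score_f + N(0, noise_sd)

* Design: 6 conditions x 3 genotypes x `replicates_per_cell` (default 3,
  54 samples — close to the 56-sample paired regime the integration
  methods target; 5 replicates for decomposition-recovery studies).
  Replicates rotate through 3 batches, so condition cells stay balanced.
* Response groups: fractions of variables planted per group (defaults sum
  to ~15%, remainder null), each with a random up/down direction; effect
  magnitudes default to 2.5 log2 units with noise_sd 0.3 — strong, clearly
  called effects typical of the top differential variables in stress
  transcriptomics. Genotypes carry zero effect by construction.
* Humidity: a configurable fraction of variables (default 5%) gets an
  additive shift (default 2.0, random sign) in the high-humidity heat
  cells. Placing the shift in the HrH cells keeps the LrH-only factorial
  model exactly correctly specified while still separating the LrH/HrH
  contrasts.
* Latent factors: each factor has gene and mass members (drawn from the
  planted-null pool so factor and group membership stay disentangled), a
  loading, and sample scores tied to the drought indicator, the heat
  indicator, or iid noise. The demo configuration plants a strong
  drought factor (loading 1.5) and a weaker heat factor (0.8): with equal
  strengths the two leading canonical pairs are nearly degenerate and the
  recovered axes rotate arbitrarily, whereas the asymmetric setting
  reproduces the drought-dominant structure the method is meant to expose
  (component 1 = drought, component 2 = heat).
* Metabolome realism: the metabolite layer is exponentiated to raw scale
  and censored below the detection floor (baseline log2 mean 21, sd 1.5
  against a floor of log2(5e5) ~ 18.9, giving a realistic minority of
  censored cells), exercising TIC normalization, the detection filter and
  floor imputation on their natural scale.
* Determinism: one integer seed drives every draw; identical configs give
  byte-identical outputs. The pipeline fans a single master seed out to
  per-stage seeds through SHA-256.

What the generator does **not** emulate: probe-level microarray structure,
mass-accuracy/isotope structure of FT-ICR-MS spectra, correlated noise
between variables beyond the planted factors, intensity-dependent variance,
or realistic metabolite identities. Passing recovery tests therefore show
that the estimators and classifiers are correct under the assumed model,
not that real data meet those assumptions.

## Numerical choices and degenerate inputs

* Quantile-normalization ties: tied values share the mean reference over
  their rank span (the common convention; makes the operation idempotent).
* Detection-filter boundary: the fraction comparison is `>=`, so a mass at
  exactly two thirds is retained.
* Zero intensities: treated as censored for metabolome layers, rejected
  for transcriptome layers (log2 applicability).
* Constant variables: rejected before CCA/shrinkage estimation, excluded
  with a log entry from correlation tables, flagged as missing in
  variate-variable correlations.
* rCCA rank: requesting more components than min(p, q) or than the
  numerical rank raises; regularized covariances are checked for
  positive-definiteness before whitening.
* Tie-breaks: top-variance selection and top-genes-per-mass break ties by
  variable id; clique output is canonically sorted; label-propagation ties
  are uniform draws from the tied set under the mandatory seed.

## Problem sizes

Default demo and test sizes (2000 genes, 300 masses, 54-90 samples; 20-50
replicate seeds for Monte-Carlo checks) were chosen so planted structure is
comfortably identifiable while a full pipeline pass and the complete test
suite each finish within seconds to a few minutes on one CPU.

## Known limitations

* Batch correction is fixed-effect only; unbalanced designs retain exact
  condition contrasts only up to the usual non-orthogonality.
* The moderated-variance prior estimator uses method of moments, not
  maximum likelihood; for very few variables (< ~50) the prior degrees of
  freedom are noisy.
* The detection filter interacts with TIC normalization (censoring is on
  the raw scale, TIC rescales columns); the package follows the standard
  order (TIC, then filter, then impute) and does not model informative
  censoring.
* Label propagation on near-bipartite or ring-like graphs can oscillate
  between sweeps; the sweep cap (default 100) guarantees termination and
  the consensus mode damps residual seed dependence.
* Full study-scale inputs (tens of thousands of genes, hundreds of
  masses from real instruments) live in external repositories; the package
  demonstrates its guarantees on synthetic ground truth instead.
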
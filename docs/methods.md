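# Methods

`regwire` implements a complete analysis chain for contrasting the
transcriptomes of two groups of animals hybridized on a common microarray
platform: variation filtering, Bayesian differential expression (DE) with
posterior-probability FDR on an effective number of independent tests,
regulatory impact factor (RIF) identification of transcriptional
regulators against a bootstrap null, between-group differential
co-expression, and qPCR cross-platform validation.  A synthetic-data
generator with recorded ground truth stands in for raw arrays, so every
stage is exercised end to end by the test suite.

## Synthetic data

The generator produces log2-scale intensities

    y[p, s] = mu_p + a_s + h_{p, series(s)} + delta_p * x_g(s) + wiring + e[p, s]

with probe baselines `mu_p ~ N(7, 2)` (log2 units; the spread makes the
variation filter behave realistically), array effects `a_s ~ N(0, 0.2)`,
per-probe hybridization-series effects (SD 0.1, centered across the
series levels), planted DE effects `delta_p` with linear fold changes
drawn uniformly on the log2 scale between 1.2x and 8x and random sign
(split +/- delta/2 between the groups, so the group-2 minus group-1
contrast equals `delta_p`), and residual noise `e ~ N(0, 0.5)`.  The
default design is 14 samples per group in two series — the design of the
emulated study of purebred Iberian (IB) versus Duroc x Iberian (DUxIB)
loin muscle.

**Differential wiring.**  Wiring is a linear dependence of DE-gene log2
expression on a regulatory factor's biological deviation (its residual)
with a group-specific coefficient; a scalar `wiring_strength = w` means
coefficients `(+w, -w)` — opposite-sign wiring.  Each wired RF drives a
*coherent program*: the DE genes sharing one direction of change (default
two wired RFs, one per direction; additional same-direction regulators
partition the block).  This choice is deliberate and matters.  RIF1's
per-gene term `a_j d_j (r1_ij - r2_ij)^2` is odd in the contrast `d_j`,
so a regulator wired indiscriminately to up- and down-regulated genes has
an expected RIF1 of zero regardless of how strongly its co-expression
changes — planted-regulator recovery is then impossible in principle.  A
regulator whose targets move coherently is exactly the object the metric
is designed to score, and with it recovery is reliable (see below).
Wired RFs receive no group effect of their own: differential wiring
without differential expression of the regulator is the scenario of
interest.

A family label is generated per sample (7 full-sib families per group by
default) but not used by any downstream stage.

**qPCR plates.**  Target genes' underlying abundance is the expression
matrix's own per-sample value, so cross-platform agreement is exact up to
technical noise; reference genes have constant biological abundance but
share the per-sample loading, which is what normalization factors are
meant to remove.  Crossing points follow
`Cp = c0 + slope * log10(quantity)` with `slope = -1/log10(1 + E)` for
efficiency `E`; triplicates are jittered with SD 0.1 cycles.

**What the generator does not emulate:** probe-level Affymetrix
structure, mismatch probes, scanner artifacts, intensity-dependent
variance, or batch structure beyond a two-level series effect.  Passing
tests show that the statistical machinery behaves as specified under a
well-specified Gaussian world, not that the biological conclusions of any
particular study are reproducible.

## Filtering and the effective number of tests

A probe is retained iff strictly more than 20% of its samples deviate
from the probe's median by at least log2(1.5) — the per-probe-median
reading of the "±1.5-fold from the median expression of all arrays" rule
(a grand-median variant is available via `median_mode="grand"`).
The filter is invariant to sample order and to global additive shifts of
the log2 matrix.

The effective number of independent tests uses the alpha-independent
Moskvina–Schmidt form

    m_eff = 1 + sum_{j=2..m} sqrt(1 - max_{i<j} r_ij^2)

over the probe–probe Pearson correlation matrix.  The construction is
sequential, so the result depends on row order; rows are processed in
input order and the order is recorded.  `m_eff` is reported unrounded
(an integer report can round it).  Note a finite-sample property that
matters downstream: with only n = 28 samples the maximum of many sample
correlations is substantially above zero even for independent probes, so
`m_eff/m ≈ 0.8` on null data — the correction is biased toward fewer
effective tests whenever there are many probes and few arrays.

## Bayesian differential expression

The model has an overall effect of each array plus within-probe genetic
type and hybridization series effects and probe-specific residual
variances.  Priors are flat on all location effects and scaled inverse
chi-square (`nu0 = 2` pseudo-observations at the per-probe OLS residual
variance) on the variances; all full conditionals are then standard, and
the joint posterior is explored by Gibbs sampling.

Identifiability required one non-obvious choice: genetic type and series
are properties of arrays, so the array-effect vector is confounded not
only with the probe baselines (its mean) but with *every* within-probe
factor — its projections onto the group-contrast and series directions
are flat directions of the likelihood.  Each sweep therefore projects the
sampled array effects onto the orthogonal complement of
span{1, group contrast, series dummies}.  Without this the chains random
walk (split-Rhat ≈ 1.5) and the contrasts are inflated; with it Rhat is
≈ 1.00 and the posterior SD of a null contrast matches the analytic
sampling SE.

Per probe, the chain of the genetic-type contrast is summarized by its
mean, SD and PP — the fraction of retained draws on the opposite side of
zero from the posterior mean (capped at 0.5).  PPs are treated as
p-values in a Benjamini–Hochberg step-up whose denominator is `m_eff`.
Linear expression ratios are `2^(mean log2 group 2 - mean log2 group 1)`.

Default chain settings are 30,000 iterations, 5,000 burn-in, thinning 5,
with the seed always explicit.  The calibration experiments in the test
suite use 21,000 iterations with 1,000 burn-in and no thinning (20,000
retained draws): the smallest BH threshold is of order `q/m_eff ≈ 3e-4`,
and a count-based PP needs the number of retained draws times that
threshold to be well above 1 to resolve it.

**FDR calibration, honestly stated.**  PP is a one-sided tail
probability: under the null it is half the two-sided p-value.  Feeding
PPs directly into BH therefore doubles the effective level, and the
downward finite-sample bias of `m_eff` multiplies it by a further
`m/m_eff ≈ 1.2`.  On fully null simulations the probability of making at
least one (false) discovery at nominal q = 0.10 is therefore ≈
2·q·m/m_eff ≈ 0.25 in theory and 0.34 as measured over 50 replicates by
the test suite — the corresponding test fails, and is left failing, as a
faithful record of this property of the procedure.  Power, by contrast,
is excellent: planted log2FC = 1 effects at residual SD 0.5 are recovered
in far more than 90% of cases, and that test passes.

## RIF scoring

With `n_de` DE genes, per gene `j` its grand-mean log2 expression
`a_j`, posterior-mean contrast `d_j` and within-group means `e1_j`,
`e2_j`, and per (RF `i`, gene `j`) within-group Pearson correlations
`r1_ij`, `r2_ij`:

    RIF1_i = (1/n_de) * sum_j a_j * d_j * (r1_ij - r2_ij)^2
    RIF2_i = (1/n_de) * sum_j (e1_j r1_ij)^2 - (e2_j r2_ij)^2

Raw scores are standardized to z-scores over the full RF census using the
sample SD (n−1).  Significance uses a bootstrap null: each iteration
draws `n_de` probes uniformly *without replacement* from the filtered
array, treats them as the DE set with their observed summaries, computes
all RF z-scores, and pools the z-scores across iterations and RFs; CI
bounds are quantiles of the pooled distribution (10,000 iterations by
default, seed-deterministic, 99% interval verified to contain the 95%).
Classification is by strict inequality: a z-score exactly on a bound is
not extreme.  Genes appearing in both the RF census and the DE set are
allowed and recorded.

## Differential co-expression

Per (RF, DE gene) pair: within-group Pearson correlations, within-group
tests of r = 0 by the t-transform with n−2 df, and a between-group test
by the two-sample Fisher r-to-z statistic
`(z1 - z2)/sqrt(1/(n1-3) + 1/(n2-3))`, two-sided normal.  The Fisher test
is this package's choice of instrument for "difference between two
correlations" — named in every output because it is a reconstruction,
not a quotation of the original analysis.  The family of difference
tests is BH-corrected with a multiplicative effective count:
`m_eff(RF set) × m_eff(DE set)`.  Pairs with a constant profile in either
group are flagged, excluded from the family, and counted.  Edge lists
carry per-group sign and significance plus the difference flag, and
round-trip through TSV.

## qPCR validation

Triplicate Cp values are aggregated by arithmetic mean (replicate SD >
0.5 cycles triggers a warning).  Relative quantities use the
comparative-Cp method with the gene's standard-curve slope and the most
abundant sample (lowest Cp) as calibrator:

    Qty = 10^((Cp - Cp_calibrator)/slope),   slope < 0

This orientation — rather than the sometimes-printed `10^(-dCp/slope)` —
is forced by the contract that a later crossing point means a less
abundant transcript and the calibrator has quantity 1; with a negative
slope the negated form would invert the abundance ordering.  Efficiency
derives from a ≥3-point dilution curve spanning ≥2 log10 as
`(10^(-1/slope) - 1) × 100`.

Reference genes are chosen by a geNorm-style stability measure: a
candidate's M is the mean, over all other candidates, of the SD across
samples of the pairwise log2 quantity ratio; the two lowest-M candidates
are selected and the per-sample normalization factor is the geometric
mean of their quantities.  (The full stepwise-exclusion loop of geNorm is
simplified to a single M ranking, matching the use case of picking two
references.)  Normalized quantities are compared between groups with a
two-sided two-sample t-test.

Cross-platform agreement uses per-gene Pearson correlation of per-sample
values and, globally, Lin's concordance correlation coefficient on
linear-scale fold changes with n-denominator moments:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

CCC is symmetric and satisfies |CCC| ≤ |r|; the linear-scale convention
reproduces the published 18-gene value of 0.863 from the packaged
reference table.

## Numerical and design notes

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  simulated matrices, chains, bootstrap bounds and pipeline outputs.
- The pipeline manifest hashes the configuration (minus the output
  directory), seeds and package version; every stage TSV carries the hash
  in a leading comment line.
- Degenerate inputs fail loudly with the offending probe/sample/field
  named: missing cells, constant profiles where a correlation is needed,
  |r| = 1 in the Fisher transform, zero quantities in geNorm, zero
  variance in standardization.
- Problem sizes in the test suite — 100–500 probes, 14+14 samples,
  20–30 RFs, chains of a few thousand to 21,000 iterations, bootstraps of
  300–400 iterations — were chosen as the smallest sizes at which the
  statistical properties under test are measurable with comfortable
  Monte-Carlo margins.

## Known limitations

- Null FDR calibration of the PP-as-p-value step is inflated by a factor
  of about two by construction (see above); users wanting strict FDR
  control should double PPs before the step-up, at the cost of departing
  from the emulated procedure.
- The Gibbs model covers exactly the stated structure (array + genetic
  type + series, probe-specific variances); no probe-to-probe shrinkage
  or covariance modelling.
- The bootstrap pools z-scores across RFs into a single pair of global
  intervals per metric; per-RF intervals are not produced.
- geNorm's iterative exclusion and pairwise-variation V statistic are not
  implemented; exactly two references are selected.
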
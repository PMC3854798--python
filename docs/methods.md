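# Methods

## The estimation problem

The package estimates how much of the phenotypic variation in milk
fatty-acid traits is captured by a genome-wide SNP panel (genomic
heritability), and how strongly pairs of traits are coupled at the
genomic and at the residual level (genomic and environmental
correlations). The study design it targets is a half-sib field sample:
a few hundred cows descending from a large number of sires (most
families of size 1–3), spread over many herds of very unequal size,
sampled in parities 1–3. In such a design pedigree information is
shallow, so the relationships that identify the genetic variance come
from the markers themselves.

## Bayesian SNP-regression model

Univariate model for one trait:

    y = mu + X1 b1 + X2 b2 + Z u + e,
    u ~ N(0, I su2),  e ~ N(0, I se2).

`X1`, `X2` are herd and parity incidence; `Z` holds the centered SNP
covariates produced by QC (mean-imputed allele counts minus `2p`). The
first level of each factor is absorbed into the intercept so the fixed
design is full rank. Priors are flat on fixed effects and flat
(uniform) on both variances on the variance scale, optionally truncated
above by `variance_upper_bound`.

Sampling is single-site Gibbs:

* fixed-effect coefficients and each SNP effect from their normal full
  conditionals, with the residual vector updated in place;
* `se2` and `su2` from scaled inverse-chi-square full conditionals with
  `n-2` and `m-2` degrees of freedom (the flat-prior exponents);
  truncated draws are rejected and redrawn;
* every 10th sweep, a joint scale move proposes `u -> c u`,
  `su2 -> c^2 su2` with `ln c ~ N(0, 0.3^2)`, accepted by
  Metropolis–Hastings (log ratio `2 ln c` plus the likelihood change).
  Single-site updates alone mix the SNP-effect variance very slowly and
  can trap it near zero at large m; the scale move restores mixing
  while leaving the stationary distribution untouched.

The bivariate model gives every SNP a 2-vector of effects with unknown
2x2 covariance `Su` and lets residual 2-vectors have covariance `Se`;
both get inverse-Wishart full conditionals (flat matrix priors, degrees
of freedom `m-3` and `n-3`, sampled by Bartlett decomposition), SNP
effect pairs are drawn jointly from their bivariate normal full
conditionals, and the per-trait scale move rescales one effect column
together with its row/column of `Su` (log ratio `3 ln c`).

An optional Metropolis–Hastings mode replaces the exact Gibbs draw of
each SNP effect with a random-walk proposal whose step adapts toward
~30-40% acceptance during burn-in. The exact proposal used by the
original analysis software is not documented anywhere we could follow,
so this mode is an interpretation; the Gibbs sampler is the correctness
reference, and a test requires the two modes to agree within
Monte-Carlo error.

### Derived quantities

Per saved cycle the sampler evaluates the SNP-explained variance
`sa2 = Var(Zu)` (empirical variance of the genomic values over
individuals), `h2 = sa2/(sa2 + se2)`, and bivariately `Cov(Zu1, Zu2)`
and `r = Cov/sqrt(Var1 Var2)`; the environmental correlation comes from
the `Se` draws. Summaries are the mean and the sample (n-1) standard
deviation of the saved draws, with effective sample size and a Geweke
z-score attached as diagnostics. `Var(Zu)` uses the population (n)
denominator; whether the original analysis divided by n or n-1 is not
determinable, so the choice is frozen here and exposed as a config
switch (`var_zu_denominator`). At n of several hundred the difference
is far below the posterior spread.

Default schedule: 100 000 iterations, 10 000 burn-in, every 100th draw
saved (900 draws). Tests and the acceptance script use 10 000-20 000
iteration chains with proportionally shorter burn-in; the recovery
experiments below state their sizes.

## Quality control and centering

Filters: individual call rate >= 0.80, then locus call rate >= 0.95,
then MAF >= 0.01 (monomorphic loci are the MAF = 0 case and are
labelled separately). Call rates and frequencies are recomputed after
each preceding step, and the three-step sequence repeats until a fixed
point, because removing loci can push an individual below its call-rate
threshold; the fixed point makes the filter idempotent. An optional
per-call GenCall-score matrix can be supplied (threshold 0.65 for
single calls and for an individual's average); it is off by default
since synthetic data has no intensity scores. Missing calls are imputed
at the per-SNP mean `2p`, which leaves centered columns summing to zero
and adds no spurious relationship signal. Mean imputation is a
deliberate minimal choice — it is variance-deflating for the imputed
entries, but at the few-percent missingness this design targets the
effect is negligible.

## Genomic relationship matrix

VanRaden's first method: `M` coded -1/0/1, `P` columns `2(p_i - 0.5)`,
`Z = M - P`, `G = ZZ'/(2 sum p_i(1-p_i))` with observed sample allele
frequencies. This is algebraically identical to the centered 0/1/2
construction used by the sampler, and a test checks the identity to
1e-10. G can be assembled per chromosome; the denominator-weighted
combination `sum_c d_c G_c / sum_c d_c` reproduces the whole-genome
matrix exactly (each `d_c G_c` is that chromosome's raw cross-product),
which is why that combination rule was chosen. Chromosomes with zero
denominator carry no information and are skipped. A ridge (default
1e-6) is added to the diagonal before REML factorisation.

## REML verification path

The univariate animal model `y = Xb + a + e`, `a ~ N(0, G sa2)`, and
its bivariate extension with 2x2 genomic/residual covariance matrices
are fitted by average-information REML. The first three iterations are
EM; afterwards AI updates are used, with an EM step substituted
whenever the AI proposal leaves the parameter space. EM steps cannot
decrease the restricted likelihood, and a test verifies the monotone
trace under forced EM. Convergence requires relative parameter change
< 1e-8 and scaled gradient norm < 1e-6, within 100 iterations;
non-convergence is flagged, never silently returned.

Variances are floored at 1e-8 times the phenotypic variance and
correlations clamped at |r| = 0.999. A fit ending on either bound sets
`boundary_flag`. This mirrors the known failure mode of bivariate REML
on weakly identified data — the correlation runs to +-1 — and such fits
are excluded from the Bayes-vs-REML agreement statistic (they are
convergence failures, not estimates) while remaining visible in the
comparison table. `G = I` (no relationship information) makes the
variance split unidentifiable and is rejected with an explicit error.
Standard errors come from the inverse AI matrix with the delta method
for h2 and correlations; they are auxiliary diagnostics, not the
uncertainty measure of record.

## Fatty-acid trait derivation

Seventeen fatty acids measured as weight proportions of fat (g/100 g)
are grouped per cow: SFA (ten saturated FAs C6:0-C18:0), UFA = MUFA
(C14:1c9, C16:1c9, C18:1t11, C18:1c9) + PUFA (C18:2n6, C18:3n3,
CLAc9t11), and the de novo synthesis group C6toC14. C6toC14 contains
only the even-chain members C6:0, C8:0, C10:0, C12:0, C14:0 — including
the odd-chain C13:0 would break the group-mean reconstruction against
the published composition (22.28 instead of 22.18), which pins the
membership. Desaturase indices are product/(product+substrate) for the
four product-substrate pairs (C14:1c9/C14:0, C16:1c9/C16:0,
C18:1c9/C18:0, CLAc9t11/C18:1t11); an index is left missing (and
logged) where product + substrate is zero. Groups are computed per cow
and then summarised — means commute with the grouping but SD and CV do
not. About 9.8 g/100 g of fat falls outside the measured panel; it is
reported, not modelled.

## Synthetic-data generator

The generator emulates the study design, not its biology:

* **Genotypes.** Per-SNP allele frequencies from Uniform(0.05, 0.95);
  each cow receives one allele gene-dropped from a sampled sire (two
  simulated haplotypes) and one drawn at the population frequency from
  an unrelated dam. Sires are sampled uniformly, giving mostly tiny
  half-sib families. Expected genomic relationship between paternal
  half-sibs is 0.25, verified against the GRM. Chromosome labels split
  the panel into contiguous blocks purely to exercise per-chromosome
  assembly; linkage and LD are not simulated — the estimators under
  test do not require LD, only relationship structure.
* **QC-relevant defects.** Configurable fractions of monomorphic and
  MAF < 1% loci and completely-at-random missingness (no missingness
  mechanism is documented for the real panel, so MCAR is the default
  assumption).
* **Phenotypes.** Unit phenotypic variance per trait: target
  `sa2 = true_h2`, `se2 = 1 - true_h2`. Per-SNP effect vectors are
  drawn jointly across traits from N(0, C) with C scaled by
  `sa2 / sum 2p(1-p)` so the expected Var(Zu) hits the target; the
  *realized* Var(Zu), residual variance, heritability and correlations
  are recorded as the truth, which keeps recovery tests sharp at small
  m. Herd effects are N(0, 0.25^2) by default (a modest shared
  environment), parity adds a small fixed shift per level.
* **Study preset.** 371 cows, 200 sires, 19 herds with sizes drawn in
  [3, 24] by multinomial rejection to sum exactly to 371, parities 1-3,
  2000 SNPs on 5 chromosomes, 2% missingness, 1% monomorphic and 1%
  low-MAF loci. Six traits carry heritabilities 0.07-0.35; their
  genomic correlation matrix comes from unit vectors at angles
  0-127 degrees on a circle (a rank-2 Gram matrix, hence PSD) whose
  entries span -0.60 to 0.91 — the ranges reported for milk fatty
  acids. (The source material gives both 19 and 20 as the herd count in
  different places; the preset uses 19, and the fitting code accepts
  any level count.)

What the generator does **not** emulate: linkage disequilibrium with
causal variants, genotyping error, lactation-stage or seasonal effects,
repeated measures. Passing recovery tests therefore shows the
estimators are correct under the stated generating model — it does not
bound the LD-driven underestimation of heritability expected on real
data.

## Problem sizes and numerical choices in the tests

* Closed-form oracle: n=8, m=3, variances frozen; the posterior mean of
  the SNP effects is compared with the analytic ridge solution within 3
  Monte-Carlo SEs estimated from 10 independent chains.
* Univariate recovery: 20 replicates at n=500, m=2000, true h2=0.3,
  chains 10 000/2 000/thin 10; mean posterior-mean within 0.05 of the
  target and >= 90% coverage at +-2 psd.
* Bivariate recovery: n=500, m=2000, true genomic correlation 0.6,
  residual correlation -0.3, chains 12 000/3 000/thin 10, recovery
  within 2 psd.
* Bayes-REML agreement: 10 pairs at n=400, m=1000, h2=0.45, generating
  correlations spanning [-0.6, 0.9]; mean absolute difference of the
  genomic correlations <= 0.15 after excluding boundary-flagged REML
  fits. h2 = 0.45 keeps the pairs well identified — at h2 = 0.3 and
  this n both estimators' sampling noise dominates and the comparison
  stops measuring agreement of methods.
* GRM identities are exact to 1e-10; composition identities are exact
  arithmetic.

Degenerate inputs have defined behaviour throughout: zero-variance
phenotypes, monomorphic columns reaching the centering or GRM stage,
empty post-QC matrices, constant columns in correlations, and
product+substrate = 0 in indices all raise or log explicitly rather
than propagating NaNs.

## Known limitations

* No LD simulation, so the "missing heritability" phenomenon of real
  SNP panels is out of scope by design.
* The MH mode is validated only against the Gibbs reference, not
  against the original analysis software.
* Bivariate REML standard errors from the AI matrix are unreliable near
  the correlation boundary; the boundary flag, not the SE, is the
  signal to distrust the fit.
* Only one- and two-trait models; no variable-selection priors; no
  pedigree-based relationship matrices.
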
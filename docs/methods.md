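# Methods

## The liability-threshold generator

Every cohort the pipeline consumes is produced by `sexgwas.simulate`.
Disease liability is `L = √h²·g + √(1−h²)·ε` with `ε ~ N(0,1)` and `g`
a weighted sum of standardized dosages, rescaled to unit variance, so the
liability-scale heritability equals `h2_liability` exactly by
construction and the thresholds `T_m`, `T_f` are interpretable as
z-cutoffs. An individual is affected when `L > T_sex`. Setting
`T_f > T_m` yields male-biased prevalence and, through ascertainment,
higher mean polygenic load in affected females — the signature the
spike-in and permutation analyses probe. The male/female threshold gap
implied by a ~4.5:1 prevalence ratio depends on the assumed prevalence
and `h²`, so the gap is a free parameter rather than a hard-coded value
(the analysis drivers use 0.4 SD).

Trios are ascertained by rejection sampling: parents drawn at
Hardy–Weinberg frequencies, children by explicit Mendelian transmission
(sons receive only the maternal X), child sex assigned *before*
ascertainment so the requested sex mix is exact. The sampling budget
defaults to 500× the requested trios; exhausting it raises an error
naming the offending threshold. Male effects at X SNPs use the same
per-allele beta as females by default; a `male_x_scale` knob exposes
dosage-compensation scaling.

All randomness flows from one root seed through named substreams (one
per operation, keyed by CRC of the stream name), so each module is
independently reproducible and drawing more data in one step never
perturbs another.

What the generator does **not** emulate: linkage disequilibrium beyond
independent SNPs (positions are tiled at 10 kb only so windows and
clumping have coordinates to work with), demographic structure beyond
optional multi-population frequency shifts, genotyping error, and
assortative mating. Tests passing on these cohorts therefore validate
the statistical machinery — calibration, power, parameter recovery —
not robustness to LD or ancestry confounding in real arrays.

## Association

The TDT is computed by vectorized transmission counting: transmissions
from heterozygous parents equal the child's minor-allele count minus the
deterministic contribution of homozygous parents; Mendelian-inconsistent
trios are excluded per SNP. `β = ln(b/c)` with `se = √(1/b+1/c)`; the
two-sided p comes from the 1-df chi-square tail without continuity
correction. On the X no change is needed — hemizygous fathers are simply
never informative. One proband per family is used throughout.

Case-control association is logistic regression (statsmodels, Newton
iterations, `tol` 1e-8, 50 iterations max) of affection on dosage with
an intercept, optional principal components, and — for X SNPs in
mixed-sex cohorts — sex as a covariate. Fits with `|β| > 20` or
non-convergence are flagged and dropped from the meta-analysis.
Principal components are the top eigenvectors of the standardized
autosomal genotype covariance, sign-fixed by making each vector's
largest-magnitude loading positive.

Effects are always reported for the minor allele as observed in the
analysis cohort, the orientation the sign tests assume.

## Meta-analysis and heterogeneity

Inverse-variance fixed effects; Cochran's Q across the contributing
strata with k−1 df (1 df for male vs female). Benjamini–Hochberg
q-values come from statsmodels and are checked in the tests against a
literal step-up enumeration. LD clumping is greedy by ascending p
(ties by chromosome, position, id) with defaults r² > 0.2 within 500 kb
— the clumping tool's defaults are not published, so these are exposed
in `RunConfig` and logged. The binomial sign test is two-sided by the
sum-of-smaller-probabilities convention (scipy's `binomtest`).

## Sex permutation

Units are whole trio families (labelled by proband sex) and individual
case-control subjects. Strata are genotyping batch × design, with
case-control individuals further stratified by case/control status: the
purpose of the construction is to hold power fixed, and permuting cases
and controls into a common pool would let the case:control ratio drift
between permutations. Within each stratum exactly the true number of
males is drawn without replacement into the pseudo-male set per
permutation. Principal components are computed once on the full cohort
and not recomputed per permutation — sex permutation does not alter
genotypes, so the genotype covariance is unchanged.

The enrichment statistic is the fraction of SNPs (within the stated
scope: autosomes, one chromosome, X, or a SNP set) with BH `q < 0.8`,
q-values recomputed within the scope. The empirical p is the plain
proportion of permuted statistics at least as extreme as the observed
one, one-sided in the direction of the tested hypothesis; the
`(r+1)/(n+1)` variant is available by flag since a plain 0/100 is
otherwise reportable as zero.

## Heritability, spike-in, BLUP

The GRM is `A = WW′/m` over autosomal, polymorphic SNPs with missing
dosages mean-imputed. Relatedness filtering removes, greedily and
deterministically, one member of each pair with off-diagonal > 0.1 —
a GRM-based proxy for the IBD-based PI_HAT rule, adequate for simulated
unrelated/duplicate/parent-offspring structure.

REML for `y = Xb + g + e` is computed in the eigenbasis of the
covariate-projected GRM: with `K` an orthonormal basis of the complement
of col(X) and `K′AK = U·diag(d)·U′`, the restricted log-likelihood
separates into independent terms in `λᵢ = V_g dᵢ + V_e`. The likelihood
is maximized directly (Nelder–Mead from three starting fractions of the
phenotypic variance) rather than by average-information iterations — the
objective is 2-dimensional and each evaluation is O(n) after one
decomposition, so direct maximization is simpler and equally exact.
Estimates are unconstrained: `V_g` may go negative and `h²` may leave
[0,1], which the spike-in correlation analysis requires (clamping would
bias the trend). Standard errors come from the analytic Fisher
information (the average-information matrix) at the optimum with a delta
method step for `h²`. Non-convergence is flagged, and flagged sets are
recorded as missing in series analyses rather than dropped silently.

A note on an invariance that does *not* hold exactly: adding a covariate
orthogonal to the phenotype, the genotypes and the intercept still
changes the restricted degrees of freedom by one and shifts the REML
optimum by O(V_p/n); the tests assert that bound rather than machine
precision.

The spike-in series adds proband/pseudo-control pairs in nested steps of
10 (final step partial), refits REML per set, and reports Spearman's
rank correlation between pairs added and `h²` over converged sets; 953
pairs yield 97 sets including the base.

BLUP: `ĝ = V_g A V⁻¹ỹ` with GLS-residualized `ỹ`, transformed to SNP
solutions `u = W′A⁺ĝ/m` (pseudo-inverse so rank-deficient GRMs, m < n,
remain defined); `Wu = ĝ` on the training set, and `u` equals ridge
regression with penalty `m·V_e/V_g` — both are test invariants. Risk
scores standardize target dosages with the *training* allele
frequencies; missing SNPs contribute zero and are counted, and fewer
than 50% shared SNPs is a hard error. Group comparisons use Welch's
t-test.

## Gene sets and pleiotropy

Gene windows are ±5 kb around 1-based inclusive intervals (BED input is
converted on read). Length-matched null sets draw, per gene of interest,
one gene uniformly from the 100 pool genes nearest in length (ties by id;
without replacement within a permuted set). AH SNPs are selected at
sex-difference `P < 10⁻³` from the stratified summary statistics using
the two-sample z-test `z = (β_m − β_f)/√(se_m² + se_f²)` — algebraically
identical to two-stratum Cochran's Q (asserted to 1e-10 in tests).
Association-matched null lists draw from the 100 pool SNPs nearest in
combined-sex trait p, excluding the selected AH SNPs (exclusion of
selected-only is the default; a flag widens it). SC gene scores average
per-panel Pearson correlations with a sex-linked module's first
principal component via Fisher's z, weighted by panel sample size, and
classify at |r̄| > 0.3.

## Power

TDT power: under a multiplicative per-allele relative risk γ the joint
distribution of parental and child genotypes conditional on an affected
child is proportional to `HWE(g_f)·HWE(g_m)·Mendel(g_c|g_f,g_m)·γ^{g_c}`
(prevalence cancels); the heterozygous-parent transmission probability is
`t = γ/(1+γ)` and the expected informative transmissions `N` follow from
the enumeration. The statistic is a scaled non-central chi-square:
power = `ncx2.sf(c/v, 1, N(2t−1)²/v)` with `v = 4t(1−t)` the binomial
variance per transmission and `c` the chi-square critical value. A
simulation mode draws trios from the same conditional distribution and
pushes them through the transmission test; analytic and simulated power
agree within Monte-Carlo error across a (γ, MAF) grid. At the study
design point (2,000 trios, γ = 1.35, MAF 0.30, α = 5×10⁻⁸) the analytic
power is 80.3%.

t-test power uses the non-central t with ncp `d·√(n/2)` and 2n−2 df;
at n = 953 per group and d = 0.13 it is 81.0%.

## Problem sizes used in the test suite

Simulation-backed tests run at deliberately modest sizes chosen so each
check retains its statistical meaning: calibration scans use 2,000 SNPs
× 2,000 trios + 1,000 case-control subjects; REML recovery uses
n = 2,000, m = 1,000 (3-SE tolerance from the analytic information);
BLUP scoring trains on 3,000 subjects and scores 500 + 500 held-out
pairs per sex; the qualitative-reproduction suites run 50 replicates
with 50 permutations over 200–2,000-SNP panels. Empirical-p calibration
uses 19–20 permutations with the add-one estimator, whose null
distribution is exactly uniform on a known grid.

## Known limitations

- No LD-aware simulation: clumping is exercised on engineered correlated
  pairs, not realistic haplotype structure.
- Logistic regression, not mixed models, for case-control association;
  population structure is handled only through principal components.
- Observed-scale heritability only; no liability-scale transformation and
  no ascertainment correction (the analyses compare like with like, so
  the scale cancels from the comparisons).
- PED files carry no allele-order metadata; on read, A1 is the
  alphabetically first allele observed at each SNP.
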
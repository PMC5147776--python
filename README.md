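# sexgwas

Sex-stratified GWAS inference for disorders with sex-biased prevalence,
built around the analysis chain used to dissect sexual dimorphism in
autism spectrum disorder: family-based and case-control association,
power-matched sex-permutation nulls, observed-scale SNP heritability with
stepwise spike-in, BLUP polygenic risk scoring, and permutation-based
gene-set/pleiotropy enrichment — exercised end-to-end on synthetic
cohorts ascertained under a sex-specific liability-threshold model.

## The scientific problem

Under a liability-threshold model, disease occurs when a latent liability
`L = g + e` (polygenic value `g` with variance `h²`, Gaussian residual
`e`) exceeds a threshold `T`. A higher female threshold
(`T_f > T_m`) produces male-biased prevalence and predicts that affected
females carry **more** polygenic load than affected males. Testing that
prediction — and the alternatives of X-linked risk, autosomal
gene-by-sex interaction, and pleiotropy with secondary sex
characteristics — requires comparing male- and female-specific datasets
of very different sizes. The central device is the **power-matched sex
permutation**: sex labels are permuted within genotyping batch × study
design at counts matched to the true male/female proband counts, so every
permuted "female" dataset has exactly the power of the real one, and any
statistic of the real dataset can be referred to its permuted
distribution for an empirical *P*.

Core statistics, in the field's standard notation:

- **TDT** — `b`/`c` transmissions/non-transmissions of the minor allele
  from heterozygous parents; `(b−c)²/(b+c) ~ χ²₁`, `β = ln(b/c)`,
  `se = √(1/b + 1/c)`. On the X, hemizygous fathers are never
  informative; nothing else changes.
- **Fixed-effects meta-analysis** — `β = Σwᵢβᵢ/Σwᵢ`, `wᵢ = 1/seᵢ²`;
  sex heterogeneity by Cochran's `Q = Σwᵢ(βᵢ − β̄)² ~ χ²_{k−1}`.
- **Enrichment metric** — the fraction of SNPs with Benjamini–Hochberg
  `q < 0.8` (a comparison metric against permuted datasets, not a
  significance claim).
- **GREML / BLUP** — `y = Xb + g + e`, `g ~ (0, A·V_g)` with GRM
  `A = WW′/m`; unconstrained REML for observed-scale
  `h² = V_g/(V_g+V_e)`; BLUP individual values
  `ĝ = V_g A V⁻¹ ỹ` transformed to SNP effects `u = W′A⁺ĝ/m` for
  out-of-sample risk scores.
- **Matched permutation nulls** — length-matched gene sets (±5 kb
  windows) and association-matched SNP lists for anthropometric-
  heterogeneous (AH) SNPs, so enrichment is tested against sets with the
  same footprint and the same trait-association profile.

## Layout

- `src/sexgwas/` — the library: `simulate` (liability-threshold cohort
  generator), `io` (PLINK BED/BIM/FAM and PED/MAP with metadata sidecar),
  `assoc` (TDT, logistic, X coding, PCs), `meta` (meta-analysis, Q, BH,
  clumping, sign test), `permutation` (sex-permutation nulls),
  `heritability` (GRM, REML, spike-in, BLUP, risk scores), `genesets`,
  `power`.
- `analysis/01…06_*.py` — numbered drivers that run the full pipeline on
  a simulated study-style cohort and write tables under `results/`.
- `docs/methods.md` — model, parameter and design documentation.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/06_power.py
```

prints (numbers produced by the code):

```
cohort: 4200 individuals x 962 SNPs -> results/data/cohort.bed/.bim/.fam
  trios: 1200 probands (16% female)
...
TDT, 2,000 trios, GRR 1.35, MAF 0.30, alpha 5e-8: power 80.3% analytic (80.4% by simulation)
t-test, 953 per group, d = 0.13, alpha 0.05: power 81.0%
```

The first block writes the simulated study cohort (male-biased trios plus
a case-control arm, shared and male-limited X risk SNPs, higher female
threshold). The power lines reproduce the study-design calculations: a
trio cohort of 2,000 affected children gives ~80% power at genome-wide
significance for a per-allele relative risk of 1.35 at a common allele,
and 953 case/pseudo-control pairs give ~80% power to detect a 0.13 SD
polygenic-score difference. Scripts 02–05 then run association,
sex-permutation enrichment, heritability/BLUP, and gene-set analyses on
the simulated cohort.

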
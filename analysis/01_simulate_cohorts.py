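"""Simulate the study-style cohorts every later step consumes.

Builds a male-biased trio cohort plus a smaller case-control cohort under a
liability-threshold architecture with a higher female threshold, writes
them as PLINK filesets with metadata sidecars, and writes sex-stratified
anthropometric summary statistics and expression panels.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

from pathlib import Path

import numpy as np

import sexgwas as sg
from sexgwas.simulate import ArchitectureSpec, CausalSet

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2024

# architecture: 900 autosomal + 60 X SNPs; 120 shared-effect risk SNPs and
# 20 male-limited X SNPs; female threshold 0.4 SD above the male one,
# roughly matching a 4-5x male-biased prevalence at these thresholds
auto_idx = tuple(range(0, 600, 5))
x_idx = tuple(range(900, 920))
spec = ArchitectureSpec(
    n_snps_by_chrom={**{str(c): 41 for c in range(1, 23)}, "X": 60},
    causal_sets=(
        CausalSet(auto_idx, tuple([1.0] * 120), tuple([1.0] * 120)),
        CausalSet(x_idx, tuple([1.0] * 20), tuple([0.0] * 20)),
    ),
    h2_liability=0.4,
    threshold_male=1.0,
    threshold_female=1.4,
    seed=SEED,
)

# 16% female probands, as in the assembled trio datasets
trios = sg.simulate_trios(spec, 1_200, 0.16, batches=("B1", "B2", "B3"))
pop = sg.simulate_population(spec, 600, sex_ratio=0.4, batch="B4")
rng = np.random.default_rng(SEED)
case = rng.permutation(pop.n) < 300
pop.meta.loc[case, "role"] = "case"
pop.meta.loc[case, "affection"] = 2
cohort = trios.concat(pop)

sg.write_plink(cohort, OUT / "cohort")
print(f"cohort: {cohort.n} individuals x {cohort.m} SNPs -> {OUT}/cohort.bed/.bim/.fam")
pro = cohort.meta[cohort.meta["role"] == "proband"]
print(f"  trios: {len(pro)} probands ({(pro['sex'] == 'female').mean():.0%} female)")

sumstats = sg.simulate_anthro_sumstats(5_000, 0.05, seed=SEED)
sumstats.to_csv(OUT / "anthro_sumstats.tsv", sep="\t", index=False)
print(f"anthropometric summary statistics: {sumstats['snp'].nunique()} SNPs x "
      f"{sumstats['trait'].nunique()} traits -> {OUT}/anthro_sumstats.tsv")

panels = sg.simulate_expression_panels(1_000, (40, 60, 80), 0.08, seed=SEED)
for p in panels.panels:
    p.expr.to_csv(OUT / f"expr_{p.name}.tsv", sep="\t")
print(f"expression panels: {len(panels.panels)} panels of 1,000 genes "
      f"({len(panels.biased_genes)} sex-biased) -> {OUT}/expr_*.tsv")
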
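"""Gene-set and pleiotropy enrichment with matched permutation nulls.

Defines gene windows (+/- 5 kb) on a synthetic gene annotation, builds
length-matched null gene sets, selects anthropometric-heterogeneous (AH)
SNPs from the sex-stratified summary statistics with p-matched null SNP
lists, computes FDR-threshold enrichment for each against the disease
scan, and classifies sex-correlated genes from the expression panels.

Run after 01 and 02:  python analysis/05_genesets.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sexgwas as sg
from sexgwas.genesets import (
    ah_select,
    gene_set_snps,
    length_matched_null_sets,
    matched_assoc_null_sets,
    sc_gene_scores,
    set_enrichment,
    snps_in_gene_windows,
)
from sexgwas.simulate import ExpressionPanel

OUT = Path("results")
cfg = sg.RunConfig(seed=2024)
rng = np.random.default_rng(cfg.seed)

records = sg.read_association(OUT / "assoc_female.tsv")
cohort = sg.read_genotypes("results/data/cohort")

# synthetic annotation: 120 genes tiled over the autosomes
auto = cohort.snp_info[cohort.snp_info["chrom"] != "X"]
genes = []
for i in range(120):
    row = auto.sample(1, random_state=int(rng.integers(2**31))).iloc[0]
    length = int(rng.integers(5_000, 80_000))
    genes.append((f"gene{i:03d}", row["chrom"], max(1, row["pos"] - length // 2),
                  row["pos"] + length // 2))
genes = pd.DataFrame(genes, columns=["gene", "chrom", "start", "end"])
windows = snps_in_gene_windows(genes, cohort.snp_info, flank=cfg.gene_flank_bp)

target = genes["gene"][:20].tolist()  # a 20-gene set of interest
null_sets = length_matched_null_sets(
    genes[genes["gene"].isin(target)], genes, n_perm=cfg.n_permutations, seed=cfg.seed
)
res = set_enrichment(
    gene_set_snps(windows, target),
    [gene_set_snps(windows, s) for s in null_sets],
    records, q_threshold=cfg.enrichment_q,
)
print(f"gene set ({len(target)} genes): enrichment {res.observed_fraction:.3f}, "
      f"empirical P = {res.empirical_p:.2f} vs {len(null_sets)} length-matched sets")

sumstats = pd.read_csv("results/data/anthro_sumstats.tsv", sep="\t")
ah = ah_select(sumstats, cfg.ah_p_cut)
nulls = matched_assoc_null_sets(ah, sumstats, n_perm=cfg.n_permutations, seed=cfg.seed)
print(f"AH SNPs: {len(ah)} selected at sex-difference P < {cfg.ah_p_cut}")

panels = []
for path in sorted(Path("results/data").glob("expr_panel*.tsv")):
    expr = pd.read_csv(path, sep="\t", index_col=0)
    ns = expr.shape[1]
    sex = np.array(["male"] * (ns // 2) + ["female"] * (ns - ns // 2))
    score = np.where(sex == "male", 1.0, -1.0)
    panels.append(ExpressionPanel(path.stem, expr, sex, score))
sc = sc_gene_scores(panels)
sc.to_csv(OUT / "sc_gene_scores.tsv", sep="\t", index=False)
n_pos = (sc["classification"] == "male-correlated").sum()
n_neg = (sc["classification"] == "anti-correlated").sum()
print(f"SC genes: {n_pos} male-correlated, {n_neg} anti-correlated "
      f"(|r| > 0.3) -> {OUT}/sc_gene_scores.tsv")
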
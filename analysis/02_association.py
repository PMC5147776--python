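"""Sex-stratified association scans and the fixed-effects meta-analysis.

Reads the simulated cohort, applies the common-variant filters, runs the
TDT on trios and PC-adjusted logistic regression on the case-control
subset, meta-analyzes per sex and combined, and reports genome-wide
significant loci and top sex-heterogeneous SNPs.

Run after 01:  python analysis/02_association.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sexgwas as sg
from sexgwas.meta import cochran_q, bh_qvalues
from sexgwas.permutation import sex_specific_scan, true_sex_cohort

OUT = Path("results")
cfg = sg.RunConfig(seed=2024)

cohort = sg.read_genotypes("results/data/cohort")
cohort = sg.apply_common_filters(cohort, cfg.maf_floor, cfg.call_rate_floor)
print(f"after filters: {cohort.m} SNPs, {cohort.n} individuals")

pcs = sg.pca_covariates(cohort, k=cfg.n_pcs)
pcs_by_iid = pd.DataFrame(pcs, index=cohort.meta["iid"])

scans = {}
for name, table in [
    ("combined", cohort),
    ("male", true_sex_cohort(cohort, "male")),
    ("female", true_sex_cohort(cohort, "female")),
]:
    scans[name] = sex_specific_scan(table, covariates=pcs_by_iid)
    scans[name]["q"] = bh_qvalues(scans[name]["p_meta"].to_numpy())
    sg.write_association(scans[name], OUT / f"assoc_{name}.tsv")
    hits = scans[name][scans[name]["p_meta"] <= cfg.gwas_alpha]
    print(f"{name}: {len(hits)} genome-wide significant SNPs "
          f"(min p = {scans[name]['p_meta'].min():.2e})")

merged = scans["male"].merge(scans["female"], on="snp", suffixes=("_m", "_f"))
Q, p_Q = cochran_q(
    merged["beta_meta_m"].to_numpy(), merged["se_meta_m"].to_numpy(),
    merged["beta_meta_f"].to_numpy(), merged["se_meta_f"].to_numpy(),
)
het = pd.DataFrame({"snp": merged["snp"], "Q": Q, "p_Q": p_Q}).sort_values("p_Q")
sg.write_association(het, OUT / "sex_heterogeneity.tsv")
print("top sex-heterogeneous SNPs (Cochran's Q):")
print(het.head(5).to_string(index=False))
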
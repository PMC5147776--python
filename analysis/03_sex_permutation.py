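"""Power-matched sex-permutation null: FDR-threshold enrichment per sex.

Permutes sex labels within batch x design at true per-stratum counts,
recomputes the association pipeline per permutation (one scan per
pseudo-sex cohort, reused for every scope), and reports the fraction of
SNPs passing q < 0.8 for the true male and female datasets against their
permuted distributions (autosomes and X separately), plus the top-20 X
heterogeneity excess.

Run after 01:  python analysis/03_sex_permutation.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sexgwas as sg
from sexgwas.meta import bh_qvalues
from sexgwas.permutation import (
    apply_plan,
    empirical_p,
    enrichment_fraction,
    make_permutation_plans,
    sex_specific_scan,
    top_het_fraction,
    true_sex_cohort,
)

OUT = Path("results")
cfg = sg.RunConfig(seed=2024)
N_PERM = 50  # half the study's 100 to keep this driver quick; configurable

cohort = sg.read_genotypes("results/data/cohort")
cohort = sg.apply_common_filters(cohort, cfg.maf_floor, cfg.call_rate_floor)
plans = make_permutation_plans(cohort, n_perm=N_PERM, seed=cfg.seed)
scopes = {"autosomes": cohort.autosome_mask, "X": cohort.x_mask}
scope_snps = {k: set(cohort.snp_info.loc[m, "snp"]) for k, m in scopes.items()}


def summarize(scans):
    """Per-scope enrichment fractions per sex, plus male top-20 X het."""
    out = {}
    for sex in ("male", "female"):
        p = scans[sex].set_index("snp")["p_meta"]
        for scope, ids in scope_snps.items():
            out[(sex, scope)] = enrichment_fraction(
                bh_qvalues(p.reindex(p.index.intersection(ids)).to_numpy()),
                cfg.enrichment_q,
            )
    out[("male", "X-top20-het")] = top_het_fraction(
        scans, cohort, "male", k=cfg.top_k_x, q_level=cfg.x_top_q_male,
        r2_max=cfg.clump_r2, window_bp=cfg.clump_window_bp,
        scope_mask=cohort.x_mask,
    )
    return out


observed = summarize(
    {s: sex_specific_scan(true_sex_cohort(cohort, s)) for s in ("male", "female")}
)
permuted = {key: [] for key in observed}
for i in range(N_PERM):
    scans = {s: sex_specific_scan(apply_plan(cohort, plans, i, s)) for s in ("male", "female")}
    for key, val in summarize(scans).items():
        permuted[key].append(val)

rows = []
for (sex, scope), obs in observed.items():
    perm = np.asarray(permuted[(sex, scope)])
    p_emp = empirical_p(obs, perm, "greater")
    rows.append((sex, scope, obs, perm.mean(), p_emp))
    print(f"{sex}/{scope}: observed {obs:.3f}, permuted mean {perm.mean():.3f}, "
          f"empirical P = {p_emp:.2f}")

pd.DataFrame(
    rows, columns=["sex", "scope", "observed", "permuted_mean", "empirical_p"]
).to_csv(OUT / "sex_permutation_enrichment.tsv", sep="\t", index=False)
print(f"-> {OUT}/sex_permutation_enrichment.tsv")
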
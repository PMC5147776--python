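"""Genetic load: observed-scale heritability, spike-in series, BLUP scores.

Builds proband/pseudo-control pairs from the trio cohort, filters related
individuals on GRM off-diagonals, estimates observed-scale h2 by
unconstrained REML, runs the female spike-in series, trains BLUP SNP
effects on a male discovery set and scores held-out male and female pairs.

Run after 01:  python analysis/04_heritability_blup.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

import sexgwas as sg
from sexgwas.heritability import (
    blup_snp_effects,
    compute_grm,
    grm_relatedness_filter,
    group_compare,
    reml_h2,
    risk_scores,
    spike_in_series,
)

OUT = Path("results")
cfg = sg.RunConfig(seed=2024)

cohort = sg.read_genotypes("results/data/cohort")
trios = cohort.subset_individuals((cohort.meta["design"] == "trio").to_numpy())
pairs_tbl = sg.make_pseudo_controls(trios)

grm_all = compute_grm(pairs_tbl)
# the study's 0.1 cutoff assumes genome-wide SNP counts; at this panel size
# GRM off-diagonal noise is ~1/sqrt(m), so keep the cutoff at >=5 noise SD
cutoff = max(cfg.relatedness_cutoff, 5.0 / np.sqrt(grm_all.m))
kept = set(grm_relatedness_filter(grm_all, cutoff))
print(f"relatedness filter (cutoff {cutoff:.2f}): kept {len(kept)} of {pairs_tbl.n}")

meta = pairs_tbl.meta
fam_sex = meta[meta["role"] == "proband"].set_index("family")["sex"]
male_fams = [f for f in fam_sex.index if fam_sex[f] == "male"
             and {f + "_c", f + "_pc"} <= kept]
female_fams = [f for f in fam_sex.index if fam_sex[f] == "female"
               and {f + "_c", f + "_pc"} <= kept]
n_f = len(female_fams)
base_fams, test_fams = male_fams[: len(male_fams) - n_f], male_fams[len(male_fams) - n_f:]

ids = lambda fams: [i for f in fams for i in (f + "_c", f + "_pc")]
base_ids = ids(base_fams)

# female spike-in series and the matched male comparison series
for label, fams in [("female", female_fams), ("male", test_fams)]:
    pairs = [(f + "_c", f + "_pc") for f in fams]
    sets, rho, p = spike_in_series(
        pairs_tbl, base_ids, pairs, cfg.pairs_per_step, grm=grm_all
    )
    sets.to_csv(OUT / f"spikein_{label}.tsv", sep="\t", index=False)
    print(f"{label} spike-in: {len(sets)} nested sets, "
          f"Spearman rho = {rho:.3f} (P = {p:.3g})")

# BLUP on the male discovery set; score held-out male and female pairs
train = pairs_tbl.subset_individuals(base_ids)
grm = compute_grm(train)
y = (train.meta["affection"] == 2).to_numpy(float)
est = reml_h2(grm, y)
print(f"male discovery h2_obs = {est.h2_obs:.3f} (se {est.se_h2:.3f}, "
      f"n={est.n}, m={est.m})")
eff = blup_snp_effects(grm, train, y, est)
eff.table.to_csv(OUT / "blup_snp_effects.tsv", sep="\t", index=False)

rows = []
for label, fams in [("male", test_fams), ("female", female_fams)]:
    target = pairs_tbl.subset_individuals(ids(fams))
    scores = risk_scores(eff, target)
    d, t, p = group_compare(scores, (scores["affection"] == 2).to_numpy())
    rows.append((label, len(fams), d, t, p))
    print(f"{label} test set ({len(fams)} pairs): case - pseudo-control "
          f"score difference {d:.3f} (t = {t:.2f}, P = {p:.2e})")
pd.DataFrame(rows, columns=["sex", "n_pairs", "mean_diff", "t", "p"]).to_csv(
    OUT / "risk_score_tests.tsv", sep="\t", index=False
)
print(f"-> {OUT}/spikein_*.tsv, blup_snp_effects.tsv, risk_score_tests.tsv")
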
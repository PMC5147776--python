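"""Study-design power: the TDT at genome-wide alpha and the risk-score t-test.

Prints the two design points the study reports -- ~80% TDT power for a
genotype relative risk of 1.35 (MAF 0.30, 2,000 trios, alpha 5e-8) and
~80% t-test power for a 0.13 SD score difference at 953 per group -- and
writes a power grid over relative risk and sample size.

Run:  python analysis/06_power.py
"""

from pathlib import Path

import pandas as pd

from sexgwas.power import PowerQuery, tdt_power, ttest_power

OUT = Path("results")
OUT.mkdir(exist_ok=True)

p_tdt = tdt_power(PowerQuery("tdt", 2_000, 1.35, maf=0.30, alpha=5e-8))
p_sim = tdt_power(
    PowerQuery("tdt", 2_000, 1.35, maf=0.30, alpha=5e-8,
               method="simulation", n_sims=100_000, seed=1)
)
print(f"TDT, 2,000 trios, GRR 1.35, MAF 0.30, alpha 5e-8: "
      f"power {p_tdt:.1%} analytic ({p_sim:.1%} by simulation)")

p_t = ttest_power(PowerQuery("ttest", 953, 0.13, alpha=0.05))
print(f"t-test, 953 per group, d = 0.13, alpha 0.05: power {p_t:.1%}")

rows = []
for n in (500, 1_000, 2_000, 4_000):
    for grr in (1.1, 1.2, 1.35, 1.5):
        rows.append((n, grr, tdt_power(PowerQuery("tdt", n, grr, maf=0.30, alpha=5e-8))))
grid = pd.DataFrame(rows, columns=["n_trios", "grr", "power"])
grid.to_csv(OUT / "power_grid.tsv", sep="\t", index=False)
print(f"-> {OUT}/power_grid.tsv")
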
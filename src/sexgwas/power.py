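"""Power calculations: TDT under a multiplicative risk model, two-sample t.

TDT power is computed analytically by exact enumeration of the nine
parental mating types.  Under a multiplicative per-allele genotype
relative risk ``grr`` and HWE allele frequency ``p``, the joint
distribution of (father, mother, child) genotypes conditional on an
affected child is proportional to
``HWE(gf) * HWE(gm) * Mendel(gc | gf, gm) * grr**gc`` (disease prevalence
cancels).  From it follow the expected number of heterozygous-parent
transmissions per trio and the transmission probability of the risk
allele from a heterozygous parent, ``t = grr / (1 + grr)``.  The TDT
statistic is then a scaled non-central chi-square: with ``N`` expected
informative transmissions, ``(b - c)^2/(b + c)`` has mean parameter
``N (2t - 1)^2`` and binomial variance ``4 t (1 - t)`` per transmission,
so power is the tail of a non-central chi-square with both the critical
value and the non-centrality rescaled by that variance.

A simulation mode draws trios from the same conditional distribution and
pushes them through the test, as a cross-check of the analytics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import substream


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of one power evaluation.

    ``design`` selects the calculation: 'tdt' (n = trios, effect = genotype
    relative risk, needs ``maf``) or 'ttest' (n = per group, effect =
    standardized mean difference d).
    """

    design: str
    n: int
    effect: float
    maf: float = 0.3
    alpha: float = 5e-8
    method: str = "analytic"
    n_sims: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.design not in ("tdt", "ttest"):
            raise ValueError("design must be 'tdt' or 'ttest'")
        if self.design == "tdt" and self.effect <= 0:
            raise ValueError("genotype relative risk must be positive")
        if self.design == "ttest" and self.effect < 0:
            raise ValueError("standardized difference must be non-negative")


def _mating_table(p: float, grr: float):
    """Joint P(gf, gm, gc | affected child) over the 9 mating types.

    Returns (prob[gf, gm, gc], hwe) as a 3x3x3 array.
    """
    q = 1.0 - p
    hwe = np.array([q**2, 2 * p * q, p**2])  # genotype = risk-allele count

    def transmit(g):  # P(transmit risk allele | parent genotype)
        return {0: 0.0, 1: 0.5, 2: 1.0}[g]

    joint = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            tf, tm = transmit(gf), transmit(gm)
            child = {
                0: (1 - tf) * (1 - tm),
                1: tf * (1 - tm) + (1 - tf) * tm,
                2: tf * tm,
            }
            for gc, pc in child.items():
                joint[gf, gm, gc] = hwe[gf] * hwe[gm] * pc * grr**gc
    return joint / joint.sum(), hwe


def tdt_expectations(p: float, grr: float):
    """(expected het-parent transmissions per trio, risk-transmission prob).

    Both quantities are conditional on an affected child under the
    multiplicative model; the transmission probability equals
    ``grr / (1 + grr)`` analytically and is recovered here from the
    enumeration as a consistency guarantee.
    """
    joint, _ = _mating_table(p, grr)
    e_het = 0.0
    e_risk_from_het = 0.0
    for gf in range(3):
        for gm in range(3):
            for gc in range(3):
                pr = joint[gf, gm, gc]
                if pr == 0:
                    continue
                n_het = (gf == 1) + (gm == 1)
                # risk transmissions from het parents: child risk copies minus
                # the deterministic contribution of homozygous-risk parents
                t_het = gc - (gf == 2) - (gm == 2)
                e_het += pr * n_het
                e_risk_from_het += pr * t_het
    t = e_risk_from_het / e_het if e_het > 0 else 0.5
    return e_het, t


def tdt_power(q: PowerQuery) -> float:
    """Power of the TDT at significance ``alpha`` (two-sided, 1-df)."""
    if q.design != "tdt":
        raise ValueError("query design must be 'tdt'")
    e_het, t = tdt_expectations(q.maf, q.effect)
    if q.method == "analytic":
        N = q.n * e_het
        crit = stats.chi2.isf(q.alpha, df=1)
        var = 4.0 * t * (1.0 - t)
        if var <= 0:
            return 1.0
        ncp = N * (2.0 * t - 1.0) ** 2 / var
        return float(stats.ncx2.sf(crit / var, df=1, nc=ncp))
    if q.method == "simulation":
        return _tdt_power_sim(q)
    raise ValueError("method must be 'analytic' or 'simulation'")


def _tdt_power_sim(q: PowerQuery) -> float:
    """Monte-Carlo power: trios drawn from the conditional mating-type
    distribution, pushed through the transmission-count test."""
    rng = substream(q.seed, "tdt-power-sim")
    joint, _ = _mating_table(q.maf, q.effect)
    # per-trio distribution of (n het parents, risk transmissions from them)
    outcomes = {}
    for gf in range(3):
        for gm in range(3):
            for gc in range(3):
                pr = joint[gf, gm, gc]
                if pr <= 0:
                    continue
                key = ((gf == 1) + (gm == 1), gc - (gf == 2) - (gm == 2))
                outcomes[key] = outcomes.get(key, 0.0) + pr
    keys = list(outcomes)
    probs = np.array([outcomes[k] for k in keys])
    n_het = np.array([k[0] for k in keys])
    t_risk = np.array([k[1] for k in keys])
    crit = stats.chi2.isf(q.alpha, df=1)

    reject = 0
    chunk = 2_000
    done = 0
    while done < q.n_sims:
        c = min(chunk, q.n_sims - done)
        counts = rng.multinomial(q.n, probs, size=c)
        b = counts @ t_risk
        n = counts @ n_het
        # residual binomial noise within ambiguous double-het trios is already
        # captured: t_risk is the realized transmission count per mating type,
        # but double-het types need an extra draw to split b between parents.
        # Transmission counts, not per-parent attribution, enter the statistic,
        # so no extra randomness is required.
        cminus = n - b
        with np.errstate(invalid="ignore"):
            statv = (b - cminus) ** 2 / np.maximum(n, 1)
        reject += int((statv > crit).sum())
        done += c
    return reject / q.n_sims


def ttest_power(q: PowerQuery) -> float:
    """Two-sided two-sample t-test power from the non-central t.

    Non-centrality ``d * sqrt(n/2)`` with ``2n - 2`` degrees of freedom.
    """
    if q.design != "ttest":
        raise ValueError("query design must be 'ttest'")
    if q.n < 2:
        raise ValueError("need at least 2 per group")
    df = 2 * q.n - 2
    ncp = q.effect * np.sqrt(q.n / 2.0)
    tcrit = stats.t.isf(q.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
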
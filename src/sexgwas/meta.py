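"""Fixed-effects meta-analysis, sex heterogeneity, FDR, clumping, sign tests.

Strata (trio vs case-control, or male vs female) are combined by
inverse-variance weighting: ``beta = sum(w_i b_i) / sum(w_i)`` with
``w_i = 1/se_i^2`` and ``se = 1/sqrt(sum w_i)``.  Sex heterogeneity is
Cochran's Q, the weighted sum of squared deviations of the stratum
estimates from the combined estimate, chi-square with k-1 df (1 df for
male vs female).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class MetaRecord:
    snp: str
    beta_meta: float
    se_meta: float
    p_meta: float
    betas: tuple = field(default_factory=tuple)
    ses: tuple = field(default_factory=tuple)
    Q: float | None = None
    p_Q: float | None = None


def ivw_meta(betas, ses):
    """Inverse-variance fixed-effects combination.

    Accepts scalars-per-stratum (1-D) or per-SNP arrays stacked along the
    first axis (k x m); returns (beta, se, p) with two-sided normal p.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    scalar = b.ndim == 1
    if scalar:
        b = b[:, None]
        s = s[:, None]
    w = 1.0 / s**2
    beta = (w * b).sum(axis=0) / w.sum(axis=0)
    se = 1.0 / np.sqrt(w.sum(axis=0))
    p = 2 * stats.norm.sf(np.abs(beta / se))
    if scalar:
        return float(beta[0]), float(se[0]), float(p[0])
    return beta, se, p


def fixed_effects_meta(records) -> MetaRecord:
    """Combine a list of AssociationRecord-like objects for one SNP.

    Records with non-finite standard errors (flagged fits) are dropped; a
    single surviving record passes through unchanged with Q undefined.
    """
    usable = [r for r in records if np.isfinite(r.se) and r.se > 0 and getattr(r, "converged", True)]
    if not usable:
        raise ValueError("no usable stratum records")
    betas = [r.beta for r in usable]
    ses = [r.se for r in usable]
    if len(usable) == 1:
        r = usable[0]
        return MetaRecord(r.snp, r.beta, r.se, r.p, (r.beta,), (r.se,))
    beta, se, p = ivw_meta(betas, ses)
    Q, p_Q = cochran_q_k(betas, ses)
    return MetaRecord(usable[0].snp, beta, se, p, tuple(betas), tuple(ses), Q, p_Q)


def cochran_q_k(betas, ses):
    """Generic k-stratum Cochran's Q with k-1 df."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    w = 1.0 / s**2
    mean = (w * b).sum() / w.sum()
    Q = float((w * (b - mean) ** 2).sum())
    return Q, float(stats.chi2.sf(Q, df=len(b) - 1))


def cochran_q(beta_m, se_m, beta_f, se_f):
    """Male-vs-female heterogeneity: Q on 1 df.

    Vectorized: scalar or array inputs; returns (Q, p_Q).  Undefined (NaN)
    where either stratum is untestable.
    """
    bm, sm = np.asarray(beta_m, float), np.asarray(se_m, float)
    bf, sf = np.asarray(beta_f, float), np.asarray(se_f, float)
    wm, wf = 1.0 / sm**2, 1.0 / sf**2
    mean = (wm * bm + wf * bf) / (wm + wf)
    Q = wm * (bm - mean) ** 2 + wf * (bf - mean) ** 2
    p = stats.chi2.sf(Q, df=1)
    bad = ~(np.isfinite(bm) & np.isfinite(bf) & np.isfinite(sm) & np.isfinite(sf))
    Q = np.where(bad, np.nan, Q)
    p = np.where(bad, np.nan, p)
    if np.isscalar(beta_m):
        return float(Q), float(p)
    return Q, p


def meta_scan(strata: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-SNP fixed-effects meta-analysis across named strata.

    Each frame needs columns ``snp, beta, se`` (and optionally
    ``converged``); SNPs are merged on id, flagged records dropped
    per-stratum, and SNPs with no usable stratum dropped with a warning.
    Output carries per-stratum betas/ses, the combined estimate, and
    Cochran's Q across the contributing strata.
    """
    frames = []
    for name, df in strata.items():
        sub = df[["snp", "beta", "se"]].copy()
        if "converged" in df.columns:
            sub.loc[~df["converged"].to_numpy(), ["beta", "se"]] = np.nan
        sub.columns = ["snp", f"beta_{name}", f"se_{name}"]
        frames.append(sub)
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on="snp", how="outer")
    names = list(strata.keys())
    B = np.vstack([out[f"beta_{n}"].to_numpy(float) for n in names])
    S = np.vstack([out[f"se_{n}"].to_numpy(float) for n in names])
    ok = np.isfinite(B) & np.isfinite(S) & (S > 0)
    W = np.where(ok, 1.0 / np.where(ok, S, 1.0) ** 2, 0.0)
    wsum = W.sum(axis=0)
    any_ok = wsum > 0
    if (~any_ok).any():
        logger.warning("dropping %d SNPs with no usable stratum", int((~any_ok).sum()))
    beta = np.where(any_ok, (W * np.where(ok, B, 0.0)).sum(axis=0) / np.where(any_ok, wsum, 1.0), np.nan)
    se = np.where(any_ok, 1.0 / np.sqrt(np.where(any_ok, wsum, 1.0)), np.nan)
    p = 2 * stats.norm.sf(np.abs(beta / se))
    Q = (W * (np.where(ok, B, 0.0) - beta[None, :]) ** 2).sum(axis=0)
    k = ok.sum(axis=0)
    p_Q = np.where(k >= 2, stats.chi2.sf(Q, df=np.maximum(k - 1, 1)), np.nan)
    out["beta_meta"] = beta
    out["se_meta"] = se
    out["p_meta"] = p
    out["Q"] = np.where(k >= 2, Q, np.nan)
    out["p_Q"] = p_Q
    return out[any_ok].reset_index(drop=True)


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone non-decreasing in p).

    NaN p-values propagate to NaN q-values without affecting the ranks of
    the finite entries.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def ld_clump(
    records: pd.DataFrame,
    g,
    r2_max: float = 0.2,
    window_bp: int = 500_000,
    k: int | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping: ascending p, absorb neighbors with r^2 > r2_max.

    ``records`` needs columns ``snp, chrom, pos, p``; r^2 is the squared
    Pearson correlation of dosages in ``g`` (mean-imputed).  Ties in p break
    by (chrom, pos, snp).  Returns the first ``k`` index SNPs (all if
    ``k`` is None); warns when fewer than ``k`` independent SNPs exist.
    """
    rec = records.dropna(subset=["p"]).copy()
    rec = rec.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    order = {s: j for j, s in enumerate(g.snp_info["snp"])}
    D = g.dosages.astype(float)
    D = np.where(D < 0, np.nan, D)
    col_mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), col_mean, D)

    index_rows = []
    absorbed: set[str] = set()
    for _, row in rec.iterrows():
        s = row["snp"]
        if s in absorbed or s not in order:
            continue
        index_rows.append(row)
        same = rec[(rec["chrom"] == row["chrom"]) & ((rec["pos"] - row["pos"]).abs() <= window_bp)]
        xi = D[:, order[s]]
        for s2, pos2 in zip(same["snp"], same["pos"]):
            if s2 == s or s2 in absorbed or s2 not in order:
                continue
            xj = D[:, order[s2]]
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(xi, xj)[0, 1]
            if np.isfinite(r) and r**2 > r2_max:
                absorbed.add(s2)
        if k is not None and len(index_rows) >= k:
            break
    out = pd.DataFrame(index_rows).reset_index(drop=True)
    if k is not None and len(out) < k:
        logger.warning("only %d independent SNPs available (requested %d)", len(out), k)
    return out


def sign_test(
    top: pd.DataFrame,
    other: pd.DataFrame,
    expected_fraction: float = 0.5,
):
    """Direction concordance of top SNPs in the other sex.

    ``top`` and ``other`` need columns ``snp, beta`` with effects oriented
    to the minor allele.  Returns ``(fraction_same, p)`` with a two-sided
    exact binomial p against ``expected_fraction`` (in practice the mean
    concordance of sex-permuted runs).  Zero or missing betas drop out of
    the count.
    """
    merged = top[["snp", "beta"]].merge(
        other[["snp", "beta"]], on="snp", suffixes=("_top", "_other")
    )
    b1 = merged["beta_top"].to_numpy(float)
    b2 = merged["beta_other"].to_numpy(float)
    ok = np.isfinite(b1) & np.isfinite(b2) & (b1 != 0) & (b2 != 0)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("sign test: %d SNPs excluded (zero or missing beta)", n_drop)
    same = int((np.sign(b1[ok]) == np.sign(b2[ok])).sum())
    n = int(ok.sum())
    if n == 0:
        return np.nan, np.nan
    res = stats.binomtest(same, n, expected_fraction, alternative="two-sided")
    return same / n, res.pvalue
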
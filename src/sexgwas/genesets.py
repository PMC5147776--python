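"""Gene-set and pleiotropy enrichment with matched permutation nulls.

Two null constructions control for the obvious confounders of set-based
GWAS enrichment:

* length-matched gene permutation -- for each gene of interest one gene is
  drawn from the 100 pool genes closest in length, so permuted sets carry
  the same SNP-count footprint;
* association-matched SNP permutation -- for each anthropometric-
  heterogeneous (AH) SNP one SNP is drawn from the 100 pool SNPs with the
  closest combined-sex trait association p, so permuted lists are equally
  trait-associated but not ascertained for sexual dimorphism.

Sex-correlated (SC) gene scores average per-panel Pearson correlations to
a sex-linked module's first principal component via Fisher's z, weighted
by panel sample size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_qvalues
from .permutation import empirical_p, enrichment_fraction
from ._util import substream

logger = logging.getLogger(__name__)


def snps_in_gene_windows(
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    flank: int = 5_000,
) -> dict[str, list[str]]:
    """SNPs within +/- ``flank`` bp of each gene (1-based inclusive bounds).

    ``genes`` needs columns ``gene, chrom, start, end``; ``snps`` needs
    ``snp, chrom, pos``.  A SNP belongs to a gene iff
    ``start - flank <= pos <= end + flank`` on the same chromosome.
    """
    if genes.empty:
        raise ValueError("empty gene list")
    out: dict[str, list[str]] = {}
    by_chrom = {c: sub for c, sub in snps.groupby("chrom")}
    for _, row in genes.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            out[row["gene"]] = []
            continue
        lo, hi = row["start"] - flank, row["end"] + flank
        hit = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
        out[row["gene"]] = list(hit["snp"])
    return out


def gene_set_snps(window_map: dict[str, list[str]], genes) -> list[str]:
    """De-duplicated union of the windows of a gene set (order-stable)."""
    seen, out = set(), []
    for gene in genes:
        for s in window_map.get(gene, []):
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def length_matched_null_sets(
    target_genes: pd.DataFrame,
    pool: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    n_candidates: int = 100,
) -> list[list[str]]:
    """Length-matched permuted gene sets.

    For each target gene, candidates are the ``n_candidates`` pool genes
    (target ids excluded) with smallest absolute length difference, ties by
    id order; each permutation samples one candidate per target without
    replacement within the permuted set.
    """
    rng = substream(seed, "length-matched-genes")
    pool = pool[~pool["gene"].isin(set(target_genes["gene"]))].copy()
    pool["length"] = pool["end"] - pool["start"] + 1
    pool = pool.sort_values(["length", "gene"]).reset_index(drop=True)
    if len(pool) < n_candidates:
        logger.warning("pool of %d genes smaller than %d candidates", len(pool), n_candidates)
    target = target_genes.copy()
    target["length"] = target["end"] - target["start"] + 1

    candidates = []
    for _, row in target.iterrows():
        diff = (pool["length"] - row["length"]).abs()
        order = np.lexsort((pool["gene"].to_numpy(), diff.to_numpy()))
        candidates.append(pool["gene"].to_numpy()[order[:n_candidates]])

    sets = []
    for _ in range(n_perm):
        chosen: list[str] = []
        used: set[str] = set()
        for cand in candidates:
            free = [c for c in cand if c not in used]
            pickable = free if free else list(cand)
            pick = pickable[rng.integers(len(pickable))]
            used.add(pick)
            chosen.append(pick)
        sets.append(chosen)
    return sets


def sex_difference_p(beta_m, se_m, beta_f, se_f) -> np.ndarray:
    """Two-sample z-test p for a male-female effect difference."""
    z = (np.asarray(beta_m) - np.asarray(beta_f)) / np.sqrt(
        np.asarray(se_m) ** 2 + np.asarray(se_f) ** 2
    )
    return 2 * stats.norm.sf(np.abs(z))


def ah_select(sumstats: pd.DataFrame, p_cut: float = 1e-3) -> list[str]:
    """Anthropometric-heterogeneous SNPs: sex-difference p below ``p_cut``
    in any trait.

    ``sumstats`` is the tidy per-SNP-per-trait frame with columns
    ``snp, trait, beta_m, se_m, beta_f, se_f``.  Rows with a missing sex are
    skipped with a log entry.  Returns the de-duplicated SNP list.
    """
    ss = sumstats.copy()
    ok = np.isfinite(ss["beta_m"]) & np.isfinite(ss["beta_f"])
    if (~ok).any():
        logger.warning("ah_select: skipping %d rows with a missing sex", int((~ok).sum()))
        ss = ss[ok]
    ss["p_diff"] = sex_difference_p(ss["beta_m"], ss["se_m"], ss["beta_f"], ss["se_f"])
    hits = ss.loc[ss["p_diff"] < p_cut, "snp"]
    return list(dict.fromkeys(hits))


def matched_assoc_null_sets(
    target_snps,
    sumstats: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    n_candidates: int = 100,
    match_col: str = "p_all",
) -> list[list[str]]:
    """Association-matched permuted SNP lists.

    For each target SNP, candidates are the ``n_candidates`` pool SNPs with
    the closest combined-sex trait association p (target SNPs excluded from
    the pool, so permuted lists never intersect the AH set); one is sampled
    per permutation, without replacement within a permuted list.
    """
    rng = substream(seed, "assoc-matched-snps")
    target_snps = list(target_snps)
    per_snp = sumstats.groupby("snp", sort=False)[match_col].min()
    target_p = per_snp.reindex(target_snps)
    pool = per_snp.drop(index=[s for s in target_snps if s in per_snp.index])
    pool_snps = pool.index.to_numpy()
    pool_p = pool.to_numpy()

    candidates = []
    for p in target_p.to_numpy():
        diff = np.abs(pool_p - p)
        order = np.lexsort((pool_snps, diff))
        candidates.append(pool_snps[order[:n_candidates]])

    sets = []
    for _ in range(n_perm):
        chosen: list[str] = []
        used: set[str] = set()
        for cand in candidates:
            free = [c for c in cand if c not in used]
            pickable = free if free else list(cand)
            pick = pickable[rng.integers(len(pickable))]
            used.add(pick)
            chosen.append(pick)
        sets.append(chosen)
    return sets


def set_enrichment(
    set_snps,
    null_sets,
    records: pd.DataFrame,
    q_threshold: float = 0.8,
    p_col: str = "p_meta",
):
    """FDR-threshold enrichment of a SNP set against its permuted nulls.

    q-values are recomputed within each set's scope.  Returns an object
    with the observed fraction, the permuted fractions and the empirical p
    (proportion of null sets with fraction >= observed).
    """
    from .permutation import EnrichmentResult

    pmap = records.set_index("snp")[p_col]

    def frac(snps):
        p = pmap.reindex([s for s in snps if s in pmap.index]).to_numpy(float)
        q = bh_qvalues(p)
        return enrichment_fraction(q, q_threshold)

    observed = frac(set_snps)
    permuted = np.array([frac(s) for s in null_sets])
    p_emp = empirical_p(observed, permuted, "greater")
    return EnrichmentResult(observed, permuted, p_emp, q_threshold, "SNP set")


def sc_gene_scores(panels, module_scores=None, r_cut: float = 0.3) -> pd.DataFrame:
    """Sex-correlated gene classification from expression panels.

    Per panel, each gene's Pearson r against the module first principal
    component is Fisher-transformed (atanh), averaged across panels with
    sample-size weights, and back-transformed.  Genes with mean r above
    ``r_cut`` are 'male-correlated', below ``-r_cut`` 'anti-correlated',
    otherwise unclassified.  Constant-expression genes are dropped with a
    log entry.

    ``panels`` is an :class:`~sexgwas.simulate.ExpressionPanels` or list of
    panels; ``module_scores`` optionally overrides each panel's stored
    module score.
    """
    plist = getattr(panels, "panels", panels)
    rows: dict[str, list[tuple[float, int]]] = {}
    dropped: set[str] = set()
    for k, panel in enumerate(plist):
        score = panel.module_score if module_scores is None else np.asarray(module_scores[k])
        expr = panel.expr
        sd = expr.std(axis=1, ddof=1)
        const = sd <= 0
        for gene in expr.index[const]:
            dropped.add(gene)
        ok = expr.index[~const]
        centered = expr.loc[ok].to_numpy() - expr.loc[ok].to_numpy().mean(axis=1, keepdims=True)
        s = score - score.mean()
        denom = np.sqrt((centered**2).sum(axis=1) * (s**2).sum())
        r = np.clip((centered @ s) / denom, -0.999999, 0.999999)
        for gene, rv in zip(ok, r):
            rows.setdefault(gene, []).append((float(rv), panel.n_samples))
    if dropped:
        logger.warning("sc_gene_scores: dropped %d constant-expression genes", len(dropped))
    out = []
    for gene, vals in rows.items():
        z = np.array([np.arctanh(r) for r, _ in vals])
        w = np.array([n for _, n in vals], dtype=float)
        zbar = float((z * w).sum() / w.sum())
        rbar = float(np.tanh(zbar))
        cls = "male-correlated" if rbar > r_cut else (
            "anti-correlated" if rbar < -r_cut else "unclassified"
        )
        out.append((gene, rbar, zbar, cls))
    return pd.DataFrame(out, columns=["gene", "r_mean", "z_mean", "classification"])
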
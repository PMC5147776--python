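"""Per-SNP association tests.

Trio cohorts are tested with the transmission disequilibrium test (TDT):
``b`` transmissions and ``c`` non-transmissions of the minor allele from
heterozygous parents give the statistic ``(b - c)^2 / (b + c)`` on a 1-df
chi-square, with log-odds ``ln(b/c)`` and standard error
``sqrt(1/b + 1/c)``.  On the X chromosome no change to the test is needed:
hemizygous fathers are never informative, so only heterozygous mothers
contribute transmissions.

Case-control cohorts are tested by logistic regression of affection on
dosage with principal-component covariates; X-linked SNPs use 0/1 male and
0/1/2 female coding with sex added as a covariate in mixed-sex analyses.

Effects are always reported for the minor allele as observed in the
analysis cohort, the orientation the downstream sign tests rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import GenotypeTable, mendelian_consistent, trio_arrays

logger = logging.getLogger(__name__)


@dataclass
class AssociationRecord:
    """One SNP's association result (``b``/``c`` only for the TDT)."""

    snp: str
    test: str
    beta: float
    se: float
    p: float
    b: int | None = None
    c: int | None = None
    n_eff: int = 0
    converged: bool = True
    q: float | None = None


def _tdt_counts(trios: GenotypeTable):
    """Vectorized minor-allele transmission counts per SNP.

    Returns (b, c) for the allele counted in ``dosages`` (a1); orientation
    to the minor allele happens in :func:`tdt_scan`.
    """
    F, M, C, sexes, _ = trio_arrays(trios)
    x_mask = trios.x_mask
    is_male = sexes == "male"
    ok = mendelian_consistent(F, M, C, x_mask, is_male)

    het_f = (F == 1).astype(np.int64)
    het_m = (M == 1).astype(np.int64)
    n_het = het_f + het_m
    # transmissions of a1 from heterozygous parents: child's a1 copies minus
    # the deterministic contribution of homozygous parents
    t_het = C - (F == 2).astype(np.int64) - (M == 2).astype(np.int64)

    if x_mask.any():
        xm = x_mask[None, :]
        son = is_male[:, None] & xm
        daughter = (~is_male[:, None]) & xm
        # fathers are hemizygous on X: never informative
        t_son = C - (M == 2).astype(np.int64)
        t_dau = (C - F) - (M == 2).astype(np.int64)
        t_het = np.where(son, t_son, np.where(daughter, t_dau, t_het))
        n_het = np.where(xm, het_m, n_het)

    t_het = np.where(ok, t_het, 0)
    n_het = np.where(ok, n_het, 0)
    b = t_het.sum(axis=0)
    c = (n_het - t_het).sum(axis=0)
    return b, c


def tdt_scan(trios: GenotypeTable, snps=None) -> pd.DataFrame:
    """TDT over every SNP (or a subset), minor-allele oriented.

    Returns a frame with columns ``snp, chrom, pos, test, b, c, stat, p,
    beta, se, n_eff``; SNPs with no informative transmissions get NaN
    statistics and are flagged ``testable = False``.
    """
    table = trios if snps is None else trios.subset_snps(snps)
    b, c = _tdt_counts(table)
    flip = table.cohort_freqs() > 0.5
    b, c = np.where(flip, c, b), np.where(flip, b, c)

    n = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(n > 0, (b - c) ** 2 / np.maximum(n, 1), np.nan)
        p = stats.chi2.sf(stat, df=1)
        beta = np.where((b > 0) & (c > 0), np.log(np.maximum(b, 1) / np.maximum(c, 1)), np.nan)
        se = np.where((b > 0) & (c > 0), np.sqrt(1.0 / np.maximum(b, 1) + 1.0 / np.maximum(c, 1)), np.nan)
    out = table.snp_info[["snp", "chrom", "pos"]].copy()
    out["test"] = "TDT"
    out["b"] = b
    out["c"] = c
    out["stat"] = stat
    out["p"] = p
    out["beta"] = beta
    out["se"] = se
    out["n_eff"] = n
    out["testable"] = n > 0
    return out


def tdt(trios: GenotypeTable, snp: str) -> AssociationRecord:
    """TDT for a single SNP."""
    row = tdt_scan(trios, snps=[snp]).iloc[0]
    return AssociationRecord(
        snp=snp, test="TDT", beta=row["beta"], se=row["se"], p=row["p"],
        b=int(row["b"]), c=int(row["c"]), n_eff=int(row["n_eff"]),
        converged=bool(row["testable"]),
    )


def encode_x(g: GenotypeTable, snp: str) -> np.ndarray:
    """X-chromosome dosage coding: males 0/1, females 0/1/2.

    Male hemizygotes already carry 0/1 dosages in a valid table; a male
    dosage of 2 is a hard error naming the individual.
    """
    j = int(np.flatnonzero((g.snp_info["snp"] == snp).to_numpy())[0])
    if g.snp_info.loc[j, "chrom"] != "X":
        raise ValueError(f"{snp} is not on the X chromosome")
    d = g.dosages[:, j].astype(float)
    male = (g.meta["sex"] == "male").to_numpy()
    bad = male & (d > 1)
    if bad.any():
        iid = g.meta.loc[bad, "iid"].iloc[0]
        raise ValueError(f"male X dosage 2 for individual {iid!r}")
    d[d < 0] = np.nan
    return d


def logistic_assoc(
    g: GenotypeTable,
    snp: str,
    covariates: np.ndarray | None = None,
    max_abs_beta: float = 20.0,
) -> AssociationRecord:
    """Logistic regression of affection (2 = case) on one SNP's dosage.

    X-linked SNPs use the 0/1 male, 0/1/2 female coding; in mixed-sex
    analyses sex is added as a covariate.  Records failing to converge or
    showing separation (|beta| above ``max_abs_beta``) are flagged so the
    meta-analysis can drop them.
    """
    j = int(np.flatnonzero((g.snp_info["snp"] == snp).to_numpy())[0])
    on_x = bool(g.snp_info.loc[j, "chrom"] == "X")
    if on_x:
        dose = encode_x(g, snp)
    else:
        dose = g.dosages[:, j].astype(float)
        dose[dose < 0] = np.nan

    y = (g.meta["affection"].to_numpy() == 2).astype(float)
    cols = [dose]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != g.n:
            cov = cov.T
        cols += [cov[:, k] for k in range(cov.shape[1])]
    sexes = g.meta["sex"].to_numpy()
    if on_x and len(set(sexes)) > 1:
        cols.append((sexes == "male").astype(float))
    X = np.column_stack(cols)
    keep = np.isfinite(X).all(axis=1)
    X, yk = X[keep], y[keep]
    if len(set(yk)) < 2:
        raise ValueError("phenotype must contain both cases and controls")

    flip = g.cohort_freqs()[j] > 0.5
    Xd = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(yk, Xd).fit(disp=0, maxiter=50, tol=1e-8)
        beta, se = fit.params[1], fit.bse[1]
        p = fit.pvalues[1]
        converged = bool(fit.mle_retvals.get("converged", True)) and abs(beta) <= max_abs_beta and np.isfinite(se)
    except Exception:  # perfect separation raises in statsmodels
        beta, se, p, converged = np.nan, np.nan, np.nan, False
    if flip and np.isfinite(beta):
        beta = -beta
    if not converged:
        logger.warning("logistic fit for %s flagged (separation or non-convergence)", snp)
    return AssociationRecord(
        snp=snp, test="logistic", beta=beta, se=se, p=p,
        n_eff=int(keep.sum()), converged=converged,
    )


def _irls_batch(y: np.ndarray, D: np.ndarray, C: np.ndarray, max_abs_beta: float = 20.0):
    """Newton/IRLS logistic fits for many SNPs sharing the same covariates.

    ``D`` is n x m dosages (no missing), ``C`` n x p shared columns
    (intercept first).  Parameters are solved per SNP simultaneously;
    convergence is |delta loglik| < 1e-8 within 50 iterations.  Returns
    (beta, se, p, converged) for the dosage coefficient.
    """
    n, m = D.shape
    p_cov = C.shape[1]
    k = p_cov + 1
    # X_j = [C, D[:, j]]; keep dosage as the last coefficient
    theta = np.zeros((m, k))
    ll_old = np.full(m, -np.inf)
    active = np.ones(m, dtype=bool)
    for _ in range(50):
        eta = C @ theta[:, :p_cov].T + D * theta[:, p_cov].T  # n x m
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        # gradient and Hessian blocks per SNP
        gC = C.T @ r                       # p x m
        gD = (D * r).sum(axis=0)           # m
        HCC = np.einsum("np,nm,nq->mpq", C, w, C)
        HCD = np.einsum("np,nm,nm->mp", C, w, D)
        HDD = (w * D * D).sum(axis=0)
        H = np.empty((m, k, k))
        H[:, :p_cov, :p_cov] = HCC
        H[:, :p_cov, p_cov] = HCD
        H[:, p_cov, :p_cov] = HCD
        H[:, p_cov, p_cov] = HDD
        grad = np.concatenate([gC.T, gD[:, None]], axis=1)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(k), grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.einsum("mij,mj->mi", np.linalg.pinv(H), grad)
        theta = theta + np.where(active[:, None], step, 0.0)
        with np.errstate(invalid="ignore"):
            ll = (y[:, None] * eta - np.log1p(np.exp(eta))).sum(axis=0)
        active = np.abs(ll - ll_old) > 1e-8
        ll_old = ll
        if not active.any():
            break
    converged = ~active
    eta = np.clip(C @ theta[:, :p_cov].T + D * theta[:, p_cov].T, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    HCC = np.einsum("np,nm,nq->mpq", C, w, C)
    HCD = np.einsum("np,nm,nm->mp", C, w, D)
    HDD = (w * D * D).sum(axis=0)
    H = np.empty((m, k, k))
    H[:, :p_cov, :p_cov] = HCC
    H[:, :p_cov, p_cov] = HCD
    H[:, p_cov, :p_cov] = HCD
    H[:, p_cov, p_cov] = HDD
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(H)
        se = np.sqrt(cov[:, p_cov, p_cov])
    beta = theta[:, p_cov]
    converged = converged & np.isfinite(se) & (np.abs(beta) <= max_abs_beta)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return beta, se, pvals, converged


def logistic_scan(
    g: GenotypeTable,
    covariates: np.ndarray | None = None,
    snps=None,
) -> pd.DataFrame:
    """Logistic association over every SNP (or a subset).

    Autosomal and X SNPs are fitted in two vectorized IRLS batches (X adds
    the sex covariate in mixed-sex cohorts); SNPs with missing dosages fall
    back to the per-SNP path.  Effects are minor-allele oriented.
    """
    table = g if snps is None else g.subset_snps(snps)
    y = (table.meta["affection"].to_numpy() == 2).astype(float)
    if len(set(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    cols = [np.ones(table.n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != table.n:
            cov = cov.T
        cols += [cov[:, j] for j in range(cov.shape[1])]
    C = np.column_stack(cols)
    sexes = table.meta["sex"].to_numpy()
    mixed = len(set(sexes)) > 1
    C_x = np.column_stack([C, (sexes == "male").astype(float)]) if mixed else C

    D = table.dosages.astype(float)
    has_missing = (D < 0).any(axis=0)
    flip = table.cohort_freqs() > 0.5

    m = table.m
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pv = np.full(m, np.nan)
    conv = np.zeros(m, dtype=bool)
    for on_x, Cb in ((False, C), (True, C_x)):
        sel = np.flatnonzero((table.x_mask == on_x) & ~has_missing)
        if sel.size == 0:
            continue
        b, s, p, c = _irls_batch(y, D[:, sel], Cb)
        beta[sel], se[sel], pv[sel], conv[sel] = b, s, p, c
    for j in np.flatnonzero(has_missing):
        r = logistic_assoc(table, table.snp_info["snp"].iloc[j], covariates=covariates)
        # logistic_assoc already orients to the minor allele
        beta[j] = -r.beta if flip[j] and np.isfinite(r.beta) else r.beta
        se[j], pv[j], conv[j] = r.se, r.p, r.converged
    beta = np.where(flip, -beta, beta)
    out = table.snp_info[["snp", "chrom", "pos"]].copy()
    out["test"] = "logistic"
    out["beta"] = beta
    out["se"] = se
    out["p"] = pv
    out["n_eff"] = table.n
    out["converged"] = conv
    return out


def pca_covariates(g: GenotypeTable, k: int = 10) -> np.ndarray:
    """Top-k principal components of standardized autosomal genotypes.

    Returns an ``n x k`` matrix of unit-norm eigenvectors of the individual
    covariance, each with its largest-magnitude loading made positive so the
    sign is reproducible.  If the genotype matrix has rank below ``k``,
    fewer columns come back with a warning.
    """
    if g.n < k + 1:
        raise ValueError(f"need at least {k + 1} individuals for {k} components")
    W = g.standardized()[:, g.autosome_mask]
    W = W - W.mean(axis=0)
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    rank = int((s > s.max() * 1e-9).sum()) if s.size else 0
    kk = min(k, rank)
    if kk < k:
        logger.warning("requested %d components but genotype rank is %d", k, rank)
    V = U[:, :kk]
    for j in range(kk):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V
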
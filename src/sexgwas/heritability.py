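"""Genetic load: GRM, unconstrained observed-scale REML, spike-in series,
BLUP SNP effects and out-of-sample risk scores.

The variance model is the single-component GREML model

    y = X b + g + e,   g ~ (0, A Vg),   e ~ (0, I Ve),

with A the genetic relationship matrix from standardized autosomal
dosages.  The restricted likelihood is maximized without boundary
constraints, so Vg may go negative and the observed-scale heritability
``h2 = Vg / (Vg + Ve)`` may fall outside [0, 1] -- deliberately, since the
stepwise spike-in analysis correlates raw estimates with sample
composition and clamping would bias that correlation.

REML is computed in the eigenbasis of the covariate-projected GRM: with
``K`` an orthonormal basis of the complement of the covariate column
space and ``K' A K = U diag(d) U'``, the restricted log-likelihood is a
sum of independent terms in ``lambda_i = Vg d_i + Ve``, which makes each
evaluation O(n) after one decomposition.  Standard errors come from the
inverse Fisher information of (Vg, Ve) with a delta-method propagation
to h2, matching the usual GREML asymptotics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeTable
from ._util import standardize_dosages

logger = logging.getLogger(__name__)


@dataclass
class Grm:
    """Pairwise genetic relationship matrix over ``m`` SNPs."""

    matrix: np.ndarray
    ids: list[str]
    m: int
    snps: list[str] = field(default_factory=list)
    freqs: np.ndarray | None = None

    def sub(self, ids) -> "Grm":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return Grm(self.matrix[np.ix_(idx, idx)], list(ids), self.m, self.snps, self.freqs)


@dataclass
class HeritabilityEstimate:
    V_g: float
    V_e: float
    h2_obs: float
    se_h2: float
    loglik: float
    converged: bool
    n: int
    m: int
    se_Vg: float = np.nan


@dataclass
class SnpEffects:
    """Per-SNP BLUP solutions on the standardized-genotype scale."""

    table: pd.DataFrame  # snp, a1, u
    freqs: np.ndarray  # training allele frequencies for standardization
    training_ids: list[str]


def write_grm(grm: Grm, prefix, binary: bool = True) -> None:
    """Serialize a GRM in the GCTA layout.

    Binary: ``.grm.bin`` (float32 lower triangle, row-major), ``.grm.N.bin``
    (float32 SNP counts) and ``.grm.id`` (family/individual TSV).  With
    ``binary=False`` a plain ``.grm.tsv`` triplet (i, j, value over the
    lower triangle) is written instead.
    """
    from pathlib import Path

    prefix = Path(prefix)
    n = len(grm.ids)
    tri = grm.matrix[np.tril_indices(n)]
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")
    if binary:
        tri.astype("<f4").tofile(prefix.with_suffix(".grm.bin"))
        np.full(tri.shape, grm.m, dtype="<f4").tofile(prefix.with_suffix(".grm.N.bin"))
    else:
        ii, jj = np.tril_indices(n)
        pd.DataFrame({"i": ii + 1, "j": jj + 1, "grm": tri}).to_csv(
            prefix.with_suffix(".grm.tsv"), sep="\t", index=False
        )


def read_grm(prefix) -> Grm:
    """Read a GRM written by :func:`write_grm` (binary or TSV layout)."""
    from pathlib import Path

    prefix = Path(prefix)
    ids = [line.split("\t")[1].strip() for line in
           prefix.with_suffix(".grm.id").read_text().splitlines()]
    n = len(ids)
    A = np.zeros((n, n))
    if prefix.with_suffix(".grm.bin").exists():
        tri = np.fromfile(prefix.with_suffix(".grm.bin"), dtype="<f4").astype(float)
        m = int(np.fromfile(prefix.with_suffix(".grm.N.bin"), dtype="<f4")[0])
    else:
        df = pd.read_csv(prefix.with_suffix(".grm.tsv"), sep="\t")
        tri = df["grm"].to_numpy()
        m = 0
    A[np.tril_indices(n)] = tri
    A = A + np.tril(A, -1).T
    return Grm(A, ids, m)


def compute_grm(g: GenotypeTable, autosomes_only: bool = True) -> Grm:
    """GCTA-style GRM: ``A = W W' / m`` with ``W`` standardized dosages.

    Missing dosages are mean-imputed per SNP (zero after centering);
    monomorphic SNPs are excluded with a warning.
    """
    mask = g.autosome_mask if autosomes_only else np.ones(g.m, dtype=bool)
    freqs = g.cohort_freqs()
    poly = (freqs > 0) & (freqs < 1) & np.isfinite(freqs)
    n_mono = int((mask & ~poly).sum())
    if n_mono:
        logger.warning("GRM: excluding %d monomorphic SNPs", n_mono)
    mask = mask & poly
    male = (g.meta["sex"] == "male").to_numpy()[:, None]
    ploidy = np.where(male & g.x_mask[None, :], 1, 2)[:, mask]
    W = standardize_dosages(g.dosages[:, mask], freqs[mask], ploidy)
    m = int(mask.sum())
    A = (W @ W.T) / m
    return Grm(A, list(g.meta["iid"]), m, list(g.snp_info.loc[mask, "snp"]), freqs[mask])


def grm_relatedness_filter(grm: Grm, cutoff: float = 0.1) -> list[str]:
    """Ids surviving greedy removal of related pairs (off-diagonal > cutoff).

    At each step the individual involved in the most over-threshold pairs is
    removed (ties break by index order), until no pair remains.
    """
    A = grm.matrix.copy()
    np.fill_diagonal(A, 0.0)
    alive = np.ones(len(grm.ids), dtype=bool)
    while True:
        over = (A > cutoff) & alive[:, None] & alive[None, :]
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        alive[int(np.argmax(counts))] = False
    return [iid for iid, a in zip(grm.ids, alive) if a]


def _reml_core(A: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Eigen-reduced restricted likelihood ingredients (d, u, n-p)."""
    n = len(y)
    Q, _ = np.linalg.qr(X, mode="complete")
    K = Q[:, X.shape[1]:]
    B = K.T @ A @ K
    d, U = np.linalg.eigh((B + B.T) / 2.0)
    u = U.T @ (K.T @ y)
    return d, u


def reml_h2(
    grm: Grm,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 100,
) -> HeritabilityEstimate:
    """Unconstrained single-GRM REML of observed-scale heritability.

    ``covariates`` (n x p, without intercept -- one is always added) are
    treated as fixed effects.  Non-convergence is flagged rather than
    raised so series analyses can skip the estimate.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError("REML needs at least 50 individuals")
    if grm.matrix.shape[0] != n:
        raise ValueError("GRM and phenotype sizes differ")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    d, u = _reml_core(grm.matrix, y, X)
    u2 = u**2

    def negloglik(theta):
        vg, ve = theta
        lam = vg * d + ve
        if np.any(lam <= 1e-10):
            return 1e10 + 1e6 * abs(float(np.min(lam)))
        return 0.5 * float(np.sum(np.log(lam)) + np.sum(u2 / lam))

    vp = float(np.var(y, ddof=1))
    best = None
    for frac in (0.5, 0.1, 0.9):
        res = optimize.minimize(
            negloglik, x0=[frac * vp, (1 - frac) * vp], method="Nelder-Mead",
            options={"maxiter": 200 * max_iter, "xatol": 1e-10, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    vg, ve = best.x
    converged = bool(best.success) and best.fun < 1e9

    lam = vg * d + ve
    # Fisher information of (Vg, Ve) in the eigenbasis
    i11 = 0.5 * np.sum(d**2 / lam**2)
    i12 = 0.5 * np.sum(d / lam**2)
    i22 = 0.5 * np.sum(1.0 / lam**2)
    info = np.array([[i11, i12], [i12, i22]])
    try:
        cov = np.linalg.inv(info)
        vtot = vg + ve
        grad = np.array([ve, -vg]) / vtot**2
        se_h2 = float(np.sqrt(grad @ cov @ grad))
        se_vg = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        se_h2, se_vg, converged = np.nan, np.nan, False
    return HeritabilityEstimate(
        V_g=float(vg), V_e=float(ve), h2_obs=float(vg / (vg + ve)), se_h2=se_h2,
        loglik=-float(best.fun), converged=converged, n=n, m=grm.m, se_Vg=se_vg,
    )


def spike_in_counts(n_pool: int, pairs_per_step: int = 10) -> list[int]:
    """Nested-set sizes (pairs added) for a stepwise spike-in series."""
    counts = list(range(0, n_pool + 1, pairs_per_step))
    if counts[-1] != n_pool:
        counts.append(n_pool)
    return counts


def spike_in_series(
    g: GenotypeTable,
    base_ids,
    pool_pairs,
    pairs_per_step: int = 10,
    grm: Grm | None = None,
    covariates_by_iid: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Stepwise spike-in heritability series.

    Starting from the base case/pseudo-control set, ``pool_pairs`` (ordered
    (proband, pseudo-control) id pairs, disjoint from the base) are added in
    nested steps of ``pairs_per_step`` (final step may be partial).  REML
    runs per set on the case/control coding (affection 2 -> 1, else 0);
    non-converged sets are recorded as missing.  Returns the per-set frame,
    Spearman's rho between pairs added and h2, and its p-value.
    """
    base_ids = list(base_ids)
    pool_pairs = list(pool_pairs)
    overlap = set(base_ids) & {i for pair in pool_pairs for i in pair}
    if overlap:
        raise ValueError(f"pool pairs overlap the base set: {sorted(overlap)[:3]} ...")
    if grm is None:
        grm = compute_grm(g)
    pheno = dict(zip(g.meta["iid"], (g.meta["affection"] == 2).astype(float)))

    rows = []
    for n_added in spike_in_counts(len(pool_pairs), pairs_per_step):
        ids = base_ids + [i for pair in pool_pairs[:n_added] for i in pair]
        sub = grm.sub(ids)
        y = np.array([pheno[i] for i in ids])
        cov = None
        if covariates_by_iid is not None:
            cov = covariates_by_iid.reindex(ids).to_numpy(float)
        est = reml_h2(sub, y, covariates=cov)
        rows.append(
            (n_added, est.h2_obs if est.converged else np.nan, est.se_h2,
             est.V_g, est.V_e, est.converged, len(ids))
        )
    sets = pd.DataFrame(
        rows, columns=["n_added", "h2_obs", "se_h2", "V_g", "V_e", "converged", "n"]
    )
    ok = sets["converged"] & np.isfinite(sets["h2_obs"])
    if ok.sum() < 3:
        return sets, np.nan, np.nan
    rho, p = stats.spearmanr(sets.loc[ok, "n_added"], sets.loc[ok, "h2_obs"])
    return sets, float(rho), float(p)


def blup_snp_effects(
    grm: Grm,
    g: GenotypeTable,
    phenotype: np.ndarray,
    estimate: HeritabilityEstimate,
    covariates: np.ndarray | None = None,
) -> SnpEffects:
    """BLUP individual genetic values transformed to per-SNP solutions.

    With ``V = Vg A + Ve I`` and GLS-residualized phenotype ``y~``, the
    individual BLUPs are ``g^ = Vg A V^{-1} y~`` and the SNP solutions
    ``u = W' A^+ g^ / m`` (pseudo-inverse, so rank-deficient GRMs remain
    defined); scoring the training genotypes with ``u`` reproduces ``g^``.
    """
    if not (estimate.converged and estimate.V_g > 0):
        raise ValueError("BLUP requires a converged estimate with V_g > 0")
    if list(g.meta["iid"]) != list(grm.ids):
        raise ValueError("training table rows must match the GRM individual order")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    A = grm.matrix
    V = estimate.V_g * A + estimate.V_e * np.eye(n)
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ b
    ghat = estimate.V_g * A @ (Vi @ resid)

    mask = g.snp_info["snp"].isin(grm.snps).to_numpy()
    W = standardize_dosages(g.dosages[:, mask], np.asarray(grm.freqs))
    u = (W.T @ np.linalg.pinv(A, rcond=1e-10) @ ghat) / grm.m
    table = pd.DataFrame(
        {"snp": g.snp_info.loc[mask, "snp"].to_numpy(),
         "a1": g.snp_info.loc[mask, "a1"].to_numpy(),
         "u": u}
    )
    return SnpEffects(table, np.asarray(grm.freqs), list(grm.ids))


def risk_scores(effects: SnpEffects, target: GenotypeTable) -> pd.DataFrame:
    """Per-individual polygenic score: standardized dosage times BLUP effect.

    Standardization uses the training allele frequencies; missing dosages
    contribute zero and are counted.  Requires at least half of the trained
    SNPs in the target panel.
    """
    pos = {s: j for j, s in enumerate(target.snp_info["snp"])}
    shared = [s in pos for s in effects.table["snp"]]
    if np.mean(shared) < 0.5:
        raise ValueError("fewer than 50% of scored SNPs present in the target panel")
    snps = effects.table.loc[shared, "snp"].to_numpy()
    u = effects.table.loc[shared, "u"].to_numpy()
    freqs = effects.freqs[np.asarray(shared)]
    cols = np.array([pos[s] for s in snps])
    D = target.dosages[:, cols]
    n_missing = (D < 0).sum(axis=1)
    W = standardize_dosages(D, freqs)
    scores = W @ u
    return pd.DataFrame(
        {"iid": target.meta["iid"], "score": scores, "n_missing": n_missing,
         "affection": target.meta["affection"], "sex": target.meta["sex"]}
    )


def group_compare(scores: pd.DataFrame, grouping) -> tuple[float, float, float]:
    """Welch two-sample t-test of mean score between two groups.

    ``grouping`` is a boolean array aligned with ``scores`` rows (True =
    group 1).  Returns (mean difference, t, p).
    """
    grp = np.asarray(grouping, dtype=bool)
    a = scores.loc[grp, "score"].to_numpy()
    b = scores.loc[~grp, "score"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two members")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(t), float(p)
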
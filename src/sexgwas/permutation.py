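"""Power-matched sex-permutation nulls.

The central null construction: sex labels are permuted within technical
batch x study design at counts matched to the true per-stratum male and
female proband counts, so every permuted "male" and "female" dataset has
exactly the power of the corresponding true dataset.  Trios permute as
whole families (a pseudo-male trio contributes a TDT trio to the
pseudo-male analysis); case-control individuals permute individually,
stratified additionally by case/control status so permuted cohorts keep
the true case:control balance.

Association signal is summarized as the fraction of SNPs passing an FDR
q-value threshold (q = 0.8 by default) -- a comparison metric, not a
significance claim -- and the observed fraction is referred to the
permuted fractions for an empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import logistic_scan, tdt_scan
from .meta import bh_qvalues, cochran_q, ld_clump, meta_scan
from .simulate import GenotypeTable
from ._util import substream

logger = logging.getLogger(__name__)


def _units(meta: pd.DataFrame) -> pd.DataFrame:
    """Permutable units: one row per trio family (labelled by proband sex)
    and one per case-control individual, with stratum labels."""
    trios = meta[(meta["design"] == "trio") & (meta["role"] == "proband")]
    t = pd.DataFrame(
        {
            "unit": trios["family"].to_numpy(),
            "kind": "family",
            "sex": trios["sex"].to_numpy(),
            "stratum": (trios["batch"] + "|trio").to_numpy(),
        }
    )
    cc = meta[meta["design"] == "case-control"]
    c = pd.DataFrame(
        {
            "unit": cc["iid"].to_numpy(),
            "kind": "individual",
            "sex": cc["sex"].to_numpy(),
            "stratum": (cc["batch"] + "|cc|" + cc["role"]).to_numpy(),
        }
    )
    return pd.concat([t, c], ignore_index=True)


def make_permutation_plans(g: GenotypeTable, n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Stratified pseudo-sex assignments for ``n_perm`` permutations.

    Within every stratum, units are sampled without replacement into a
    pseudo-male set of exactly the stratum's true male count; the remainder
    is pseudo-female.  Deterministic given ``seed``.
    """
    units = _units(g.meta)
    if units.empty:
        raise ValueError("no permutable units (missing batch/design metadata?)")
    rng = substream(seed, "sex-permutation")
    plans = []
    for stratum, sub in units.groupby("stratum", sort=True):
        n_male = int((sub["sex"] == "male").sum())
        ids = sub["unit"].to_numpy()
        kinds = sub["kind"].to_numpy()
        if n_male > len(ids):
            raise ValueError(f"stratum {stratum!r} smaller than its male target")
        for perm in range(n_perm):
            order = rng.permutation(len(ids))
            pseudo = np.full(len(ids), "female", dtype=object)
            pseudo[order[:n_male]] = "male"
            plans.append(
                pd.DataFrame(
                    {
                        "perm": perm,
                        "stratum": stratum,
                        "unit": ids,
                        "kind": kinds,
                        "pseudo_sex": pseudo,
                    }
                )
            )
    return pd.concat(plans, ignore_index=True)


def _cohort_from_units(g: GenotypeTable, unit_rows: pd.DataFrame) -> GenotypeTable:
    fams = set(unit_rows.loc[unit_rows["kind"] == "family", "unit"])
    iids = set(unit_rows.loc[unit_rows["kind"] == "individual", "unit"])
    mask = (
        g.meta["family"].isin(fams) & (g.meta["design"] == "trio")
    ) | g.meta["iid"].isin(iids)
    return g.subset_individuals(mask.to_numpy())


def apply_plan(g: GenotypeTable, plans: pd.DataFrame, perm: int, sex: str) -> GenotypeTable:
    """Cohort of units assigned pseudo-sex ``sex`` in permutation ``perm``."""
    sub = plans[(plans["perm"] == perm) & (plans["pseudo_sex"] == sex)]
    return _cohort_from_units(g, sub)


def true_sex_cohort(g: GenotypeTable, sex: str) -> GenotypeTable:
    """The observed sex-specific dataset: trios with ``sex`` probands plus
    ``sex`` cases and controls."""
    units = _units(g.meta)
    return _cohort_from_units(g, units[units["sex"] == sex])


def sex_specific_scan(g: GenotypeTable, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Association over one cohort: TDT on its trios, logistic on its
    case-control part, fixed-effects meta of the two.

    ``covariates`` is an optional frame indexed by individual id (principal
    components computed once on the full cohort; sex permutation does not
    alter genotypes, so they are not recomputed per permutation).
    """
    strata = {}
    trio_mask = (g.meta["design"] == "trio").to_numpy()
    if trio_mask.any():
        strata["tdt"] = tdt_scan(g.subset_individuals(trio_mask))
    cc_mask = (g.meta["design"] == "case-control").to_numpy()
    if cc_mask.any():
        cc = g.subset_individuals(cc_mask)
        if (cc.meta["affection"] == 2).any() and (cc.meta["affection"] == 1).any():
            cov = None
            if covariates is not None:
                cov = covariates.reindex(cc.meta["iid"]).to_numpy(float)
            strata["cc"] = logistic_scan(cc, covariates=cov)
    if not strata:
        raise ValueError("cohort contains neither testable trios nor case-control data")
    if len(strata) == 1:
        df = next(iter(strata.values())).copy()
        df["beta_meta"], df["se_meta"], df["p_meta"] = df["beta"], df["se"], df["p"]
        return df
    merged = meta_scan(strata)
    info_cols = next(iter(strata.values()))[["snp", "chrom", "pos"]]
    return info_cols.merge(merged, on="snp")


@dataclass
class EnrichmentResult:
    observed_fraction: float
    permuted_fractions: np.ndarray
    empirical_p: float
    q_threshold: float
    snp_scope: str = "autosomes"
    extras: dict = field(default_factory=dict)


def enrichment_fraction(qvals, q_threshold: float = 0.8) -> float:
    """Fraction of SNPs whose FDR q-value falls below the threshold."""
    q = np.asarray(qvals, dtype=float)
    q = q[np.isfinite(q)]
    if q.size == 0:
        raise ValueError("empty SNP scope for enrichment fraction")
    return float((q < q_threshold).mean())


def empirical_p(observed, permuted, direction: str = "greater", add_one: bool = False) -> float:
    """Proportion of permuted statistics at least as extreme as observed."""
    perm = np.asarray(permuted, dtype=float)
    if perm.size == 0:
        raise ValueError("need at least one permuted value")
    if direction == "greater":
        r = int((perm >= observed).sum())
    elif direction == "less":
        r = int((perm <= observed).sum())
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    if add_one:
        return (r + 1) / (perm.size + 1)
    return r / perm.size


def sex_permutation_null(
    g: GenotypeTable,
    plans: pd.DataFrame,
    stat_fn,
    sexes=("male", "female"),
) -> dict[str, np.ndarray]:
    """Null distribution of any cohort-level statistic under sex permutation.

    ``stat_fn(cohort)`` maps a GenotypeTable to a float; it is evaluated on
    every permutation's pseudo-``sex`` cohort.
    """
    perms = sorted(plans["perm"].unique())
    out = {}
    for sex in sexes:
        vals = np.empty(len(perms))
        for i, perm in enumerate(perms):
            vals[i] = stat_fn(apply_plan(g, plans, perm, sex))
        out[sex] = vals
    return out


def fdr_enrichment_stat(
    scope_mask: np.ndarray | None = None,
    q_threshold: float = 0.8,
    covariates: pd.DataFrame | None = None,
):
    """Build a cohort -> enrichment-fraction statistic for a SNP scope.

    q-values are recomputed within the scope of each cohort's scan, per the
    rule that the FDR metric is always computed over the stated SNP scope
    only.
    """

    def stat(cohort: GenotypeTable) -> float:
        scan = sex_specific_scan(cohort, covariates=covariates)
        if scope_mask is not None:
            keep = cohort.snp_info["snp"].isin(
                cohort.snp_info.loc[scope_mask, "snp"]
            ).to_numpy()
            scan = scan[scan["snp"].isin(cohort.snp_info.loc[keep, "snp"])]
        q = bh_qvalues(scan["p_meta"].to_numpy())
        return enrichment_fraction(q, q_threshold)

    return stat


def association_enrichment(
    g: GenotypeTable,
    plans: pd.DataFrame,
    sex: str,
    scope_mask: np.ndarray | None = None,
    q_threshold: float = 0.8,
    covariates: pd.DataFrame | None = None,
    scope_name: str = "autosomes",
) -> EnrichmentResult:
    """Observed vs sex-permuted FDR-threshold association enrichment."""
    stat = fdr_enrichment_stat(scope_mask, q_threshold, covariates)
    observed = stat(true_sex_cohort(g, sex))
    permuted = sex_permutation_null(g, plans, stat, sexes=(sex,))[sex]
    p = empirical_p(observed, permuted, "greater")
    return EnrichmentResult(observed, permuted, p, q_threshold, scope_name)


def _effect_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a scan frame to plain beta/se/p columns (meta if present)."""
    if "p_meta" in df.columns:
        out = df[["snp"] + [c for c in ("chrom", "pos") if c in df.columns]].copy()
        out["beta"] = df["beta_meta"]
        out["se"] = df["se_meta"]
        out["p"] = df["p_meta"]
        return out
    return df


def top_het_fraction(
    scan_by_sex: dict[str, pd.DataFrame],
    g: GenotypeTable,
    sex: str,
    k: int = 20,
    q_level: float = 0.2,
    r2_max: float = 0.2,
    window_bp: int = 500_000,
    scope_mask: np.ndarray | None = None,
) -> float:
    """Fraction of a sex's top-k clumped SNPs with heterogeneity q below
    ``q_level`` (q-values computed within the top-k set)."""
    own = _effect_columns(scan_by_sex[sex])
    other = _effect_columns(scan_by_sex["female" if sex == "male" else "male"])
    if scope_mask is not None:
        keep = set(g.snp_info.loc[scope_mask, "snp"])
        own = own[own["snp"].isin(keep)]
        other = other[other["snp"].isin(keep)]
    top = ld_clump(own, g, r2_max=r2_max, window_bp=window_bp, k=k)
    merged = top[["snp", "beta", "se"]].merge(
        other[["snp", "beta", "se"]], on="snp", suffixes=("_a", "_b")
    )
    _, p_Q = cochran_q(
        merged["beta_a"].to_numpy(), merged["se_a"].to_numpy(),
        merged["beta_b"].to_numpy(), merged["se_b"].to_numpy(),
    )
    q = bh_qvalues(p_Q)
    return enrichment_fraction(q, q_level)


def permuted_het_excess(
    g: GenotypeTable,
    plans: pd.DataFrame,
    sex: str = "male",
    k: int = 20,
    q_level: float = 0.2,
    scope_mask: np.ndarray | None = None,
    scope_name: str = "X",
    r2_max: float = 0.2,
    window_bp: int = 500_000,
    covariates: pd.DataFrame | None = None,
) -> EnrichmentResult:
    """Observed vs sex-permuted top-k heterogeneity excess.

    For the observed value the top-k SNPs come from the true sex-specific
    scan; under each permutation the whole pipeline (both pseudo-sex scans,
    clumping, Q, within-set q-values) is recomputed.
    """

    def both_scans(male_cohort, female_cohort):
        return {
            "male": sex_specific_scan(male_cohort, covariates=covariates),
            "female": sex_specific_scan(female_cohort, covariates=covariates),
        }

    obs_scans = both_scans(true_sex_cohort(g, "male"), true_sex_cohort(g, "female"))
    observed = top_het_fraction(
        obs_scans, g, sex, k=k, q_level=q_level, r2_max=r2_max,
        window_bp=window_bp, scope_mask=scope_mask,
    )
    perms = sorted(plans["perm"].unique())
    vals = np.empty(len(perms))
    for i, perm in enumerate(perms):
        scans = both_scans(
            apply_plan(g, plans, perm, "male"), apply_plan(g, plans, perm, "female")
        )
        vals[i] = top_het_fraction(
            scans, g, sex, k=k, q_level=q_level, r2_max=r2_max,
            window_bp=window_bp, scope_mask=scope_mask,
        )
    p = empirical_p(observed, vals, "greater")
    return EnrichmentResult(observed, vals, p, q_level, scope_name)
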
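"""Synthetic cohorts under a sex-specific liability-threshold model.

Disease liability is the sum of a polygenic genetic value and a standard
Gaussian residual; an individual is affected when liability exceeds a
sex-specific threshold (in liability SD units).  A higher female threshold
produces male-biased prevalence and, among affected individuals, a higher
mean polygenic load in females -- the ascertainment signature the downstream
analyses are designed to detect.

Genetic values are built from standardized dosages so that the liability
heritability is exact by construction: with per-SNP effects ``beta`` on
unit-variance genotypes, the genetic value is rescaled to variance
``h2_liability`` and the residual carries ``1 - h2_liability``.

The module also generates sex-stratified anthropometric summary statistics
(with a ground-truth heterogeneous subset) and fetal-brain-like expression
panels with sex-biased genes, the inputs of the pleiotropy analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import MISSING, AscertainmentError, standardize_dosages, substream

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(c) for c in range(1, 23))


@dataclass(frozen=True)
class CausalSet:
    """SNP indices (into the spec's SNP table) with per-sex liability effects."""

    indices: tuple[int, ...]
    beta_male: tuple[float, ...]
    beta_female: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.indices) == len(self.beta_male) == len(self.beta_female)):
            raise ValueError("causal set fields must have equal length")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of the simulated disorder.

    Parameters
    ----------
    n_snps_by_chrom
        SNP counts per chromosome label ('1'..'22', 'X').
    maf_range
        Allele frequencies drawn uniformly from this interval, in (0, 0.5].
    causal_sets
        Groups of SNPs with per-sex liability-scale effects; empty for a
        null architecture.
    h2_liability
        Variance of the genetic value on the liability scale, in [0, 1].
    threshold_male, threshold_female
        Liability cutoffs in SD units. ``threshold_female >= threshold_male``
        reproduces male-biased prevalence.
    male_x_scale
        Multiplier applied to male effects at X-linked SNPs (1.0 = the same
        per-allele effect as in females, i.e. no dosage-compensation scaling).
    """

    n_snps_by_chrom: Mapping[str, int]
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_sets: tuple[CausalSet, ...] = ()
    h2_liability: float = 0.2
    threshold_male: float = 1.0
    threshold_female: float = 1.0
    male_x_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0 <= self.h2_liability <= 1:
            raise ValueError("h2_liability must be in [0, 1]")
        for c in self.n_snps_by_chrom:
            if str(c) not in AUTOSOMES + ("X",):
                raise ValueError(f"unknown chromosome label {c!r}")

    @property
    def n_snps(self) -> int:
        return int(sum(self.n_snps_by_chrom.values()))

    def snp_info(self) -> pd.DataFrame:
        """Deterministic SNP table: ids, positions, alleles, frequencies."""
        rng = substream(self.seed, "snp-freqs")
        chroms, positions, ids = [], [], []
        for chrom in list(AUTOSOMES) + ["X"]:
            n = int(self.n_snps_by_chrom.get(str(chrom), 0))
            if n == 0:
                continue
            chroms += [str(chrom)] * n
            positions += list(10_000 * (1 + np.arange(n)))
            ids += [f"snp_{chrom}_{i + 1}" for i in range(n)]
        freqs = rng.uniform(*self.maf_range, size=len(ids))
        if not np.all(np.isfinite(freqs)):
            raise ValueError("non-finite allele frequencies")
        return pd.DataFrame(
            {
                "snp": ids,
                "chrom": chroms,
                "pos": np.asarray(positions, dtype=np.int64),
                "a1": "A",
                "a2": "G",
                "freq": freqs,
            }
        )

    def effect_vectors(self, snp_info: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP liability effects (male, female) on the standardized scale."""
        m = len(snp_info)
        beta_m = np.zeros(m)
        beta_f = np.zeros(m)
        on_x = (snp_info["chrom"] == "X").to_numpy()
        for cs in self.causal_sets:
            idx = np.asarray(cs.indices, dtype=int)
            beta_m[idx] += np.asarray(cs.beta_male, dtype=float)
            beta_f[idx] += np.asarray(cs.beta_female, dtype=float)
        beta_m[on_x] *= self.male_x_scale
        return beta_m, beta_f

    def with_seed(self, seed: int) -> "ArchitectureSpec":
        return replace(self, seed=int(seed))


def null_spec(n_auto: int = 100, n_x: int = 0, seed: int = 0, **kw) -> ArchitectureSpec:
    """Architecture with no causal SNPs, spread over chromosomes 1-22 (+X)."""
    per = {str(c): 0 for c in AUTOSOMES}
    for i in range(n_auto):
        per[str(1 + i % 22)] += 1
    counts = {c: n for c, n in per.items() if n}
    if n_x:
        counts["X"] = n_x
    return ArchitectureSpec(n_snps_by_chrom=counts, seed=seed, **kw)


@dataclass
class GenotypeTable:
    """Individuals x SNPs dosage matrix with per-individual metadata.

    ``dosages`` counts copies of allele ``a1`` (int8; autosomes 0/1/2, male X
    0/1, missing = -1).  ``meta`` has one row per individual with columns
    ``iid, sex, role, batch, design, affection, family, father, mother``
    (affection: 1 = unaffected, 2 = affected).
    """

    snp_info: pd.DataFrame
    dosages: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.meta), len(self.snp_info)):
            raise ValueError("dosage matrix shape does not match metadata")
        if self.meta["iid"].duplicated().any():
            dup = self.meta.loc[self.meta["iid"].duplicated(), "iid"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        self._check_male_x()

    def _check_male_x(self):
        x = self.x_mask
        if not x.any():
            return
        male = (self.meta["sex"] == "male").to_numpy()
        bad = self.dosages[np.ix_(male, x)] > 1
        if bad.any():
            i, j = np.argwhere(bad)[0]
            iid = self.meta.loc[male, "iid"].iloc[i]
            raise ValueError(f"male X dosage 2 for individual {iid!r}")

    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def m(self) -> int:
        return len(self.snp_info)

    @property
    def x_mask(self) -> np.ndarray:
        return (self.snp_info["chrom"] == "X").to_numpy()

    @property
    def autosome_mask(self) -> np.ndarray:
        return ~self.x_mask

    def cohort_freqs(self) -> np.ndarray:
        """Observed a1 frequency per SNP (male X counted as 1 chromosome)."""
        d = self.dosages.astype(float)
        male = (self.meta["sex"] == "male").to_numpy()[:, None]
        ploidy = np.where(male & self.x_mask[None, :], 1.0, 2.0)
        obs = d >= 0
        alleles = np.where(obs, ploidy, 0.0).sum(axis=0)
        counts = np.where(obs, d, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return counts / alleles

    def subset_individuals(self, sel) -> "GenotypeTable":
        """Select rows by boolean mask or iterable of individual ids."""
        if isinstance(sel, np.ndarray) and sel.dtype == bool:
            mask = sel
        else:
            wanted = set(sel)
            mask = self.meta["iid"].isin(wanted).to_numpy()
        return GenotypeTable(
            self.snp_info.copy(), self.dosages[mask], self.meta.loc[mask].reset_index(drop=True)
        )

    def subset_snps(self, sel) -> "GenotypeTable":
        if isinstance(sel, np.ndarray) and sel.dtype == bool:
            mask = sel
        else:
            wanted = set(sel)
            mask = self.snp_info["snp"].isin(wanted).to_numpy()
        return GenotypeTable(
            self.snp_info.loc[mask].reset_index(drop=True), self.dosages[:, mask], self.meta.copy()
        )

    def concat(self, other: "GenotypeTable") -> "GenotypeTable":
        if not self.snp_info["snp"].equals(other.snp_info["snp"]):
            raise ValueError("SNP panels differ")
        return GenotypeTable(
            self.snp_info.copy(),
            np.vstack([self.dosages, other.dosages]),
            pd.concat([self.meta, other.meta], ignore_index=True),
        )

    def standardized(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Float matrix of unit-variance dosages (male X at ploidy 1)."""
        f = self.cohort_freqs() if freqs is None else freqs
        male = (self.meta["sex"] == "male").to_numpy()[:, None]
        ploidy = np.where(male & self.x_mask[None, :], 1, 2)
        return standardize_dosages(self.dosages, f, ploidy)


def _meta_frame(iids, sex, role, batch, design, affection, family=None, father="0", mother="0"):
    n = len(iids)
    return pd.DataFrame(
        {
            "iid": iids,
            "sex": sex if not np.isscalar(sex) else [sex] * n,
            "role": role if not np.isscalar(role) else [role] * n,
            "batch": batch if not np.isscalar(batch) else [batch] * n,
            "design": design if not np.isscalar(design) else [design] * n,
            "affection": affection if not np.isscalar(affection) else [affection] * n,
            "family": family if family is not None else list(iids),
            "father": father if not np.isscalar(father) else [father] * n,
            "mother": mother if not np.isscalar(mother) else [mother] * n,
        }
    )


def _draw_dosages(rng, freqs, sexes, x_mask):
    """Binomial dosages at HWE: autosomes Bin(2, p); male X Bin(1, p)."""
    n, m = len(sexes), len(freqs)
    male = np.asarray(sexes) == "male"
    ploidy = np.where(male[:, None] & x_mask[None, :], 1, 2)
    return rng.binomial(ploidy, freqs[None, :]).astype(np.int8)


def simulate_population(
    spec: ArchitectureSpec,
    n_individuals: int,
    sex_ratio: float = 0.5,
    batch: str = "B1",
    stream: str = "population",
) -> GenotypeTable:
    """Unascertained individuals with HWE dosages at the spec's frequencies.

    ``sex_ratio`` is the female fraction.  Serves as the substrate for
    case-control cohorts and for population-level checks.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = substream(spec.seed, stream)
    info = spec.snp_info()
    n_f = int(round(sex_ratio * n_individuals))
    sexes = np.array(["female"] * n_f + ["male"] * (n_individuals - n_f))
    x_mask = (info["chrom"] == "X").to_numpy()
    dos = _draw_dosages(rng, info["freq"].to_numpy(), sexes, x_mask)
    meta = _meta_frame(
        [f"ind{i + 1:06d}" for i in range(n_individuals)],
        sexes, "control", batch, "case-control", 1,
    )
    return GenotypeTable(info, dos, meta)


def genetic_values(spec: ArchitectureSpec, info: pd.DataFrame, dosages, sexes) -> np.ndarray:
    """Standardized genetic liability values (variance 1 if any causal SNP)."""
    beta_m, beta_f = spec.effect_vectors(info)
    male = np.asarray(sexes) == "male"
    x_mask = (info["chrom"] == "X").to_numpy()
    ploidy = np.where(male[:, None] & x_mask[None, :], 1, 2)
    w = standardize_dosages(dosages, info["freq"].to_numpy(), ploidy)
    g = np.where(male, w @ beta_m, w @ beta_f)
    norm = np.where(male, np.sqrt((beta_m**2).sum()), np.sqrt((beta_f**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(norm > 0, g / np.maximum(norm, 1e-300), 0.0)
    return g


def _liability(spec, info, dosages, sexes, rng):
    g = genetic_values(spec, info, dosages, sexes)
    eps = rng.standard_normal(len(g))
    h2 = spec.h2_liability
    return np.sqrt(h2) * g + np.sqrt(1.0 - h2) * eps, np.sqrt(h2) * g


def _mendelian_child(rng, F, M, sex_is_male, x_mask):
    """Child dosages by Mendelian transmission; returns int8 matrix."""
    pf = F.astype(float) / 2.0
    tm = rng.binomial(1, M.astype(float) / 2.0)
    tf = rng.binomial(1, pf)
    child = (tf + tm).astype(np.int8)
    if x_mask.any():
        # sons: maternal X only; daughters: paternal hemizygous allele + maternal
        xm = x_mask[None, :]
        son = sex_is_male[:, None] & xm
        daughter = (~sex_is_male[:, None]) & xm
        child = np.where(son, tm, child).astype(np.int8)
        child = np.where(daughter, F + tm, child).astype(np.int8)
    return child


def simulate_trios(
    spec: ArchitectureSpec,
    n_trios: int,
    proband_sex_fraction_female: float = 0.5,
    batches: Sequence[str] = ("B1",),
    budget_factor: int = 500,
    stream: str = "trios",
) -> GenotypeTable:
    """Trios ascertained for an affected child under the liability threshold.

    Child sex is assigned before ascertainment so the requested sex mix is
    exact; children are retained only if their liability exceeds their sex's
    threshold (rejection sampling).  Batch labels cycle over ``batches``
    family-by-family.

    Raises
    ------
    AscertainmentError
        If more than ``budget_factor * n_trios`` candidate trios are drawn
        per sex before the quota is filled (threshold too extreme).
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    rng = substream(spec.seed, stream)
    info = spec.snp_info()
    freqs = info["freq"].to_numpy()
    x_mask = (info["chrom"] == "X").to_numpy()
    n_female = int(round(proband_sex_fraction_female * n_trios))
    quotas = {"female": n_female, "male": n_trios - n_female}
    thresholds = {"female": spec.threshold_female, "male": spec.threshold_male}

    kept: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {"female": [], "male": []}
    for sex, quota in quotas.items():
        if quota == 0:
            continue
        need, attempts = quota, 0
        thr = thresholds[sex]
        while need > 0:
            size = int(min(max(4 * need, 256), 20_000))
            attempts += size
            F = _draw_dosages(rng, freqs, np.array(["male"] * size), x_mask)
            M = _draw_dosages(rng, freqs, np.array(["female"] * size), x_mask)
            is_male = np.full(size, sex == "male")
            C = _mendelian_child(rng, F, M, is_male, x_mask)
            liab, _ = _liability(spec, info, C, np.array([sex] * size), rng)
            hit = np.flatnonzero(liab > thr)[:need]
            for i in hit:
                kept[sex].append((F[i], M[i], C[i]))
            need -= len(hit)
            if need > 0 and attempts > budget_factor * max(quota, 1):
                raise AscertainmentError(
                    f"ascertainment budget exhausted for {sex} probands at "
                    f"threshold {thr:.3f} ({attempts} candidates for {quota} trios)"
                )

    rows_d, rows_m = [], []
    order = [("female", i) for i in range(quotas["female"])] + [
        ("male", i) for i in range(quotas["male"])
    ]
    for fam_i, (sex, i) in enumerate(order, start=1):
        F, M, C = kept[sex][i]
        fam = f"fam{fam_i:05d}"
        b = batches[(fam_i - 1) % len(batches)]
        fid, mid, cid = f"{fam}_f", f"{fam}_m", f"{fam}_c"
        rows_d += [F, M, C]
        rows_m.append(("male", "father", fid, "0", "0", 1, fam, b))
        rows_m.append(("female", "mother", mid, "0", "0", 1, fam, b))
        rows_m.append((sex, "proband", cid, fid, mid, 2, fam, b))
    meta = pd.DataFrame(
        rows_m, columns=["sex", "role", "iid", "father", "mother", "affection", "family", "batch"]
    )
    meta["design"] = "trio"
    meta = meta[["iid", "sex", "role", "batch", "design", "affection", "family", "father", "mother"]]
    return GenotypeTable(info, np.vstack(rows_d), meta)


def trio_arrays(trios: GenotypeTable):
    """Aligned (father, mother, child) dosage arrays plus child sex/family.

    Families missing a complete father/mother/proband triple are dropped.
    """
    meta = trios.meta
    probands = meta[meta["role"] == "proband"]
    idx = pd.Series(np.arange(len(meta)), index=meta["iid"])
    fi = idx.reindex(probands["father"]).to_numpy()
    mi = idx.reindex(probands["mother"]).to_numpy()
    ok = np.isfinite(fi) & np.isfinite(mi)
    fi = fi[ok].astype(int)
    mi = mi[ok].astype(int)
    ci = idx.reindex(probands["iid"]).to_numpy().astype(int)[ok]
    D = trios.dosages
    return (
        D[fi].astype(np.int16),
        D[mi].astype(np.int16),
        D[ci].astype(np.int16),
        probands["sex"].to_numpy()[ok],
        probands["family"].to_numpy()[ok],
    )


def mendelian_consistent(F, M, C, x_mask, child_is_male) -> np.ndarray:
    """Boolean (trios x SNPs) mask of Mendelian-consistent dosage triples."""
    n_het = (F == 1).astype(int) + (M == 1).astype(int)
    lo = (F == 2).astype(int) + (M == 2).astype(int)
    ok = (C >= lo) & (C <= lo + n_het) & (F >= 0) & (M >= 0) & (C >= 0)
    if x_mask.any():
        xm = x_mask[None, :]
        son = child_is_male[:, None] & xm
        mat_lo = (M == 2).astype(int)
        ok_son = (C >= mat_lo) & (C <= mat_lo + (M == 1).astype(int)) & (M >= 0) & (C >= 0)
        mat = C - F  # daughters: maternal allele after removing the paternal one
        ok_dau = (mat >= mat_lo) & (mat <= mat_lo + (M == 1).astype(int)) & (F >= 0) & (M >= 0)
        ok = np.where(son, ok_son, np.where((~child_is_male[:, None]) & xm, ok_dau, ok))
    return ok


def make_pseudo_controls(trios: GenotypeTable) -> GenotypeTable:
    """Probands plus pseudo-controls built from untransmitted parental alleles.

    At every autosomal SNP the pseudo-control dosage is
    ``father + mother - child``, so proband + pseudo-control sums to the
    parental total.  On X, a male pseudo-control carries the untransmitted
    maternal allele and a female pseudo-control the paternal allele plus the
    untransmitted maternal allele.  Pseudo-control sex is copied from the
    proband.  Mendelian-inconsistent SNPs are set missing for that pair.
    """
    F, M, C, sexes, fams = trio_arrays(trios)
    x_mask = trios.x_mask
    is_male = sexes == "male"
    pseudo = (F + M - C).astype(np.int16)
    if x_mask.any():
        xm = x_mask[None, :]
        son = is_male[:, None] & xm
        daughter = (~is_male[:, None]) & xm
        pseudo = np.where(son, M - C, pseudo)
        pseudo = np.where(daughter, 2 * F + M - C, pseudo)
    ok = mendelian_consistent(F, M, C, x_mask, is_male)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("pseudo-controls: %d Mendelian-inconsistent trio/SNP pairs masked", n_bad)
    pseudo = np.where(ok, pseudo, MISSING).astype(np.int8)
    child = np.where(ok, C, MISSING).astype(np.int8)

    pmeta = trios.meta[trios.meta["role"] == "proband"].reset_index(drop=True)
    pro_meta = pmeta.copy()
    pro_meta["design"] = "trio"
    pc_meta = pmeta.copy()
    pc_meta["iid"] = [f"{fam}_pc" for fam in pc_meta["family"]]
    pc_meta["role"] = "pseudo-control"
    pc_meta["affection"] = 1
    pc_meta["father"] = "0"
    pc_meta["mother"] = "0"
    meta = pd.concat([pro_meta, pc_meta], ignore_index=True)
    return GenotypeTable(trios.snp_info.copy(), np.vstack([child, pseudo]), meta)


ANTHRO_TRAITS = ("height", "weight", "BMI", "WC", "HIP")


def simulate_anthro_sumstats(
    n_snps: int,
    frac_heterogeneous: float,
    traits: Sequence[str] = ANTHRO_TRAITS,
    seed: int = 0,
    se: float = 0.02,
    het_delta_se: float = 4.0,
    polygenic_scale: float = 1.0,
) -> pd.DataFrame:
    """Sex-stratified per-SNP summary statistics for anthropometric traits.

    All SNPs carry small polygenic trait effects shared between the sexes;
    a fraction ``frac_heterogeneous`` additionally has a true male-female
    effect difference of ``het_delta_se * sqrt(se_m^2 + se_f^2)`` in one
    randomly chosen trait.  Returns a tidy frame with one row per SNP x
    trait and a ``true_het`` ground-truth column.
    """
    if not 0 <= frac_heterogeneous <= 1:
        raise ValueError("frac_heterogeneous must be in [0, 1]")
    rng = substream(seed, "anthro-sumstats")
    snps = np.array([f"gsnp{i + 1:06d}" for i in range(n_snps)])
    n_het = int(round(frac_heterogeneous * n_snps))
    het_snps = rng.choice(n_snps, size=n_het, replace=False)
    het_trait = rng.integers(len(traits), size=n_het)
    delta = het_delta_se * se * np.sqrt(2.0)

    frames = []
    for t_i, trait in enumerate(traits):
        base = rng.normal(0.0, polygenic_scale * se, size=n_snps)
        true_m = base.copy()
        true_f = base.copy()
        sel = het_snps[het_trait == t_i]
        sign = rng.choice([-1.0, 1.0], size=len(sel))
        true_m[sel] += sign * delta / 2.0
        true_f[sel] -= sign * delta / 2.0
        beta_m = true_m + rng.normal(0.0, se, size=n_snps)
        beta_f = true_f + rng.normal(0.0, se, size=n_snps)
        flags = np.zeros(n_snps, dtype=bool)
        flags[sel] = True
        frames.append(
            pd.DataFrame(
                {
                    "snp": snps,
                    "trait": trait,
                    "beta_m": beta_m,
                    "se_m": se,
                    "beta_f": beta_f,
                    "se_f": se,
                    "p_m": 2 * norm.sf(np.abs(beta_m) / se),
                    "p_f": 2 * norm.sf(np.abs(beta_f) / se),
                    "true_het": flags,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    # combined-sex (inverse-variance) association used for p-matched nulls
    w_m, w_f = 1 / out["se_m"] ** 2, 1 / out["se_f"] ** 2
    out["beta_all"] = (w_m * out["beta_m"] + w_f * out["beta_f"]) / (w_m + w_f)
    out["se_all"] = np.sqrt(1 / (w_m + w_f))
    out["p_all"] = 2 * norm.sf(np.abs(out["beta_all"] / out["se_all"]))
    return out


@dataclass
class ExpressionPanel:
    """One expression dataset: genes x samples plus sample sex and the
    sex-linked module score the SC analysis correlates genes against."""

    name: str
    expr: pd.DataFrame
    sample_sex: np.ndarray
    module_score: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]


@dataclass
class ExpressionPanels:
    panels: list[ExpressionPanel]
    biased_genes: list[str] = field(default_factory=list)


def simulate_expression_panels(
    n_genes: int,
    n_samples_per_panel: Sequence[int] = (30, 50),
    sex_biased_gene_fraction: float = 0.1,
    bias: float = 2.0,
    module_noise: float = 0.0,
    seed: int = 0,
) -> ExpressionPanels:
    """Fetal-brain-like expression panels with a sex-biased gene subset.

    Sex-biased genes are shifted by ``bias/2`` toward one sex; the module
    score is the sex indicator (+1 male, -1 female) plus optional Gaussian
    noise, standing in for the first principal component of a sex-linked
    coexpression module.
    """
    if len(n_samples_per_panel) < 2:
        raise ValueError("at least two panels are required for weighted averaging")
    rng = substream(seed, "expression-panels")
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    n_biased = int(round(sex_biased_gene_fraction * n_genes))
    biased = list(rng.choice(genes, size=n_biased, replace=False))
    biased_set = set(biased)
    panels = []
    for k, ns in enumerate(n_samples_per_panel):
        n_m = ns // 2
        s = np.array([1.0] * n_m + [-1.0] * (ns - n_m))
        vals = rng.standard_normal((n_genes, ns))
        shift = np.array([bias / 2.0 if g in biased_set else 0.0 for g in genes])
        vals += shift[:, None] * s[None, :]
        expr = pd.DataFrame(vals, index=genes, columns=[f"p{k}_s{j}" for j in range(ns)])
        score = s + module_noise * rng.standard_normal(ns)
        sex = np.where(s > 0, "male", "female")
        panels.append(ExpressionPanel(f"panel{k + 1}", expr, sex, score))
    return ExpressionPanels(panels, biased)
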
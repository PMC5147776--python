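"""Readers and writers for the standard formats, plus the run configuration.

PLINK text (PED/MAP) and binary (BED/BIM/FAM) genotypes are supported,
with a sidecar TSV carrying the metadata PLINK files cannot (role, batch,
design).  Dosages are oriented as the count of allele A1 as listed in the
MAP/BIM; male X genotypes are stored homozygous (the PLINK convention)
and mapped back to 0/1 hemizygous dosages on read.

Gene intervals arrive as BED (0-based half-open) and are converted to the
1-based inclusive convention used throughout the package.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GenotypeTable
from ._util import MISSING, FormatError

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes -> dosage of A1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclass
class RunConfig:
    """Analysis thresholds, every one defaulting to the study's value."""

    gwas_alpha: float = 5e-8
    maf_floor: float = 0.01
    call_rate_floor: float = 0.9
    enrichment_q: float = 0.8
    n_permutations: int = 100
    gene_flank_bp: int = 5_000
    ah_p_cut: float = 1e-3
    x_top_q_male: float = 0.2
    x_top_q_female: float = 0.01
    auto_top_q_male: float = 0.2
    auto_top_q_female: float = 0.001
    clump_r2: float = 0.2
    clump_window_bp: int = 500_000
    top_k_x: int = 20
    top_k_auto: int = 100
    relatedness_cutoff: float = 0.1
    pairs_per_step: int = 10
    n_pcs: int = 10
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _meta_from_fam(fam: pd.DataFrame, sidecar: pd.DataFrame | None) -> pd.DataFrame:
    sex = fam["sex_code"].map({1: "male", 2: "female"})
    bad = sex.isna()
    if bad.any():
        logger.warning("excluding %d individuals with unknown sex code", int(bad.sum()))
    meta = pd.DataFrame(
        {
            "iid": fam["iid"],
            "sex": sex,
            "role": "control",
            "batch": "B1",
            "design": "case-control",
            "affection": fam["phenotype"].where(fam["phenotype"].isin([1, 2]), 1).astype(int),
            "family": fam["fid"],
            "father": fam["father"],
            "mother": fam["mother"],
        }
    )
    if sidecar is not None:
        sidecar = sidecar.set_index("iid")
        for col in ("role", "batch", "design"):
            if col in sidecar.columns:
                meta[col] = sidecar[col].reindex(meta["iid"]).fillna(meta[col]).to_numpy()
    return meta


def _finalize(snp_info, dosages, meta) -> GenotypeTable:
    keep = meta["sex"].notna().to_numpy()
    meta = meta.loc[keep].reset_index(drop=True)
    dosages = dosages[keep]
    # male X: PLINK stores hemizygotes as homozygous
    x = (snp_info["chrom"] == "X").to_numpy()
    if x.any():
        male = (meta["sex"] == "male").to_numpy()
        sub = dosages[np.ix_(male, x)]
        het = sub == 1
        if het.any():
            logger.warning("setting %d heterozygous male X calls to missing", int(het.sum()))
            sub[het] = MISSING
        sub[sub == 2] = 1
        dosages[np.ix_(male, x)] = sub
    return GenotypeTable(snp_info.reset_index(drop=True), dosages, meta)


def _norm_chrom(c: str) -> str:
    return {"23": "X", "x": "X"}.get(str(c), str(c))


def write_plink(g: GenotypeTable, prefix) -> None:
    """Write BED/BIM/FAM plus a ``.meta.tsv`` sidecar (role, batch, design)."""
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": g.snp_info["chrom"],
            "snp": g.snp_info["snp"],
            "cm": 0,
            "pos": g.snp_info["pos"],
            "a1": g.snp_info["a1"],
            "a2": g.snp_info["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    _write_fam_sidecar(g, prefix)

    male = (g.meta["sex"] == "male").to_numpy()
    x = g.x_mask
    n = g.n
    codes = np.empty((g.m, n), dtype=np.uint8)
    for code_val, dosage in ((0b00, 2), (0b01, MISSING), (0b10, 1), (0b11, 0)):
        codes[(g.dosages == dosage).T] = code_val
    if x.any():
        # hemizygous males: 1 -> hom A1, 0 -> hom A2
        sub = g.dosages[np.ix_(male, x)]
        c = np.where(sub == 1, 0b00, np.where(sub == 0, 0b11, 0b01)).astype(np.uint8)
        codes[np.ix_(x, male)] = c.T
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.full((g.m, pad), 0b01, dtype=np.uint8)])
    packed = (
        codes[:, 0::4] | (codes[:, 1::4] << 2) | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _write_fam_sidecar(g: GenotypeTable, prefix: Path) -> None:
    fam = pd.DataFrame(
        {
            "fid": g.meta["family"],
            "iid": g.meta["iid"],
            "father": g.meta["father"],
            "mother": g.meta["mother"],
            "sex_code": g.meta["sex"].map({"male": 1, "female": 2}),
            "phenotype": g.meta["affection"],
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    g.meta[["iid", "role", "batch", "design"]].to_csv(
        prefix.with_suffix(".meta.tsv"), sep="\t", index=False
    )


def write_ped(g: GenotypeTable, prefix) -> None:
    """Write PED/MAP plus the metadata sidecar."""
    prefix = Path(prefix)
    mp = g.snp_info[["chrom", "snp", "pos"]].copy()
    mp.insert(2, "cm", 0)
    mp.to_csv(prefix.with_suffix(".map"), sep="\t", header=False, index=False)
    a1 = g.snp_info["a1"].to_numpy()
    a2 = g.snp_info["a2"].to_numpy()
    male = (g.meta["sex"] == "male").to_numpy()
    x = g.x_mask
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(g.n):
            row = g.meta.iloc[i]
            d = g.dosages[i].astype(int)
            if male[i] and x.any():
                d = d.copy()
                d[x & (d == 1)] = 2  # hemizygote written homozygous
            pairs = []
            for j, dj in enumerate(d):
                if dj < 0:
                    pairs.append("0 0")
                elif dj == 2:
                    pairs.append(f"{a1[j]} {a1[j]}")
                elif dj == 1:
                    pairs.append(f"{a1[j]} {a2[j]}")
                else:
                    pairs.append(f"{a2[j]} {a2[j]}")
            sex_code = 1 if row["sex"] == "male" else 2
            fh.write(
                f"{row['family']} {row['iid']} {row['father']} {row['mother']} "
                f"{sex_code} {row['affection']} " + " ".join(pairs) + "\n"
            )
    g.meta[["iid", "role", "batch", "design"]].to_csv(
        prefix.with_suffix(".meta.tsv"), sep="\t", index=False
    )


def read_genotypes(path) -> GenotypeTable:
    """Read a PLINK fileset (BED/BIM/FAM or PED/MAP) with optional sidecar.

    ``path`` may be a prefix or any member file of the set.
    """
    p = Path(path)
    prefix = p.with_suffix("") if p.suffix in {".bed", ".bim", ".fam", ".ped", ".map"} else p
    sidecar = None
    sc_path = prefix.with_suffix(".meta.tsv")
    if sc_path.exists():
        sidecar = pd.read_csv(sc_path, sep="\t", dtype=str)
    if prefix.with_suffix(".bed").exists():
        return _read_bed(prefix, sidecar)
    if prefix.with_suffix(".ped").exists():
        return _read_ped(prefix, sidecar)
    raise FormatError(f"no PLINK fileset at prefix {prefix}")


def _read_bed(prefix: Path, sidecar) -> GenotypeTable:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex_code", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not a SNP-major PLINK BED)")
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != m * bytes_per_snp:
        raise FormatError(
            f"{prefix}.bed: payload of {payload.size} bytes does not match "
            f"{m} SNPs x {n} individuals"
        )
    payload = payload.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, 0::4] = payload & 0b11
    codes[:, 1::4] = (payload >> 2) & 0b11
    codes[:, 2::4] = (payload >> 4) & 0b11
    codes[:, 3::4] = (payload >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    bim["chrom"] = bim["chrom"].map(_norm_chrom)
    snp_info = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    snp_info["freq"] = np.nan
    meta = _meta_from_fam(fam, sidecar)
    g = _finalize(snp_info, dosages, meta)
    g.snp_info["freq"] = g.cohort_freqs()
    return g


def _read_ped(prefix: Path, sidecar) -> GenotypeTable:
    mp = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str},
    )
    mp["chrom"] = mp["chrom"].map(_norm_chrom)
    m = len(mp)
    fam_rows, geno_rows = [], []
    a1 = [None] * m  # inferred A1 = first allele listed in the file per SNP
    alleles: list[set] = [set() for _ in range(m)]
    raw = []
    for line in Path(prefix.with_suffix(".ped")).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(f"{prefix}.ped: row with {len(parts)} fields, expected {6 + 2 * m}")
        fam_rows.append(parts[:6])
        raw.append(parts[6:])
        for j in range(m):
            for al in parts[6 + 2 * j : 8 + 2 * j]:
                if al != "0":
                    alleles[j].add(al)
    pair = [sorted(a) for a in alleles]
    a1 = [p[0] if p else "A" for p in pair]
    a2 = [p[1] if len(p) > 1 else ("G" if p and p[0] != "G" else "A") for p in pair]
    dosages = np.full((len(raw), m), MISSING, dtype=np.int8)
    for i, row in enumerate(raw):
        for j in range(m):
            x, y = row[2 * j], row[2 * j + 1]
            if x == "0" or y == "0":
                continue
            dosages[i, j] = int(x == a1[j]) + int(y == a1[j])
    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "father", "mother", "sex_code", "phenotype"])
    fam["sex_code"] = fam["sex_code"].astype(int)
    fam["phenotype"] = pd.to_numeric(fam["phenotype"], errors="coerce").fillna(1).astype(int)
    snp_info = pd.DataFrame(
        {"snp": mp["snp"], "chrom": mp["chrom"], "pos": mp["pos"], "a1": a1, "a2": a2, "freq": np.nan}
    )
    meta = _meta_from_fam(fam, sidecar)
    g = _finalize(snp_info, dosages, meta)
    g.snp_info["freq"] = g.cohort_freqs()
    return g


def apply_common_filters(
    g: GenotypeTable,
    maf_floor: float = 0.01,
    call_rate_floor: float = 0.9,
) -> GenotypeTable:
    """Drop SNPs below the MAF floor or the per-SNP call-rate floor."""
    if not (0 <= maf_floor <= 1 and 0 <= call_rate_floor <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    f = g.cohort_freqs()
    maf = np.minimum(f, 1 - f)
    call = (g.dosages >= 0).mean(axis=0)
    keep = (maf >= maf_floor) & (call >= call_rate_floor) & np.isfinite(maf)
    if maf_floor == 0 and call_rate_floor == 0:
        keep = np.ones(g.m, dtype=bool)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filters removed %d of %d SNPs", n_drop, g.m)
    if not keep.any():
        raise ValueError("no SNPs survive the filters")
    return g.subset_snps(keep)


def write_association(df: pd.DataFrame, path) -> None:
    """Per-SNP association TSV (snp, chr, bp, beta, se, p, q, n, test...)."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_association(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})


def read_gene_bed(path) -> pd.DataFrame:
    """Gene intervals from BED: 0-based half-open -> 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start0", "end0", "gene"], usecols=range(4), dtype={"chrom": str},
    )
    df["chrom"] = df["chrom"].str.replace("chr", "", regex=False).map(_norm_chrom)
    out = pd.DataFrame(
        {"gene": df["gene"], "chrom": df["chrom"], "start": df["start0"] + 1, "end": df["end0"]}
    )
    bad = out["start"] > out["end"]
    if bad.any():
        raise FormatError(f"{path}: {int(bad.sum())} intervals with start > end")
    return out


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    """1-based inclusive intervals -> BED (0-based half-open)."""
    pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start0": genes["start"] - 1,
            "end0": genes["end"],
            "gene": genes["gene"],
        }
    ).to_csv(path, sep="\t", header=False, index=False)
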
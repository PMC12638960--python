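"""Readers and writers for every on-disk format the pipeline touches.

Genotypes: PLINK bed/bim/fam (variant-major, 2-bit) or a headered TSV matrix
(rows = samples, first column ``sample_id``, remaining columns = variant
ids).  Weights, summary statistics, phenotypes and PRS outputs are headered
TSVs; run configuration is YAML.  All TSV writers emit headers; readers
reject headerless files.  Coordinates are 1-based and dosages count the
declared effect allele (PLINK allele 1 by default).  Floats are written at
10 significant digits so write/read round-trips are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pgxtl.baselines import SummaryStats, WeightTable
from pgxtl.core import GenotypeMatrix, PGxCohort

__all__ = [
    "RunConfig",
    "read_genotypes",
    "read_plink",
    "write_plink",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_weight_table",
    "write_weight_table",
    "read_sumstats",
    "write_sumstats",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_prs",
    "load_cohort",
]

_FLOAT_FMT = "%.10g"
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # variant-major
# 2-bit PLINK codes -> dosage of allele 1 (NaN = missing)
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class RunConfig:
    """Resolved run configuration for the command-line pipeline."""

    genotypes: str
    phenotype: str
    output_dir: str
    weights: str | None = None
    sumstats: str | None = None
    covariates: list[str] = field(default_factory=list)
    strategy: str = "M1"
    mode: str = "real"
    seed: int = 0
    k_outer: int = 5
    global_residualize: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.strategy.upper() not in {f"M{i}" for i in range(1, 7)}:
            raise ValueError(f"strategy must be M1..M6, got {cfg.strategy}")
        for p in (cfg.genotypes, cfg.phenotype):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset; dosages count bim allele 1."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chr", "variant_id", "cm", "pos", "a1", "a2"], dtype={"chr": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    if bim["variant_id"].duplicated().any():
        dup = bim.loc[bim["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id in bim: {dup}")
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a variant-major PLINK bed file (bad magic bytes)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise ValueError(
            f"bed payload is {len(raw)} bytes but {expected} expected for "
            f"{n} samples x {m} variants"
        )
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample-within-byte little-endian
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T
    return GenotypeMatrix(
        dosages,
        fam["iid"].to_numpy(dtype=object),
        bim["variant_id"].to_numpy(dtype=object),
        bim["a1"].astype(str).to_numpy(dtype=object),
        bim["a2"].astype(str).to_numpy(dtype=object),
        bim["chr"].astype(str).to_numpy(dtype=object),
        bim["pos"].to_numpy(dtype=int),
    )


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK 1 fileset; non-integral dosages are rounded to {0,1,2}."""
    prefix = Path(prefix)
    n, m = g.n_samples, g.n_variants
    pos = g.pos if g.pos is not None else np.arange(1, m + 1)
    chrom = g.chrom if g.chrom is not None else ["1"] * m
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(
                f"{chrom[j]}\t{g.variant_ids[j]}\t0\t{int(pos[j])}\t"
                f"{g.effect_alleles[j]}\t{g.other_alleles[j]}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    dosage_to_code = {2: 0, 1: 2, 0: 3}
    bytes_per_variant = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    for j in range(m):
        col = g.dosages[:, j]
        codes = np.empty(bytes_per_variant * 4, dtype=np.uint8)
        codes[:] = 1  # pad + missing code
        for i in range(n):
            v = col[i]
            codes[i] = 1 if np.isnan(v) else dosage_to_code[int(round(v))]
        packed = (
            codes[0::4] | (codes[1::4] << 2) | (codes[2::4] << 4) | (codes[3::4] << 6)
        )
        out.extend(packed.tobytes())
    Path(prefix.with_suffix(".bed")).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} file {path} is missing header columns {missing}; "
            "headerless files are not accepted"
        )
    return df


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Headered dosage matrix: ``sample_id`` column + one column per variant."""
    df = _read_tsv(path, ["sample_id"], "genotype matrix")
    variant_ids = [c for c in df.columns if c != "sample_id"]
    if not variant_ids:
        raise ValueError("genotype matrix has no variant columns")
    dosages = df[variant_ids].to_numpy(dtype=float)
    m = len(variant_ids)
    # the TSV dialect carries no allele annotation; '.' marks that downstream
    # harmonization should trust the stated weight orientation
    return GenotypeMatrix(
        dosages,
        df["sample_id"].astype(str).to_numpy(dtype=object),
        np.asarray(variant_ids, dtype=object),
        np.asarray(["."] * m, dtype=object),
        np.asarray(["."] * m, dtype=object),
    )


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.dosages, columns=g.variant_ids.astype(str))
    df.insert(0, "sample_id", g.sample_ids.astype(str))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_genotypes(path: str | Path, format: str = "plink") -> GenotypeMatrix:
    if format == "plink":
        return read_plink(path)
    if format == "tsv":
        return read_genotype_tsv(path)
    raise ValueError("format must be 'plink' or 'tsv'")


def read_weight_table(path: str | Path) -> WeightTable:
    df = _read_tsv(path, ["variant_id", "effect_allele", "other_allele"], "weight")
    if "weight" not in df.columns and "beta_g" in df.columns:
        df = df.rename(columns={"beta_g": "weight"})
    return WeightTable(df)


def write_weight_table(w: WeightTable, path: str | Path) -> None:
    w.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_sumstats(path: str | Path) -> SummaryStats:
    df = _read_tsv(
        path,
        ["variant_id", "chr", "pos", "effect_allele", "other_allele", "beta", "se", "p"],
        "summary statistics",
    )
    return SummaryStats(df)


def write_sumstats(s: SummaryStats, path: str | Path) -> None:
    s.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Headered table keyed by ``sample_id`` with ``phenotype``, ``treatment``
    and any covariate columns."""
    return _read_tsv(path, ["sample_id", "phenotype", "treatment"], "phenotype")


def write_phenotype_table(
    cohort: PGxCohort, path: str | Path, covariate_names: list[str] | None = None
) -> None:
    df = pd.DataFrame({
        "sample_id": cohort.genotypes.sample_ids.astype(str),
        "phenotype": cohort.phenotype,
        "treatment": cohort.treatment.astype(int),
    })
    if cohort.covariates is not None:
        names = covariate_names or [f"covariate_{j}" for j in range(cohort.covariates.shape[1])]
        for j, name in enumerate(names):
            df[name] = cohort.covariates[:, j]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_prs(
    sample_ids: np.ndarray,
    prs_g: np.ndarray,
    prs_gt: np.ndarray,
    path: str | Path,
    fold: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame({
        "sample_id": np.asarray(sample_ids, dtype=str),
        "prs_g": prs_g,
        "prs_gt": prs_gt,
    })
    df["fold"] = fold if fold is not None else 0
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_cohort(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    genotype_format: str = "plink",
    covariate_names: list[str] | None = None,
) -> PGxCohort:
    """Assemble a cohort from a genotype fileset and a phenotype table.

    Samples are matched by id; phenotype rows are reordered to the genotype
    sample order and missing samples raise.
    """
    g = read_genotypes(genotype_path, genotype_format)
    pheno = read_phenotype_table(phenotype_path).set_index("sample_id")
    pheno.index = pheno.index.astype(str)
    ids = g.sample_ids.astype(str)
    missing = [s for s in ids if s not in pheno.index]
    if missing:
        raise ValueError(f"phenotype table lacks {len(missing)} genotyped samples "
                         f"(first: {missing[0]})")
    pheno = pheno.loc[ids]
    cov = None
    if covariate_names:
        cov = pheno[list(covariate_names)].to_numpy(dtype=float)
    return PGxCohort(
        g,
        pheno["treatment"].to_numpy(dtype=float),
        pheno["phenotype"].to_numpy(dtype=float),
        cov,
    )
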
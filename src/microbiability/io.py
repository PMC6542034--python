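"""Plain-text readers and writers plus the run configuration.

Formats:
  * OTU TSV — first column ``animal_id``, one integer column per OTU;
    optional taxonomy sidecar TSV ``otu_id<TAB>lineage``.
  * Genotype TSV — first column ``animal_id``, SNP columns with 0/1/2/NA;
    the PLINK ``--recode A`` dialect (FID IID PAT MAT SEX PHENOTYPE SNP...)
    is auto-detected and accepted.
  * Phenotype CSV — ``animal_id,herd,parity,dim,<trait columns...>``.
  * Kernel TSV — header row/column of animal ids, full symmetric matrix at
    10 significant digits.

Parsing is strict: malformed cells fail fast with their coordinates rather
than being coerced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, TableFormatError
from .kernels import RelationshipMatrix
from .tables import PHENO_META_COLUMNS, GenotypeTable, OtuCountTable, PhenotypeRecords

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------- OTU tables

def read_otu_table(path, taxonomy_path=None) -> OtuCountTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "animal_id":
        raise TableFormatError(f"{path}: first column must be 'animal_id', got {df.columns[0]!r}")
    animal_ids = list(df["animal_id"])
    otu_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:]
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        num = pd.to_numeric(raw[col], errors="coerce")
        if num.isna().any():
            i = int(num.isna().idxmax())
            raise TableFormatError(
                f"{path}: non-numeric count {raw[col].iloc[i]!r} at "
                f"animal {animal_ids[i]!r}, OTU {col!r}")
        if (num < 0).any():
            i = int((num < 0).idxmax())
            raise TableFormatError(
                f"{path}: negative count {raw[col].iloc[i]!r} at "
                f"animal {animal_ids[i]!r}, OTU {col!r}")
        if not np.all(np.mod(num.to_numpy(dtype=float), 1) == 0):
            i = int(np.argmax(np.mod(num.to_numpy(dtype=float), 1) != 0))
            raise TableFormatError(
                f"{path}: non-integer count {raw[col].iloc[i]!r} at "
                f"animal {animal_ids[i]!r}, OTU {col!r}")
        counts[:, j] = num.to_numpy(dtype=np.int64)
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", header=None, names=["otu_id", "lineage"])
        taxonomy = dict(zip(tax["otu_id"], tax["lineage"]))
    return OtuCountTable(animal_ids, otu_ids, counts, taxonomy=taxonomy)


def write_otu_table(table: OtuCountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


# ------------------------------------------------------------------ genotypes

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _detect_dialect(path) -> str:
    with open(path) as fh:
        header = fh.readline().split()
    if header[:2] == ["FID", "IID"]:
        return "plink-raw"
    return "simple-tsv"


def read_genotypes(path, dialect: str = "auto") -> GenotypeTable:
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise TableFormatError(f"{path}: PLINK-RAW header missing {missing_meta}")
        animal_ids = list(df["IID"].astype(str))
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        raw = df[snp_cols]
    elif dialect == "simple-tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.columns[0] != "animal_id":
            raise TableFormatError(
                f"{path}: first column must be 'animal_id', got {df.columns[0]!r}")
        animal_ids = list(df["animal_id"])
        snp_cols = list(df.columns[1:])
        raw = df[snp_cols]
    else:
        raise ConfigurationError(f"unknown genotype dialect {dialect!r}")
    codes = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        num = pd.to_numeric(raw[col].replace("NA", np.nan), errors="coerce")
        bad = num.isna() & raw[col].notna() & (raw[col].astype(str) != "NA")
        if bad.any():
            i = int(bad.idxmax())
            raise TableFormatError(
                f"{path}: invalid genotype code {raw[col].iloc[i]!r} at "
                f"animal {animal_ids[i]!r}, SNP {col!r}")
        codes[:, j] = num.to_numpy(dtype=float)
    return GenotypeTable(animal_ids, list(raw.columns), codes)


def write_genotypes(gt: GenotypeTable, path) -> None:
    df = gt.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


# ----------------------------------------------------------------- phenotypes

def read_phenotypes(path) -> PhenotypeRecords:
    df = pd.read_csv(path)
    missing = [c for c in PHENO_META_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: phenotype CSV missing columns {missing}")
    df["animal_id"] = df["animal_id"].astype(str)
    return PhenotypeRecords(df)


def write_phenotypes(pheno: PhenotypeRecords, path) -> None:
    df = pheno.data.copy()
    for c in pheno.trait_names:
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else _FLOAT_FMT % v)
    df.to_csv(path, index=False)


# -------------------------------------------------------------------- kernels

def write_kernel(K: RelationshipMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(map(str, K.animal_ids)) + "\n")
        for aid, row in zip(K.animal_ids, K.values):
            fh.write(str(aid) + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_kernel(path, kind: str = "G") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = 0.5 * (values + values.T)  # writer rounding can break symmetry slightly
    return RelationshipMatrix(list(df.columns), values, kind)


# ----------------------------------------------------------------- run config

_FILTER_KEYS = {"min_otu_count": 10, "min_sample_reads": 50_000,
                "min_individual_call_rate": 0.80, "min_locus_call_rate": 0.95,
                "min_maf": 0.01, "max_dim": 400, "linkage": "complete"}
_CV_KEYS = {"n_val": 50, "n_reps": 10}


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline run."""

    otu_path: str
    genotype_path: str
    phenotype_path: str
    output_dir: str
    seed: int = 0
    traits: list | str = "all"
    filters: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for key, default in _FILTER_KEYS.items():
            self.filters.setdefault(key, default)
        unknown = set(self.filters) - set(_FILTER_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown filter keys: {sorted(unknown)}")
        for key, default in _CV_KEYS.items():
            self.cv.setdefault(key, default)
        unknown = set(self.cv) - set(_CV_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown cv keys: {sorted(unknown)}")
        if not (0 <= self.filters["min_individual_call_rate"] <= 1
                and 0 <= self.filters["min_locus_call_rate"] <= 1
                and 0 <= self.filters["min_maf"] <= 0.5):
            raise ConfigurationError("filter thresholds out of documented ranges")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    missing = [k for k in ("otu_path", "genotype_path", "phenotype_path", "output_dir")
               if k not in raw]
    if missing:
        raise ConfigurationError(f"config missing required keys: {missing}")
    return RunConfig(**raw)


# -------------------------------------------------------------- study writers

def write_study(study, outdir) -> dict:
    """Write a SyntheticStudy's tables plus ground truth to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "otus": outdir / "otus.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_genotypes(study.genotypes, paths["genotypes"])
    write_otu_table(study.otu_counts, paths["otus"])
    write_phenotypes(study.phenotypes, paths["phenotypes"])
    truth = {
        trait: {
            "effects": {c: [float(x) for x in v] for c, v in comp.items()},
            "sigma2": study.sigma2[trait],
            "realized_variances": study.realized_variances[trait],
        }
        for trait, comp in study.truth.items()
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
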
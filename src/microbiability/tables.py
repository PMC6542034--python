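"""In-memory containers for the three input tables and derived matrices.

All containers keep an explicit ``animal_ids`` sequence so that downstream
stages (kernels, REML, cross-validation) can be reconciled by id rather than
by positional index.  Genotype codes are stored as a float array with ``nan``
for missing calls; OTU counts are non-negative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TableFormatError

#: columns every phenotype table must carry before the trait columns
PHENO_META_COLUMNS = ("animal_id", "herd", "parity", "dim")


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise TableFormatError(f"duplicate {what} ids: {sorted(set(map(str, dups)))[:5]}")
    return ids


@dataclass
class OtuCountTable:
    """Animals x OTUs table of non-negative integer sequence counts."""

    animal_ids: list
    otu_ids: list
    counts: np.ndarray  # (n_animals, n_otus) integer
    taxonomy: dict | None = None
    dropped_animals: list = field(default_factory=list)
    dropped_otus: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.animal_ids = _check_unique(self.animal_ids, "animal")
        self.otu_ids = _check_unique(self.otu_ids, "OTU")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.animal_ids), len(self.otu_ids)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise TableFormatError(
                    f"non-integer count at animal {self.animal_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at animal {self.animal_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def library_sizes(self) -> np.ndarray:
        """Total read count per animal."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.animal_ids, name="animal_id"),
                            columns=self.otu_ids)


@dataclass
class GenotypeTable:
    """Animals x SNPs additive genotype codes {0, 1, 2}; ``nan`` = missing."""

    animal_ids: list
    snp_ids: list
    codes: np.ndarray  # (n_animals, n_snps) float with nan for missing

    def __post_init__(self) -> None:
        self.animal_ids = _check_unique(self.animal_ids, "animal")
        self.snp_ids = _check_unique(self.snp_ids, "SNP")
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise TableFormatError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(observed[~np.isin(observed, (0.0, 1.0, 2.0))]))
            raise TableFormatError(f"genotype codes outside {{0,1,2,NA}}: {bad[:5]}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def call_rate_individuals(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=1)

    def call_rate_loci(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP, over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=pd.Index(self.animal_ids, name="animal_id"),
                            columns=self.snp_ids)


@dataclass
class PhenotypeRecords:
    """Per-animal herd/parity/days-in-milk metadata plus trait columns.

    Traits are milk fat %, protein % and individual fatty acids (wt/wt % of
    total fat); values may be missing per animal.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_META_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"phenotype table missing columns: {missing}")
        _check_unique(self.data["animal_id"], "animal")
        if (self.data["dim"] < 1).any():
            bad = self.data.loc[self.data["dim"] < 1, "animal_id"].iloc[0]
            raise TableFormatError(f"days in milk < 1 for animal {bad!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def animal_ids(self) -> list:
        return list(self.data["animal_id"])

    @property
    def trait_names(self) -> list:
        return [c for c in self.data.columns if c not in PHENO_META_COLUMNS]

    @property
    def n_animals(self) -> int:
        return len(self.data)

    def trait(self, name: str) -> pd.Series:
        if name not in self.trait_names:
            raise ConfigurationError(f"unknown trait {name!r}; have {self.trait_names}")
        return self.data.set_index("animal_id")[name]

    def subset(self, animal_ids) -> "PhenotypeRecords":
        keep = self.data["animal_id"].isin(set(animal_ids))
        return PhenotypeRecords(self.data.loc[keep].copy())


@dataclass
class StandardizedOtuMatrix:
    """Column-standardized OTU abundances (the B matrix).

    Each retained column has mean 0 and sample SD 1 (n-1 divisor); constant
    columns are dropped and listed in ``dropped_otus`` with a reason.
    """

    animal_ids: list
    otu_ids: list
    values: np.ndarray
    dropped_otus: list = field(default_factory=list)
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)
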
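"""Quality-control filters, OTU standardization, descriptive statistics and
cow clustering.

The filters mirror a standard rumen 16S + 50K SNP chip workflow: animals
with fewer than 50,000 reads are dropped before OTUs with a total count
below 10; genotyped individuals need a call rate of at least 80% and loci at
least 95% with a minor-allele frequency of at least 1%; animals must have
matched rumen, milk and genotype records and at most 400 days in milk.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, EmptyTableError, FitError
from .tables import GenotypeTable, OtuCountTable, PhenotypeRecords, StandardizedOtuMatrix

logger = logging.getLogger(__name__)


def filter_otus(table: OtuCountTable, min_total_count: int = 10,
                min_sample_reads: int = 50_000) -> OtuCountTable:
    """Drop low-depth animals, then low-count OTUs.

    Animals whose row total is below ``min_sample_reads`` are removed first;
    OTUs whose column total over the remaining animals is below
    ``min_total_count`` are removed second.  Removed ids are recorded on the
    returned table and logged.
    """
    row_tot = table.counts.sum(axis=1)
    keep_rows = row_tot >= min_sample_reads
    dropped_animals = [a for a, k in zip(table.animal_ids, keep_rows) if not k]
    counts = table.counts[keep_rows]
    if counts.shape[0] == 0:
        raise EmptyTableError(f"no animal reaches {min_sample_reads} reads")
    col_tot = counts.sum(axis=0)
    keep_cols = col_tot >= min_total_count
    dropped_otus = [o for o, k in zip(table.otu_ids, keep_cols) if not k]
    counts = counts[:, keep_cols]
    if counts.shape[1] == 0:
        raise EmptyTableError(f"no OTU reaches a total count of {min_total_count}")
    if dropped_animals:
        logger.info("filter_otus: removed %d animals below %d reads: %s",
                    len(dropped_animals), min_sample_reads, dropped_animals[:10])
    if dropped_otus:
        logger.info("filter_otus: removed %d OTUs below total count %d",
                    len(dropped_otus), min_total_count)
    kept_otus = [o for o, k in zip(table.otu_ids, keep_cols) if k]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {o: table.taxonomy[o] for o in kept_otus if o in table.taxonomy}
    return OtuCountTable(
        [a for a, k in zip(table.animal_ids, keep_rows) if k],
        kept_otus, counts, taxonomy=taxonomy,
        dropped_animals=dropped_animals, dropped_otus=dropped_otus,
    )


def standardize_counts(table: OtuCountTable) -> StandardizedOtuMatrix:
    """Center and scale OTU counts columnwise into the B matrix.

    Constant columns carry no signal and are dropped (recorded with reason);
    the SD uses the n−1 divisor, so BBᵀ/c later has trace n−1.
    """
    if table.n_animals < 2:
        raise ConfigurationError("standardization needs at least 2 animals")
    X = table.counts.astype(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0.0
    dropped = [(o, "zero variance") for o, k in zip(table.otu_ids, keep) if not k]
    if not keep.any():
        raise EmptyTableError("all OTU columns are constant; nothing to standardize")
    if dropped:
        logger.info("standardize_counts: dropped %d constant OTU columns", len(dropped))
    values = (X[:, keep] - means[keep]) / sds[keep]
    return StandardizedOtuMatrix(
        list(table.animal_ids),
        [o for o, k in zip(table.otu_ids, keep) if k],
        values, dropped_otus=dropped,
        column_means=means[keep], column_sds=sds[keep],
    )


def filter_genotypes(gt: GenotypeTable, min_individual_call_rate: float = 0.80,
                     min_locus_call_rate: float = 0.95,
                     min_maf: float = 0.01) -> GenotypeTable:
    """Drop individuals by call rate, then loci by call rate and MAF.

    MAF is recomputed after the individual drop, so locus decisions reflect
    the retained animals only.
    """
    keep_ind = gt.call_rate_individuals() >= min_individual_call_rate
    if not keep_ind.any():
        raise EmptyTableError(f"no individual reaches call rate {min_individual_call_rate}")
    animal_ids = [a for a, k in zip(gt.animal_ids, keep_ind) if k]
    sub = GenotypeTable(animal_ids, list(gt.snp_ids), gt.codes[keep_ind])
    keep_loci = (sub.call_rate_loci() >= min_locus_call_rate) & (sub.maf() >= min_maf)
    if not keep_loci.any():
        raise EmptyTableError(
            f"no locus survives call rate {min_locus_call_rate} and MAF {min_maf}")
    n_ind_dropped = int((~keep_ind).sum())
    n_loci_dropped = int((~keep_loci).sum())
    if n_ind_dropped or n_loci_dropped:
        logger.info("filter_genotypes: dropped %d individuals, %d loci",
                    n_ind_dropped, n_loci_dropped)
    return GenotypeTable(animal_ids,
                         [s for s, k in zip(gt.snp_ids, keep_loci) if k],
                         sub.codes[:, keep_loci])


def filter_animals(pheno: PhenotypeRecords, matched_ids,
                   max_dim: int = 400) -> PhenotypeRecords:
    """Keep animals present in every matched id set with DIM ≤ ``max_dim``.

    ``matched_ids`` is an iterable of id collections (e.g. rumen, milk and
    genotype tables); an animal must appear in all of them.
    """
    keep = pheno.data["dim"] <= max_dim
    for ids in matched_ids:
        keep &= pheno.data["animal_id"].isin(set(ids))
    if not keep.any():
        raise EmptyTableError("no animal has matched records and DIM within range")
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_animals: removed %d of %d animals", removed, len(keep))
    return PhenotypeRecords(pheno.data.loc[keep].copy())


def descriptive_stats(pheno: PhenotypeRecords) -> pd.DataFrame:
    """Per-trait mean, sample SD (n−1) and CV% over non-missing values.

    CV% = 100·SD/mean; reported as missing when the mean is zero.
    """
    rows = []
    for trait in pheno.trait_names:
        vals = pheno.data[trait].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            raise ConfigurationError(f"trait {trait!r} has fewer than 2 non-missing values")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0.0 else np.nan
        rows.append({"trait": trait, "mean": mean, "sd": sd, "cv_pct": cv})
    return pd.DataFrame(rows)


def pearson_distance(B: StandardizedOtuMatrix) -> np.ndarray:
    """Pairwise animal distances d(i,k) = 1 − Pearson r between rows of B."""
    if B.n_animals < 2:
        raise ConfigurationError("Pearson distance needs at least 2 animals")
    sds = B.values.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = B.animal_ids[int(np.argmax(sds == 0))]
        raise FitError(f"row for animal {bad!r} has zero variance; Pearson distance undefined")
    D = 1.0 - np.corrcoef(B.values)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def hierarchical_cluster(distances: np.ndarray, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns the scipy linkage matrix (merge tree with heights); complete
    linkage is the default, matching the usual hclust default.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ConfigurationError("distance matrix must be square")
    if np.abs(distances - distances.T).max(initial=0.0) > 1e-8:
        raise ConfigurationError("distance matrix must be symmetric")
    if (distances < 0).any():
        raise ConfigurationError("distance matrix must be non-negative")
    return linkage(squareform(distances, checks=False), method=method)
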
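"""Relationship kernels: genomic (G), microbial (M), and interaction (M∘G).

G follows VanRaden's first method: missing codes are mean-imputed to 2p,
columns are centered at 2p, and the cross-product is scaled by 2·Σ p(1−p)
with p the observed counted-allele frequency.  M is BBᵀ/c from the
column-standardized OTU matrix B with c OTUs, so trace(M) = n−1 under the
n−1 SD divisor.  The interaction kernel is the elementwise (Hadamard)
product of M and G, which is PSD whenever both factors are (Schur product
theorem); it is not rescaled, so its diagonal is not ~1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FitError
from .tables import GenotypeTable, StandardizedOtuMatrix

#: jitter ladder tried, in order, when a kernel fails the PSD tolerance
PSD_JITTERS = (1e-8, 1e-6, 1e-4)
PSD_TOL = -1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric n×n similarity kernel keyed by animal ids."""

    animal_ids: list
    values: np.ndarray
    kind: str  # "G" | "M" | "GxM" | "I"
    psd_adjustment: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ConfigurationError(
                f"kernel shape {self.values.shape} does not match {n} animal ids"
            )
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ConfigurationError("kernel is not symmetric")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def ensure_psd(values: np.ndarray, animal_ids, kind: str) -> RelationshipMatrix:
    """Wrap a symmetric matrix, adding the smallest ladder jitter if needed."""
    values = 0.5 * (values + values.T)  # kill numerical asymmetry
    if np.linalg.eigvalsh(values)[0] >= PSD_TOL:
        return RelationshipMatrix(animal_ids, values, kind)
    for delta in PSD_JITTERS:
        jittered = values + delta * np.eye(values.shape[0])
        if np.linalg.eigvalsh(jittered)[0] >= PSD_TOL:
            return RelationshipMatrix(animal_ids, jittered, kind, psd_adjustment=delta)
    raise FitError(f"kernel {kind!r} not positive semidefinite even after jitter {PSD_JITTERS[-1]}")


def grm_vanraden(gt: GenotypeTable) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1: ZZᵀ / (2 Σ p(1−p))."""
    p = gt.allele_freq()
    poly = ~np.isnan(p)
    p = np.where(poly, p, 0.0)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise FitError("all loci monomorphic: VanRaden denominator 2·Σp(1−p) is zero")
    codes = gt.codes.copy()
    # mean-impute missing calls to the column expectation 2p
    miss = np.isnan(codes)
    if miss.any():
        codes[miss] = np.broadcast_to(2.0 * p, codes.shape)[miss]
    Z = codes - 2.0 * p
    G = (Z @ Z.T) / denom
    return ensure_psd(G, list(gt.animal_ids), "G")


def microbial_relationship(B: StandardizedOtuMatrix) -> RelationshipMatrix:
    """Microbial relationship matrix M = BBᵀ/c with c the number of OTUs."""
    if B.n_otus < 1:
        raise ConfigurationError("standardized OTU matrix has no columns")
    M = (B.values @ B.values.T) / B.n_otus
    return ensure_psd(M, list(B.animal_ids), "M")


def hadamard_kernel(K1: RelationshipMatrix, K2: RelationshipMatrix) -> RelationshipMatrix:
    """Elementwise product of two kernels over the same animals (no rescaling)."""
    if list(K1.animal_ids) != list(K2.animal_ids):
        raise ConfigurationError("Hadamard product requires identical animal id order")
    return ensure_psd(K1.values * K2.values, list(K1.animal_ids), "GxM")


def identity_kernel(animal_ids) -> RelationshipMatrix:
    return RelationshipMatrix(list(animal_ids), np.eye(len(animal_ids)), "I")


def align_kernel(K: RelationshipMatrix, ids) -> RelationshipMatrix:
    """Subset/reorder a kernel's rows and columns to the given animal ids."""
    index = {a: i for i, a in enumerate(K.animal_ids)}
    unknown = [a for a in ids if a not in index]
    if unknown:
        raise ConfigurationError(f"animal id(s) not in kernel: {unknown[:5]}")
    pos = np.array([index[a] for a in ids], dtype=int)
    return RelationshipMatrix(list(ids), K.values[np.ix_(pos, pos)], K.kind,
                              psd_adjustment=K.psd_adjustment)
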
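"""Synthetic herd generator: genotypes, rumen OTU counts and milk traits.

The generator emulates the statistical structure the downstream analysis
assumes: Hardy–Weinberg SNP genotypes with missing-completely-at-random
calls, Dirichlet–multinomial OTU counts with a fixed top-heavy rank-abundance
pattern (few dominant taxa, strong overdispersion), and phenotypes built as

    y = μ + herd + parity + b1·DIM + b2·e^(−0.05·DIM) + g + m + g×m + e

with g ~ N(0, G σ_g²), m ~ N(0, M σ_m²), g×m ~ N(0, (M∘G) σ_gxm²) and
e ~ N(0, I σ_e²), where G and M are built from the simulated tables by the
same kernel code the analysis uses.  Component variances are set from the
target ratios per-component, i.e. σ_g² = h²_g/(1−h²_g)·σ_e² so that
σ_g²/(σ_g²+σ_e²) equals the target exactly — matching how heritability and
microbiability are later defined (each denominator excludes the other
random component).

All randomness flows from one master seed; genotypes, OTU counts,
covariates and per-trait effects each draw from deterministic child
streams, so any sub-table is reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FitError, SimulationError
from .kernels import RelationshipMatrix, grm_vanraden, hadamard_kernel, microbial_relationship
from .preprocess import standardize_counts
from .tables import GenotypeTable, OtuCountTable, PhenotypeRecords


@dataclass
class SimulationConfig:
    """Study-design and trait-architecture parameters for one synthetic herd."""

    n_animals: int = 292
    n_snps: int = 5000
    n_otus: int = 3055
    maf_range: tuple = (0.05, 0.5)
    genotype_missing_rate: float = 0.01
    library_size_range: tuple = (60_000, 150_000)
    dominance_shape: float = 1.0
    herd_count: int = 3
    parity_levels: int = 2
    dim_range: tuple = (3, 398)
    intercept: float = 4.0
    wilmink_b1: float = -0.0025
    wilmink_b2: float = 2.0
    herd_effects: tuple = (0.0, 0.25, -0.25)
    parity_effects: tuple = (0.0, 0.2)
    target_h2_g: float = 0.3
    target_h2_b: float = 0.25
    target_h2_gxm: float = 0.0
    sigma_e2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("target_h2_g", "target_h2_b", "target_h2_gxm"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if self.dominance_shape <= 0.0:
            raise ConfigurationError("dominance_shape must be positive")
        if self.sigma_e2 <= 0.0:
            raise ConfigurationError("sigma_e2 must be positive")
        if not (0.0 <= self.genotype_missing_rate <= 1.0):
            raise ConfigurationError("genotype_missing_rate must be a probability")
        if min(self.library_size_range) < 1:
            raise ConfigurationError("library sizes must be >= 1")
        if len(self.herd_effects) != self.herd_count:
            raise ConfigurationError("herd_effects length must equal herd_count")
        if len(self.parity_effects) != self.parity_levels:
            raise ConfigurationError("parity_effects length must equal parity_levels")
        if self.n_animals < 2 or self.n_otus < 2 or self.n_snps < 1:
            raise ConfigurationError("need n_animals >= 2, n_otus >= 2, n_snps >= 1")


@dataclass
class SyntheticStudy:
    """A simulated herd together with its ground-truth effect vectors."""

    config: SimulationConfig
    genotypes: GenotypeTable
    otu_counts: OtuCountTable
    phenotypes: PhenotypeRecords
    kernels: dict  # {"G": .., "M": .., "GxM": ..} RelationshipMatrix
    truth: dict  # trait -> {"g"|"m"|"gxm"|"e": per-animal vector}
    sigma2: dict  # trait -> {component: simulation variance}
    realized_variances: dict = field(default_factory=dict)  # trait -> {component: empirical var}

    def _single(self) -> str:
        if len(self.truth) != 1:
            raise ConfigurationError("study holds multiple traits; index truth by name")
        return next(iter(self.truth))

    @property
    def true_g(self) -> np.ndarray:
        return self.truth[self._single()]["g"]

    @property
    def true_m(self) -> np.ndarray:
        return self.truth[self._single()]["m"]

    @property
    def true_gxm(self) -> np.ndarray:
        return self.truth[self._single()]["gxm"]

    @property
    def true_e(self) -> np.ndarray:
        return self.truth[self._single()]["e"]


def _animal_ids(n: int) -> list:
    return [f"cow_{i + 1:04d}" for i in range(n)]


def simulate_genotypes(n_animals: int, n_snps: int, maf_range=(0.05, 0.5),
                       missing_rate: float = 0.0, seed: int = 0) -> GenotypeTable:
    """Draw Hardy–Weinberg genotypes with uniform allele frequencies.

    Each SNP's counted-allele frequency is uniform in ``maf_range``; each
    genotype is the sum of two Bernoulli(p) draws; entries are set missing
    independently with ``missing_rate``.
    """
    if n_animals < 2 or n_snps < 1:
        raise ConfigurationError("need n_animals >= 2 and n_snps >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not (0.0 <= missing_rate <= 1.0):
        raise ConfigurationError("missing_rate must be a probability")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    codes = (rng.binomial(1, p, size=(n_animals, n_snps))
             + rng.binomial(1, p, size=(n_animals, n_snps))).astype(float)
    if missing_rate > 0.0:
        codes[rng.random((n_animals, n_snps)) < missing_rate] = np.nan
    snp_ids = [f"snp_{j + 1:05d}" for j in range(n_snps)]
    return GenotypeTable(_animal_ids(n_animals), snp_ids, codes)


def simulate_otu_counts(n_animals: int, n_otus: int,
                        library_size_range=(60_000, 150_000),
                        dominance_shape: float = 1.0, seed: int = 0) -> OtuCountTable:
    """Draw Dirichlet–multinomial OTU counts with a Zipf-like base pattern.

    Per-animal compositions are Dirichlet with concentration
    α_j = 100 · dominance_shape · q_j, where q_j ∝ j^(−1/dominance_shape) is
    a fixed rank-abundance pattern shared across animals.  A small
    ``dominance_shape`` steepens the pattern (few dominant OTUs) and lowers
    the total concentration (strong between-animal overdispersion); a very
    large value gives near-uniform, tightly concentrated compositions.  The
    default (Zipf exponent 1, total concentration 100) puts ~10% of reads on
    the top OTU with a between-animal CV around 30% for dominant taxa,
    resembling a Prevotella-dominated rumen community.  Library sizes are
    uniform integers in ``library_size_range``.
    """
    if n_otus < 2 or n_animals < 1:
        raise ConfigurationError("need n_otus >= 2 and n_animals >= 1")
    if dominance_shape <= 0.0:
        raise ConfigurationError("dominance_shape must be positive")
    lo, hi = library_size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid library_size_range {library_size_range}")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n_otus + 1, dtype=float)
    q = ranks ** (-1.0 / dominance_shape)
    q /= q.sum()
    alpha = 100.0 * dominance_shape * q
    libs = rng.integers(lo, hi + 1, size=n_animals)
    counts = np.empty((n_animals, n_otus), dtype=np.int64)
    for i in range(n_animals):
        # gamma construction keeps tiny alphas numerically safe
        gam = rng.gamma(alpha)
        tot = gam.sum()
        if tot <= 0.0:  # pragma: no cover - pathological underflow
            gam[:] = q
            tot = 1.0
        counts[i] = rng.multinomial(libs[i], gam / tot)
    otu_ids = [f"otu_{j + 1:05d}" for j in range(n_otus)]
    return OtuCountTable(_animal_ids(n_animals), otu_ids, counts)


def _mvn_from_kernel(K: RelationshipMatrix, sigma2: float, rng: np.random.Generator,
                     eig_cache: dict) -> np.ndarray:
    """Sample N(0, K·σ²) via a cached eigendecomposition of K."""
    if sigma2 <= 0.0:
        return np.zeros(K.n_animals)
    if id(K) not in eig_cache:
        d, U = np.linalg.eigh(K.values)
        if d[0] < -1e-6:
            raise SimulationError(f"kernel {K.kind} is not PSD (min eigenvalue {d[0]:.2e})")
        eig_cache[id(K)] = (np.clip(d, 0.0, None), U)
    d, U = eig_cache[id(K)]
    z = rng.standard_normal(K.n_animals)
    return U @ (np.sqrt(d * sigma2) * z)


def _ratio_to_sigma2(h2: float, sigma_e2: float) -> float:
    return h2 / (1.0 - h2) * sigma_e2


def simulate_study(config: SimulationConfig, trait_targets: dict | None = None) -> SyntheticStudy:
    """Simulate a full study: tables, kernels, covariates and trait(s).

    ``trait_targets`` maps trait name -> (h²_g, h²_B, h²_gxm); by default a
    single trait named ``"trait"`` uses the config's targets.  All traits
    share the genotypes, OTU counts and covariates; effect vectors are drawn
    per trait from independent child streams.
    """
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_otu, s_cov, s_eff = ss.spawn(4)

    genotypes = simulate_genotypes(config.n_animals, config.n_snps, config.maf_range,
                                   config.genotype_missing_rate, seed=s_geno)
    otu_counts = simulate_otu_counts(config.n_animals, config.n_otus,
                                     config.library_size_range, config.dominance_shape,
                                     seed=s_otu)
    try:
        G = grm_vanraden(genotypes)
        M = microbial_relationship(standardize_counts(otu_counts))
        GxM = hadamard_kernel(M, G)
    except FitError as exc:
        raise SimulationError(str(exc)) from exc

    rng_cov = np.random.default_rng(s_cov)
    herd = rng_cov.integers(0, config.herd_count, size=config.n_animals)
    parity = rng_cov.integers(0, config.parity_levels, size=config.n_animals)
    dim = rng_cov.integers(config.dim_range[0], config.dim_range[1] + 1,
                           size=config.n_animals)
    fixed_part = (config.intercept
                  + np.asarray(config.herd_effects)[herd]
                  + np.asarray(config.parity_effects)[parity]
                  + config.wilmink_b1 * dim
                  + config.wilmink_b2 * np.exp(-0.05 * dim))

    if trait_targets is None:
        trait_targets = {"trait": (config.target_h2_g, config.target_h2_b,
                                   config.target_h2_gxm)}

    eig_cache: dict = {}
    truth: dict = {}
    sigma2: dict = {}
    realized: dict = {}
    pheno = pd.DataFrame({
        "animal_id": genotypes.animal_ids,
        "herd": [f"herd_{h + 1}" for h in herd],
        "parity": parity + 1,
        "dim": dim,
    })
    rng_eff = np.random.default_rng(s_eff)
    for trait, (h2g, h2b, h2gxm) in trait_targets.items():
        for name, v in (("h2_g", h2g), ("h2_B", h2b), ("h2_gxm", h2gxm)):
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} target for trait {trait!r} must be in [0,1)")
        s2 = {
            "g": _ratio_to_sigma2(h2g, config.sigma_e2),
            "m": _ratio_to_sigma2(h2b, config.sigma_e2),
            "gxm": _ratio_to_sigma2(h2gxm, config.sigma_e2),
            "e": config.sigma_e2,
        }
        g = _mvn_from_kernel(G, s2["g"], rng_eff, eig_cache)
        m = _mvn_from_kernel(M, s2["m"], rng_eff, eig_cache)
        gxm = _mvn_from_kernel(GxM, s2["gxm"], rng_eff, eig_cache)
        e = rng_eff.standard_normal(config.n_animals) * np.sqrt(config.sigma_e2)
        pheno[trait] = fixed_part + g + m + gxm + e
        truth[trait] = {"g": g, "m": m, "gxm": gxm, "e": e}
        sigma2[trait] = s2
        realized[trait] = {c: float(np.var(v)) for c, v in truth[trait].items()}

    return SyntheticStudy(config, genotypes, otu_counts, PhenotypeRecords(pheno),
                          {"G": G, "M": M, "GxM": GxM}, truth, sigma2, realized)
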
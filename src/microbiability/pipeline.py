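"""End-to-end orchestration: preprocess → kernels → variance components →
cross-validation → model comparison.

Every stage logs input/output dimensions and filter counts; all randomness
flows from the single config seed, and the report files are written with
fixed 10-significant-digit formatting so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import cv as cvmod
from . import io as iomod
from .errors import MicrobiabilityError
from .kernels import align_kernel, grm_vanraden, hadamard_kernel, microbial_relationship
from .preprocess import filter_animals, filter_genotypes, filter_otus, standardize_counts
from .varcomp import build_design_matrix, variance_table

logger = logging.getLogger(__name__)
_FMT = "%.10g"


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: _FMT % v)
    return out


def run_pipeline(config: iomod.RunConfig) -> dict:
    """Run the full analysis; returns a dict of output file paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed: %d", config.seed)

    try:
        otus = iomod.read_otu_table(config.otu_path)
        geno = iomod.read_genotypes(config.genotype_path)
        pheno = iomod.read_phenotypes(config.phenotype_path)
    except MicrobiabilityError as exc:
        raise MicrobiabilityError(f"[read] {exc}") from exc
    logger.info("inputs: %d animals x %d OTUs; %d animals x %d SNPs; %d phenotyped",
                otus.n_animals, otus.n_otus, geno.n_animals, geno.n_snps, pheno.n_animals)

    f = config.filters
    try:
        otus = filter_otus(otus, f["min_otu_count"], f["min_sample_reads"])
        geno = filter_genotypes(geno, f["min_individual_call_rate"],
                                f["min_locus_call_rate"], f["min_maf"])
        pheno = filter_animals(pheno, [otus.animal_ids, geno.animal_ids], f["max_dim"])
    except MicrobiabilityError as exc:
        raise MicrobiabilityError(f"[preprocess] {exc}") from exc
    ids = pheno.animal_ids
    logger.info("after QC: %d matched animals, %d OTUs, %d SNPs",
                len(ids), otus.n_otus, geno.n_snps)

    try:
        B = standardize_counts(otus)
        G = align_kernel(grm_vanraden(geno), ids)
        M = align_kernel(microbial_relationship(B), ids)
        GxM = hadamard_kernel(M, G)
    except MicrobiabilityError as exc:
        raise MicrobiabilityError(f"[kernels] {exc}") from exc
    paths = {}
    for name, K in (("G", G), ("M", M), ("GxM", GxM)):
        paths[f"kernel_{name}"] = outdir / f"kernel_{name}.tsv"
        iomod.write_kernel(K, paths[f"kernel_{name}"])

    traits = pheno.trait_names if config.traits == "all" else list(config.traits)
    try:
        vc = variance_table(pheno, G, M, traits)
    except MicrobiabilityError as exc:
        raise MicrobiabilityError(f"[varcomp] {exc}") from exc
    paths["variance_components"] = outdir / "variance_components.tsv"
    _fmt_frame(vc).to_csv(paths["variance_components"], sep="\t", index=False)
    logger.info("variance components written for %d traits", len(traits))

    X = build_design_matrix(pheno)
    kernels = {"G": G, "M": M, "GxM": GxM}
    reports = {}
    try:
        for trait in traits:
            ytilde = cvmod.adjust_phenotypes(pheno, X, trait)
            reports[trait] = cvmod.cross_validate(
                ytilde, kernels, n_val=config.cv["n_val"],
                n_reps=config.cv["n_reps"], seed=config.seed)
        comparisons = cvmod.compare_models(reports)
    except MicrobiabilityError as exc:
        raise MicrobiabilityError(f"[cv] {exc}") from exc

    rows = []
    pmap = {(r["trait"], r["pair"]): r for _, r in comparisons.iterrows()}
    for trait, rep in reports.items():
        row = {"trait": trait}
        for m in rep.pa:
            row[f"pa_{m}"] = rep.mean_pa[m]
            row[f"rmse_{m}"] = rep.mean_rmse[m]
        for pair in ("M4vsM6", "M5vsM6", "M6vsM7"):
            r = pmap[(trait, pair)]
            row[f"p_{pair}"] = r["p_one_sided"]
            row[f"sig_{pair}"] = "*" if r["significant_bonferroni"] else ""
        rows.append(row)
    paths["cv_report"] = outdir / "cv_report.tsv"
    _fmt_frame(pd.DataFrame(rows)).to_csv(paths["cv_report"], sep="\t", index=False)
    paths["comparisons"] = outdir / "comparisons.tsv"
    _fmt_frame(comparisons).to_csv(paths["comparisons"], sep="\t", index=False)

    replicate_payload = {
        trait: {"pa": rep.pa, "rmse": rep.rmse, "splits": rep.splits,
                "seed": rep.seed, "n_val": rep.n_val}
        for trait, rep in reports.items()
    }
    paths["cv_replicates"] = outdir / "cv_replicates.json"
    with open(paths["cv_replicates"], "w") as fh:
        json.dump(replicate_payload, fh, indent=1, sort_keys=True,
                  default=lambda v: round(float(v), 12))
    logger.info("cross-validation written: %d traits x %d models",
                len(reports), len(next(iter(reports.values())).pa) if reports else 0)
    return {k: str(v) for k, v in paths.items()}
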
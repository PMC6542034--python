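"""Two-step cross-validated prediction and model comparison.

Step one regresses each trait on the fixed effects only (herd, parity,
Wilmink DIM terms) and keeps the residuals ỹ.  Step two fits, per training
fold, mean + random-effect models on ỹ:

    M4: g            (genomic kernel G)
    M5: m            (microbial kernel M)
    M6: g + m
    M7: g + m + g×m  (Hadamard interaction kernel M∘G)

Validation animals' phenotypes are predicted by the conditional expectation
ŷ_val = μ̂ + Σ_k σ̂_k² K_(val,train) V_train⁻¹ (ỹ_train − 1μ̂), the GFBLUP
predictor.  Predictive ability is the Pearson correlation between ŷ and ỹ
in the validation set, averaged over replicates; models are compared with
one-sided Welch t tests (richer model tested as greater) under a Bonferroni
correction across all traits and contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FitError
from .kernels import align_kernel
from .tables import PhenotypeRecords
from .varcomp import DesignMatrix, VarianceComponentFit, intercept_design, reml_fit

#: model name -> kernels it uses (keys into the kernel dict)
DEFAULT_MODELS = {
    "M4": ("G",),
    "M5": ("M",),
    "M6": ("G", "M"),
    "M7": ("G", "M", "GxM"),
}

#: contrast name -> (richer model, baseline model); richer is the 'greater' arm
DEFAULT_CONTRASTS = {
    "M4vsM6": ("M6", "M4"),
    "M5vsM6": ("M6", "M5"),
    "M6vsM7": ("M7", "M6"),
}


@dataclass
class AdjustedPhenotype:
    """Fixed-effects-adjusted trait values (OLS residuals), no missing entries."""

    animal_ids: list
    trait: str
    values: np.ndarray

    def subset(self, ids) -> "AdjustedPhenotype":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        pos = [index[a] for a in ids]
        return AdjustedPhenotype(list(ids), self.trait, self.values[pos])

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.animal_ids, name=self.trait)


@dataclass
class CvReport:
    """Replicate-level predictive abilities and RMSEs for one trait."""

    trait: str
    pa: dict  # model -> list of replicate correlations
    rmse: dict  # model -> list of replicate RMSEs
    splits: list  # per replicate: list of validation animal ids
    seed: int
    n_val: int

    @property
    def mean_pa(self) -> dict:
        return {m: float(np.mean(v)) for m, v in self.pa.items()}

    @property
    def mean_rmse(self) -> dict:
        return {m: float(np.mean(v)) for m, v in self.rmse.items()}


def adjust_phenotypes(pheno: PhenotypeRecords, X: DesignMatrix,
                      trait: str) -> AdjustedPhenotype:
    """OLS residuals of one trait on the fixed-effects design."""
    y = pheno.trait(trait).reindex(X.animal_ids)
    keep = y.notna().to_numpy()
    ids = [a for a, k in zip(X.animal_ids, keep) if k]
    Xs = X.subset(ids)
    if len(ids) <= Xs.n_columns:
        raise FitError(f"trait {trait!r}: {len(ids)} records for {Xs.n_columns} columns")
    yv = y.to_numpy(dtype=float)[keep]
    beta, *_ = np.linalg.lstsq(Xs.values, yv, rcond=None)
    return AdjustedPhenotype(ids, trait, yv - Xs.values @ beta)


def gfblup_predict(y_train: AdjustedPhenotype, kernels,
                   fit: VarianceComponentFit, validation_ids) -> np.ndarray:
    """GFBLUP conditional-expectation prediction for validation animals.

    ``kernels`` must cover training ∪ validation ids; ``fit`` carries the
    variance components estimated on the training fold, ordered as the
    kernels (residual last).
    """
    train_ids = list(y_train.animal_ids)
    val_ids = list(validation_ids)
    sig = fit.theta()
    if len(sig) != len(kernels) + 1:
        raise ConfigurationError("fit has a different number of components than kernels")
    n_t = len(train_ids)
    V = sig[-1] * np.eye(n_t)
    K_vt_parts = []
    for s, K in zip(sig[:-1], kernels):
        Ka = align_kernel(K, train_ids + val_ids).values
        V += s * Ka[:n_t, :n_t]
        K_vt_parts.append(s * Ka[n_t:, :n_t])
    y = y_train.values
    one = np.ones(n_t)
    try:
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, one)
    except np.linalg.LinAlgError:
        V = V + 1e-8 * np.eye(n_t)
        try:
            Vinv_y = np.linalg.solve(V, y)
            Vinv_1 = np.linalg.solve(V, one)
        except np.linalg.LinAlgError as exc:
            raise FitError("training V matrix singular even after jitter") from exc
    mu = float(one @ Vinv_y) / float(one @ Vinv_1)
    alpha = np.linalg.solve(V, y - mu * one)
    pred = mu * np.ones(len(val_ids))
    for K_vt in K_vt_parts:
        pred += K_vt @ alpha
    return pred


def _pearson_pa(pred: np.ndarray, obs: np.ndarray) -> float:
    # predictions varying only at the variance-bound scale are numerically
    # constant; correlating them with obs would return pure noise
    if np.std(pred) <= 1e-8 * max(np.std(obs), 1e-300) or np.std(obs) == 0.0:
        warnings.warn("constant predictions in a replicate; PA recorded as 0",
                      stacklevel=3)
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def draw_splits(animal_ids, n_val: int, n_reps: int, seed: int) -> list:
    """Reproducible validation sets: uniform without replacement per replicate."""
    ids = list(animal_ids)
    if n_val >= len(ids):
        raise ConfigurationError(
            f"n_val={n_val} must be smaller than the {len(ids)} available animals")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_reps):
        take = rng.choice(len(ids), size=n_val, replace=False)
        splits.append([ids[i] for i in sorted(take)])
    return splits


def cross_validate(ytilde: AdjustedPhenotype, kernels: dict, n_val: int = 50,
                   n_reps: int = 10, seed: int = 0, models: dict | None = None,
                   splits: list | None = None) -> CvReport:
    """Repeated random-split cross-validation of the kernel models.

    Variance components are re-estimated on every training fold (mean-only
    design).  Splits derive from ``seed`` alone, so runs on different traits
    or models with the same seed and animal set share identical folds.
    """
    if models is None:
        models = DEFAULT_MODELS
    missing = {k for names in models.values() for k in names} - set(kernels)
    if missing:
        raise ConfigurationError(f"kernel(s) {sorted(missing)} required by models but absent")
    if splits is None:
        splits = draw_splits(ytilde.animal_ids, n_val, n_reps, seed)
    pa = {m: [] for m in models}
    rmse = {m: [] for m in models}
    all_ids = set(ytilde.animal_ids)
    for val_ids in splits:
        train_ids = [a for a in ytilde.animal_ids if a not in set(val_ids)]
        assert set(val_ids) | set(train_ids) == all_ids
        y_tr = ytilde.subset(train_ids)
        y_va = ytilde.subset(val_ids)
        X_tr = intercept_design(train_ids)
        for model, kernel_names in models.items():
            Ks = [kernels[k] for k in kernel_names]
            fit = reml_fit(y_tr.series(), X_tr, Ks)
            pred = gfblup_predict(y_tr, Ks, fit, val_ids)
            pa[model].append(_pearson_pa(pred, y_va.values))
            rmse[model].append(float(np.sqrt(np.mean((pred - y_va.values) ** 2))))
    return CvReport(ytilde.trait, pa, rmse, splits, seed, len(splits[0]))


def welch_t(a, b, alternative: str = "greater"):
    """Welch's unequal-variance t test of mean(a) vs mean(b).

    Returns ``(t, dof, p)`` with Welch–Satterthwaite degrees of freedom and
    a one-sided p-value for mean(a) > mean(b) by default.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("Welch test needs at least 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ConfigurationError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_models(reports: dict, alpha: float = 0.05,
                   contrasts: dict | None = None) -> pd.DataFrame:
    """Pairwise model contrasts across traits with Bonferroni control.

    ``reports`` maps trait -> CvReport.  Each contrast tests one-sided
    whether the richer model's replicate PAs exceed the baseline's; the
    Bonferroni denominator is the total number of tests over all traits and
    contrasts (e.g. 19 traits × 3 contrasts = 57), and significance uses
    the strict inequality p < alpha/n.
    """
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    rows = []
    n_comparisons = len(reports) * len(contrasts)
    threshold = alpha / n_comparisons
    for trait, report in reports.items():
        for pair, (richer, baseline) in contrasts.items():
            for m in (richer, baseline):
                if m not in report.pa:
                    raise ConfigurationError(f"model {m!r} missing from report for {trait!r}")
            t, dof, p = welch_t(report.pa[richer], report.pa[baseline])
            rows.append({
                "trait": trait, "pair": pair,
                "t_statistic": t, "dof": dof, "p_one_sided": p,
                "significant_bonferroni": bool(p < threshold),
            })
    out = pd.DataFrame(rows)
    out.attrs["n_comparisons"] = n_comparisons
    out.attrs["threshold"] = threshold
    return out
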
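"""REML variance components, heritability and microbiability.

The single-kernel animal models are

    y = Xβ + g + e,   g ~ N(0, G σ_g²),  e ~ N(0, I σ_e²)      (genomic)
    y = Xβ + m + e,   m ~ N(0, M σ_m²),  e ~ N(0, I σ_e²)      (microbial)

with fixed effects X = [intercept | herd | parity | DIM | e^(−0.05·DIM)]
(Wilmink lactation-curve adjustment).  The ratios are defined per model:
h²_g = σ_g²/(σ_g²+σ_e²) and h²_B = σ_m²/(σ_m²+σ_e²) — "microbiability".
The two models are fitted separately; a joint G+M fit is available through
the generic multi-kernel interface but is not used for the headline ratios.

Estimation is average-information (AI) REML: Newton-type steps using the AI
approximation to the Hessian, projected onto the feasible region
(variances ≥ 1e−9), with step-halving and an EM-REML fallback so the
restricted log-likelihood never decreases across accepted iterations.
Ratio standard errors come from the delta method on the inverse AI matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import ConfigurationError, FitError
from .kernels import RelationshipMatrix, align_kernel
from .tables import PhenotypeRecords

logger = logging.getLogger(__name__)

#: lower bound for every variance component (keeps V invertible)
VARIANCE_BOUND = 1e-9
WILMINK_RATE = -0.05


@dataclass
class DesignMatrix:
    """Fixed-effects design: intercept, herd/parity contrasts, Wilmink terms."""

    animal_ids: list
    column_names: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.animal_ids), len(self.column_names)):
            raise ConfigurationError("design matrix shape mismatch")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise FitError("design matrix is rank deficient "
                           "(empty factor level or collinear columns)")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def subset(self, ids) -> "DesignMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        pos = [index[a] for a in ids]
        return DesignMatrix(list(ids), list(self.column_names), self.values[pos])


def build_design_matrix(pheno: PhenotypeRecords) -> DesignMatrix:
    """Intercept + treatment contrasts for herd and parity + DIM + e^(−0.05·DIM)."""
    df = pheno.data
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in ("herd", "parity"):
        levels = sorted(df[factor].unique(), key=str)
        for lev in levels[1:]:
            cols.append((df[factor] == lev).to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]")
    dim = df["dim"].to_numpy(dtype=float)
    cols.append(dim)
    names.append("dim_linear")
    cols.append(np.exp(WILMINK_RATE * dim))
    names.append("dim_wilmink")
    return DesignMatrix(list(df["animal_id"]), names, np.column_stack(cols))


def intercept_design(animal_ids) -> DesignMatrix:
    """Mean-only design, used by the second-step prediction models."""
    return DesignMatrix(list(animal_ids), ["intercept"], np.ones((len(animal_ids), 1)))


@dataclass
class VarianceComponentFit:
    """REML estimates for one trait: per-kernel variances plus residual."""

    component_names: list  # kernel components, then "residual" last
    sigma2: dict
    ai_matrix: np.ndarray
    loglik_reml: float
    converged: bool
    n_iterations: int
    boundary_flags: dict = field(default_factory=dict)
    animal_ids: list = field(default_factory=list)

    def theta(self) -> np.ndarray:
        return np.array([self.sigma2[c] for c in self.component_names])


@dataclass
class RatioEstimate:
    """A variance ratio σ_c²/(σ_c²+σ_e²) with its delta-method SE."""

    name: str
    value: float
    se: float


def _component_names(kernels) -> list:
    names, seen = [], {}
    for K in kernels:
        base = K.kind
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}{seen[base]}")
    return names + ["residual"]


class _RemlWorkspace:
    """Aligned y/X/kernels plus the likelihood/score/AI evaluations."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Ks: list):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.Vcomps = Ks + [np.eye(self.n)]

    def evaluate(self, theta: np.ndarray):
        """Restricted log-likelihood, score vector and AI matrix at theta."""
        n, p = self.n, self.p
        V = sum(t * K for t, K in zip(theta, self.Vcomps))
        try:
            cho = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - bound prevents this
            raise FitError(f"V singular at theta={theta}") from exc
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        Vinv = cho_solve(cho, np.eye(n))
        VinvX = Vinv @ self.X
        XtViX = self.X.T @ VinvX
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise FitError("XᵀV⁻¹X not positive definite (singular design)")
        P = Vinv - VinvX @ np.linalg.solve(XtViX, VinvX.T)
        Py = P @ self.y
        ll = -0.5 * (logdet_V + logdet_X + float(self.y @ Py))
        k = len(self.Vcomps)
        score = np.empty(k)
        u = []  # K_i P y
        for i, K in enumerate(self.Vcomps):
            KPy = K @ Py
            u.append(KPy)
            # tr(P K) via elementwise sum: both symmetric
            score[i] = -0.5 * (float(np.sum(P * K)) - float(Py @ KPy))
        U = np.column_stack(u)
        AI = 0.5 * (U.T @ P @ U)
        return ll, score, AI, P, Py

    def loglik(self, theta: np.ndarray) -> float:
        return self.evaluate(theta)[0]


def _em_step(theta, P, Py, Vcomps, n):
    new = theta.copy()
    for i, K in enumerate(Vcomps):
        KPy = K @ Py
        new[i] = theta[i] + theta[i] ** 2 * (float(Py @ KPy) - float(np.sum(P * K))) / n
    return np.clip(new, VARIANCE_BOUND, None)


def reml_fit(y, X: DesignMatrix, kernels, max_iter: int = 200,
             tol: float = 1e-8) -> VarianceComponentFit:
    """AI-REML fit of one or more variance components plus a residual.

    ``y`` is a pandas Series indexed by animal id (or an array aligned with
    ``X.animal_ids``); animals with missing phenotype are dropped from all
    inputs before fitting.  Returns estimates bounded below at 1e−9, the AI
    matrix at the optimum, and per-component boundary flags.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(X.animal_ids)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        if yv.shape[0] != len(X.animal_ids):
            raise ConfigurationError("y length does not match design matrix")
    keep = ~np.isnan(yv)
    ids = [a for a, k in zip(X.animal_ids, keep) if k]
    if len(ids) <= X.n_columns:
        raise FitError(f"only {len(ids)} records for {X.n_columns} fixed effects")
    yv = yv[keep]
    Xs = X.subset(ids)
    Ks = [align_kernel(K, ids).values for K in kernels]
    names = _component_names(kernels)

    ws = _RemlWorkspace(yv, Xs.values, Ks)
    # start: residual variance of the fixed-effects fit, split evenly
    beta, *_ = np.linalg.lstsq(Xs.values, yv, rcond=None)
    resid = yv - Xs.values @ beta
    total = max(float(resid @ resid) / max(len(yv) - Xs.n_columns, 1), 10 * VARIANCE_BOUND)
    theta = np.full(len(Ks) + 1, total / (len(Ks) + 1))

    ll, score, AI, P, Py = ws.evaluate(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        accepted = None
        # active set: components pinned at the bound with a negative score
        # would drag the AI direction downhill once clipped, so they are
        # held fixed and the Newton system is solved for the rest
        active = (theta > VARIANCE_BOUND * (1.0 + 1e-3)) | (score > 0.0)
        delta = None
        if active.any():
            try:
                sub = np.ix_(active, active)
                delta = np.zeros(len(theta))
                delta[active] = np.linalg.solve(
                    AI[sub] + 1e-12 * np.eye(int(active.sum())), score[active])
            except np.linalg.LinAlgError:
                delta = None
        if delta is not None:
            step = 1.0
            for _ in range(11):  # full step + up to 10 halvings
                prop = np.clip(theta + step * delta, VARIANCE_BOUND, None)
                try:
                    res = ws.evaluate(prop)
                except FitError:
                    step *= 0.5
                    continue
                if res[0] >= ll - 1e-10:
                    accepted = (prop, res)
                    break
                step *= 0.5
        if accepted is None:
            prop = _em_step(theta, P, Py, ws.Vcomps, ws.n)
            accepted = (prop, ws.evaluate(prop))
        new_theta, (ll, score, AI, P, Py) = accepted
        # relative change, with the denominator floored at a small fraction of
        # the total-variance scale so components pinned at the bound cannot
        # keep the fit "unconverged" by sub-noise wiggles around 1e-9
        scale = max(float(np.sum(new_theta)) * 1e-6, VARIANCE_BOUND)
        rel = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), scale))
        theta = new_theta
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations", stacklevel=2)
    if np.linalg.cond(AI) > 1e10:
        warnings.warn(
            "AI matrix nearly singular at the optimum: variance components are "
            "weakly identified (flat restricted likelihood, e.g. a kernel "
            "proportional to the identity)", stacklevel=2)

    sigma2 = dict(zip(names, map(float, theta)))
    # a component counts as "at the boundary" when it is numerically
    # negligible against the total variance (covers near-zero estimates such
    # as 1e-7 on a unit-variance trait, not only exact hits of the bound)
    near_zero = max(10.0 * VARIANCE_BOUND, 1e-6 * float(np.sum(theta)))
    flags = {c: bool(v <= near_zero) for c, v in sigma2.items()}
    if all(flags[c] for c in names[:-1]) and len(names) > 1:
        logger.debug("all non-residual components at the boundary")
    return VarianceComponentFit(names, sigma2, AI, float(ll), converged, it,
                                boundary_flags=flags, animal_ids=ids)


def variance_ratio(fit: VarianceComponentFit, component: str) -> RatioEstimate:
    """h² = σ_c²/(σ_c²+σ_e²) with delta-method SE from the inverse AI matrix."""
    if component not in fit.sigma2:
        raise ConfigurationError(f"component {component!r} not in fit {fit.component_names}")
    sc = fit.sigma2[component]
    se2 = fit.sigma2["residual"]
    denom = sc + se2
    if denom <= 0.0:
        raise FitError("σ_c² + σ_e² is zero; ratio undefined")
    value = sc / denom
    grad = np.zeros(len(fit.component_names))
    ic = fit.component_names.index(component)
    ie = fit.component_names.index("residual")
    grad[ic] = se2 / denom ** 2
    grad[ie] = -sc / denom ** 2
    try:
        cov = np.linalg.pinv(fit.ai_matrix)
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = float("nan")
    return RatioEstimate("h2_g" if component == "G" else
                         "h2_B" if component == "M" else f"ratio_{component}",
                         float(value), se)


def profile_reml_oracle(y, X: DesignMatrix, kernel: RelationshipMatrix,
                        ratio_grid=None, refine: bool = True):
    """Profile-REML over the single ratio λ = σ_k²/σ_e² (test oracle).

    Evaluates the restricted likelihood profiled over β and the scale σ_e²
    on a λ grid (default 10^(−4..4)), optionally refining the argmax by
    golden-section search between its grid neighbours.  Returns
    ``(best_lambda, curve)`` where ``curve`` is a DataFrame with columns
    ``lam`` and ``loglik``.
    """
    if ratio_grid is None:
        ratio_grid = np.logspace(-4, 4, 161)
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    if isinstance(y, pd.Series):
        y = y.reindex(X.animal_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    ids = [a for a, k in zip(X.animal_ids, keep) if k]
    y = y[keep]
    Xs = X.subset(ids)
    K = align_kernel(kernel, ids).values
    n, p = Xs.values.shape

    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ Xs.values

    def ll(lam: float) -> float:
        w = 1.0 / (lam * d + 1.0)  # diag of (λK+I)^{-1} in the eigenbasis
        XtWX = Xt.T @ (w[:, None] * Xt)
        XtWy = Xt.T @ (w * yt)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        quad = float(r @ (w * r))
        sign, logdet_X = np.linalg.slogdet(XtWX)
        logdet_W = float(np.sum(np.log(lam * d + 1.0)))
        s2 = quad / (n - p)
        return -0.5 * ((n - p) * np.log(s2) + logdet_W + logdet_X + (n - p))

    lls = np.array([ll(lam) for lam in ratio_grid])
    i = int(np.argmax(lls))
    best = ratio_grid[i]
    if refine and 0 < i < len(ratio_grid) - 1:
        from scipy.optimize import minimize_scalar
        lo, hi = np.log(ratio_grid[i - 1]), np.log(ratio_grid[i + 1])
        res = minimize_scalar(lambda t: -ll(float(np.exp(t))), bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-10})
        best = float(np.exp(res.x))
    curve = pd.DataFrame({"lam": ratio_grid, "loglik": lls})
    return float(best), curve


def variance_table(pheno: PhenotypeRecords, G: RelationshipMatrix,
                   M: RelationshipMatrix, traits=None) -> pd.DataFrame:
    """Per-trait h²_g and h²_B with SEs, fitting the two models separately.

    Produces one row per trait: trait, h2_g, se_g, h2_B, se_B and boundary
    flags — the shape of a variance-partitioning summary table.
    """
    if traits is None:
        traits = pheno.trait_names
    X = build_design_matrix(pheno)
    rows = []
    for trait in traits:
        y = pheno.trait(trait)
        fit_g = reml_fit(y, X, [G])
        fit_m = reml_fit(y, X, [M])
        rg = variance_ratio(fit_g, "G")
        rm = variance_ratio(fit_m, "M")
        rows.append({
            "trait": trait,
            "h2_g": rg.value, "se_g": rg.se,
            "h2_B": rm.value, "se_B": rm.se,
            "boundary_g": fit_g.boundary_flags["G"],
            "boundary_B": fit_m.boundary_flags["M"],
        })
    return pd.DataFrame(rows)
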
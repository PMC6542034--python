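"""Phenotype adjustment, GFBLUP prediction, cross-validation, Welch tests."""

import numpy as np
import pandas as pd
import pytest

import microbiability as mb
from microbiability.cv import CvReport, draw_splits
from microbiability.errors import ConfigurationError
from microbiability.varcomp import VarianceComponentFit


def make_fit(components, sigma2):
    names = list(components) + ["residual"]
    return VarianceComponentFit(names, dict(zip(names, sigma2)),
                                np.eye(len(names)), 0.0, True, 1,
                                {c: False for c in names})


class TestAdjustPhenotypes:
    def test_exact_linear_combination_gives_zero_residuals(self, small_study):
        st = small_study
        X = mb.build_design_matrix(st.phenotypes)
        ph = mb.PhenotypeRecords(st.phenotypes.data.copy())
        ph.data["lin"] = X.values @ np.arange(X.n_columns, dtype=float)
        out = mb.adjust_phenotypes(ph, X, "lin")
        assert np.abs(out.values).max() < 1e-8

    def test_constant_absorbed_by_intercept(self, small_study):
        st = small_study
        X = mb.build_design_matrix(st.phenotypes)
        ph = mb.PhenotypeRecords(st.phenotypes.data.copy())
        ph.data["const"] = 7.5
        out = mb.adjust_phenotypes(ph, X, "const")
        assert np.abs(out.values).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, small_study):
        st = small_study
        X = mb.build_design_matrix(st.phenotypes)
        out = mb.adjust_phenotypes(st.phenotypes, X, "trait")
        assert abs(out.values.mean()) < 1e-10
        assert np.abs(X.values.T @ out.values).max() < 1e-8


class TestGfblupPredict:
    def test_zero_variances_predict_the_mean(self, small_study):
        st = small_study
        ids = st.phenotypes.animal_ids
        train, val = ids[:80], ids[80:]
        y = mb.AdjustedPhenotype(train, "t", np.linspace(-1, 1, 80) + 0.3)
        fit = make_fit(["G"], [0.0, 1.0])
        pred = mb.gfblup_predict(y, [st.kernels["G"]], fit, val)
        mu = y.values.mean()  # GLS mean under V = sigma_e^2 I is the plain mean
        np.testing.assert_allclose(pred, mu, atol=1e-10)

    def test_duplicate_kernel_row_recovers_training_phenotype(self):
        # validation animal identical to training animal a0 in the kernel;
        # as sigma_e -> 0 the prediction converges to a0's phenotype
        B = np.array([[1.0, -1.0, 0.5], [-0.5, 1.0, -1.0], [1.0, -1.0, 0.5]])
        K = mb.RelationshipMatrix(["a0", "a1", "v0"], (B @ B.T) / 3 + 1e-9 * np.eye(3), "M")
        y = mb.AdjustedPhenotype(["a0", "a1"], "t", np.array([1.7, -0.9]))
        fit = make_fit(["M"], [1.0, 1e-9])
        pred = mb.gfblup_predict(y, [K], fit, ["v0"])
        assert pred[0] == pytest.approx(1.7, abs=1e-3)

    def test_matches_hand_inverted_two_by_two(self):
        # 2 train + 1 validation, worked with an explicit 2x2 inverse
        K = np.array([[1.0, 0.2, 0.6], [0.2, 1.0, -0.1], [0.6, -0.1, 1.0]])
        kern = mb.RelationshipMatrix(["t1", "t2", "v"], K, "G")
        s2g, s2e = 0.8, 0.5
        y = np.array([0.9, -0.4])
        V = s2g * K[:2, :2] + s2e * np.eye(2)
        a, b, c, d = V[0, 0], V[0, 1], V[1, 0], V[1, 1]
        Vinv = np.array([[d, -b], [-c, a]]) / (a * d - b * c)
        one = np.ones(2)
        mu = (one @ Vinv @ y) / (one @ Vinv @ one)
        expect = mu + s2g * K[2, :2] @ Vinv @ (y - mu * one)
        fit = make_fit(["G"], [s2g, s2e])
        pred = mb.gfblup_predict(mb.AdjustedPhenotype(["t1", "t2"], "t", y),
                                 [kern], fit, ["v"])
        assert pred[0] == pytest.approx(expect, abs=1e-12)


class TestCrossValidate:
    def test_splits_reproducible_disjoint_and_exhaustive(self):
        ids = [f"a{i}" for i in range(292)]
        s1 = draw_splits(ids, 50, 10, seed=3)
        s2 = draw_splits(ids, 50, 10, seed=3)
        assert s1 == s2
        for val in s1:
            assert len(val) == 50 and len(set(val)) == 50
            assert set(val) <= set(ids)

    def test_full_validation_set_rejected(self, small_study):
        st = small_study
        X = mb.build_design_matrix(st.phenotypes)
        yt = mb.adjust_phenotypes(st.phenotypes, X, "trait")
        with pytest.raises(ConfigurationError):
            mb.cross_validate(yt, st.kernels, n_val=100, n_reps=2, seed=0)

    def test_signal_beats_destroyed_signal(self):
        # ytilde equal to the true genetic values: the real G must predict
        # better than a permuted (signal-destroyed) G on nearly every split.
        # A low-rank G (few markers) makes genetic values predictable across
        # folds, so the contrast is sharp.
        gt = mb.simulate_genotypes(100, 40, seed=17)
        G = mb.grm_vanraden(gt)
        ids = list(gt.animal_ids)
        d, U = np.linalg.eigh(G.values)
        rng = np.random.default_rng(9)
        g = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(100))
        yt = mb.AdjustedPhenotype(ids, "g_true", g - g.mean())
        perm = rng.permutation(len(ids))
        Gp = mb.RelationshipMatrix([ids[i] for i in perm], G.values, "G")
        kernels = {"G": G, "Gperm": mb.align_kernel(Gp, ids)}
        rep = mb.cross_validate(yt, kernels, n_val=25, n_reps=10, seed=11,
                                models={"real": ("G",), "permuted": ("Gperm",)})
        wins = sum(r > p for r, p in zip(rep.pa["real"], rep.pa["permuted"]))
        assert wins >= 9

    def test_rmse_of_mean_predictor_equals_validation_sd(self, small_study):
        st = small_study
        ids = st.phenotypes.animal_ids
        train, val = ids[:80], ids[80:]
        X = mb.build_design_matrix(st.phenotypes)
        yt = mb.adjust_phenotypes(st.phenotypes, X, "trait")
        y_tr, y_va = yt.subset(train), yt.subset(val)
        fit = make_fit(["G"], [0.0, 1.0])
        pred = mb.gfblup_predict(y_tr, [st.kernels["G"]], fit, val)
        rmse = np.sqrt(np.mean((pred - y_va.values) ** 2))
        mu = y_tr.values.mean()
        assert rmse == pytest.approx(np.sqrt(np.mean((y_va.values - mu) ** 2)), abs=1e-10)


class TestWelchT:
    def test_identical_samples(self):
        t, dof, p = mb.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_direction(self):
        _, _, p = mb.welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p > 0.99

    def test_matches_textbook_formulas(self):
        a = np.array([0.30, 0.35, 0.40, 0.32, 0.38])
        b = np.array([0.10, 0.15, 0.12, 0.11, 0.14])
        t, dof, p = mb.welch_t(a, b)
        # independent hand computation of the Welch statistic and dof
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof_hand = (va + vb) ** 2 / (va ** 2 / 4 + vb ** 2 / 4)
        from scipy.stats import t as tdist
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert dof == pytest.approx(dof_hand, rel=1e-12)
        assert p == pytest.approx(tdist.sf(t_hand, dof_hand), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            mb.welch_t([1.0, 1.0], [2.0, 2.0])


class TestCompareModels:
    def _report(self, trait, rng):
        pa = {m: list(rng.normal(0.2, 0.05, 10)) for m in ("M4", "M5", "M6", "M7")}
        rmse = {m: list(rng.uniform(0.5, 1.0, 10)) for m in pa}
        return CvReport(trait, pa, rmse, [[f"v{i}"] for i in range(10)], 0, 1)

    def test_nineteen_traits_give_57_comparisons(self, rng):
        reports = {f"trait{i}": self._report(f"trait{i}", rng) for i in range(19)}
        out = mb.compare_models(reports)
        assert len(out) == 57
        assert out.attrs["n_comparisons"] == 57
        assert out.attrs["threshold"] == pytest.approx(0.05 / 57)

    def test_single_trait_threshold(self, rng):
        out = mb.compare_models({"t": self._report("t", rng)})
        assert len(out) == 3
        assert out.attrs["threshold"] == pytest.approx(0.05 / 3)

    def test_significance_is_strict_inequality(self, rng):
        out = mb.compare_models({f"t{i}": self._report(f"t{i}", rng) for i in range(19)})
        thr = out.attrs["threshold"]
        assert (out["significant_bonferroni"] == (out["p_one_sided"] < thr)).all()

    def test_missing_model_rejected(self, rng):
        rep = self._report("t", rng)
        del rep.pa["M7"]
        with pytest.raises(ConfigurationError):
            mb.compare_models({"t": rep})
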
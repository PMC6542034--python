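"""QC filters, standardization, descriptive statistics and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import microbiability as mb
from microbiability.errors import ConfigurationError, EmptyTableError, FitError
from conftest import random_otu_table


def otu_table(counts, **kw):
    counts = np.asarray(counts)
    return mb.OtuCountTable([f"a{i}" for i in range(counts.shape[0])],
                            [f"o{j}" for j in range(counts.shape[1])], counts, **kw)


class TestFilterOtus:
    def test_otu_total_threshold_is_strict_below(self):
        # column totals 9 and 10 with ample per-animal depth
        counts = np.array([[5, 5, 100_000], [4, 5, 100_000]])
        out = mb.filter_otus(otu_table(counts), min_total_count=10, min_sample_reads=0)
        assert out.otu_ids == ["o1", "o2"]
        assert out.dropped_otus == ["o0"]

    def test_sample_read_threshold_is_strict_below(self):
        counts = np.array([[49_999], [50_000]])
        out = mb.filter_otus(otu_table(counts), min_total_count=0)
        assert out.animal_ids == ["a1"]
        assert out.dropped_animals == ["a0"]

    def test_all_zero_table_errors(self):
        with pytest.raises(EmptyTableError):
            mb.filter_otus(otu_table(np.zeros((3, 3), dtype=int)))

    def test_idempotent(self, rng):
        # thresholds realistically small next to library sizes, so the reads
        # removed with low-count OTUs cannot push an animal below the cutoff
        tab = random_otu_table(rng, n=8, c=40, low=0, high=60)
        tab.counts[:, :5] = rng.integers(0, 2, size=(8, 5))  # rare OTUs
        tab = mb.OtuCountTable(tab.animal_ids, tab.otu_ids, tab.counts)
        once = mb.filter_otus(tab, min_total_count=10, min_sample_reads=900)
        twice = mb.filter_otus(once, min_total_count=10, min_sample_reads=900)
        np.testing.assert_array_equal(once.counts, twice.counts)
        assert once.otu_ids == twice.otu_ids and once.animal_ids == twice.animal_ids


class TestStandardizeCounts:
    def test_two_point_column(self):
        B = mb.standardize_counts(otu_table([[0], [10]]))
        np.testing.assert_allclose(B.values[:, 0], [-0.7071067811865476, 0.7071067811865476])

    def test_constant_column_dropped_and_logged(self):
        B = mb.standardize_counts(otu_table([[5, 1], [5, 3], [5, 9]]))
        assert B.otu_ids == ["o1"]
        assert B.dropped_otus == [("o0", "zero variance")]

    def test_columns_standardized(self, rng):
        tab = random_otu_table(rng, n=6, c=8, high=40)
        B = mb.standardize_counts(tab)
        assert np.abs(B.values.mean(axis=0)).max() < 1e-12
        assert np.abs(B.values.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_round_trip_reconstruction(self, rng):
        tab = random_otu_table(rng, n=7, c=5, high=25)
        B = mb.standardize_counts(tab)
        rebuilt = B.values * B.column_sds + B.column_means
        kept = [tab.otu_ids.index(o) for o in B.otu_ids]
        np.testing.assert_allclose(rebuilt, tab.counts[:, kept].astype(float), atol=1e-10)

    def test_all_constant_errors(self):
        with pytest.raises(EmptyTableError):
            mb.standardize_counts(otu_table([[3, 3], [3, 3]]))


class TestFilterGenotypes:
    def _table(self, codes):
        codes = np.asarray(codes, dtype=float)
        return mb.GenotypeTable([f"a{i}" for i in range(codes.shape[0])],
                                [f"s{j}" for j in range(codes.shape[1])], codes)

    def test_locus_call_rate_threshold(self):
        # 100 animals x 22 loci; missing calls spread so individual call
        # rates stay above 80%.  Locus s20 at 94% is removed, s21 at 95% kept.
        codes = np.ones((100, 22))
        codes[:6, 20] = np.nan   # 94% call rate
        codes[6:11, 21] = np.nan  # 95% call rate
        out = mb.filter_genotypes(self._table(codes), min_maf=0.0)
        assert "s20" not in out.snp_ids and "s21" in out.snp_ids

    def test_maf_threshold(self):
        n = 1000
        codes = np.zeros((n, 2))
        codes[:9, 0] = 1.0   # MAF 0.0045 -> removed
        codes[:60, 1] = 1.0  # MAF 0.03  -> kept
        out = mb.filter_genotypes(self._table(codes))
        assert out.snp_ids == ["s1"]

    def test_individual_call_rate_before_loci(self):
        codes = np.tile([0.0, 1.0, 2.0, 1.0], (10, 1))
        codes[0, :3] = np.nan  # 25% call rate individual -> dropped first
        out = mb.filter_genotypes(self._table(codes), min_maf=0.0)
        assert "a0" not in out.animal_ids
        assert out.n_snps == 4  # loci fully observed after the drop

    def test_clean_table_passes_through(self, rng):
        codes = rng.integers(0, 3, size=(12, 6)).astype(float)
        codes[:, 0] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2]
        tab = self._table(codes)
        out = mb.filter_genotypes(tab)
        if out.n_snps == tab.n_snps:  # only if all MAFs clear 1%
            np.testing.assert_array_equal(out.codes, tab.codes)


class TestFilterAnimals:
    def _pheno(self, dims):
        return mb.PhenotypeRecords(pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(len(dims))],
            "herd": "h1", "parity": 1, "dim": dims,
            "fat_pct": np.linspace(3, 5, len(dims)),
        }))

    def test_dim_boundary(self):
        ph = self._pheno([400, 401])
        out = mb.filter_animals(ph, [["a0", "a1"]])
        assert out.animal_ids == ["a0"]

    def test_unmatched_id_removed(self):
        ph = self._pheno([100, 100])
        out = mb.filter_animals(ph, [["a0", "a1"], ["a1"]])
        assert out.animal_ids == ["a1"]

    def test_identity_when_all_matched(self):
        ph = self._pheno([100, 200])
        out = mb.filter_animals(ph, [["a0", "a1"]])
        assert out.animal_ids == ph.animal_ids

    def test_empty_intersection_errors(self):
        with pytest.raises(EmptyTableError):
            mb.filter_animals(self._pheno([100]), [["zz"]])


class TestDescriptiveStats:
    def _pheno(self, **traits):
        n = len(next(iter(traits.values())))
        df = pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                           "herd": "h1", "parity": 1, "dim": 100})
        for k, v in traits.items():
            df[k] = v
        return mb.PhenotypeRecords(df)

    def test_two_point_arithmetic(self):
        out = mb.descriptive_stats(self._pheno(t=[1.0, 3.0]))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0))
        assert row["cv_pct"] == pytest.approx(70.71067811865476)

    def test_zero_sd_gives_zero_cv(self):
        out = mb.descriptive_stats(self._pheno(t=[4.0, 4.0, 4.0]))
        assert out.iloc[0]["cv_pct"] == 0.0

    def test_zero_mean_cv_missing(self):
        out = mb.descriptive_stats(self._pheno(t=[-1.0, 1.0]))
        assert np.isnan(out.iloc[0]["cv_pct"])

    def test_cv_from_unrounded_values(self):
        # CV recomputed from the data, not from rounded mean/SD
        vals = np.array([4.0, 3.2, 4.8, 5.1, 2.9])
        out = mb.descriptive_stats(self._pheno(t=vals))
        assert out.iloc[0]["cv_pct"] == pytest.approx(
            100 * vals.std(ddof=1) / vals.mean())


class TestPearsonDistance:
    def _B(self, values):
        values = np.asarray(values, dtype=float)
        return mb.StandardizedOtuMatrix([f"a{i}" for i in range(values.shape[0])],
                                        [f"o{j}" for j in range(values.shape[1])], values)

    def test_identical_rows_distance_zero(self):
        D = mb.pearson_distance(self._B([[1, 2, 3], [1, 2, 3]]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_row_distance_two(self):
        D = mb.pearson_distance(self._B([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]]))
        assert D[0, 1] == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        vals = rng.normal(size=(5, 20))
        D = mb.pearson_distance(self._B(vals))
        for i in range(5):
            for k in range(5):
                r = np.corrcoef(vals[i], vals[k])[0, 1]
                assert D[i, k] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_row_named_in_error(self):
        with pytest.raises(FitError, match="a1"):
            mb.pearson_distance(self._B([[1.0, 2.0], [5.0, 5.0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(float, (4, 6), elements=st.floats(-50, 50)))
    def test_distances_in_zero_two(self, vals):
        vals = vals + np.arange(6) * 1e-3  # avoid exactly-constant rows
        if np.any(vals.std(axis=1) == 0):
            return
        D = mb.pearson_distance(self._B(vals))
        assert (D > -1e-12).all() and (D < 2 + 1e-12).all()


class TestHierarchicalCluster:
    def test_nearest_pair_merges_first(self):
        D = np.full((3, 3), 1.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        Z = mb.hierarchical_cluster(D)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.1)

    def test_two_points(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        Z = mb.hierarchical_cluster(D)
        assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(0.7)

    def test_complete_linkage_heights_monotone(self, rng):
        X = rng.normal(size=(8, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        Z = mb.hierarchical_cluster(D, method="complete")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ConfigurationError):
            mb.hierarchical_cluster(np.array([[0.0, 1.0], [0.5, 0.0]]))
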
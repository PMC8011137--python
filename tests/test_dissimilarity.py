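"""Matrix operations, the Euclid/Pearson distance identity, and partial
correlations."""

import numpy as np
import pandas as pd
import pytest

from robustcorr import (
    DegenerateDataError,
    average_duplicates,
    corr_matrix,
    correlation,
    corr_test,
    dist_matrix,
    generalized_partial_corr,
    linkage_from_dist,
    partial_corr,
    pearson,
    pvalue_matrix,
    read_table,
    write_matrix,
)


@pytest.fixture
def toy_matrix(rng):
    data = rng.multivariate_normal(np.zeros(4),
                                   0.5 + 0.5 * np.eye(4), size=12).T
    return pd.DataFrame(data, index=["g1", "g2", "g3", "g4"],
                        columns=[f"s{i}" for i in range(12)])


class TestAverageDuplicates:
    def test_no_duplicates_identity(self, toy_matrix):
        pd.testing.assert_frame_equal(average_duplicates(toy_matrix),
                                      toy_matrix)

    def test_mean_of_duplicate_rows(self):
        df = pd.DataFrame([[1.0, 2, 3], [3.0, 4, 5], [9.0, 9, 9]],
                          index=["a", "a", "b"])
        out = average_duplicates(df)
        assert list(out.index) == ["a", "b"]
        np.testing.assert_array_equal(out.loc["a"], [2.0, 3.0, 4.0])

    def test_identical_duplicates_collapse_unchanged(self):
        df = pd.DataFrame([[1.0, 2], [1.0, 2]], index=["a", "a"])
        np.testing.assert_array_equal(average_duplicates(df).loc["a"], [1.0, 2])


class TestCorrMatrix:
    @pytest.mark.parametrize("method", ["taba", "pearson", "tabwil_rank"])
    def test_entries_equal_pairwise_calls(self, toy_matrix, method):
        pm = corr_matrix(toy_matrix, method)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = correlation(toy_matrix.iloc[i], toy_matrix.iloc[j],
                                       method).r
                assert pm.values.iloc[i, j] == expected

    def test_identical_rows_give_one(self, toy_matrix):
        df = toy_matrix.copy()
        df.loc["g2"] = df.loc["g1"]
        pm = corr_matrix(df, "taba")
        assert pm.values.loc["g1", "g2"] == pytest.approx(1.0)

    def test_negated_row_gives_minus_one(self, toy_matrix):
        df = toy_matrix.copy()
        df.loc["g2"] = -df.loc["g1"]
        pm = corr_matrix(df, "taba")
        assert pm.values.loc["g1", "g2"] == pytest.approx(-1.0)

    def test_exact_symmetry_and_unit_diagonal(self, toy_matrix):
        v = corr_matrix(toy_matrix, "tabwil").values.to_numpy()
        np.testing.assert_array_equal(v, v.T)
        np.testing.assert_array_equal(np.diag(v), np.ones(4))

    def test_row_permutation_commutes(self, toy_matrix):
        perm = ["g3", "g1", "g4", "g2"]
        a = corr_matrix(toy_matrix.loc[perm], "taba").values
        b = corr_matrix(toy_matrix, "taba").values.loc[perm, perm]
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_row_names_offender(self, toy_matrix):
        df = toy_matrix.copy()
        df.loc["g3"] = 1.0
        with pytest.raises(DegenerateDataError, match="g3"):
            corr_matrix(df, "taba")

    def test_duplicate_ids_rejected(self, toy_matrix):
        df = toy_matrix.copy()
        df.index = ["g1", "g1", "g3", "g4"]
        with pytest.raises(ValueError, match="average_duplicates"):
            corr_matrix(df, "taba")


class TestDistMatrix:
    def test_conventions(self, toy_matrix):
        pm = corr_matrix(toy_matrix, "pearson")
        r = pm.values.to_numpy()
        half = dist_matrix(pm).values.to_numpy()
        one = dist_matrix(pm, "one_minus_r").values.to_numpy()
        ab = dist_matrix(pm, "one_minus_abs_r").values.to_numpy()
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(half[iu], (1 - r[iu]) / 2)
        np.testing.assert_allclose(one[iu], 1 - r[iu])
        np.testing.assert_allclose(ab[iu], 1 - np.abs(r[iu]))
        for d in (half, one, ab):
            np.testing.assert_array_equal(np.diag(d), np.zeros(4))

    def test_extremes(self):
        df = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 3, 2, 1]],
                          index=list("abc"))
        d = dist_matrix(corr_matrix(df, "pearson")).values
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_euclid_pearson_identity(self, rng):
        """For column-standardized rows, d_Euclid = 2 sqrt(n d_Pearson)
        under the (1 - r)/2 convention."""
        n = 15
        data = rng.normal(size=(5, n))
        data = (data - data.mean(axis=1, keepdims=True))
        data /= data.std(axis=1, keepdims=True)  # population SD: |row| = sqrt(n)
        pm = corr_matrix(pd.DataFrame(data), "pearson")
        d = dist_matrix(pm, "half_one_minus_r").values.to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                euclid = np.linalg.norm(data[i] - data[j])
                assert euclid == pytest.approx(2 * np.sqrt(n * d[i, j]),
                                               abs=1e-10)

    def test_wrong_kind_rejected(self, toy_matrix):
        pm = corr_matrix(toy_matrix, "pearson")
        with pytest.raises(ValueError):
            dist_matrix(dist_matrix(pm))


class TestPvalueMatrix:
    def test_entries_equal_elementwise_tests(self, toy_matrix):
        pm = pvalue_matrix(toy_matrix, "taba")
        cm = corr_matrix(toy_matrix, "taba")
        n = toy_matrix.shape[1]
        for i in range(4):
            for j in range(i + 1, 4):
                expected = corr_test(cm.values.iloc[i, j], n).p
                assert pm.values.iloc[i, j] == expected

    def test_identical_rows_p_near_zero(self, toy_matrix):
        df = toy_matrix.copy()
        df.loc["g2"] = df.loc["g1"]
        pm = pvalue_matrix(df, "taba")
        # r = 1 at n = 12 gives t = sqrt(2 * 10), p ~ 1.2e-3
        assert pm.values.loc["g1", "g2"] < 0.01

    def test_diagonal_zero_and_symmetry(self, toy_matrix):
        v = pvalue_matrix(toy_matrix, "pearson").values.to_numpy()
        np.testing.assert_array_equal(np.diag(v), np.zeros(4))
        np.testing.assert_array_equal(v, v.T)

    def test_bh_adjustment_monotone(self, toy_matrix):
        raw = pvalue_matrix(toy_matrix, "pearson").values.to_numpy()
        adj = pvalue_matrix(toy_matrix, "pearson", adjust="bh").values.to_numpy()
        iu = np.triu_indices(4, 1)
        assert np.all(adj[iu] >= raw[iu] - 1e-15)


class TestPartialCorr:
    def test_orthogonal_controls_change_little(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.7 * x + 0.5 * rng.normal(size=n)
        c = rng.normal(size=(n, 1))  # independent of both
        plain = correlation(x, y, "pearson").r
        part = partial_corr(x, y, c, method="pearson").r
        assert part == pytest.approx(plain, abs=0.05)

    def test_confounder_removed(self, rng):
        """x and y share only a confounder: partialling it out kills the
        correlation; matches a residualize-then-correlate oracle."""
        n = 20
        z = rng.normal(size=n)
        x = z + 0.3 * rng.normal(size=n)
        y = z + 0.3 * rng.normal(size=n)
        est = partial_corr(x, y, z, method="taba")
        # independent stepwise oracle via polynomial least squares
        def resid(v):
            coef = np.polyfit(z, v, 1)
            return v - np.polyval(coef, z)
        expected = correlation(resid(x), resid(y), "taba").r
        assert est.r == pytest.approx(expected, abs=1e-10)
        assert abs(est.r) < abs(correlation(x, y, "taba").r)

    def test_semi_partial_residualizes_one_side(self, rng):
        n = 50
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = rng.normal(size=n)
        semi = partial_corr(x, y, z, method="pearson", semi="x")
        coef = np.polyfit(z, x, 1)
        expected = pearson(x - np.polyval(coef, z), y).r
        assert semi.r == pytest.approx(expected, abs=1e-10)

    def test_symmetry_when_both_residualized(self, rng):
        n = 40
        c = rng.normal(size=(n, 2))
        x = c @ [1.0, -0.5] + rng.normal(size=n)
        y = c @ [0.3, 0.8] + rng.normal(size=n)
        assert partial_corr(x, y, c, "taba").r == pytest.approx(
            partial_corr(y, x, c, "taba").r, abs=1e-12)

    def test_outcome_in_span_of_controls(self, rng):
        n = 30
        c = rng.normal(size=(n, 2))
        y = c @ [2.0, -1.0] + 3.0
        with pytest.raises(DegenerateDataError):
            partial_corr(rng.normal(size=n), y, c, "pearson")

    def test_rank_deficient_controls(self, rng):
        n = 30
        z = rng.normal(size=n)
        c = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="rank"):
            partial_corr(rng.normal(size=n), rng.normal(size=n), c)


class TestGeneralizedPartial:
    def test_identical_linear_controls_reduce_to_partial(self, rng):
        n = 60
        c = rng.normal(size=(n, 2))
        x = c @ [1.0, 0.5] + rng.normal(size=n)
        y = c @ [-0.2, 1.0] + rng.normal(size=n)
        gp = generalized_partial_corr(x, y, c, c, method="taba")
        p = partial_corr(x, y, c, method="taba")
        assert gp.r == pytest.approx(p.r, abs=1e-10)

    def test_empty_controls_reduce_to_plain(self, rng):
        n = 40
        x, y = rng.normal(size=n), rng.normal(size=n)
        gp = generalized_partial_corr(x, y, None, None, method="pearson")
        assert gp.r == pytest.approx(pearson(x, y).r, abs=1e-12)

    def test_logistic_linear_mixed_links(self, rng):
        """Binary x / continuous y triple: matches a fit-then-correlate
        oracle built directly on statsmodels."""
        import statsmodels.api as sm
        n = 120
        z = rng.normal(size=n)
        x = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float)
        y = 0.5 * z + rng.normal(size=n)
        gp = generalized_partial_corr(x, y, z, z, link_x="logistic",
                                      method="pearson")
        design = sm.add_constant(z)
        rx = x - sm.GLM(x, design, family=sm.families.Binomial()).fit().fittedvalues
        ry = y - sm.GLM(y, design, family=sm.families.Gaussian()).fit().fittedvalues
        assert gp.r == pytest.approx(pearson(rx, ry).r, abs=1e-8)

    def test_link_outcome_compatibility(self, rng):
        n = 30
        y = rng.normal(size=n)
        with pytest.raises(ValueError):
            generalized_partial_corr(y, y, link_x="logistic",
                                     controls_x=rng.normal(size=n))
        with pytest.raises(ValueError):
            generalized_partial_corr(y, y, link_x="poisson",
                                     controls_x=rng.normal(size=n))


class TestIO:
    def test_round_trip(self, toy_matrix, tmp_path):
        pm = corr_matrix(toy_matrix, "taba")
        path = tmp_path / "corr.csv"
        write_matrix(pm, path, comments=["method=taba", "seed=0"])
        back = read_table(path)
        np.testing.assert_allclose(back.to_numpy(), pm.values.to_numpy(),
                                   atol=1e-12)

    def test_tsv_dialect(self, toy_matrix, tmp_path):
        path = tmp_path / "expr.tsv"
        toy_matrix.to_csv(path, sep="\t")
        pd.testing.assert_frame_equal(read_table(path), toy_matrix)

    def test_missing_values_rejected_with_coordinates(self, toy_matrix,
                                                      tmp_path):
        df = toy_matrix.copy()
        df.iloc[1, 2] = np.nan
        path = tmp_path / "bad.csv"
        df.to_csv(path)
        with pytest.raises(ValueError, match="g2"):
            read_table(path)


def test_linkage_from_average_distance(toy_matrix):
    link = linkage_from_dist(dist_matrix(corr_matrix(toy_matrix, "taba")))
    assert link.shape == (3, 4)
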
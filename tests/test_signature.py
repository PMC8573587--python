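"""Count filtering, normalization, covariate adjustment, QC, eigen scoring,
group tests and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mircog import signature
from mircog.signature import (EigenScore, cluster_scores, compare_groups,
                              correlate_phenotype, drop_outliers,
                              eigen_expression, filter_features,
                              normalize_log2, regress_out_covariates,
                              sample_quality_z, _elbow_from_wss)


def frame(rows, index=None, columns=None):
    return pd.DataFrame(np.asarray(rows), index=index, columns=columns)


class TestFilter:
    def test_hand_counted_toy_matrix(self):
        counts = frame([[5, 5, 0, 0], [5, 5, 5, 5], [0, 0, 0, 0], [4, 4, 4, 4]],
                       index=list("abcd"))
        kept = filter_features(counts, min_reads=5, min_fraction=0.5)
        assert list(kept.index) == ["a", "b"]

    def test_vacuous_and_allzero_cases(self):
        counts = frame([[0, 0], [1, 2]], index=["zero", "one"])
        assert len(filter_features(counts, 0, 0.5)) == 2
        assert list(filter_features(counts, 1, 0.5).index) == ["one"]
        with pytest.raises(ValueError, match="every feature"):
            filter_features(frame([[0, 0]]), 1, 0.5)


class TestNormalize:
    def test_stated_transform(self):
        counts = frame([[1], [10**6 - 1]], index=["a", "rest"])
        expr = normalize_log2(counts)
        assert expr.loc["a"].iloc[0] == pytest.approx(1.0)  # log2(1 + 1 CPM..)

    def test_cpm_removes_library_scale(self):
        counts = frame([[10, 20], [30, 60], [5, 10]])
        expr = normalize_log2(counts)
        np.testing.assert_allclose(expr[0], expr[1])
        assert normalize_log2(frame([[0, 1], [1, 1]])).iloc[0, 0] == 0.0

    def test_provenance_guard_and_zero_library(self):
        counts = frame([[1, 0], [1, 0]], columns=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            normalize_log2(counts)
        expr = normalize_log2(frame([[1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_log2(expr)


class TestRegression:
    def test_orthogonal_covariate_leaves_feature_alone(self):
        expr = frame([[1.0, -1.0, 1.0, -1.0]], index=["f"],
                     columns=list("wxyz"))
        meta = pd.DataFrame({"c": [1.0, 1.0, -1.0, -1.0]}, index=list("wxyz"))
        out = regress_out_covariates(expr, meta, ["c"])
        np.testing.assert_allclose(out.loc["f"], expr.loc["f"], atol=1e-12)

    def test_perfect_fit_leaves_grand_mean(self):
        meta = pd.DataFrame({"c": [0.0, 1.0, 2.0, 3.0]}, index=list("wxyz"))
        expr = frame([[2.0, 4.0, 6.0, 8.0]], index=["f"], columns=list("wxyz"))
        out = regress_out_covariates(expr, meta, ["c"])
        np.testing.assert_allclose(out.loc["f"], np.full(4, 5.0), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        expr = frame(rng.normal(size=(6, 8)), columns=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({"a": rng.normal(size=8), "b": rng.normal(size=8)},
                            index=expr.columns)
        out = regress_out_covariates(expr, meta, ["a", "b"])
        X = np.column_stack([np.ones(8), meta["a"], meta["b"]])
        for i in range(6):
            y = expr.iloc[i].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent solve
            expect = y - X @ beta + y.mean()
            np.testing.assert_allclose(out.iloc[i], expect, atol=1e-10)

    def test_collinear_design_reported(self):
        expr = frame(np.random.default_rng(1).normal(size=(3, 5)))
        meta = pd.DataFrame({"a": [1., 2., 3., 4., 5.],
                             "b": [2., 4., 6., 8., 10.]}, index=expr.columns)
        with pytest.raises(ValueError, match="collinear"):
            regress_out_covariates(expr, meta, ["a", "b"])
        with pytest.raises(KeyError, match="missing_cov"):
            regress_out_covariates(expr, meta, ["missing_cov"])


class TestQualityZ:
    def test_scrambled_sample_is_flagged_and_removed(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=50)
        cols = {f"s{i}": base + rng.normal(0, 0.1, 50) for i in range(19)}
        cols["weird"] = rng.permutation(base)  # destroys correlation
        expr = pd.DataFrame(cols)
        z = sample_quality_z(expr)
        assert z.idxmin() == "weird"
        kept = drop_outliers(expr, threshold=2.5)
        assert "weird" not in kept.columns and kept.shape[1] == 19

    def test_degenerate_inputs_guarded(self):
        expr = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0],
                             "c": [1.0, 2.0], "d": [1.0, 2.0]})
        z = sample_quality_z(expr)
        assert (z == 0).all()  # identical samples: zero connectivity spread
        small = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.warns(UserWarning, match="fewer than 4"):
            out = drop_outliers(small)
        assert out.shape == small.shape


class TestEigenExpression:
    def test_rank_one_set(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr = frame([v, v, v], index=["a", "b", "c"])
        es = eigen_expression(expr, ["a", "b", "c"])
        assert es.variance_explained == pytest.approx(1.0)
        z = (v - v.mean()) / v.std()
        assert np.corrcoef(es.scores, z)[0, 1] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        expr = frame(rng.normal(size=(3, 12)), index=["a", "b", "c"])
        es = eigen_expression(expr, ["a", "b", "c"])
        Z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0),
                                                    axis=0).to_numpy()
        w, U = np.linalg.eigh(Z @ Z.T)  # independent eigen route
        lead = U[:, np.argmax(w)]
        proj = lead @ Z
        if np.corrcoef(proj, es.scores)[0, 1] < 0:
            proj = -proj
        np.testing.assert_allclose(es.scores, proj, atol=1e-10)

    def test_sign_convention_holds(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            expr = frame(rng.normal(size=(4, 10)),
                         index=["a", "b", "c", "d"])
            es = eigen_expression(expr, ["a", "b", "c", "d"])
            z = expr.sub(expr.mean(axis=1), axis=0).div(
                expr.std(axis=1, ddof=0), axis=0)
            assert np.corrcoef(es.scores, z.mean(axis=0))[0, 1] >= 0

    def test_feature_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        expr = frame(rng.normal(size=(3, 9)), index=["a", "b", "c"])
        es1 = eigen_expression(expr, ["a", "b", "c"])
        expr2 = expr.copy()
        expr2.loc["a"] = 100.0 + 7.0 * expr2.loc["a"]
        es2 = eigen_expression(expr2, ["a", "b", "c"])
        np.testing.assert_allclose(es1.scores, es2.scores, atol=1e-9)

    def test_errors_and_warnings(self):
        expr = frame([[1.0, 2.0, 3.0], [1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                     index=["a", "flat", "b"])
        with pytest.raises(KeyError, match="ghost"):
            eigen_expression(expr, ["a", "ghost"])
        with pytest.warns(UserWarning, match="flat"):
            es = eigen_expression(expr, ["a", "flat", "b"])
        assert len(es.scores) == 3

    def test_score_outlier_pass(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(3, 30))
        base[:, 0] += 50.0  # one wildly deviant sample
        expr = frame(base, index=["a", "b", "c"],
                     columns=[f"s{i}" for i in range(30)])
        es = eigen_expression(expr, ["a", "b", "c"], drop_score_outliers=True)
        assert "s0" in es.dropped_samples


def rank_sum_enumeration_p(a, b):
    """Exact two-sided rank-sum p by full enumeration (oracle)."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(a)
    observed = ranks[:n1].sum()
    mean_w = ranks.sum() * n1 / len(pooled)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(observed - mean_w) - 1e-9:
            count += 1
    return count / total


class TestCompareGroups:
    def test_textbook_case(self):
        s = pd.Series([1, 2, 3, 4, 5, 6.0], index=list("abcdef"))
        g = pd.Series(["x"] * 3 + ["y"] * 3, index=s.index)
        w, p = compare_groups(s, g)
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1)

    def test_no_separation(self):
        s = pd.Series([2.0, 2.0, 2.0, 2.0], index=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=s.index)
        assert compare_groups(s, g)[1] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_small_samples(self):
        rng = np.random.default_rng(8)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 5)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            s = pd.Series(np.concatenate([a, b]))
            g = pd.Series(["a"] * n1 + ["b"] * n2)
            _, p = compare_groups(s, g)
            assert p == pytest.approx(rank_sum_enumeration_p(a, b))

    def test_empty_group_rejected(self):
        s = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError):
            compare_groups(s, pd.Series(["x", "x"]))


class TestCorrelate:
    def test_self_and_anti_correlation(self):
        s = pd.Series([1.0, 2.0, 4.0, 3.0])
        assert correlate_phenotype(s, s)[0] == pytest.approx(1.0)
        assert correlate_phenotype(s, -s)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        x = pd.Series(rng.normal(size=10))
        y = pd.Series(rng.normal(size=10), index=x.index)
        r, _ = correlate_phenotype(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        expect = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_phenotype(pd.Series([1.0, 1.0, 1.0]),
                                pd.Series([1.0, 2.0, 3.0]))


class TestClustering:
    def test_elbow_second_difference_arithmetic(self):
        assert _elbow_from_wss([100.0, 10.0, 9.0, 8.0]) == 2

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(10)
        s = pd.Series(np.concatenate([rng.normal(0, 0.1, 20),
                                      rng.normal(10, 0.1, 20)]))
        k, assign, order = cluster_scores(s, k_max=6, seed=0)
        assert k == 2
        assert assign.iloc[:20].nunique() == 1
        assert assign.iloc[20:].nunique() == 1
        assert assign.iloc[0] != assign.iloc[-1]
        assert len(order) == 40

    def test_identical_points_collapse_to_one_cluster(self):
        s = pd.Series(np.ones(10))
        k, assign, _ = cluster_scores(s, k_max=4, seed=0)
        assert k == 1 and assign.nunique() == 1

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            cluster_scores(pd.Series([1.0, 2.0]), k_max=2)
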
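"""Correlation-graph construction: transform, correlate, threshold."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cliquekit import ExpressionMatrix, correlate, log_transform, threshold_graph
from cliquekit.correlation import FewConditionsWarning, TransformError
from cliquekit.graph import GraphError


def matrix(rows: dict, conditions=None) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if conditions is not None:
        df.columns = conditions
    with pytest.warns(FewConditionsWarning):
        return ExpressionMatrix(df)


def wide_matrix(rows: dict) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    return ExpressionMatrix(df)


class TestExpressionMatrix:
    def test_fewer_than_two_conditions_is_error(self):
        with pytest.raises(GraphError, match="at least 2"):
            ExpressionMatrix(pd.DataFrame({"c1": [1.0, 2.0]}, index=["p1", "p2"]))

    def test_under_twelve_conditions_warns_not_errors(self):
        df = pd.DataFrame([[1.0] * 5, [2.0] * 5], index=["p1", "p2"])
        with pytest.warns(FewConditionsWarning):
            ExpressionMatrix(df)
        with pytest.raises(GraphError):
            ExpressionMatrix(df, strict=True)

    def test_from_tsv_missing_markers(self):
        tsv = "probe\tc1\tc2\tc3\np1\t1.5\tNA\t2.5\np2\t2\t3\t\n"
        with pytest.warns(FewConditionsWarning):
            X = ExpressionMatrix.from_tsv(io.StringIO(tsv))
        assert X.probe_ids == ("p1", "p2")
        assert math.isnan(X.values.iat[0, 1]) and math.isnan(X.values.iat[1, 2])


class TestLogTransform:
    def test_base2_values(self):
        X = matrix({"p1": [8.0, 1.0], "p2": [2.0, 4.0]})
        Y = log_transform(X)
        assert Y.values.loc["p1"].tolist() == [3.0, 0.0]
        assert Y.values.loc["p2"].tolist() == [1.0, 2.0]

    def test_missing_entries_preserved(self):
        X = matrix({"p1": [4.0, np.nan, 16.0]})
        Y = log_transform(X)
        assert math.isnan(Y.values.iat[0, 1]) and Y.values.iat[0, 2] == 4.0

    def test_non_positive_value_names_probe_and_condition(self):
        X = matrix({"p1": [1.0, 2.0], "bad": [0.0, 2.0]}, conditions=["c1", "c2"])
        with pytest.raises(TransformError, match=r"'bad'.*'c1'"):
            log_transform(X)


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        X = matrix({"a": [1, 2, 3], "b": [2, 4, 6], "c": [3, 2, 1]})
        W = correlate(X)
        assert W.entries[("a", "b")] == pytest.approx(1.0)
        assert W.entries[("a", "c")] == pytest.approx(-1.0)
        assert W.pair_support[("a", "b")] == 3

    def test_pvalue_matches_t_distribution_closed_form(self):
        # oracle: two-sided tail of t = r*sqrt((n-2)/(1-r^2)) with n-2 dof,
        # independently computed by scipy.stats.pearsonr
        rows = {"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 6]}
        W = correlate(matrix(rows), weight_kind="pvalue")
        r_ref, p_ref = stats.pearsonr(rows["a"], rows["b"])
        t_ref = r_ref * math.sqrt(3 / (1 - r_ref**2))
        assert W.entries[("a", "b")] == pytest.approx(2 * stats.t.sf(t_ref, 3))
        assert W.entries[("a", "b")] == pytest.approx(p_ref)

    def test_pairwise_complete_support_and_low_support_omitted(self):
        X = matrix({
            "a": [1, 2, 3, 4],
            "b": [1, np.nan, 3, 5],      # support 3 with a
            "c": [np.nan, np.nan, 1, 2],  # support 2 with a -> omitted
        })
        W = correlate(X)
        assert W.pair_support[("a", "b")] == 3
        assert ("a", "c") not in W.entries
        assert any(pair == ("a", "c") and "support" in reason for pair, reason in W.omitted)

    def test_zero_variance_pair_omitted(self):
        X = matrix({"a": [1, 1, 1], "b": [1, 2, 3]})
        W = correlate(X)
        assert ("a", "b") not in W.entries
        assert any("variance" in reason for _, reason in W.omitted)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(3, 15))
        X1 = wide_matrix({"a": base[0], "b": base[1], "c": base[2]})
        X2 = wide_matrix({"a": 3.0 * base[0] + 1.0, "b": base[1], "c": 0.5 * base[2] - 4.0})
        W1, W2 = correlate(X1), correlate(X2)
        for pair in W1.entries:
            assert W2.entries[pair] == pytest.approx(W1.entries[pair])

    def test_complete_data_matches_full_vector_correlation(self):
        rng = np.random.default_rng(11)
        rows = {f"p{i}": rng.normal(size=14) for i in range(4)}
        W = correlate(wide_matrix(rows))
        for (a, b), w in W.entries.items():
            assert w == pytest.approx(stats.pearsonr(rows[a], rows[b])[0])


class TestThresholdGraph:
    def weights(self):
        X = matrix({"a": [1, 2, 3, 4], "b": [1.1, 1.9, 3.2, 3.9], "c": [4, 3, 2.5, 1]})
        return correlate(X)

    def test_inclusive_keep_at_exact_threshold(self):
        W = self.weights()
        t = W.entries[("a", "b")]
        G = threshold_graph(W, t)
        assert G.has_edge("a", "b")

    def test_high_threshold_keeps_only_strong_pair(self):
        W = self.weights()
        G = threshold_graph(W, 0.81)
        assert list(G.edges()) == [("a", "b")]
        assert G.n == 3  # isolated probe retained

    def test_drop_isolated(self):
        G = threshold_graph(self.weights(), 0.81, drop_isolated=True)
        assert set(G.vertices) == {"a", "b"}

    def test_monotone_in_threshold(self):
        W = self.weights()
        e_low = set(threshold_graph(W, -1.0).edges())
        e_high = set(threshold_graph(W, 0.5).edges())
        assert e_high <= e_low

    def test_pvalue_direction_flips(self):
        X = matrix({
            "a": list(range(1, 9)),
            "b": [1, 2, 3, 4, 5, 6, 7, 8.5],   # tiny p
            "c": [5, 1, 4, 2, 6, 2, 5, 3],      # large p
        })
        W = correlate(X, weight_kind="pvalue")
        G = threshold_graph(W, 0.01)
        assert G.has_edge("a", "b") and not G.has_edge("a", "c")

    def test_absolute_thresholding_keeps_anticorrelated(self):
        W = self.weights()
        assert not threshold_graph(W, 0.9).has_edge("a", "c")
        assert threshold_graph(W, 0.9, absolute=True).has_edge("a", "c")

    def test_threshold_out_of_range(self):
        with pytest.raises(GraphError):
            threshold_graph(self.weights(), 1.5)
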
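"""Welch-t differential abundance, BH adjustment, fold-change clustering
and cross-dataset comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secretomap import ConfigError, ValidationError
from secretomap.differential import (bh_adjust, cluster_regulated, cross_comparison,
                                     differential_abundance)

from conftest import make_experiment


def two_condition_experiment(values_a, values_b, extra=None):
    """Cre+ channels only for two conditions; one token cre_neg per condition."""
    n_a, n_b = len(next(iter(values_a.values()))), len(next(iter(values_b.values())))
    specs = ([(f"a{i}", "cre_pos", "A") for i in range(n_a)]
             + [("an", "cre_neg", "A")]
             + [(f"b{i}", "cre_pos", "B") for i in range(n_b)]
             + [("bn", "cre_neg", "B")])
    vals = {pid: [*values_a[pid], 1.0, *values_b[pid], 1.0] for pid in values_a}
    if extra:
        vals.update(extra)
    return make_experiment(vals, specs)


def welch_oracle(a, b):
    """Closed-form Welch t-test with Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    from scipy.stats import t as tdist
    return t, df, 2 * tdist.sf(abs(t), df)


class TestDifferentialAbundance:
    def test_closed_form_welch(self):
        # log2 values {1,2,3} vs {4,5,6}: intensities are their powers of two
        q = two_condition_experiment({"P": [2.0, 4.0, 8.0]}, {"P": [16.0, 32.0, 64.0]})
        diff = differential_abundance(q, {"P"}, ("A", "B"))
        row = diff.iloc[0]
        _, _, p_expected = welch_oracle([1, 2, 3], [4, 5, 6])
        assert row["log2fc"] == pytest.approx(-3.0)
        assert row["p"] == pytest.approx(p_expected)
        assert row["q"] == pytest.approx(p_expected)  # single test: q = p

    def test_identical_groups_not_significant(self):
        q = two_condition_experiment({"P": [2.0, 4.0, 8.0]}, {"P": [2.0, 4.0, 8.0]})
        row = differential_abundance(q, {"P"}, ("A", "B")).iloc[0]
        assert row["log2fc"] == pytest.approx(0.0)
        assert not row["significant"]

    def test_antisymmetry_of_contrast_direction(self):
        rng = np.random.default_rng(5)
        vals = {f"P{i}": rng.lognormal(5, 1, 6) for i in range(20)}
        a = {k: v[:3] for k, v in vals.items()}
        b = {k: v[3:] for k, v in vals.items()}
        q = two_condition_experiment(a, b)
        fwd = differential_abundance(q, vals.keys(), ("A", "B")).set_index("protein")
        rev = differential_abundance(q, vals.keys(), ("B", "A")).set_index("protein")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_underquantified_protein_gets_absent_p(self):
        q = two_condition_experiment({"P": [2.0, 4.0, 8.0]}, {"P": [16.0, 32.0, 64.0]},
                                     extra={"Q": [2.0, np.nan, np.nan, 1.0,
                                                  4.0, 8.0, 16.0, 1.0]})
        diff = differential_abundance(q, {"P", "Q"}, ("A", "B")).set_index("protein")
        assert np.isnan(diff.at["Q", "p"]) and np.isnan(diff.at["Q", "q"])
        assert not diff.at["Q", "significant"]
        assert np.isfinite(diff.at["Q", "log2fc"])  # means still computable

    def test_unknown_condition_is_contrast_error(self):
        q = two_condition_experiment({"P": [2.0, 4.0]}, {"P": [4.0, 8.0]})
        with pytest.raises(ConfigError, match="chow"):
            differential_abundance(q, {"P"}, ("chow", "A"))

    def test_only_passing_proteins_tested(self):
        q = two_condition_experiment({"P": [2.0, 4.0, 8.0], "R": [2.0, 4.0, 8.0]},
                                     {"P": [16.0, 32.0, 64.0], "R": [16.0, 32.0, 64.0]})
        diff = differential_abundance(q, {"P"}, ("A", "B"))
        assert list(diff["protein"]) == ["P"]

    def test_significance_gates_follow_printed_thresholds(self):
        # |log2fc| = 2.2 with a tiny p must be flagged; fc below 1.5 must not
        rng = np.random.default_rng(0)
        big = {"UP": 2 ** (10 + 2.2 + rng.normal(0, 0.01, 4))}
        base = {"UP": 2 ** (10 + rng.normal(0, 0.01, 4))}
        small = {"FLAT": 2 ** (10 + 0.3 + rng.normal(0, 0.01, 4))}
        base2 = {"FLAT": 2 ** (10 + rng.normal(0, 0.01, 4))}
        q = two_condition_experiment({**big, **small}, {**base, **base2})
        diff = differential_abundance(q, {"UP", "FLAT"}, ("A", "B")).set_index("protein")
        assert diff.at["UP", "significant"]
        assert diff.at["UP", "log2fc"] == pytest.approx(2.2, abs=0.05)
        assert not diff.at["FLAT", "significant"]  # p tiny but FC gate fails


def bh_oracle(pvals):
    """Independent brute-force step-up: q_i = min_{j: p_j >= p_i} min(1, m*p_j/rank_j)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_case(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    def test_q_dominates_p_and_preserves_order(self, pvals):
        q = bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all() and (q <= 1.0).all()
        # adjusted values are monotone in the raw p-values
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


def diff_frame(fcs: dict[str, list[float]], contrasts: list[str],
               significant=None) -> pd.DataFrame:
    rows = []
    for pid, vals in fcs.items():
        for c, fc in zip(contrasts, vals):
            if fc is None:
                continue
            sig = significant[pid] if significant else True
            rows.append({"protein": pid, "contrast": c, "log2fc": fc, "p": 0.01,
                         "q": 0.02, "significant": sig, "n_a": 3, "n_b": 3})
    return pd.DataFrame(rows)


class TestClusterRegulated:
    def test_identical_vectors_merge_first_at_zero_distance(self):
        df = diff_frame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [9.0, 9.0]},
                        ["c1", "c2"])
        hm = cluster_regulated(df)
        first = hm.linkage[0]
        assert first[2] == pytest.approx(0.0)
        merged = {hm.linkage[0][0], hm.linkage[0][1]}
        assert merged == {0.0, 1.0}  # A and B (sorted positions 0, 1)

    def test_nearest_pair_merges_before_distant_third(self):
        df = diff_frame({"A": [0.0, 0.0], "B": [0.0, 0.1], "C": [5.0, 5.0]},
                        ["c1", "c2"])
        hm = cluster_regulated(df)
        assert {hm.linkage[0][0], hm.linkage[0][1]} == {0.0, 1.0}

    def test_leaf_order_invariant_to_input_permutation(self):
        df = diff_frame({"A": [1.0, 0.5], "B": [-1.0, 2.0], "C": [0.3, 0.1],
                         "D": [2.0, -1.0]}, ["c1", "c2"])
        hm1 = cluster_regulated(df)
        hm2 = cluster_regulated(df.sample(frac=1, random_state=3))
        assert hm1.proteins == hm2.proteins

    def test_missing_contrast_imputed_and_flagged(self):
        df = diff_frame({"A": [1.0, None], "B": [1.0, 2.0], "C": [0.0, 3.0]},
                        ["c1", "c2"])
        hm = cluster_regulated(df, contrasts=["c1", "c2"])
        assert ("A", "c2") in hm.imputed
        assert hm.values.at["A", "c2"] == 0.0

    def test_fewer_than_two_regulated_is_error(self):
        df = diff_frame({"A": [1.0]}, ["c1"])
        with pytest.raises(ValidationError, match=">=2"):
            cluster_regulated(df)


class TestCrossComparison:
    def test_quadrants_and_margins(self):
        x = diff_frame({"A": [1.0], "B": [-2.0], "C": [0.5]}, ["c"])
        y = diff_frame({"A": [-1.0], "B": [-1.0], "D": [2.0]}, ["c"])
        out = cross_comparison(x, y).set_index("protein")
        assert out.at["A", "quadrant"] == "x_up_y_down"
        assert out.at["B", "quadrant"] == "x_down_y_down"
        assert out.at["C", "only_in"] == "x" and out.at["D", "only_in"] == "y"

    def test_self_join_is_diagonal(self):
        x = diff_frame({"A": [1.0], "B": [-2.0]}, ["c"])
        out = cross_comparison(x, x)
        assert (out["only_in"] == "both").all()
        np.testing.assert_allclose(out["log2fc_x"], out["log2fc_y"])
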
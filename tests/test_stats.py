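import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cnvcurves import stats

from conftest import brute_force_bh


class TestGeneTest:
    def test_identical_groups_give_p_one(self):
        assert stats.gene_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_highly_significant(self):
        p = stats.gene_test([0, 0.1, -0.1, 0.05], [10, 10.1, 9.9, 10.05])
        assert p < 1e-6
        # agrees with the closed-form Welch computation
        expected = sps.ttest_ind(
            [0, 0.1, -0.1, 0.05], [10, 10.1, 9.9, 10.05], equal_var=False
        ).pvalue
        assert p == pytest.approx(expected)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            stats.gene_test([1.0], [1.0, 2.0])

    def test_constant_equal_and_constant_different(self):
        assert stats.gene_test([2.0, 2.0], [2.0, 2.0]) == 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            p = stats.gene_test([2.0, 2.0], [3.0, 3.0])
        assert 0 < p < 1e-300

    def test_rank_test_option(self):
        p = stats.gene_test([1, 2, 3, 4], [10, 11, 12, 13], method="rank")
        expected = sps.mannwhitneyu(
            [1, 2, 3, 4], [10, 11, 12, 13], alternative="two-sided"
        ).pvalue
        assert p == pytest.approx(expected)

    def test_type_i_error_near_nominal_on_gaussian_null(self):
        rng = np.random.default_rng(2024)
        n_genes, n = 2000, 20
        a = rng.normal(size=(n_genes, n))
        b = rng.normal(size=(n_genes, n))
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = float((p < 0.05).mean())
        assert 0.03 <= rate <= 0.07
        # spot-check the vectorized null against gene_test on a few genes
        for i in (0, 500, 1999):
            assert stats.gene_test(a[i], b[i]) == pytest.approx(p[i])


class TestAdjustPvalues:
    def test_stepup_hand_example(self):
        q = stats.adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(stats.adjust_pvalues([0.03]), [0.03])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=100,
        )
    )
    def test_matches_brute_force_stepup(self, p):
        np.testing.assert_allclose(
            stats.adjust_pvalues(p), brute_force_bh(p), atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.adjust_pvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            stats.adjust_pvalues([1.5])

    def test_bonferroni_threshold(self):
        assert stats.bonferroni_threshold(0.05, 1000) == pytest.approx(5e-05)


class TestDirectionalSign:
    @pytest.mark.parametrize("m1,m2,expected", [(1.0, 2.0, -1), (2.0, 1.0, 1), (1.0, 1.0, 0)])
    def test_rule(self, m1, m2, expected):
        assert stats.directional_sign(m1, m2) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stats.directional_sign(np.nan, 1.0)


def _matrix(rng, n_genes, n_samples, prefix="s"):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"{prefix}{i}" for i in range(n_samples)],
    )


class TestManhattan:
    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng, 2000, 20)
        out = stats.manhattan_stats(m, m.columns[:10], m.columns[10:])
        assert (out["q_value"] < 0.05).sum() <= 0.05 * len(out)
        assert (out["sign"] == 1).all()  # regular mode

    def test_spiked_gene_attains_max_score(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng, 200, 20)
        m.loc["G0", m.columns[:10]] += 5.0  # 5-sd shift
        out = stats.manhattan_stats(m, m.columns[:10], m.columns[10:])
        top = out.loc[out["neg_log10_q"].idxmax(), "symbol"]
        assert top == "G0"

    def test_directional_signs_follow_medians(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng, 50, 12)
        m[m.columns[:6]] -= 10.0  # group1 uniformly lower
        out = stats.manhattan_stats(
            m, m.columns[:6], m.columns[6:], directional=True
        )
        assert (out["sign"] == -1).all()

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng, 5, 6)
        with pytest.raises(ValueError, match="overlap"):
            stats.manhattan_stats(m, m.columns[:4], m.columns[3:])

    def test_q_invariant_under_gene_permutation(self):
        rng = np.random.default_rng(10)
        m = _matrix(rng, 100, 10)
        out1 = stats.manhattan_stats(m, m.columns[:5], m.columns[5:])
        perm = m.sample(frac=1, random_state=0)
        out2 = stats.manhattan_stats(perm, m.columns[:5], m.columns[5:])
        merged = out1.merge(out2, on="symbol", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["q_value_a"], merged["q_value_b"])


class TestDeflection:
    def test_constructed_amplitudes_and_winner(self):
        rng = np.random.default_rng(11)
        # type1: strong gain in tumors; type2: weak difference
        t1 = _matrix(rng, 30, 10, "t1_") + 0.0
        n1 = _matrix(rng, 30, 10, "n1_")
        t1.loc["G0"] += 3.0
        t2 = _matrix(rng, 30, 10, "t2_")
        n2 = _matrix(rng, 30, 10, "n2_")
        out = stats.deflection_stats(t1, n1, t2, n2).set_index("symbol")
        g0 = out.loc["G0"]
        assert g0["amplitude1"] > 0  # tumor median above nonmalignant
        assert g0["winner"] == "type1"

    def test_amplitude_sign_tracks_median_difference(self):
        rng = np.random.default_rng(12)
        t1 = _matrix(rng, 20, 8, "t1_")
        n1 = _matrix(rng, 20, 8, "n1_")
        t2 = _matrix(rng, 20, 8, "t2_")
        n2 = _matrix(rng, 20, 8, "n2_")
        t1.loc["G3"] -= 4.0  # deletion: tumor median below controls
        out = stats.deflection_stats(t1, n1, t2, n2).set_index("symbol")
        assert out.loc["G3", "amplitude1"] < 0
        for g in out.index:
            d = np.median(t1.loc[g]) - np.median(n1.loc[g])
            amp = out.loc[g, "amplitude1"]
            if amp != 0:
                assert np.sign(amp) == np.sign(d)

    def test_q_of_one_gives_zero_amplitude_tie(self):
        const = pd.DataFrame(
            {"a": [1.0], "b": [1.0], "c": [1.0], "d": [1.0]}, index=["G"]
        )
        out = stats.deflection_stats(
            const[["a", "b"]], const[["c", "d"]], const[["a", "b"]], const[["c", "d"]]
        )
        assert out.loc[0, "amplitude1"] == 0.0
        assert out.loc[0, "winner"] == "tie"

    def test_empty_common_gene_set_rejected(self):
        rng = np.random.default_rng(13)
        a = _matrix(rng, 5, 4, "a")
        b = _matrix(rng, 5, 4, "b")
        c = _matrix(rng, 5, 4, "c")
        d = _matrix(rng, 5, 4, "d")
        c.index = d.index = [f"H{i}" for i in range(5)]
        with pytest.raises(ValueError, match="common gene"):
            stats.deflection_stats(a, b, c, d)


class TestVolcano:
    def test_fold_change_arithmetic(self):
        m1 = pd.DataFrame({"a": [200.0, 100.0], "b": [200.0, 100.0]}, index=["G1", "G2"])
        m2 = pd.DataFrame({"c": [99.8, 100.2], "d": [100.2, 99.8]}, index=["G1", "G2"])
        out = stats.volcano_stats(m1, m2, pseudo_count=0.0).set_index("symbol")
        assert out.loc["G1", "log2_fold_change"] == pytest.approx(1.0, abs=1e-3)
        assert out.loc["G2", "log2_fold_change"] == pytest.approx(0.0, abs=1e-3)

    def test_boundary_p_not_significant_at_strict_cutoff(self):
        rng = np.random.default_rng(14)
        m1 = _matrix(rng, 50, 10, "a").abs()
        m2 = _matrix(rng, 50, 10, "b").abs()
        out = stats.volcano_stats(m1, m2)
        assert (out["significant"] == (out["p_value"] < 0.05)).all()
        assert out["neg_log10_p"].min() >= 0

    def test_negative_expression_rejected(self):
        m1 = pd.DataFrame({"a": [-1.0], "b": [1.0]}, index=["G"])
        m2 = pd.DataFrame({"c": [1.0], "d": [1.0]}, index=["G"])
        with pytest.raises(ValueError, match="negative"):
            stats.volcano_stats(m1, m2)

    def test_cnv_mode_effect_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(15)
        m1 = _matrix(rng, 30, 8, "a")
        m2 = _matrix(rng, 30, 8, "b")
        fwd = stats.volcano_stats(m1, m2, value_kind="cnv").set_index("symbol")
        rev = stats.volcano_stats(m2, m1, value_kind="cnv").set_index("symbol")
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev.loc[fwd.index, "log2_fold_change"]
        )

    def test_expression_fc_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(16)
        m1 = _matrix(rng, 30, 8, "a").abs() * 100
        m2 = _matrix(rng, 30, 8, "b").abs() * 100
        fwd = stats.volcano_stats(m1, m2).set_index("symbol")
        rev = stats.volcano_stats(m2, m1).set_index("symbol")
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev.loc[fwd.index, "log2_fold_change"]
        )


class TestCorrelation:
    def _matrices(self, cnv_vals, expr_vals):
        cols = [f"s{i}" for i in range(len(cnv_vals))]
        cnv = pd.DataFrame([cnv_vals], index=["G"], columns=cols)
        expr = pd.DataFrame([expr_vals], index=["G"], columns=cols)
        return cnv, expr

    def test_exact_linear_relation(self):
        cnv, expr = self._matrices([0.0, 0.5, 1.0, 2.0], [1.0, 2.0, 3.0, 5.0])
        res = stats.cnv_expression_correlation("G", cnv, expr)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.n == 4

    def test_anticorrelation(self):
        cnv, expr = self._matrices([0.0, 1.0, 2.0], [0.0, -1.0, -2.0])
        res = stats.cnv_expression_correlation("G", cnv, expr)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        cnv, expr = self._matrices([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="constant"):
            stats.cnv_expression_correlation("G", cnv, expr)

    def test_missing_values_dropped_pairwise(self):
        cnv, expr = self._matrices([0.0, 1.0, 2.0, np.nan], [1.0, 3.0, 5.0, 7.0])
        res = stats.cnv_expression_correlation("G", cnv, expr)
        assert res.n == 3
        assert res.slope == pytest.approx(2.0)


class TestBeeswarm:
    def test_no_collisions_all_offsets_zero(self):
        offsets = stats.beeswarm_layout([0.0, 1.0, 2.0], point_diameter=0.5)
        np.testing.assert_allclose(offsets, 0.0)

    def test_identical_values_packed_at_diameter(self):
        d = 0.3
        offsets = stats.beeswarm_layout([1.0] * 5, point_diameter=d)
        assert len(set(np.round(offsets, 9))) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert abs(offsets[i] - offsets[j]) >= d - 1e-9

    def test_empty_input(self):
        assert stats.beeswarm_layout([], 0.1).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=40)
    )
    def test_never_places_points_closer_than_one_diameter(self, values):
        d = 0.4
        offsets = stats.beeswarm_layout(values, point_diameter=d)
        pts = np.column_stack([np.asarray(values), offsets])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.hypot(*(pts[i] - pts[j])) >= d - 1e-6

    def test_offsets_alternate_around_zero(self):
        offsets = stats.beeswarm_layout([0.0] * 6, point_diameter=1.0)
        n_pos = (offsets > 0).sum()
        n_neg = (offsets < 0).sum()
        assert abs(n_pos - n_neg) <= 1  # sides fill alternately
        assert np.abs(offsets).max() <= 3.0 + 1e-9  # tight packing
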
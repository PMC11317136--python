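"""RPKM, signed-rank testing and upregulation calls.

The in-package signed-rank p is cross-checked against a sign-flip
enumeration oracle written here, and against scipy's exact method in the
tie-free regime where both are defined.
"""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ltrscope import expression as expr


def enumeration_oracle(diffs):
    """Independent oracle: full 2^n sign-flip enumeration of the signed
    rank statistic (usable for any n that fits in memory)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    n = d.size
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = bits.astype(float) @ ranks
    return np.mean(np.abs(w_all - mu) >= abs(w - mu) - 1e-9)


class TestRPKM:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(10, 1000, 1e6, 10.0), (0, 500, 2e6, 0.0), (250, 500, 5e6, 100.0)],
    )
    def test_formula(self, count, length, lib, expected):
        assert expr.compute_rpkm(count, length, lib) == pytest.approx(expected)

    def test_negative_count_error(self):
        with pytest.raises(ValueError):
            expr.compute_rpkm(-1, 1000, 1e6)

    def test_linearity_and_library_split(self):
        base = expr.compute_rpkm(30, 1500, 4e6)
        assert expr.compute_rpkm(60, 1500, 4e6) == pytest.approx(2 * base)
        # splitting the library into equal halves and averaging is a no-op
        halves = np.mean(
            [expr.compute_rpkm(15, 1500, 2e6), expr.compute_rpkm(15, 1500, 2e6)]
        )
        assert halves == pytest.approx(base)


class TestWilcoxonSignedRank:
    def test_all_positive_n6_exact(self):
        # 2 of the 2^6 sign assignments are as extreme: p = 2/64
        assert expr.wilcoxon_signed_rank([1, 2, 3, 4, 5, 6]) == pytest.approx(0.03125)

    def test_antisymmetric_pair(self):
        assert expr.wilcoxon_signed_rank([2.0, -2.0]) == pytest.approx(1.0)

    def test_all_zero_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert expr.wilcoxon_signed_rank([0.0, 0.0]) == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, size=12)
            ours = expr.wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(13)
        d = rng.normal(0.4, 1.0, size=20)
        approx = expr.wilcoxon_signed_rank(d)  # n=20 -> approximation path
        exact = enumeration_oracle(d)
        assert approx == pytest.approx(exact, abs=0.005)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            expr.wilcoxon_signed_rank([])


def _counts(values, prefix):
    # values: element -> list per replicate
    return pd.DataFrame(
        {f"{prefix}_{i + 1}": {e: v[i] for e, v in values.items()}
         for i in range(len(next(iter(values.values()))))}
    )


class TestCallDifferential:
    LIB = {f"treated_{i}": 1e6 for i in range(1, 7)} | {
        f"control_{i}": 1e6 for i in range(1, 7)
    }

    def test_strong_effect_called(self):
        t = _counts({"e1": [400, 410, 390, 405, 395, 402], "e2": [100] * 6}, "treated")
        c = _counts({"e1": [100, 102, 98, 101, 99, 100], "e2": [100] * 6}, "control")
        res = expr.call_differential(
            t, c, {"e1": 1000, "e2": 1000}, library_sizes=self.LIB
        )
        assert bool(res.loc["e1", "upregulated"])
        assert res.loc["e1", "p_value"] == pytest.approx(0.03125)
        assert not bool(res.loc["e2", "upregulated"])

    def test_fold_change_exactly_two_is_not_upregulated(self):
        # strict '>' on the fold change: a pseudocount-free FC of exactly 2
        # stays below threshold once epsilon is added to both means
        t = _counts({"e1": [200] * 6}, "treated")
        c = _counts({"e1": [100] * 6}, "control")
        res = expr.call_differential(
            t, c, {"e1": 1000}, test="none", library_sizes=self.LIB
        )
        assert res.loc["e1", "log2_fc"] < 1.0
        assert not bool(res.loc["e1", "upregulated"])

    def test_identical_conditions_null(self):
        t = _counts({"e1": [50, 60, 55, 52, 58, 54]}, "treated")
        c = t.copy()
        c.columns = [f"control_{i + 1}" for i in range(6)]
        res = expr.call_differential(t, c, {"e1": 1000}, library_sizes=self.LIB)
        assert res.loc["e1", "log2_fc"] == pytest.approx(0.0)
        assert not bool(res.loc["e1", "upregulated"])

    def test_mismatched_element_sets_error(self):
        t = _counts({"e1": [1] * 6}, "treated")
        c = _counts({"e2": [1] * 6}, "control")
        with pytest.raises(ValueError, match="different elements"):
            expr.call_differential(t, c, {"e1": 100, "e2": 100})

    def test_records_test_mode(self):
        t = _counts({"e1": [10] * 6}, "treated")
        c = _counts({"e1": [10] * 6}, "control")
        res = expr.call_differential(t, c, {"e1": 100}, library_sizes=self.LIB)
        assert (res["test_mode"] == "wilcoxon_replicates").all()


class TestFamilyComposition:
    def test_fractions(self):
        rec = pd.DataFrame(
            {
                "family": ["LTR12C"] * 52 + ["LTR7"] * 48,
                "upregulated": [True] * 100,
            }
        )
        comp = expr.family_composition(rec)
        ltr12c = comp.set_index("family").loc["LTR12C"]
        assert ltr12c["count"] == 52 and ltr12c["fraction"] == pytest.approx(0.52)
        assert comp["fraction"].sum() == pytest.approx(1.0)

    def test_single_family(self):
        rec = pd.DataFrame({"family": ["X"] * 5, "upregulated": [True] * 5})
        comp = expr.family_composition(rec)
        assert comp["fraction"].iloc[0] == pytest.approx(1.0)

    def test_empty_warns(self):
        rec = pd.DataFrame({"family": [], "upregulated": []})
        with pytest.warns(UserWarning):
            assert expr.family_composition(rec).empty

    def test_top_n_pools_others(self):
        rec = pd.DataFrame(
            {"family": [f"f{i}" for i in range(12)], "upregulated": [True] * 12}
        )
        comp = expr.family_composition(rec, top_n=3)
        assert "others" in set(comp["family"]) and len(comp) == 4


class TestCompareElementSets:
    def test_identical_and_disjoint(self):
        df = expr.compare_element_sets({"a": {"x", "y"}, "b": {"x", "y"}})
        ab = df[(df.set_a == "a") & (df.set_b == "b")].iloc[0]
        assert ab["fraction_of_a"] == pytest.approx(1.0)
        df2 = expr.compare_element_sets({"a": {"x"}, "b": {"y"}})
        assert df2[(df2.set_a == "a") & (df2.set_b == "b")]["fraction_of_a"].iloc[0] == 0

    def test_published_style_overlap_arithmetic(self):
        a = {f"e{i}" for i in range(610)}
        b = {f"e{i}" for i in range(602)} | {f"z{i}" for i in range(50)}
        df = expr.compare_element_sets({"a": a, "b": b})
        frac = df[(df.set_a == "a") & (df.set_b == "b")]["fraction_of_a"].iloc[0]
        assert round(100 * frac, 1) == 98.7


class TestWilcoxonFromBins:
    """Positional-bin replication unit for designs with few replicates."""

    def test_planted_difference_detected(self):
        from ltrscope.core import GenomicInterval, RepeatCopy, SignalTrack

        el = RepeatCopy(GenomicInterval("c", 1000, 3000, "+"), "LTR12C", "e")
        treated = SignalTrack({"c": [(1000, 3000, 5.0)]}, 1e6)
        control = SignalTrack(
            {"c": [(1000 + 100 * i, 1100 + 100 * i, 1.0 + 0.01 * i) for i in range(20)]},
            1e6,
        )
        p = expr.wilcoxon_from_bins(treated, control, el, bin_size=100)
        assert p < 0.001

    def test_identical_tracks_p_one(self):
        from ltrscope.core import GenomicInterval, RepeatCopy, SignalTrack

        el = RepeatCopy(GenomicInterval("c", 1000, 3000, "+"), "LTR12C", "e")
        t = SignalTrack({"c": [(1000, 3000, 2.0)]}, 1e6)
        with pytest.warns(UserWarning):
            assert expr.wilcoxon_from_bins(t, t, el, bin_size=200) == 1.0
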
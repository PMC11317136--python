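"""Signal aggregation, enrichment classification, summit shift,
methylation aggregation and profile matrices."""
import numpy as np
import pandas as pd
import pytest

from ltrscope import epistate as epi
from ltrscope.core import CpGRecord, GenomicInterval, RepeatCopy, SignalTrack


def make_element(start, end, strand, chrom="c", family="LTR12C"):
    return RepeatCopy(
        GenomicInterval(chrom, start, end, strand), family, f"{family}:{chrom}:{start}:{end}"
    )


def uniform_track(value, length=100_000, chrom="c"):
    return SignalTrack({chrom: [(0, length, value)]}, library_scale=1e6)


class TestAggregateSignal:
    def test_uniform_track(self):
        el = make_element(5000, 6500, "+")
        out = epi.aggregate_signal(uniform_track(3.0), [el], 400, 100)
        assert out[el.copy_id] == pytest.approx(3.0)

    def test_empty_track(self):
        el = make_element(5000, 6500, "+")
        out = epi.aggregate_signal(SignalTrack({}, 1e6), [el], 400, 100)
        assert out[el.copy_id] == 0.0

    def test_strand_mirror_symmetry(self):
        L = 10_000
        track = SignalTrack({"c": [(4000, 4500, 2.0), (4500, 5000, 7.0)]}, 1e6)
        mirrored = SignalTrack(
            {"c": [(L - e, L - s, v) for s, e, v in track.triples()["c"]]}, 1e6
        )
        plus = make_element(4200, 4900, "+")
        minus = make_element(L - 4900, L - 4200, "-")
        a = epi.aggregate_signal(track, [plus], 300, 150)[plus.copy_id]
        b = epi.aggregate_signal(mirrored, [minus], 300, 150)[minus.copy_id]
        assert a == pytest.approx(b)


class TestBindingSpecificity:
    def _elements(self, n_target, n_other):
        els = [make_element(1000 * i, 1000 * i + 500, "+") for i in range(n_target)]
        els += [
            make_element(1000 * (i + n_target), 1000 * (i + n_target) + 500, "+", family="LTR7")
            for i in range(n_other)
        ]
        return els

    def test_only_target_bound(self):
        els = self._elements(3, 3)
        peaks = [GenomicInterval("c", e.interval.start, e.interval.end) for e in els[:3]]
        counts, spec = epi.binding_specificity(peaks, els, "LTR12C")
        assert spec == pytest.approx(1.0)

    def test_ninety_nine_percent(self):
        els = self._elements(99, 1)
        peaks = [GenomicInterval("c", e.interval.start, e.interval.start + 10) for e in els]
        _, spec = epi.binding_specificity(peaks, els, "LTR12C")
        assert spec == pytest.approx(0.99)

    def test_no_peaks_nan(self):
        _, spec = epi.binding_specificity([], self._elements(2, 2), "LTR12C")
        assert np.isnan(spec)

    def test_invariant_to_peak_fragmentation(self):
        els = self._elements(5, 5)
        whole = [GenomicInterval("c", 0, 5500)]
        split = [GenomicInterval("c", i * 100, (i + 1) * 100) for i in range(55)]
        _, a = epi.binding_specificity(whole, els, "LTR12C")
        _, b = epi.binding_specificity(split, els, "LTR12C")
        assert a == b


class TestClassify:
    def _tracks(self, k27_fold, k4_fold, el, bg=0.5):
        L = 200_000
        base = [(0, L, bg)]
        tss = el.tss
        k27_iv = epi.oriented_window(tss, el.strand, 400, 100)
        k4_iv = epi.oriented_window(tss, el.strand, 0, 2000)

        def bump(iv, fold):
            s, e = iv
            return SignalTrack(
                {"c": [(0, s, bg), (s, e, bg * fold), (e, L, bg)]}, 1e6
            )

        k27 = bump(k27_iv, k27_fold) if k27_fold > 1 else SignalTrack({"c": base}, 1e6)
        k4 = bump(k4_iv, k4_fold) if k4_fold > 1 else SignalTrack({"c": base}, 1e6)
        return k4, k27

    @pytest.mark.parametrize(
        "k27_fold,k4_fold,expected",
        [(10, 10, "co_marked"), (10, 1, "single_marked"), (1, 1, "unmarked"),
         (1, 10, "unmarked")],  # H3K4me3 alone fits neither marked class
    )
    def test_classes(self, k27_fold, k4_fold, expected):
        el = make_element(50_000, 51_500, "+")
        k4, k27 = self._tracks(k27_fold, k4_fold, el)
        out = epi.classify_epistate(k4, k27, [], [el])
        assert out.loc[el.copy_id, "epi_class"] == expected

    def test_minus_strand_windows(self):
        el = make_element(50_000, 51_500, "-")
        k4, k27 = self._tracks(10, 10, el)
        out = epi.classify_epistate(k4, k27, [], [el])
        assert out.loc[el.copy_id, "epi_class"] == "co_marked"

    def test_missing_track_error(self):
        el = make_element(50_000, 51_500, "+")
        with pytest.raises(ValueError):
            epi.classify_epistate(None, uniform_track(1.0), [], [el])


class TestMarkShift:
    def test_symmetric_peak_offset_zero(self):
        el = make_element(50_000, 51_500, "+")
        tss = el.tss
        track = SignalTrack(
            {"c": [(tss - 200, tss + 201, 5.0)]}, 1e6
        )
        assert epi.detect_mark_shift(track, el) == 0

    def test_minus_strand_downstream_is_genomically_left(self):
        el = make_element(50_000, 51_500, "-")
        tss = el.tss  # 51_499
        # peaked summit planted 800 bp downstream on the element strand,
        # i.e. genomically LEFT of the TSS
        c = tss - 800
        triples = [(p, p + 1, float(np.exp(-(((p - c) / 80.0) ** 2)))) for p in range(c - 300, c + 301)]
        track = SignalTrack({"c": triples}, 1e6)
        assert epi.detect_mark_shift(track, el) == 800

    def test_flat_signal_warns_none(self):
        el = make_element(50_000, 51_500, "+")
        with pytest.warns(UserWarning):
            assert epi.detect_mark_shift(uniform_track(1.0, 200_000), el) is None


class TestMethylation:
    def region(self, start, end):
        return GenomicInterval("c", start, end)

    def test_mean_of_site_ratios(self):
        recs = [CpGRecord("c", 10, 10, 10), CpGRecord("c", 20, 0, 10)]
        out = epi.aggregate_methylation(recs, [self.region(0, 100)])
        assert out.iloc[0] == pytest.approx(0.5)

    def test_all_unmethylated(self):
        recs = [CpGRecord("c", i, 0, 5) for i in range(5)]
        assert epi.aggregate_methylation(recs, [self.region(0, 10)]).iloc[0] == 0.0

    def test_no_cpg_nan(self):
        out = epi.aggregate_methylation([], [self.region(0, 10)])
        assert np.isnan(out.iloc[0])

    def test_duplicates_pooled_before_ratio(self):
        # 1/10 and 9/10 at one site pool to 10/20 = 0.5, not mean(0.1, 0.9)
        recs = [CpGRecord("c", 10, 1, 10), CpGRecord("c", 10, 9, 10)]
        out = epi.aggregate_methylation(recs, [self.region(0, 100)])
        assert out.iloc[0] == pytest.approx(0.5)

    def test_record_order_invariance(self):
        recs = [
            CpGRecord("c", 30, 2, 4),
            CpGRecord("c", 10, 1, 2),
            CpGRecord("c", 20, 3, 3),
        ]
        a = epi.aggregate_methylation(recs, [self.region(0, 100)])
        b = epi.aggregate_methylation(recs[::-1], [self.region(0, 100)])
        assert a.iloc[0] == pytest.approx(b.iloc[0])

    def test_zero_coverage_site_skipped(self):
        recs = [CpGRecord("c", 10, 0, 0), CpGRecord("c", 20, 4, 4)]
        with pytest.warns(UserWarning):
            out = epi.aggregate_methylation(recs, [self.region(0, 100)])
        assert out.iloc[0] == pytest.approx(1.0)


class TestProfileMatrix:
    def test_uniform_flat(self):
        els = [make_element(50_000, 51_500, "+"), make_element(60_000, 61_500, "-")]
        pm = epi.build_profile_matrix(uniform_track(2.0), els, flank=1000, bin_size=50)
        assert np.allclose(pm.values, 2.0)
        assert np.allclose(pm.metaplot, 2.0)

    def test_delta_at_tss_peaks_at_zero(self):
        els = [make_element(50_000, 51_500, "+"), make_element(60_000, 61_500, "-")]
        triples = []
        for el in els:
            triples.append((el.tss - 10, el.tss + 10, 9.0))
        track = SignalTrack({"c": sorted(triples)}, 1e6)
        pm = epi.build_profile_matrix(track, els, flank=1000, bin_size=50)
        peak_bin = pm.positions[np.argmax(pm.metaplot)]
        assert abs(peak_bin) <= 50

    def test_mirrored_strands_identical_rows(self):
        L = 100_000
        plus = make_element(40_000, 41_500, "+")
        minus = make_element(L - 41_500, L - 40_000, "-")
        fwd = [(plus.tss + 100, plus.tss + 300, 4.0)]
        mirrored = [(L - e, L - s, v) for s, e, v in fwd]
        track = SignalTrack({"c": sorted(fwd + mirrored)}, 1e6)
        pm = epi.build_profile_matrix(track, [plus, minus], flank=500, bin_size=25)
        assert np.allclose(pm.values[0], pm.values[1])

    def test_row_ordering(self):
        els = [make_element(50_000, 51_500, "+"), make_element(60_000, 61_500, "+")]
        order = {els[0].copy_id: 1.0, els[1].copy_id: 5.0}
        pm = epi.build_profile_matrix(
            uniform_track(1.0), els, flank=500, bin_size=25, order_by=order
        )
        assert pm.element_ids[0] == els[1].copy_id
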
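"""Poly(A) detection, read-through attribution, gene linkage, group
comparison and TAD co-membership."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from ltrscope import linkage as lnk
from ltrscope.core import GeneModel, GenomicInterval, RepeatCopy, SignalTrack


def element(start, end, strand, family="LTR12C", chrom="c"):
    return RepeatCopy(
        GenomicInterval(chrom, start, end, strand), family, f"{family}:{chrom}:{start}:{end}"
    )


class TestPolyA:
    def test_plus_strand_at_zero(self):
        assert lnk.find_polya_signals("AATAAACCC", "+") == [0]

    def test_minus_strand_reads_reverse_complement(self):
        seq = "CCTTTATTCC"  # revcomp contains AATAAA at genomic pos 2
        assert lnk.find_polya_signals(seq, "+") == []
        assert lnk.find_polya_signals(seq, "-") == [2]

    def test_no_motif(self):
        assert lnk.find_polya_signals("ACGT" * 10, "+") == []

    def test_offset_and_alternative_hexamer(self):
        assert lnk.find_polya_signals("GGATTAAAGG", "+", offset=100) == [102]


class TestAttributeReadthrough:
    def _setup(self, downstream_strand="+", gap_value=2.0, distance=5000):
        src = element(10_000, 11_500, "+")
        down = element(11_500 + distance, 12_300 + distance, downstream_strand, family="LTR7")
        track = SignalTrack(
            {"c": [(10_000, 11_500, 4.0), (11_500, 11_500 + distance, gap_value)]},
            1e6,
        )
        return src, down, track

    def test_same_strand_continuous_coverage_attributed(self):
        src, down, track = self._setup()
        calls, frac = lnk.attribute_readthrough([down], [src], track)
        assert bool(calls["attributed"].iloc[0]) and frac == 1.0
        assert calls["source_element_id"].iloc[0] == src.copy_id

    def test_opposite_strand_not_attributed(self):
        src, down, track = self._setup(downstream_strand="-")
        calls, frac = lnk.attribute_readthrough([down], [src], track)
        assert not calls["attributed"].iloc[0] and frac == 0.0

    def test_low_gap_coverage_not_attributed(self):
        src, down, track = self._setup(gap_value=0.1)
        calls, _ = lnk.attribute_readthrough([down], [src], track)
        assert not calls["attributed"].iloc[0]

    def test_beyond_max_distance_not_attributed(self):
        src, down, track = self._setup(distance=25_000)
        calls, _ = lnk.attribute_readthrough([down], [src], track, max_distance=20_000)
        assert calls["source_element_id"].iloc[0] is None

    def test_monotone_in_max_distance(self):
        src, down, track = self._setup(distance=15_000)
        small = lnk.attribute_readthrough([down], [src], track, max_distance=10_000)[0]
        large = lnk.attribute_readthrough([down], [src], track, max_distance=20_000)[0]
        assert int(small["attributed"].sum()) <= int(large["attributed"].sum())

    def test_minus_strand_geometry(self):
        # on '-', the downstream element lies genomically LEFT of the source
        src = element(50_000, 51_500, "-")
        down = element(44_000, 44_800, "-", family="LTR7")
        track = SignalTrack({"c": [(43_000, 52_000, 3.0)]}, 1e6)
        calls, _ = lnk.attribute_readthrough([down], [src], track)
        assert bool(calls["attributed"].iloc[0])
        assert calls["distance"].iloc[0] == 50_000 - 44_800

    def test_polya_counted_in_gap(self):
        src, down, track = self._setup()
        genome = {"c": "T" * 13_000 + "AATAAA" + "T" * 10_000}
        calls, _ = lnk.attribute_readthrough([down], [src], track, genome=genome)
        assert calls["n_polya_traversed"].iloc[0] == 1


def flat_tracks(length=200_000, value=0.5):
    t = SignalTrack({"c": [(0, length, value)]}, 1e6)
    return {"k4": t, "k27": t}


class TestLinkGenes:
    def _gene(self, tss, strand="+", length=2000):
        if strand == "+":
            iv = GenomicInterval("c", tss, tss + length, "+")
            return GeneModel(iv, f"g{tss}", (tss,), (tss + length,))
        iv = GenomicInterval("c", tss - length + 1, tss + 1, "-")
        return GeneModel(iv, f"g{tss}", (tss - length + 1,), (tss + 1,))

    def test_downstream_gene_linked_with_class(self):
        el = element(10_000, 11_500, "+")
        gene = self._gene(21_500)  # 10 kb downstream of the element end
        links = lnk.link_genes(
            [el], {el.copy_id: "co_marked"}, [gene], {gene.gene_id: True},
            flat_tracks(), flat_tracks(),
        )
        row = links.iloc[0]
        assert row["linked"] and row["element_class"] == "co_marked"
        assert row["distance"] == 10_000

    def test_upstream_gene_not_linked(self):
        el = element(50_000, 51_500, "+")
        gene = self._gene(40_000)
        links = lnk.link_genes(
            [el], {el.copy_id: "co_marked"}, [gene], {gene.gene_id: True},
            flat_tracks(), flat_tracks(),
        )
        assert not links.iloc[0]["linked"] and links.iloc[0]["element_id"] is None

    def test_changed_promoter_blocks_link(self):
        el = element(10_000, 11_500, "+")
        gene = self._gene(21_500)
        treated = {
            "k4": SignalTrack({"c": [(0, 21_000, 0.5), (21_000, 22_000, 5.0), (22_000, 200_000, 0.5)]}, 1e6),
            "k27": SignalTrack({"c": [(0, 200_000, 0.5)]}, 1e6),
        }
        links = lnk.link_genes(
            [el], {el.copy_id: "co_marked"}, [gene], {gene.gene_id: True},
            treated, flat_tracks(),
        )
        assert not links.iloc[0]["linked"]
        assert links.iloc[0]["promoter_unchanged"] == False  # noqa: E712

    def test_not_upregulated_not_linked(self):
        el = element(10_000, 11_500, "+")
        gene = self._gene(21_500)
        links = lnk.link_genes(
            [el], {el.copy_id: "single_marked"}, [gene], {gene.gene_id: False},
            flat_tracks(), flat_tracks(),
        )
        assert not links.iloc[0]["linked"]

    def test_unmarked_elements_never_link(self):
        el = element(10_000, 11_500, "+")
        gene = self._gene(21_500)
        links = lnk.link_genes(
            [el], {el.copy_id: "unmarked"}, [gene], {gene.gene_id: True},
            flat_tracks(), flat_tracks(),
        )
        assert links.iloc[0]["element_id"] is None


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        df = lnk.compare_group_expression({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert df["p_value"].iloc[0] > 0.9

    def test_exact_small_sample(self):
        # complete separation of 3 vs 3: U = 0, exact two-sided p = 0.1
        df = lnk.compare_group_expression({"a": [1, 2, 3], "b": [10, 20, 30]})
        assert df["U"].iloc[0] == 0.0
        assert df["p_value"].iloc[0] == pytest.approx(0.1)

    def test_single_comparison_adjusted_equals_raw(self):
        df = lnk.compare_group_expression({"a": [1, 2, 3], "b": [2, 3, 4]})
        assert df["p_adjusted"].iloc[0] == pytest.approx(df["p_value"].iloc[0])

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            lnk.compare_group_expression({"a": [], "b": [1]})

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8)
    )
    def test_holm_dominates_raw_and_is_monotone(self, pvals):
        adj = multipletests(pvals, method="holm")[1]
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestTADs:
    tads = [GenomicInterval("c", 0, 10_000), GenomicInterval("c", 10_000, 20_000)]

    def gene(self, tss):
        return GeneModel(
            GenomicInterval("c", tss, tss + 100, "+"), f"g{tss}", (tss,), (tss + 100,)
        )

    def test_same_tad(self):
        el = element(2_000, 3_000, "+")
        series, n = lnk.tad_comembership([self.gene(5_000)], [el], self.tads)
        assert series.iloc[0] and n == 1

    def test_adjacent_tads(self):
        el = element(2_000, 3_000, "+")
        series, _ = lnk.tad_comembership([self.gene(15_000)], [el], self.tads)
        assert not series.iloc[0]

    def test_boundary_is_half_open(self):
        # TSS exactly at 10_000 belongs to the second TAD
        el = element(10_000, 11_000, "+")
        series, _ = lnk.tad_comembership([self.gene(15_000)], [el], self.tads)
        assert series.iloc[0]

    def test_gene_outside_all_tads(self):
        el = element(2_000, 3_000, "+")
        series, _ = lnk.tad_comembership([self.gene(50_000)], [el], self.tads)
        assert not series.iloc[0]
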
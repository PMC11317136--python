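"""Read-through attribution and proximal-gene linkage.

Transactivated LTR copies often transcribe past their own poly(A)
signal, so downstream repeats and genes gain expression without being
bound themselves. This module finds poly(A) hexamers, attributes each
upregulated non-target element to the nearest same-strand transactivated
source upstream (requiring continuing RNA coverage across the gap),
links upregulated coding genes to proximal transactivated elements whose
own promoters did not change, compares group expression (Mann-Whitney U
with Holm correction), and tests TAD co-membership.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval, RepeatCopy, SignalTrack, revcomp
from .epistate import oriented_window

POLYA_MOTIFS = ("AATAAA", "ATTAAA")


def find_polya_signals(sequence: str, strand: str, offset: int = 0) -> List[int]:
    """Genome coordinates (motif start, forward coords) of canonical
    poly(A) hexamers read on the given strand; overlapping occurrences
    are all reported."""
    seq = sequence.upper()
    motifs = POLYA_MOTIFS if strand == "+" else tuple(revcomp(m) for m in POLYA_MOTIFS)
    hits = []
    for motif in motifs:
        start = seq.find(motif)
        while start != -1:
            hits.append(offset + start)
            start = seq.find(motif, start + 1)
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# read-through attribution


def _gap_between(source: RepeatCopy, downstream: RepeatCopy) -> Optional[Tuple[int, int, int]]:
    """(gap_start, gap_end, distance) if ``downstream`` lies 3' of
    ``source`` on the source strand and chromosome, else None."""
    if source.chrom != downstream.chrom:
        return None
    s, d = source.interval, downstream.interval
    if source.strand == "+":
        if d.start < s.end:
            return None
        return s.end, d.start, d.start - s.end
    if d.end > s.start:
        return None
    return d.end, s.start, s.start - d.end


def attribute_readthrough(
    upregulated_nontarget: Sequence[RepeatCopy],
    transactivated_sources: Sequence[RepeatCopy],
    rna_track: SignalTrack,
    genome: Optional[Mapping[str, str]] = None,
    max_distance: int = 20000,
    min_ratio: float = 0.2,
    min_covered_fraction: float = 0.8,
) -> Tuple[pd.DataFrame, float]:
    """Attribute upregulated non-target elements to read-through from the
    nearest same-strand transactivated source upstream.

    Attributed requires: same strand, source within ``max_distance`` bp
    upstream (strand-aware), mean RNA RPM across the gap at least
    ``min_ratio`` of the mean over the source element, and continuous
    coverage — at least ``min_covered_fraction`` of gap bases at or above
    the ``min_ratio`` level. The continuity requirement separates a true
    read-through isoform (which covers the whole gap) from unrelated
    transcription islands inside a long gap. Returns the per-element
    call table plus the attributed fraction.
    """
    rows = []
    n_attr = 0
    for el in upregulated_nontarget:
        best = None  # (distance, source, gap_start, gap_end)
        for src in transactivated_sources:
            if src.strand != el.strand:
                continue
            gap = _gap_between(src, el)
            if gap is None or gap[2] > max_distance:
                continue
            if best is None or gap[2] < best[0]:
                best = (gap[2], src, gap[0], gap[1])
        if best is None:
            rows.append(
                {
                    "downstream_element_id": el.copy_id,
                    "source_element_id": None,
                    "distance": np.nan,
                    "same_strand": False,
                    "gap_coverage_ratio": np.nan,
                    "gap_covered_fraction": np.nan,
                    "n_polya_traversed": 0,
                    "attributed": False,
                }
            )
            continue
        distance, src, gap_start, gap_end = best
        src_rpm = rna_track.mean_rpm(src.chrom, src.interval.start, src.interval.end)
        if gap_end > gap_start:
            gap_rpm = rna_track.mean_rpm(src.chrom, gap_start, gap_end)
            ratio = gap_rpm / src_rpm if src_rpm > 0 else np.nan
            per_bp = rna_track.per_base(src.chrom, gap_start, gap_end)
            scale = 1e6 / rna_track.library_scale
            covered = float(np.mean(per_bp * scale >= min_ratio * src_rpm))
        else:
            ratio = 1.0  # abutting elements: coverage is trivially continuous
            covered = 1.0
        n_polya = 0
        if genome is not None and gap_end > gap_start:
            seq = genome[src.chrom][gap_start:gap_end]
            n_polya = len(find_polya_signals(seq, src.strand))
        attributed = (
            bool(ratio >= min_ratio and covered >= min_covered_fraction)
            if np.isfinite(ratio)
            else False
        )
        n_attr += attributed
        rows.append(
            {
                "downstream_element_id": el.copy_id,
                "source_element_id": src.copy_id,
                "distance": distance,
                "same_strand": True,
                "gap_coverage_ratio": ratio,
                "gap_covered_fraction": covered,
                "n_polya_traversed": n_polya,
                "attributed": attributed,
            }
        )
    df = pd.DataFrame(rows)
    frac = n_attr / len(rows) if rows else np.nan
    return df, frac


# ---------------------------------------------------------------------------
# gene linkage


def _promoter_unchanged(
    gene: GeneModel,
    tracks_treated: Mapping[str, SignalTrack],
    tracks_control: Mapping[str, SignalTrack],
    promoter_window: Tuple[int, int],
    promoter_fold: float,
    eps: float = 0.05,
) -> bool:
    a, b = oriented_window(gene.tss, gene.strand, *promoter_window)
    for mark in ("k4", "k27"):
        t = tracks_treated[mark].mean_rpm(gene.chrom, a, b)
        c = tracks_control[mark].mean_rpm(gene.chrom, a, b)
        ratio = (t + eps) / (c + eps)
        if ratio >= promoter_fold or ratio <= 1.0 / promoter_fold:
            return False
    return True


def link_genes(
    elements: Sequence[RepeatCopy],
    element_classes: Mapping[str, str],
    genes: Sequence[GeneModel],
    gene_upregulated: Mapping[str, bool],
    tracks_treated: Mapping[str, SignalTrack],
    tracks_control: Mapping[str, SignalTrack],
    max_gene_distance: int = 50000,
    promoter_fold: float = 1.5,
    promoter_window: Tuple[int, int] = (500, 500),
    symmetric: bool = False,
) -> pd.DataFrame:
    """Link upregulated genes to proximal transactivated elements.

    A candidate gene has its TSS within ``max_gene_distance`` bp
    downstream (element-strand-aware; ``symmetric=True`` allows either
    side for enhancer-style linking) of a transactivated element, and is
    linked to the nearest such element provided neither H3K4me3 nor
    H3K27ac changed by >= ``promoter_fold`` at the gene's own promoter.
    ``tracks_treated``/``tracks_control`` map {'k4','k27'} to tracks.
    Genes upregulated with no proximal element are reported with
    element_id None (candidates for distal/TAD analysis).
    """
    marked = [
        el
        for el in elements
        if element_classes.get(el.copy_id, "unmarked") != "unmarked"
    ]
    rows = []
    for gene in genes:
        up = bool(gene_upregulated.get(gene.gene_id, False))
        best = None  # (distance, element)
        for el in marked:
            if el.chrom != gene.chrom:
                continue
            if el.strand == "+":
                dist = gene.tss - el.interval.end
            else:
                dist = el.interval.start - 1 - gene.tss
            if symmetric:
                dist = abs(dist)
            if 0 <= dist <= max_gene_distance:
                if best is None or dist < best[0]:
                    best = (dist, el)
        if best is None:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "element_id": None,
                    "element_class": None,
                    "distance": np.nan,
                    "promoter_unchanged": None,
                    "linked": False,
                    "gene_upregulated": up,
                }
            )
            continue
        dist, el = best
        unchanged = _promoter_unchanged(
            gene, tracks_treated, tracks_control, promoter_window, promoter_fold
        )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "element_id": el.copy_id,
                "element_class": element_classes[el.copy_id],
                "distance": dist,
                "promoter_unchanged": unchanged,
                "linked": bool(up and unchanged),
                "gene_upregulated": up,
            }
        )
    return pd.DataFrame(rows)


def link_counts_per_class(links: pd.DataFrame) -> pd.Series:
    linked = links[links["linked"]]
    return linked.groupby("element_class").size()


# ---------------------------------------------------------------------------
# group expression comparison


def compare_group_expression(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests across named groups of
    RPKM values, with Holm step-down adjustment over the whole family of
    comparisons."""
    for name, values in groups.items():
        if len(values) == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for a, b in pairs:
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "U": float(res.statistic), "p_value": float(res.pvalue)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_value"], method="holm")[1]
    else:
        df["p_adjusted"] = []
    return df


# ---------------------------------------------------------------------------
# TAD co-membership


def tad_comembership(
    genes: Sequence[GeneModel],
    elements: Sequence[RepeatCopy],
    tads: Sequence[GenomicInterval],
) -> Tuple[pd.Series, int]:
    """Per-gene: does its TSS share a TAD with >= 1 transactivated
    element (element TSS, half-open containment)? Genes in no TAD are
    False."""
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in tads}:
        ts = sorted(t for t in tads if t.chrom == chrom)
        starts = np.array([t.start for t in ts])
        ends = np.array([t.end for t in ts])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping TADs on {chrom}")
        by_chrom[chrom] = (starts, ends)

    def tad_of(chrom: str, pos: int) -> Optional[Tuple[str, int]]:
        if chrom not in by_chrom:
            return None
        starts, ends = by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return (chrom, i)
        return None

    element_tads = {tad_of(el.chrom, el.tss) for el in elements} - {None}
    out = {}
    for gene in genes:
        t = tad_of(gene.chrom, gene.tss)
        out[gene.gene_id] = t is not None and t in element_tads
    series = pd.Series(out, name="same_tad")
    return series, int(series.sum())
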
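"""Strand-aware chromatin-state analysis around repeat TSSs.

After transactivation, most responsive copies gain H3K27ac over their
promoter/enhancer region (400 bp upstream of the TSS) while only a
subset additionally gain promoter-type H3K4me3, which sits shifted
*downstream* of the TSS rather than over it. This module aggregates
track signal in strand-oriented windows, classifies each element as
co-marked / single-marked / unmarked, locates the H3K4me3 summit
offset, computes dCas9 binding specificity from peaks, aggregates CpG
methylation, and builds heatmap/metaplot matrices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import CpGRecord, GenomicInterval, RepeatCopy, SignalTrack

Element = Union[RepeatCopy, "object"]  # anything with chrom/strand/tss


def oriented_window(tss: int, strand: str, upstream: int, downstream: int) -> Tuple[int, int]:
    """Genomic [start, end) of the window spanning ``upstream`` bp 5' of the
    TSS through ``downstream`` bp 3' of it (TSS position counts as
    downstream position 0)."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream + 1, tss + upstream + 1


def aggregate_signal(
    track: SignalTrack,
    elements: Sequence[RepeatCopy],
    window_upstream: int,
    window_downstream: int,
) -> pd.Series:
    """Mean RPM per element over the strand-oriented TSS window."""
    if window_upstream < 0 or window_downstream < 0:
        raise ValueError("window extents must be non-negative")
    vals = {}
    for el in elements:
        a, b = oriented_window(el.tss, el.strand, window_upstream, window_downstream)
        vals[el.copy_id] = track.mean_rpm(el.chrom, a, b)
    return pd.Series(vals, name="mean_rpm")


# ---------------------------------------------------------------------------
# dCas9 binding specificity


def _peak_index(peaks: Sequence[GenomicInterval]):
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = sorted(p for p in peaks if p.chrom == chrom)
        by_chrom[chrom] = (
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
        )
    return by_chrom


def element_bound(peaks_by_chrom, el) -> bool:
    if el.chrom not in peaks_by_chrom:
        return False
    starts, ends = peaks_by_chrom[el.chrom]
    iv = el.interval
    i = np.searchsorted(starts, iv.end, side="left")
    return bool(np.any(ends[:i] > iv.start))


def binding_specificity(
    peaks: Sequence[GenomicInterval],
    elements: Sequence[RepeatCopy],
    target_family: str,
) -> Tuple[pd.DataFrame, float]:
    """Per-family bound-element counts among (upregulated) elements and the
    binding specificity = bound target-family / all bound elements.

    An element is bound iff it overlaps a peak by >= 1 bp, so the result
    is invariant to splitting a peak into abutting fragments. With no
    bound element the specificity is NaN.
    """
    idx = _peak_index(peaks)
    rows = [
        {"element_id": el.copy_id, "family": el.family, "bound": element_bound(idx, el)}
        for el in elements
    ]
    df = pd.DataFrame(rows)
    if df.empty or not df["bound"].any():
        return (
            df.groupby("family")["bound"].sum().rename("n_bound").reset_index()
            if not df.empty
            else pd.DataFrame(columns=["family", "n_bound"]),
            float("nan"),
        )
    counts = df[df["bound"]].groupby("family").size().rename("n_bound").reset_index()
    n_target = int(df[(df["family"] == target_family) & df["bound"]].shape[0])
    specificity = n_target / int(df["bound"].sum())
    return counts, specificity


# ---------------------------------------------------------------------------
# background estimation


def _excluded_overlap_fn(exclusions: Sequence[GenomicInterval], chrom: str):
    ivs = sorted((e.start, e.end) for e in exclusions if e.chrom == chrom)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    if not merged:
        return lambda s, e: 0
    ms = np.array([m[0] for m in merged])
    me = np.array([m[1] for m in merged])
    prefix = np.concatenate([[0], np.cumsum(me - ms)])

    def covered_upto(x: np.ndarray) -> np.ndarray:
        i = np.searchsorted(me, x, side="left")
        partial = np.clip(x - ms[np.minimum(i, len(ms) - 1)], 0, (me - ms)[np.minimum(i, len(ms) - 1)])
        partial = np.where(i < len(ms), partial, 0)
        return prefix[i] + partial

    return lambda s, e: covered_upto(np.asarray(e)) - covered_upto(np.asarray(s))


def background_rpm(
    track: SignalTrack,
    exclude: Sequence[GenomicInterval] = (),
    trim: float = 0.05,
) -> float:
    """Genome-background RPM: bp-weighted trimmed mean of the track value,
    excluding annotated (repeat/gene) windows."""
    values: List[np.ndarray] = []
    weights: List[np.ndarray] = []
    for chrom in track.chroms:
        starts, ends, vals = track.intervals(chrom)
        w = (ends - starts).astype(float)
        if exclude:
            fn = _excluded_overlap_fn(exclude, chrom)
            w = w - fn(starts, ends)
        keep = w > 0
        values.append(vals[keep])
        weights.append(w[keep])
    if not values or sum(w.sum() for w in weights) == 0:
        return 0.0
    v = np.concatenate(values)
    w = np.concatenate(weights)
    order = np.argsort(v)
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    total = cum[-1]
    lo, hi = trim * total, (1 - trim) * total
    # bp-weighted trim: clip each interval's weight to the retained band
    left = np.concatenate([[0], cum[:-1]])
    eff = np.minimum(cum, hi) - np.maximum(left, lo)
    eff = np.clip(eff, 0, None)
    if eff.sum() == 0:
        return 0.0
    mean_value = float(np.sum(v * eff) / eff.sum())
    return mean_value * 1e6 / track.library_scale


# ---------------------------------------------------------------------------
# classification


@dataclass
class EpiParams:
    """Tunable geometry/thresholds for epi-state classification.

    Windows are (upstream, downstream) bp relative to the strand-aware
    TSS. A mark is enriched when its window RPM is at least
    ``enrich_fold`` times the genome background and above ``min_rpm``.
    """

    k27_window: Tuple[int, int] = (400, 100)
    k4_window: Tuple[int, int] = (0, 2000)
    enrich_fold: float = 2.0
    min_rpm: float = 0.05
    shift_span: Tuple[int, int] = (2000, 4000)
    smooth_bp: int = 150


CLASSES = ("co_marked", "single_marked", "unmarked")


def classify_epistate(
    k4_track: SignalTrack,
    k27_track: SignalTrack,
    ha_peaks: Sequence[GenomicInterval],
    elements: Sequence[RepeatCopy],
    params: EpiParams = EpiParams(),
    background_exclude: Sequence[GenomicInterval] = (),
) -> pd.DataFrame:
    """Classify each element as co_marked (H3K27ac + H3K4me3),
    single_marked (H3K27ac only) or unmarked.

    H3K4me3 without H3K27ac does not fit either marked class and is
    reported as unmarked. Co-marked/k4-enriched elements also get their
    H3K4me3 summit offset (strand-aware bp downstream of the TSS).
    """
    if k4_track is None or k27_track is None:
        raise ValueError("both H3K4me3 and H3K27ac tracks are required")
    bg_k4 = background_rpm(k4_track, background_exclude)
    bg_k27 = background_rpm(k27_track, background_exclude)
    k27 = aggregate_signal(k27_track, elements, *params.k27_window)
    k4 = aggregate_signal(k4_track, elements, *params.k4_window)
    peak_idx = _peak_index(ha_peaks)
    rows = []
    for el in elements:
        k27_rpm, k4_rpm = float(k27[el.copy_id]), float(k4[el.copy_id])
        k27_enr = k27_rpm >= max(params.enrich_fold * bg_k27, params.min_rpm)
        k4_enr = k4_rpm >= max(params.enrich_fold * bg_k4, params.min_rpm)
        if k27_enr and k4_enr:
            cls = "co_marked"
        elif k27_enr:
            cls = "single_marked"
        else:
            cls = "unmarked"
        offset = np.nan
        if k4_enr:
            off = detect_mark_shift(
                k4_track,
                el,
                span_upstream=params.shift_span[0],
                span_downstream=params.shift_span[1],
                smooth_bp=params.smooth_bp,
            )
            offset = np.nan if off is None else off
        rows.append(
            {
                "element_id": el.copy_id,
                "family": el.family,
                "k27_rpm": k27_rpm,
                "k4_rpm": k4_rpm,
                "k27_background": bg_k27,
                "k4_background": bg_k4,
                "ha_bound": element_bound(peak_idx, el),
                "epi_class": cls,
                "k4_summit_offset": offset,
            }
        )
    columns = [
        "element_id", "family", "k27_rpm", "k4_rpm", "k27_background",
        "k4_background", "ha_bound", "epi_class", "k4_summit_offset",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("element_id")


def detect_mark_shift(
    track: SignalTrack,
    element: RepeatCopy,
    span_upstream: int = 2000,
    span_downstream: int = 4000,
    smooth_bp: int = 150,
) -> Optional[int]:
    """Strand-aware offset of the smoothed signal summit from the TSS
    (positive = downstream). Ties pick the smallest |offset| (downstream
    preferred on exact +/- ties); a flat profile returns None with a
    warning."""
    tss, strand, chrom = element.tss, element.strand, element.chrom
    offsets = np.arange(-span_upstream, span_downstream + 1)
    pad = smooth_bp  # avoid moving-average edge taper inside the span
    if strand == "+":
        sig = track.per_base(
            chrom, tss - span_upstream - pad, tss + span_downstream + 1 + pad
        )
    else:
        sig = track.per_base(
            chrom, tss - span_downstream - pad, tss + span_upstream + 1 + pad
        )[::-1]
    if np.allclose(sig, sig[0]):
        warnings.warn(f"flat signal around {element.copy_id}; summit undefined")
        return None
    if smooth_bp > 1:
        kernel = np.ones(smooth_bp) / smooth_bp
        sig = np.convolve(sig, kernel, mode="same")
    sig = sig[pad : pad + offsets.size]
    peak = sig.max()
    cand = offsets[np.isclose(sig, peak)]
    best = min(cand, key=lambda o: (abs(int(o)), -np.sign(o)))
    return int(best)


# ---------------------------------------------------------------------------
# methylation


def aggregate_methylation(
    records: Iterable[CpGRecord],
    regions: Sequence[GenomicInterval],
) -> pd.Series:
    """Mean CpG methylation per region.

    Duplicate records at one site are pooled (summed reads) before the
    per-site ratio; the region value is the unweighted mean of per-site
    ratios. Regions without covered CpGs get NaN; zero-coverage sites are
    skipped with a warning.
    """
    pooled: Dict[Tuple[str, int], List[int]] = {}
    for r in records:
        key = (r.chrom, r.pos)
        if key in pooled:
            pooled[key][0] += r.n_meth
            pooled[key][1] += r.n_total
        else:
            pooled[key] = [r.n_meth, r.n_total]
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    skipped = 0
    for chrom in {c for c, _ in pooled}:
        items = sorted(
            (pos, m, t) for (c, pos), (m, t) in pooled.items() if c == chrom
        )
        good = [(p, m / t) for p, m, t in items if t > 0]
        skipped += sum(1 for _, _, t in items if t == 0)
        by_chrom[chrom] = (
            np.array([p for p, _ in good]),
            np.array([r for _, r in good]),
        )
    if skipped:
        warnings.warn(f"{skipped} CpG sites with zero coverage skipped")
    out = {}
    for i, region in enumerate(regions):
        name = getattr(region, "copy_id", None) or f"{region.chrom}:{region.start}-{region.end}"
        if region.chrom not in by_chrom:
            out[name] = np.nan
            continue
        pos, ratios = by_chrom[region.chrom]
        i0 = np.searchsorted(pos, region.start, side="left")
        i1 = np.searchsorted(pos, region.end, side="left")
        out[name] = float(np.mean(ratios[i0:i1])) if i1 > i0 else np.nan
    return pd.Series(out, name="mean_methylation")


# ---------------------------------------------------------------------------
# heatmap / metaplot matrices


@dataclass
class ProfileMatrix:
    """Strand-oriented per-element signal matrix around the TSS."""

    element_ids: List[str]
    positions: np.ndarray  # bin left edges, bp relative to TSS
    values: np.ndarray  # shape (n_elements, n_bins), RPM

    @property
    def metaplot(self) -> np.ndarray:
        """Column means across elements (the average occupancy profile)."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.element_ids, columns=self.positions
        ).rename_axis("element_id")


def build_profile_matrix(
    track: SignalTrack,
    elements: Sequence[RepeatCopy],
    flank: int = 3000,
    bin_size: int = 25,
    order_by: Optional[Mapping[str, float]] = None,
) -> ProfileMatrix:
    """Per-element RPM rows over [-flank, +flank) around the TSS in
    strand-oriented bins. Rows are ordered by ``order_by`` descending
    (e.g. RNA RPM per element) or kept in input order."""
    if flank <= 0 or bin_size <= 0:
        raise ValueError("flank and bin must be positive")
    n_bins = (2 * flank) // bin_size
    span = n_bins * bin_size
    half = span // 2
    rows = []
    ids = []
    scale = 1e6 / track.library_scale
    for el in elements:
        tss, strand = el.tss, el.strand
        if strand == "+":
            arr = track.per_base(el.chrom, tss - half, tss + half)
        else:
            arr = track.per_base(el.chrom, tss - half + 1, tss + half + 1)[::-1]
        rows.append(arr.reshape(n_bins, bin_size).mean(axis=1) * scale)
        ids.append(el.copy_id)
    values = np.vstack(rows) if rows else np.zeros((0, n_bins))
    if order_by is not None:
        order = sorted(
            range(len(ids)), key=lambda i: -float(order_by.get(ids[i], 0.0))
        )
        ids = [ids[i] for i in order]
        values = values[order]
    positions = np.arange(-half, half, bin_size)
    return ProfileMatrix(ids, positions, values)
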
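"""Core domain containers shared by every stage of the pipeline.

All coordinates are 0-based half-open on the forward genome strand.
1-based dialects (RepeatMasker .out, GTF) are converted at the I/O
boundary and never seen past it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (non-ACGTN mapped to N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-annotated genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatCopy:
    """One annotated repeat instance.

    The TSS of a repeat copy is its 5' terminus on its own strand:
    ``start`` on '+', ``end - 1`` on '-'.
    """

    interval: GenomicInterval
    family: str
    copy_id: str

    def __post_init__(self):
        if not self.copy_id:
            raise ValueError("copy_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("repeat copies must be stranded (+ or -)")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A gene with an exon chain; TSS is the strand-aware 5' end."""

    interval: GenomicInterval
    gene_id: str
    exon_starts: Tuple[int, ...]
    exon_ends: Tuple[int, ...]

    def __post_init__(self):
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError("need matched, non-empty exon start/end lists")
        prev_end = self.interval.start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError("exon start must precede exon end")
            if s < self.interval.start or e > self.interval.end:
                raise ValueError("exons must lie within the gene interval")
            if s <= prev_end and prev_end >= self.interval.start:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def exonic_length(self) -> int:
        return int(sum(e - s for s, e in zip(self.exon_starts, self.exon_ends)))


class SignalTrack:
    """Piecewise-constant coverage signal over a genome.

    Stores per-chromosome sorted, non-overlapping (start, end, value)
    triples plus a ``library_scale`` (total mapped reads) used to express
    window means as RPM: mean_value * 1e6 / library_scale.
    """

    def __init__(
        self,
        data: Dict[str, Sequence[Tuple[int, int, float]]],
        library_scale: float,
        chrom_sizes: Optional[Dict[str, int]] = None,
    ):
        if library_scale <= 0:
            raise ValueError("library_scale must be positive")
        self.library_scale = float(library_scale)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        self._chroms: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in data.items():
            arr = np.asarray(sorted(triples), dtype=float)
            if arr.size == 0:
                continue
            starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
            if np.any(values < 0) or not np.all(np.isfinite(values)):
                raise ValueError(f"negative or non-finite value on {chrom}")
            if np.any(starts >= ends):
                raise ValueError(f"empty interval on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._chroms[chrom] = (
                starts.astype(np.int64),
                ends.astype(np.int64),
                values,
            )

    @property
    def chroms(self) -> List[str]:
        return list(self._chroms)

    def intervals(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._chroms:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._chroms[chrom]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x bp over [start, end)."""
        if end <= start:
            return 0.0
        starts, ends, values = self.intervals(chrom)
        if starts.size == 0:
            return 0.0
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i0 >= i1:
            return 0.0
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        return float(np.sum(ov * values[i0:i1]))

    def mean_rpm(self, chrom: str, start: int, end: int) -> float:
        """Mean RPM over [start, end); clips at chromosome bounds with
        length renormalisation to the clipped extent."""
        lo, hi = start, end
        if self.chrom_sizes is not None:
            if chrom not in self.chrom_sizes:
                raise KeyError(f"unknown chromosome {chrom!r}")
            size = self.chrom_sizes[chrom]
            if start >= size or end <= 0:
                raise ValueError(
                    f"window [{start}, {end}) lies off chromosome {chrom}"
                )
            lo, hi = max(0, start), min(size, end)
        else:
            lo = max(0, start)
        if hi <= lo:
            return 0.0
        mean_value = self.window_sum(chrom, lo, hi) / (hi - lo)
        return mean_value * 1e6 / self.library_scale

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp value array over [start, end); out-of-track bp are 0."""
        out = np.zeros(end - start)
        starts, ends, values = self.intervals(chrom)
        if starts.size == 0:
            return out
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[i0:i1], ends[i0:i1], values[i0:i1]):
            out[max(s, start) - start : min(e, end) - start] = v
        return out

    def triples(self) -> Dict[str, List[Tuple[int, int, float]]]:
        return {
            chrom: [
                (int(s), int(e), float(v)) for s, e, v in zip(*self._chroms[chrom])
            ]
            for chrom in sorted(self._chroms)
        }


@dataclass(frozen=True)
class CpGRecord:
    """Methylation counts at one CpG site."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self):
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError("require 0 <= n_meth <= n_total")


def check_unique_copy_ids(copies: Iterable[RepeatCopy]) -> None:
    seen = set()
    for c in copies:
        if c.copy_id in seen:
            raise ValueError(f"duplicate copy_id {c.copy_id!r}")
        seen.add(c.copy_id)
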
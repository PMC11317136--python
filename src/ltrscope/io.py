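"""Readers and writers for the external file formats.

Every reader converts into the internal 0-based half-open convention;
every writer emits plain text (BED6/BED12, bedGraph, FASTA, TSV). No
science lives here.
"""
from __future__ import annotations

import io as _io
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CpGRecord, GeneModel, GenomicInterval, RepeatCopy, SignalTrack

# ---------------------------------------------------------------------------
# repeat annotation


def _repeat_id(family: str, chrom: str, start: int, end: int) -> str:
    return f"{family}:{chrom}:{start}:{end}"


def read_repeat_annotation(
    path,
    dialect: str = "bed6",
    merge_adjacent: bool = False,
    merge_gap: int = 0,
) -> List[RepeatCopy]:
    """Read a repeat annotation.

    dialect='repeatmasker_out': whitespace-delimited RepeatMasker .out
    (1-based inclusive coordinates, strand 'C' = minus); dialect='bed6'.
    ``merge_adjacent`` optionally merges consecutive same-family,
    same-strand rows separated by <= merge_gap bp (RepeatMasker sometimes
    splits one element across rows; default off).
    """
    if dialect not in ("repeatmasker_out", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw: List[Tuple[str, int, int, str, str]] = []  # chrom,start,end,strand,family
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            try:
                if dialect == "repeatmasker_out":
                    # skip the 2-line header + blank line of stock .out files
                    if fields[0] in ("SW", "score") or fields[0].startswith("--"):
                        continue
                    chrom = fields[4]
                    start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[6])
                    strand = "-" if fields[8] in ("C", "-") else "+"
                    family = fields[9]
                else:
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    family = fields[3]
                    strand = fields[5]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: malformed line {lineno}: strand {strand!r}")
            raw.append((chrom, start, end, strand, family))
    if merge_adjacent:
        raw = _merge_adjacent(raw, merge_gap)
    copies = [
        RepeatCopy(
            GenomicInterval(chrom, start, end, strand),
            family,
            _repeat_id(family, chrom, start, end),
        )
        for chrom, start, end, strand, family in raw
    ]
    seen = set()
    for c in copies:
        if c.copy_id in seen:
            raise ValueError(f"{path}: duplicate element {c.copy_id}")
        seen.add(c.copy_id)
    return copies


def _merge_adjacent(rows, merge_gap):
    rows = sorted(rows)
    out = []
    for row in rows:
        if out:
            chrom, start, end, strand, family = out[-1]
            c, s, e, st, f = row
            if c == chrom and f == family and st == strand and s - end <= merge_gap:
                out[-1] = (chrom, start, max(end, e), strand, family)
                continue
        out.append(row)
    return out


def write_repeat_annotation(copies: Sequence[RepeatCopy], path) -> None:
    with open(path, "w") as fh:
        for c in copies:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.family}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# signal tracks (bedGraph)


def read_signal_track(
    path, library_scale: float, chrom_sizes: Optional[Dict[str, int]] = None
) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping intervals are rejected."""
    data: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            try:
                chrom, start, end, value = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if value < 0:
                raise ValueError(f"{path}: negative value at line {lineno}")
            data.setdefault(chrom, []).append((start, end, value))
    return SignalTrack(data, library_scale, chrom_sizes)


def write_signal_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, triples in track.triples().items():
            for s, e, v in triples:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# count tables


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count table (rows = elements, header = sample names).

    Missing cells, duplicate element ids and non-integer counts are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate element_id {dup!r}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cell (no imputation is performed)")
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_integer_dtype(vals):
            as_float = pd.to_numeric(vals, errors="raise")
            if not (as_float == as_float.astype(int)).all():
                raise ValueError(f"{path}: non-integer count in column {col!r}")
            df[col] = as_float.astype(int)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="element_id")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path, dialect: str = "bed12") -> List[GeneModel]:
    """Read gene models from BED12 or a GTF-lite (exon rows with gene_id)."""
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bed12(path) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                gene_id, strand = f[3], f[5]
                n = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if len(sizes) != n or len(offsets) != n:
                raise ValueError(f"{path}: malformed line {lineno}: block counts")
            exon_starts = tuple(start + o for o in offsets)
            exon_ends = tuple(start + o + s for o, s in zip(offsets, sizes))
            genes.append(
                GeneModel(
                    GenomicInterval(chrom, start, end, strand),
                    gene_id,
                    exon_starts,
                    exon_ends,
                )
            )
    return genes


def _read_gtf(path) -> List[GeneModel]:
    exons: Dict[str, List[Tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed line {lineno}")
            if f[2] != "exon":
                continue
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            gene_id = None
            for kv in f[8].split(";"):
                kv = kv.strip()
                if kv.startswith("gene_id"):
                    gene_id = kv.split(None, 1)[1].strip('"')
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno} lacks gene_id")
            exons.setdefault(gene_id, []).append((chrom, start, end, strand))
    genes = []
    for gene_id, rows in exons.items():
        rows.sort(key=lambda r: r[1])
        chrom, strand = rows[0][0], rows[0][3]
        genes.append(
            GeneModel(
                GenomicInterval(chrom, rows[0][1], rows[-1][2], strand),
                gene_id,
                tuple(r[1] for r in rows),
                tuple(r[2] for r in rows),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(
                str(e - s) for s, e in zip(g.exon_starts, g.exon_ends)
            )
            offsets = ",".join(str(s - iv.start) for s in g.exon_starts)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(g.exon_starts)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# peaks, TADs, CpG tables, FASTA


def read_peaks(path) -> List[GenomicInterval]:
    """Read BED/narrowPeak intervals (first three columns + optional strand)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            try:
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                peaks.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t{p.strand}\n")


read_tads = read_peaks  # TADs are consumed as plain BED intervals


def read_cpg_table(path) -> List[CpGRecord]:
    """TSV with columns chrom, pos, n_meth, n_total (header optional)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if lineno == 1 and not f[1].lstrip("-").isdigit():
                continue  # header
            try:
                records.append(CpGRecord(f[0], int(f[1]), int(f[2]), int(f[3])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return records


def write_cpg_table(records: Sequence[CpGRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tn_meth\tn_total\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.n_meth}\t{r.n_total}\n")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_sequences(
    genome: Dict[str, str], copies: Iterable[RepeatCopy]
) -> Dict[str, str]:
    """Strand-oriented sequence of each copy (reverse-complemented on '-')."""
    from .core import revcomp

    out = {}
    for c in copies:
        iv = c.interval
        seq = genome[iv.chrom][iv.start : iv.end]
        out[c.copy_id] = revcomp(seq) if iv.strand == "-" else seq
    return out
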
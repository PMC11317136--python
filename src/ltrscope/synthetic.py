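"""Synthetic cohort with planted ground truth.

Generates a toy genome carrying one LTR-like repeat family diverged from
a planted ancestral consensus, decoy families, downstream internal
(ERV9-like) segments, genes, count tables, signal tracks and CpG
methylation — with every planted fact recorded in a SyntheticTruth
object so each analysis stage can be scored against a known answer.

Statistical structure emulated: a gRNA-targetable subset of family
copies is transactivated (negative-binomial counts, treated mean =
effect_size x control mean); every transactivated copy gains H3K27ac
over the 400 bp promoter/enhancer window upstream of its TSS; a planted
fraction (default 20%) is additionally co-marked by H3K4me3 with the
summit 500-1500 bp downstream of the TSS; RNA coverage runs from the
TSS to the first planted poly(A) hexamer and, for read-through events,
decays geometrically past it into a downstream element; DNA methylation
is drawn per copy and does not change with treatment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CpGRecord, GeneModel, GenomicInterval, RepeatCopy, SignalTrack, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CohortParams:
    """Generator knobs; every rate is in [0, 1], the seed is mandatory."""

    seed: int
    genome_length: int = 3_000_000
    n_target_copies: int = 120
    n_decoy_copies: int = 60
    consensus_length: int = 1500
    substitution_rate: float = 0.05
    indel_rate: float = 0.005
    fraction_with_internal: float = 0.3
    fraction_targetable: float = 0.64
    effect_size: float = 4.0
    nb_dispersion: float = 0.1
    n_replicates: int = 8
    frac_comarked: float = 0.20
    readthrough_prob: float = 0.5
    # ---- secondary structure ----
    target_family: str = "LTR12C"
    internal_family: str = "ERV9-int"
    decoy_families: Tuple[str, ...] = ("LTR7", "MER41B", "THE1B")
    frac_exact_guide: float = 0.375  # exact-match share among targetable copies
    internal_length: int = 1000
    frac_copies_with_gene: float = 0.4
    gene_length: int = 3000
    gene_distance: Tuple[int, int] = (4600, 15000)
    n_background_genes: int = 15
    n_independent_decoys: int = 10  # upregulated decoys NOT fed by read-through
    n_confounder_genes: int = 3  # upregulated genes whose own promoter changed
    base_mean: float = 50.0
    background_library: float = 1_000_000.0  # reads mapped outside the tables
    readthrough_retention: float = 0.5
    bin_size: int = 25
    background_level: float = 0.2  # RPM at library_scale 1e6
    mark_fold: float = 10.0  # planted enrichment over background
    guide_offset: int = 100  # protospacer start within the ancestral consensus
    chrom: str = "chrS"

    def validate(self) -> None:
        rates = {
            "substitution_rate": self.substitution_rate,
            "indel_rate": self.indel_rate,
            "fraction_with_internal": self.fraction_with_internal,
            "fraction_targetable": self.fraction_targetable,
            "frac_comarked": self.frac_comarked,
            "readthrough_prob": self.readthrough_prob,
            "frac_exact_guide": self.frac_exact_guide,
            "frac_copies_with_gene": self.frac_copies_with_gene,
        }
        for name, val in rates.items():
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("genome_length", "consensus_length", "n_replicates", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_target_copies < 0 or self.n_decoy_copies < 0:
            raise ValueError("copy counts must be non-negative")
        if self.effect_size <= 0 or self.nb_dispersion < 0:
            raise ValueError("effect_size > 0 and nb_dispersion >= 0 required")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the acceptance oracle for every stage."""

    params: CohortParams
    chrom: str
    ancestor: str
    guide_protospacer: str
    guide_pam: str
    copies: pd.DataFrame  # one row per repeat copy (targets + decoys + internals)
    genes: pd.DataFrame
    readthrough: pd.DataFrame  # planted source -> downstream pairs
    gene_links: pd.DataFrame
    rna_segments: pd.DataFrame  # planted RNA coverage (chrom,start,end,level)
    polya_sites: pd.DataFrame  # chrom,pos,strand


@dataclass
class SyntheticTracks:
    rna: SignalTrack
    k4: SignalTrack
    k27: SignalTrack
    ha: SignalTrack
    k4_control: SignalTrack
    k27_control: SignalTrack
    ha_peaks: List[GenomicInterval]
    cpg: List[CpGRecord]


def _rng(params: CohortParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(stream,)))


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int64)


def _codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 0, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _mutate(seq: str, mu: float, iota: float, rng: np.random.Generator) -> str:
    """Independent substitutions at rate mu (always to a different base),
    single-base deletions/insertions each at rate iota/2."""
    codes = _str_to_codes(seq)
    sub = rng.random(codes.size) < mu
    codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    if iota > 0:
        out: List[int] = []
        dele = rng.random(codes.size) < iota / 2
        ins = rng.random(codes.size) < iota / 2
        ins_base = rng.integers(0, 4, size=codes.size)
        for i, c in enumerate(codes):
            if ins[i]:
                out.append(int(ins_base[i]))
            if not dele[i]:
                out.append(int(c))
        codes = np.array(out if out else [0], dtype=np.int64)
    return _codes_to_str(codes)


def _exact_subset(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Boolean mask with exactly round(frac * n) True entries, placed at
    random (stratified planting: the fraction itself carries no binomial
    noise)."""
    k = int(round(frac * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


# ---------------------------------------------------------------------------
# genome construction


def _make_target_copy_seq(
    ancestor: str,
    guide_offset: int,
    guide_mm: Optional[int],
    params: CohortParams,
    rng: np.random.Generator,
) -> Tuple[str, int]:
    """Mutated descendant of the ancestor. ``guide_mm`` = 0/1 rewrites the
    23-nt guide site with that many protospacer substitutions (targetable
    copy); None disrupts the site with 3 substitutions. Returns the copy
    sequence and the local start of the guide site."""
    left = _mutate(ancestor[:guide_offset], params.substitution_rate, params.indel_rate, rng)
    site = list(ancestor[guide_offset : guide_offset + 23])
    right = _mutate(
        ancestor[guide_offset + 23 :], params.substitution_rate, params.indel_rate, rng
    )
    n_sub = 3 if guide_mm is None else guide_mm
    if n_sub:
        pos = rng.permutation(20)[:n_sub]
        for p in pos:
            site[p] = "ACGT"[(("ACGT".index(site[p])) + int(rng.integers(1, 4))) % 4]
    return left + "".join(site) + right, len(left)


def build_genome(
    params: CohortParams,
) -> Tuple[Dict[str, str], List[RepeatCopy], List[GeneModel], SyntheticTruth]:
    """Lay out the toy genome and return (genome, repeat annotation,
    gene models, planted truth). Deterministic in params.seed."""
    params.validate()
    rng = _rng(params, 0)
    chrom = params.chrom

    # ancestral sequences with the planted guide site
    ancestor_codes = _random_codes(rng, params.consensus_length)
    ancestor = _codes_to_str(ancestor_codes)
    protospacer = _codes_to_str(_random_codes(rng, 20))
    pam = "ACGT"[int(rng.integers(0, 4))] + "GG"
    go = params.guide_offset
    if go + 23 > len(ancestor):
        raise ValueError("guide_offset + 23 exceeds consensus length")
    ancestor = ancestor[:go] + protospacer + pam + ancestor[go + 23 :]
    internal_ancestor = _codes_to_str(_random_codes(rng, params.internal_length))

    nt = params.n_target_copies
    targetable = _exact_subset(rng, nt, params.fraction_targetable)
    n_targetable = int(targetable.sum())
    exact_among = _exact_subset(rng, n_targetable, params.frac_exact_guide)
    transactivated = targetable.copy()
    idx_trans = np.nonzero(transactivated)[0]
    comarked_mask = _exact_subset(rng, idx_trans.size, params.frac_comarked)
    readthrough_mask = _exact_subset(rng, idx_trans.size, params.readthrough_prob)
    gene_mask = _exact_subset(rng, idx_trans.size, params.frac_copies_with_gene)
    has_internal = _exact_subset(rng, nt, params.fraction_with_internal)

    co_of = dict(zip(idx_trans, comarked_mask))
    rt_of = dict(zip(idx_trans, readthrough_mask))
    gene_of = dict(zip(idx_trans, gene_mask))

    # ---- build unit canvases in local '+' orientation -------------------
    units = []  # dicts: seq, features[], strand, kind
    guide_mm_iter = iter(exact_among)
    for i in range(nt):
        feats = []
        if targetable[i]:
            mm = 0 if next(guide_mm_iter) else 1
        else:
            mm = None
        copy_seq, guide_local = _make_target_copy_seq(ancestor, go, mm, params, rng)
        lc = len(copy_seq)
        parts = [copy_seq]
        cur = lc
        feats.append(
            {
                "kind": "copy",
                "start": 0,
                "end": lc,
                "i": i,
                "guide_mm": math.inf if mm is None else mm,
                "guide_center": guide_local + 11,
            }
        )
        # 50 bp gap carrying the first poly(A) signal 20 bp past the copy
        gap = list(_mutate(_codes_to_str(_random_codes(rng, 50)), 0, 0, rng))
        gap[20:26] = "AATAAA"
        parts.append("".join(gap))
        polya1 = cur + 20
        feats.append({"kind": "polya", "start": polya1, "end": polya1 + 6})
        cur += 50
        if has_internal[i]:
            seq = _mutate(internal_ancestor, params.substitution_rate, params.indel_rate, rng)
            parts.append(seq)
            feats.append({"kind": "internal", "start": cur, "end": cur + len(seq)})
            cur += len(seq)
        rt = bool(transactivated[i] and rt_of.get(i, False))
        polya2 = None
        if rt:
            g1 = int(rng.integers(1000, 4001))
            parts.append(_codes_to_str(_random_codes(rng, g1)))
            cur += g1
            dlen = int(rng.integers(400, 801))
            fam = params.decoy_families[int(rng.integers(0, len(params.decoy_families)))]
            parts.append(_codes_to_str(_random_codes(rng, dlen)))
            feats.append(
                {"kind": "decoy", "start": cur, "end": cur + dlen, "family": fam, "rt": True}
            )
            cur += dlen
            gap2 = list(_codes_to_str(_random_codes(rng, 50)))
            gap2[20:26] = "AATAAA"
            parts.append("".join(gap2))
            polya2 = cur + 20
            feats.append({"kind": "polya", "start": polya2, "end": polya2 + 6})
            cur += 50
        with_gene = bool(transactivated[i] and gene_of.get(i, False))
        if with_gene:
            d = int(rng.integers(params.gene_distance[0], params.gene_distance[1] + 1))
            gene_tss = max(cur + 200, lc + d)
            parts.append(_codes_to_str(_random_codes(rng, gene_tss + params.gene_length - cur)))
            feats.append(
                {
                    "kind": "gene",
                    "start": gene_tss,
                    "end": gene_tss + params.gene_length,
                    "confounder": False,
                }
            )
            cur = gene_tss + params.gene_length
        # gene-bearing units get wide spacers on BOTH sides so the planted
        # element is always the nearest one (on '-' the gene mirrors to the
        # unit's left edge, facing the previous unit)
        units.append(
            {
                "seq": "".join(parts),
                "feats": feats,
                "strand": "+" if rng.random() < 0.5 else "-",
                "pad": int(rng.integers(16000, 20001)) if with_gene else int(rng.integers(800, 2001)),
                "pre_pad": int(rng.integers(16000, 20001)) if with_gene else 0,
                "rt": rt,
                "polya1": polya1,
                "polya2": polya2,
                "target_index": i,
            }
        )

    # standalone decoys (some flagged independently upregulated)
    n_dec = params.n_decoy_copies
    indep = _exact_subset(rng, n_dec, min(1.0, params.n_independent_decoys / max(n_dec, 1)))
    for j in range(n_dec):
        dlen = int(rng.integers(400, 801))
        fam = params.decoy_families[j % len(params.decoy_families)]
        units.append(
            {
                "seq": _codes_to_str(_random_codes(rng, dlen)),
                "feats": [
                    {
                        "kind": "decoy",
                        "start": 0,
                        "end": dlen,
                        "family": fam,
                        "rt": False,
                        "independent_up": bool(indep[j]),
                    }
                ],
                "strand": "+" if rng.random() < 0.5 else "-",
                "pad": int(rng.integers(800, 2001)),
                "rt": False,
                "polya1": None,
                "polya2": None,
                "target_index": None,
            }
        )

    # background + confounder genes as their own units
    for j in range(params.n_background_genes + params.n_confounder_genes):
        confounder = j >= params.n_background_genes
        units.append(
            {
                "seq": _codes_to_str(_random_codes(rng, params.gene_length)),
                "feats": [
                    {
                        "kind": "gene",
                        "start": 0,
                        "end": params.gene_length,
                        "confounder": confounder,
                    }
                ],
                "strand": "+" if rng.random() < 0.5 else "-",
                "pad": int(rng.integers(800, 2001)),
                "rt": False,
                "polya1": None,
                "polya2": None,
                "target_index": None,
            }
        )

    order = rng.permutation(len(units))
    genome_codes = _random_codes(rng, params.genome_length)
    genome_arr = BASES[genome_codes].copy()

    margin = 5000
    pos = margin
    copy_rows: List[dict] = []
    gene_rows: List[dict] = []
    rt_rows: List[dict] = []
    link_rows: List[dict] = []
    rna_rows: List[dict] = []
    polya_rows: List[dict] = []
    co_offsets_rng = rng  # summit offsets drawn below per co-marked copy
    n_target_seen = 0
    n_gene_seen = 0
    n_decoy_seen = 0

    for ui in order:
        unit = units[ui]
        seq, strand = unit["seq"], unit["strand"]
        W = len(seq)
        pos += unit.get("pre_pad", 0)
        if pos + W + unit["pad"] > params.genome_length - margin:
            raise ValueError(
                "requested elements do not fit in genome_length "
                f"(needed > {pos + W + margin} bp)"
            )
        placed = revcomp(seq) if strand == "-" else seq
        genome_arr[pos : pos + W] = np.frombuffer(placed.encode(), dtype=np.uint8)

        def g_iv(s: int, e: int) -> Tuple[int, int]:
            return (pos + s, pos + e) if strand == "+" else (pos + W - e, pos + W - s)

        unit_copy_row = None
        unit_gene_row = None
        unit_decoy_row = None
        for f in unit["feats"]:
            s, e = g_iv(f["start"], f["end"])
            if f["kind"] == "copy":
                i = f["i"]
                cid = f"{params.target_family}:{chrom}:{s}:{e}"
                trans = bool(transactivated[i])
                co = trans and co_of.get(i, False)
                offset = int(co_offsets_rng.integers(500, 1501)) if co else None
                gm = f["guide_mm"]
                gc_local = f["guide_center"]
                gc = pos + gc_local if strand == "+" else pos + W - 1 - gc_local
                row = {
                    "copy_id": cid,
                    "family": params.target_family,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "is_target_family": True,
                    "targeted": bool(targetable[i]),
                    "guide_mm": gm,
                    "guide_center": gc,
                    "transactivated": trans,
                    "epi_class": (
                        "co_marked" if co else ("single_marked" if trans else "unmarked")
                    ),
                    "planted_k4_offset": offset if offset is not None else np.nan,
                    "has_internal": bool(has_internal[i]),
                    "independent_up": False,
                    "readthrough_source": bool(unit["rt"]),
                }
                copy_rows.append(row)
                unit_copy_row = row
                n_target_seen += 1
            elif f["kind"] == "internal":
                cid = f"{params.internal_family}:{chrom}:{s}:{e}"
                copy_rows.append(
                    {
                        "copy_id": cid,
                        "family": params.internal_family,
                        "chrom": chrom,
                        "start": s,
                        "end": e,
                        "strand": strand,
                        "is_target_family": False,
                        "targeted": False,
                        "guide_mm": math.inf,
                        "guide_center": np.nan,
                        "transactivated": False,
                        "epi_class": "unmarked",
                        "planted_k4_offset": np.nan,
                        "has_internal": False,
                        "independent_up": False,
                        "readthrough_source": False,
                    }
                )
            elif f["kind"] == "decoy":
                cid = f"{f['family']}:{chrom}:{s}:{e}"
                row = {
                    "copy_id": cid,
                    "family": f["family"],
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "is_target_family": False,
                    "targeted": False,
                    "guide_mm": math.inf,
                    "guide_center": np.nan,
                    "transactivated": False,
                    "epi_class": "unmarked",
                    "planted_k4_offset": np.nan,
                    "has_internal": False,
                    "independent_up": bool(f.get("independent_up", False)),
                    "readthrough_source": False,
                }
                copy_rows.append(row)
                if f.get("rt"):
                    unit_decoy_row = row
                n_decoy_seen += 1
            elif f["kind"] == "gene":
                gid = f"gene_{n_gene_seen:04d}"
                n_gene_seen += 1
                exon1 = (0, 400)
                exon2 = (1200, f["end"] - f["start"])
                ex = [g_iv(f["start"] + a, f["start"] + b) for a, b in (exon1, exon2)]
                ex.sort()
                row = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "exon_starts": tuple(a for a, _ in ex),
                    "exon_ends": tuple(b for _, b in ex),
                    "confounder": bool(f.get("confounder", False)),
                    "linked_element": None,
                    "link_class": None,
                }
                gene_rows.append(row)
                unit_gene_row = row
            elif f["kind"] == "polya":
                polya_rows.append({"chrom": chrom, "pos": s, "strand": strand})

        # planted RNA segments + cross-feature records
        if unit_copy_row is not None and unit_copy_row["transactivated"]:
            h = params.mark_fold * params.background_level
            tss = unit_copy_row["start"] if strand == "+" else unit_copy_row["end"] - 1
            p1s, p1e = g_iv(unit["polya1"], unit["polya1"] + 6)
            seg1 = (min(tss, p1s), max(tss + 1, p1e))
            rna_rows.append({"chrom": chrom, "start": seg1[0], "end": seg1[1], "level": h})
            if unit["rt"] and unit["polya2"] is not None and unit_decoy_row is not None:
                p2s, p2e = g_iv(unit["polya2"], unit["polya2"] + 6)
                a, b = (p1e, p2e) if strand == "+" else (p2s, p1s)
                rna_rows.append(
                    {
                        "chrom": chrom,
                        "start": a,
                        "end": b,
                        "level": h * params.readthrough_retention,
                    }
                )
                gap = (
                    unit_decoy_row["start"] - unit_copy_row["end"]
                    if strand == "+"
                    else unit_copy_row["start"] - unit_decoy_row["end"]
                )
                rt_rows.append(
                    {
                        "source_id": unit_copy_row["copy_id"],
                        "downstream_id": unit_decoy_row["copy_id"],
                        "distance": int(gap),
                    }
                )
            if unit_gene_row is not None:
                unit_gene_row["linked_element"] = unit_copy_row["copy_id"]
                unit_gene_row["link_class"] = unit_copy_row["epi_class"]
                link_rows.append(
                    {
                        "gene_id": unit_gene_row["gene_id"],
                        "element_id": unit_copy_row["copy_id"],
                        "epi_class": unit_copy_row["epi_class"],
                    }
                )
        pos += W + unit["pad"]

    genome = {chrom: genome_arr.tobytes().decode()}
    copies_df = pd.DataFrame(copy_rows).set_index("copy_id") if copy_rows else pd.DataFrame(
        columns=[
            "family", "chrom", "start", "end", "strand", "is_target_family",
            "targeted", "guide_mm", "guide_center", "transactivated", "epi_class",
            "planted_k4_offset", "has_internal", "independent_up", "readthrough_source",
        ]
    ).rename_axis("copy_id")
    genes_df = pd.DataFrame(gene_rows).set_index("gene_id") if gene_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "exon_starts", "exon_ends",
                 "confounder", "linked_element", "link_class"]
    ).rename_axis("gene_id")

    truth = SyntheticTruth(
        params=params,
        chrom=chrom,
        ancestor=ancestor,
        guide_protospacer=protospacer,
        guide_pam=pam,
        copies=copies_df,
        genes=genes_df,
        readthrough=pd.DataFrame(rt_rows, columns=["source_id", "downstream_id", "distance"]),
        gene_links=pd.DataFrame(link_rows, columns=["gene_id", "element_id", "epi_class"]),
        rna_segments=pd.DataFrame(rna_rows, columns=["chrom", "start", "end", "level"]),
        polya_sites=pd.DataFrame(polya_rows, columns=["chrom", "pos", "strand"]),
    )
    return genome, truth_to_repeats(truth), truth_to_genes(truth), truth


def truth_to_repeats(truth: SyntheticTruth) -> List[RepeatCopy]:
    out = []
    for cid, r in truth.copies.iterrows():
        out.append(
            RepeatCopy(
                GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["strand"]),
                r["family"],
                cid,
            )
        )
    return out


def truth_to_genes(truth: SyntheticTruth) -> List[GeneModel]:
    out = []
    for gid, r in truth.genes.iterrows():
        out.append(
            GeneModel(
                GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["strand"]),
                gid,
                tuple(r["exon_starts"]),
                tuple(r["exon_ends"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


@dataclass
class SimulatedCounts:
    elements_treated: pd.DataFrame
    elements_control: pd.DataFrame
    genes_treated: pd.DataFrame
    genes_control: pd.DataFrame
    library_sizes: pd.Series  # sample -> total mapped reads

    def __iter__(self):
        return iter(
            (self.elements_treated, self.elements_control,
             self.genes_treated, self.genes_control)
        )


def simulate_counts(
    truth: SyntheticTruth, params: Optional[CohortParams] = None
) -> SimulatedCounts:
    """Treated/control count tables for repeat copies and genes.

    Control means are lognormal around base_mean; transactivated copies,
    read-through downstream elements, independently upregulated decoys
    and linked/confounder genes get treated mean = (a multiple of)
    effect_size x control mean. Per-sample library sizes are the table
    totals plus ``background_library`` reads mapped elsewhere in the
    transcriptome (the repeat family is a tiny share of a real library,
    so fold changes must not be renormalised against it alone).
    """
    params = params or truth.params
    rng = _rng(params, 1)
    cp = truth.copies
    n = len(cp)
    control_mean = params.base_mean * rng.lognormal(0.0, 0.4, size=n)
    mult = np.ones(n)
    rt_down = set(truth.readthrough["downstream_id"])
    for k, (cid, r) in enumerate(cp.iterrows()):
        if r["transactivated"] or cid in rt_down or r["independent_up"]:
            mult[k] = params.effect_size
    cols_t = [f"treated_{i + 1}" for i in range(params.n_replicates)]
    cols_c = [f"control_{i + 1}" for i in range(params.n_replicates)]
    et = pd.DataFrame(
        {c: _nb_draw(rng, control_mean * mult, params.nb_dispersion) for c in cols_t},
        index=cp.index,
    )
    ec = pd.DataFrame(
        {c: _nb_draw(rng, control_mean, params.nb_dispersion) for c in cols_c},
        index=cp.index,
    )

    gn = truth.genes
    gmean = params.base_mean * rng.lognormal(0.0, 0.4, size=len(gn))
    gmult = np.ones(len(gn))
    for k, (gid, r) in enumerate(gn.iterrows()):
        if r["link_class"] == "co_marked":
            gmult[k] = 2.0 * params.effect_size
        elif r["link_class"] == "single_marked":
            gmult[k] = params.effect_size
        elif r["confounder"]:
            gmult[k] = params.effect_size
    gt = pd.DataFrame(
        {c: _nb_draw(rng, gmean * gmult, params.nb_dispersion) for c in cols_t},
        index=gn.index,
    )
    gc = pd.DataFrame(
        {c: _nb_draw(rng, gmean, params.nb_dispersion) for c in cols_c},
        index=gn.index,
    )
    lib = pd.Series(
        {
            c: params.background_library + float(et[c].sum()) + float(gt[c].sum())
            for c in cols_t
        }
        | {
            c: params.background_library + float(ec[c].sum()) + float(gc[c].sum())
            for c in cols_c
        },
        name="library_size",
    )
    return SimulatedCounts(et, ec, gt, gc, lib)


# ---------------------------------------------------------------------------
# tracks


def _add_rect(arr: np.ndarray, start: int, end: int, level: float) -> None:
    a, b = max(0, start), min(arr.size, end)
    if b > a:
        arr[a:b] += level


def _add_gaussian(arr: np.ndarray, center: int, sigma: float, amplitude: float) -> None:
    a = max(0, int(center - 4 * sigma))
    b = min(arr.size, int(center + 4 * sigma) + 1)
    if b <= a:
        return
    x = np.arange(a, b)
    arr[a:b] += amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def simulate_tracks(
    truth: SyntheticTruth, params: Optional[CohortParams] = None
) -> SyntheticTracks:
    """Signal tracks (25 bp bins, library_scale 1e6 so values are RPM),
    dCas9 peak intervals and the CpG methylation table."""
    params = params or truth.params
    rng = _rng(params, 2)
    L = params.genome_length
    chrom = truth.chrom
    bg = params.background_level
    amp = params.mark_fold * bg

    rna = np.zeros(L)
    k4 = np.zeros(L)
    k27 = np.zeros(L)
    ha = np.zeros(L)
    k4c = np.zeros(L)
    k27c = np.zeros(L)

    for _, seg in truth.rna_segments.iterrows():
        _add_rect(rna, int(seg["start"]), int(seg["end"]), float(seg["level"]))

    ha_peaks: List[GenomicInterval] = []
    for cid, r in truth.copies.iterrows():
        strand = r["strand"]
        tss = int(r["start"]) if strand == "+" else int(r["end"]) - 1
        sign = 1 if strand == "+" else -1
        if r["targeted"]:
            center = int(r["guide_center"])
            _add_gaussian(ha, center, 100.0, amp)
            ha_peaks.append(GenomicInterval(chrom, max(0, center - 150), center + 150, strand))
        if r["transactivated"]:
            # H3K27ac over the promoter/enhancer window [-400, +100)
            if strand == "+":
                _add_rect(k27, tss - 400, tss + 100, amp)
            else:
                _add_rect(k27, tss - 99, tss + 401, amp)
            if r["epi_class"] == "co_marked":
                summit = tss + sign * int(r["planted_k4_offset"])
                _add_gaussian(k4, summit, 300.0, amp)

    for gid, r in truth.genes.iterrows():
        strand = r["strand"]
        tss = int(r["start"]) if strand == "+" else int(r["end"]) - 1
        a, b = tss - 400, tss + 401
        if r["confounder"]:
            _add_rect(k4, a, b, amp)  # promoter gain only in treated
            _add_rect(k27, a, b, amp)
        else:
            _add_rect(k4, a, b, amp)
            _add_rect(k27, a, b, amp)
            _add_rect(k4c, a, b, amp)
            _add_rect(k27c, a, b, amp)

    def to_track(per_bp: np.ndarray, noise_rng: np.random.Generator) -> SignalTrack:
        nbins = L // params.bin_size
        binned = per_bp[: nbins * params.bin_size].reshape(nbins, params.bin_size).mean(axis=1)
        binned = binned + noise_rng.gamma(1.0, bg, size=nbins)
        starts = np.arange(nbins) * params.bin_size
        triples = [
            (int(s), int(s + params.bin_size), float(np.round(v, 5)))
            for s, v in zip(starts, binned)
        ]
        return SignalTrack({chrom: triples}, library_scale=1e6, chrom_sizes={chrom: L})

    tracks = SyntheticTracks(
        rna=to_track(rna, rng),
        k4=to_track(k4, rng),
        k27=to_track(k27, rng),
        ha=to_track(ha, rng),
        k4_control=to_track(k4c, rng),
        k27_control=to_track(k27c, rng),
        ha_peaks=ha_peaks,
        cpg=[],
    )

    # per-copy methylation, identical across conditions by construction
    cpg: List[CpGRecord] = []
    for cid, r in truth.copies.iterrows():
        if not r["is_target_family"]:
            continue
        level = float(rng.beta(2.0, 2.0))
        for p in range(int(r["start"]), int(r["end"]), 60):
            total = int(15 + rng.poisson(10))
            meth = int(rng.binomial(total, level))
            cpg.append(CpGRecord(chrom, p, meth, total))
    tracks.cpg = cpg
    return tracks
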
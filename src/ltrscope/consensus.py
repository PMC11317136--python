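"""Family consensus construction, percent identity and gRNA design.

A single gRNA can transactivate hundreds of copies of a repeat family
because the copies descend from one ancestral sequence. This module
builds a star-alignment consensus of the family, quantifies per-copy
percent identity against it, enumerates SpCas9 (NGG PAM) protospacers
on the consensus, and scores how many copies each guide still matches
at 0, 1 or 2 mismatches — both on the family and genome-wide.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .core import GenomicInterval, revcomp

logger = logging.getLogger(__name__)

# alignment scoring used throughout (affine gaps)
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2.0, -2.0, -5.0, -1.0

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]


def _rc_codes(arr: np.ndarray) -> np.ndarray:
    return np.where(arr < 4, 3 - arr, np.uint8(255)).astype(np.uint8)[::-1]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def _project_onto_anchor(anchor: str, query: str, aligner=None):
    """Align query to anchor; return (per-anchor-column query residues,
    per-anchor-position insertion counts, total alignment columns, matches).

    Residue '-' marks anchor columns deleted in the query. Insertions
    (columns gapped in the anchor) are attributed to the anchor position
    immediately to their left (position 0 for leading insertions).
    """
    aligner = aligner or _aligner()
    aln = aligner.align(anchor, query)[0]
    columns = aln.shape[1]
    res = np.full(len(anchor), ord("-"), dtype=np.uint8)
    ins = np.zeros(len(anchor) + 1, dtype=np.int64)
    matches = 0
    tb, qb = aln.aligned
    prev_q = 0
    for (ts, te), (qs, qe) in zip(tb, qb):
        gap_q = qs - prev_q  # query bases skipped = insertion before anchor pos ts
        if gap_q:
            ins[ts] += gap_q
        block_q = query[qs:qe]
        res[ts:te] = np.frombuffer(block_q.encode(), dtype=np.uint8)
        matches += sum(a == b for a, b in zip(anchor[ts:te], block_q))
        prev_q = qe
    if len(query) - prev_q:
        ins[len(anchor)] += len(query) - prev_q
    return res, ins, columns, matches


def build_consensus(sequences: Sequence[str]) -> str:
    """Star-alignment consensus of a set of family copies.

    The longest copy anchors the star; every copy (anchor included) is
    globally aligned to it and votes per anchor column. Columns where the
    gap vote strictly exceeds every base are dropped; base ties break in
    fixed order A < C < G < T.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    sequences = [s.upper() for s in sequences]
    anchor = max(sequences, key=len)
    aligner = _aligner()
    counts = np.zeros((4, len(anchor)), dtype=np.int64)
    gap_counts = np.zeros(len(anchor), dtype=np.int64)
    for seq in sequences:
        res, _, _, _ = _project_onto_anchor(anchor, seq, aligner)
        codes = _ENC[res]
        for b in range(4):
            counts[b] += codes == b
        gap_counts += res == ord("-")
    best_base = counts.argmax(axis=0)  # argmax ties -> lowest index = A<C<G<T
    best_count = counts.max(axis=0)
    keep = gap_counts <= best_count  # gap must strictly win to drop the column
    return "".join("ACGT"[b] for b in best_base[keep])


@dataclass
class IdentityProfile:
    """Overall and windowed percent identity of one copy vs the consensus."""

    overall: float
    window: int
    window_identity: np.ndarray  # NaN where the window is pure gap
    gap_mask: np.ndarray  # True where no copy residue aligns in the window


def percent_identity_profile(
    copy: str, consensus: str, window: int = 50
) -> IdentityProfile:
    """Percent identity = 100 x matches / alignment columns (gap columns
    count as non-matches). Windows tile the consensus; insertions are
    charged to the window holding the consensus position at their left.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not copy or not consensus:
        raise ValueError("sequences must be non-empty")
    copy, consensus = copy.upper(), consensus.upper()
    res, ins, columns, matches = _project_onto_anchor(consensus, copy)
    overall = 100.0 * matches / columns
    n_win = (len(consensus) + window - 1) // window
    win_match = np.zeros(n_win)
    win_cols = np.zeros(n_win)
    win_residues = np.zeros(n_win, dtype=bool)
    cons_codes = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for i in range(len(consensus)):
        w = i // window
        win_cols[w] += 1
        if res[i] != ord("-"):
            win_residues[w] = True
            if res[i] == cons_codes[i]:
                win_match[w] += 1
    for i in range(len(consensus) + 1):
        if ins[i]:  # insertion sits between positions i-1 and i
            win_cols[max(i - 1, 0) // window] += ins[i]
    with np.errstate(invalid="ignore"):
        ident = 100.0 * win_match / win_cols
    ident[~win_residues] = np.nan
    return IdentityProfile(overall, window, ident, ~win_residues)


@dataclass
class GuideCandidate:
    """A 20-nt protospacer 5' of an NGG PAM on the family consensus."""

    protospacer: str
    pam: str
    consensus_position: int  # leftmost protospacer coordinate on the consensus
    consensus_strand: str
    distance_to_tss: int  # negative = upstream of the copy TSS
    mismatch_counts: Optional[Dict[str, float]] = None  # copy_id -> min mm (inf = no site)
    conservation: Optional[Dict[int, float]] = None  # k -> f(k)

    def __post_init__(self):
        if len(self.protospacer) != 20 or set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be 20 nt over {A,C,G,T}")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise ValueError("PAM must match NGG")


def enumerate_guides(consensus: str, tss_position: int = 0) -> List[GuideCandidate]:
    """All PAM-constrained 20-mers on either strand of the consensus."""
    consensus = consensus.upper()
    if len(consensus) < 23:
        return []
    guides: List[GuideCandidate] = []
    L = len(consensus)
    for strand, seq in (("+", consensus), ("-", revcomp(consensus))):
        arr = _encode(seq)
        pam_ok = (arr[21 : L - 1] == 2) & (arr[22:L] == 2)
        for s in np.nonzero(pam_ok)[0]:
            proto = seq[s : s + 20]
            if set(proto) - set("ACGT"):
                continue
            pos = s if strand == "+" else L - int(s) - 20
            guides.append(
                GuideCandidate(
                    protospacer=proto,
                    pam=seq[s + 20 : s + 23],
                    consensus_position=int(pos),
                    consensus_strand=strand,
                    distance_to_tss=int(pos) - tss_position,
                )
            )
    guides.sort(key=lambda g: (g.consensus_position, g.consensus_strand))
    return guides


def _scan_codes(arr: np.ndarray, guide_codes: np.ndarray):
    """PAM-adjacent protospacer starts and mismatch counts on one strand."""
    L = arr.size
    if L < 23:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    starts = np.nonzero((arr[21 : L - 1] == 2) & (arr[22:L] == 2))[0]
    if starts.size == 0:
        return starts.astype(np.int64), np.zeros(0, dtype=np.int64)
    mm = np.zeros(starts.size, dtype=np.int64)
    for j in range(20):
        mm += arr[starts + j] != guide_codes[j]
    return starts.astype(np.int64), mm


def scan_sequence(seq: str, protospacer: str) -> List[Tuple[int, str, int]]:
    """All PAM-adjacent sites in ``seq`` with their Hamming distance to the
    protospacer, both strands; degenerate bases count as mismatches.
    Returns (protospacer start on forward coords, strand, mismatches).
    """
    guide_codes = _encode(protospacer.upper())
    arr = _encode(seq)
    if np.any(arr == 255):
        logger.warning("degenerate bases in sequence treated as mismatches")
    out: List[Tuple[int, str, int]] = []
    starts, mm = _scan_codes(arr, guide_codes)
    out.extend((int(s), "+", int(m)) for s, m in zip(starts, mm))
    rc = _rc_codes(arr)
    starts, mm = _scan_codes(rc, guide_codes)
    L = arr.size
    out.extend((int(L - s - 20), "-", int(m)) for s, m in zip(starts, mm))
    return out


def score_guide_conservation(
    guide: GuideCandidate, copies: Mapping[str, str], max_mm: int = 2
) -> GuideCandidate:
    """Per-copy minimum mismatch count and family conservation fractions
    f(k) = fraction of copies matched with <= k mismatches."""
    if not copies:
        raise ValueError("need at least one copy")
    mismatch_counts: Dict[str, float] = {}
    for copy_id, seq in copies.items():
        sites = scan_sequence(seq, guide.protospacer)
        mismatch_counts[copy_id] = (
            min(m for _, _, m in sites) if sites else math.inf
        )
    n = len(mismatch_counts)
    conservation = {
        k: sum(1 for m in mismatch_counts.values() if m <= k) / n
        for k in range(max_mm + 1)
    }
    guide.mismatch_counts = mismatch_counts
    guide.conservation = conservation
    return guide


def predict_genome_targets(
    guide: GuideCandidate, genome: Mapping[str, str], max_mm: int = 1
) -> List[Tuple[GenomicInterval, int]]:
    """Genome-wide PAM-adjacent sites with <= max_mm mismatches (both
    strands); intervals span the 20-nt protospacer."""
    hits: List[Tuple[GenomicInterval, int]] = []
    for chrom in sorted(genome):
        for start, strand, mm in scan_sequence(genome[chrom], guide.protospacer):
            if mm <= max_mm:
                hits.append(
                    (GenomicInterval(chrom, start, start + 20, strand), mm)
                )
    hits.sort(key=lambda h: (h[0].chrom, h[0].start, h[0].strand))
    return hits
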
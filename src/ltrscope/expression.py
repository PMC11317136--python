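"""Per-copy and per-gene expression: RPKM, upregulation calls, family
composition and cross-condition set overlap.

An element is called upregulated when its fold change exceeds 2 AND its
two-tailed Wilcoxon signed-rank p-value is below 0.05 (both strict, as
plotted on the volcano thresholds). Fold changes are computed on mean
RPKM with a one-read pseudocount on the RPKM scale so zero-count
controls yield finite fold changes.
"""
from __future__ import annotations

import itertools
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .core import RepeatCopy, SignalTrack


def compute_rpkm(count: float, element_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of element per million mapped reads."""
    if element_length_bp <= 0:
        raise ValueError("element length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (element_length_bp / 1e3) / (library_size / 1e6)


def wilcoxon_signed_rank(differences: Sequence[float]) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped. For n <= 15 remaining pairs the exact
    null distribution is enumerated over all 2^n sign assignments of the
    (mid-)ranks; beyond that a normal approximation with tie and
    continuity corrections is used. All-zero input returns p = 1 with a
    warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; returning p = 1")
        return 1.0
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if n <= 15:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = bits @ ranks
        return float(np.mean(np.abs(w_all - mu) >= np.abs(w - mu) - 1e-9))
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if sigma2 <= 0:
        warnings.warn("degenerate rank variance; returning p = 1")
        return 1.0
    dev = w - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _rpkm_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    if library_sizes is not None:
        missing = set(counts.columns) - set(library_sizes)
        if missing:
            raise ValueError(f"missing library sizes for samples {sorted(missing)}")
        lib = pd.Series({c: float(library_sizes[c]) for c in counts.columns})
    else:
        # fallback: total counts of the table itself (fine when the table
        # covers the whole transcriptome, biased when it covers one family)
        lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("a sample has zero library size")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def call_differential(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    lengths: Mapping[str, int],
    families: Optional[Mapping[str, str]] = None,
    test: str = "wilcoxon",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    library_sizes: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-element differential expression between conditions.

    ``treated``/``control`` are count tables (rows = elements, columns =
    replicates). ``library_sizes`` maps sample name -> total mapped reads
    (RPKM denominators); without it the table's own column sums are used,
    which is only appropriate for transcriptome-wide tables. Returns one
    row per element with mean RPKM per condition, log2 fold change,
    two-tailed signed-rank p (paired over replicates) and the strict
    joint upregulation call.
    """
    if test not in ("wilcoxon", "none"):
        raise ValueError(f"unknown test {test!r}")
    if set(treated.index) != set(control.index):
        raise ValueError("treated and control tables cover different elements")
    if treated.shape[1] < 1 or control.shape[1] < 1:
        raise ValueError("need at least one replicate per condition")
    control = control.loc[treated.index]
    missing = set(treated.index) - set(lengths)
    if missing:
        raise ValueError(f"missing element lengths for e.g. {sorted(missing)[:3]}")
    lengths_s = pd.Series({e: float(lengths[e]) for e in treated.index})

    rpkm_t = _rpkm_matrix(treated, lengths_s, library_sizes)
    rpkm_c = _rpkm_matrix(control, lengths_s, library_sizes)
    mean_t = rpkm_t.mean(axis=1)
    mean_c = rpkm_c.mean(axis=1)

    # pseudocount: RPKM equivalent of one read at the mean library size
    if library_sizes is not None:
        mean_lib = float(
            np.mean([library_sizes[c] for c in list(treated.columns) + list(control.columns)])
        )
    else:
        mean_lib = float(
            pd.concat([treated.sum(axis=0), control.sum(axis=0)]).mean()
        )
    eps = pd.Series(
        [compute_rpkm(pseudocount, lengths_s[e], mean_lib) for e in treated.index],
        index=treated.index,
    )
    fc = (mean_t + eps) / (mean_c + eps)
    log2_fc = np.log2(fc)

    n_pairs = min(treated.shape[1], control.shape[1])
    test_mode = "none"
    pvals = pd.Series(np.nan, index=treated.index)
    if test == "wilcoxon":
        test_mode = "wilcoxon_replicates"
        if n_pairs < 6:
            warnings.warn(
                f"{n_pairs} replicate pairs: the signed-rank test cannot reach "
                "p < 0.05 below 6 pairs; consider wilcoxon_from_bins"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for e in treated.index:
                diffs = (
                    rpkm_t.loc[e].to_numpy()[:n_pairs]
                    - rpkm_c.loc[e].to_numpy()[:n_pairs]
                )
                pvals[e] = wilcoxon_signed_rank(diffs)

    upregulated = (fc > fc_threshold) & (
        (pvals < alpha) if test == "wilcoxon" else True
    )
    fam = pd.Series(
        {e: (families.get(e, "NA") if families else "NA") for e in treated.index}
    )
    return pd.DataFrame(
        {
            "family": fam,
            "mean_rpkm_treated": mean_t,
            "mean_rpkm_control": mean_c,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "upregulated": upregulated,
            "test_mode": test_mode,
        }
    ).rename_axis("element_id")


def wilcoxon_from_bins(
    track_treated: SignalTrack,
    track_control: SignalTrack,
    element: RepeatCopy,
    bin_size: int = 100,
) -> float:
    """Alternative replication unit: paired signed-rank over coverage bins
    along the element (for designs with too few biological replicates)."""
    iv = element.interval
    edges = np.arange(iv.start, iv.end, bin_size)
    diffs = [
        track_treated.mean_rpm(iv.chrom, int(a), int(min(a + bin_size, iv.end)))
        - track_control.mean_rpm(iv.chrom, int(a), int(min(a + bin_size, iv.end)))
        for a in edges
    ]
    return wilcoxon_signed_rank(diffs)


def family_composition(records: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Family breakdown of upregulated elements (counts + fractions).

    ``records`` is the call_differential output (or any frame with
    'family' and 'upregulated'); only upregulated rows contribute. The
    top_n most abundant families are kept, the rest pooled as 'others'.
    """
    up = records[records["upregulated"]] if "upregulated" in records else records
    if up.empty:
        warnings.warn("no upregulated elements; empty composition")
        return pd.DataFrame(columns=["family", "count", "fraction"])
    counts = up["family"].value_counts()
    if len(counts) > top_n:
        head = counts.iloc[:top_n]
        counts = pd.concat([head, pd.Series({"others": counts.iloc[top_n:].sum()})])
    out = counts.rename("count").to_frame().reset_index(names="family")
    out["fraction"] = out["count"] / out["count"].sum()
    return out


def compare_element_sets(named_sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Pairwise overlap counts and fractions between named element sets.

    Returns one row per ordered pair (a, b) with |A|, |A n B| and
    |A n B| / |A|, plus one 'all' row with the global intersection.
    """
    rows = []
    for a, b in itertools.permutations(named_sets, 2):
        inter = len(named_sets[a] & named_sets[b])
        size = len(named_sets[a])
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_a": size,
                "n_intersect": inter,
                "fraction_of_a": inter / size if size else np.nan,
            }
        )
    if named_sets:
        universal = set.intersection(*map(set, named_sets.values()))
        rows.append(
            {
                "set_a": "all",
                "set_b": "all",
                "n_a": min(len(s) for s in named_sets.values()),
                "n_intersect": len(universal),
                "fraction_of_a": np.nan,
            }
        )
    return pd.DataFrame(rows)
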
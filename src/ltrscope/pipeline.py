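"""End-to-end orchestration: generate -> guides -> diffexp -> epistate ->
link, with a single seed, stage TSV outputs and a machine-readable run
manifest. Each stage reads its inputs from the run directory, so stage
subsets can be re-run against existing files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import consensus as cns
from . import epistate as epi
from . import expression as expr
from . import io as lio
from . import linkage as lnk
from . import synthetic as syn
from .core import GenomicInterval, RepeatCopy

logger = logging.getLogger(__name__)

STAGES = ("generate", "guides", "diffexp", "epistate", "link")


@dataclass
class RunConfig:
    """All tunables for a pipeline run. Unknown config keys are rejected;
    the parsed config is serialized verbatim into the output directory."""

    seed: int
    outdir: str
    stages: Tuple[str, ...] = STAGES
    cohort: Dict = field(default_factory=dict)  # CohortParams overrides
    # guides
    max_mm: int = 2
    identity_window: int = 50
    consensus_max_copies: int = 50
    # diffexp
    fc_threshold: float = 2.0
    alpha: float = 0.05
    test: str = "wilcoxon"
    pseudocount: float = 1.0
    # epistate
    k27_window: Tuple[int, int] = (400, 100)
    k4_window: Tuple[int, int] = (0, 2000)
    enrich_fold: float = 2.0
    min_rpm: float = 0.05
    # link
    max_distance: int = 20000
    min_ratio: float = 0.2
    min_covered_fraction: float = 0.8
    max_gene_distance: int = 50000
    promoter_fold: float = 1.5

    def __post_init__(self):
        unknown = set(self.cohort) - {f.name for f in dataclasses.fields(syn.CohortParams)}
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "k27_window", "k4_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def cohort_params(self) -> syn.CohortParams:
        return syn.CohortParams(seed=self.seed, **self.cohort)


# ---------------------------------------------------------------------------
# stage input manifest (for pre-flight checks)

_STAGE_INPUTS = {
    "generate": [],
    "guides": ["data/genome.fa", "data/repeats.bed"],
    "diffexp": [
        "data/counts_elements_treated.tsv",
        "data/counts_elements_control.tsv",
        "data/counts_genes_treated.tsv",
        "data/counts_genes_control.tsv",
        "data/repeats.bed",
        "data/genes.bed12",
    ],
    "epistate": [
        "data/track_k4.bedgraph",
        "data/track_k27.bedgraph",
        "data/ha_peaks.bed",
        "data/cpg.tsv",
        "data/repeats.bed",
        "data/genes.bed12",
        "elements_diff.tsv",
    ],
    "link": [
        "data/genome.fa",
        "data/track_rna.bedgraph",
        "data/track_k4.bedgraph",
        "data/track_k27.bedgraph",
        "data/track_k4_control.bedgraph",
        "data/track_k27_control.bedgraph",
        "elements_diff.tsv",
        "genes_diff.tsv",
        "epistate.tsv",
    ],
}

_STAGE_OUTPUTS = {
    "generate": _STAGE_INPUTS["guides"]
    + _STAGE_INPUTS["diffexp"][:6]
    + _STAGE_INPUTS["epistate"][:4]
    + ["data/track_rna.bedgraph", "data/track_k4_control.bedgraph",
       "data/track_k27_control.bedgraph", "data/track_ha.bedgraph"],
    "guides": ["guides.tsv", "identity_profile.tsv"],
    "diffexp": ["elements_diff.tsv", "genes_diff.tsv", "family_composition.tsv"],
    "epistate": ["epistate.tsv", "methylation.tsv", "specificity.tsv"],
    "link": ["readthrough.tsv", "gene_links.tsv", "group_comparison.tsv"],
}


def _preflight(config: RunConfig, outdir: Path) -> None:
    produced = set()
    errors = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        for rel in _STAGE_INPUTS[stage]:
            if rel in produced or (outdir / rel).exists():
                continue
            errors.append(f"stage {stage!r}: missing input {rel}")
        produced.update(_STAGE_OUTPUTS[stage])
    if errors:
        raise FileNotFoundError("; ".join(errors))


# ---------------------------------------------------------------------------
# stages


def stage_generate(config: RunConfig, outdir: Path) -> Dict[str, int]:
    params = config.cohort_params()
    genome, copies, genes, truth = syn.build_genome(params)
    sim = syn.simulate_counts(truth, params)
    et, ec, gt, gc = sim
    tracks = syn.simulate_tracks(truth, params)
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)
    lio.write_fasta(genome, data / "genome.fa")
    lio.write_repeat_annotation(copies, data / "repeats.bed")
    lio.write_gene_models(genes, data / "genes.bed12")
    lio.write_counts(et, data / "counts_elements_treated.tsv")
    lio.write_counts(ec, data / "counts_elements_control.tsv")
    lio.write_counts(gt, data / "counts_genes_treated.tsv")
    lio.write_counts(gc, data / "counts_genes_control.tsv")
    for name, tr in (
        ("rna", tracks.rna),
        ("k4", tracks.k4),
        ("k27", tracks.k27),
        ("ha", tracks.ha),
        ("k4_control", tracks.k4_control),
        ("k27_control", tracks.k27_control),
    ):
        lio.write_signal_track(tr, data / f"track_{name}.bedgraph")
    sim.library_sizes.rename_axis("sample").to_csv(
        data / "library_sizes.tsv", sep="\t"
    )
    lio.write_peaks(tracks.ha_peaks, data / "ha_peaks.bed")
    lio.write_cpg_table(tracks.cpg, data / "cpg.tsv")
    truth.copies.to_csv(data / "truth_copies.tsv", sep="\t")
    truth.genes.to_csv(data / "truth_genes.tsv", sep="\t")
    truth.readthrough.to_csv(data / "truth_readthrough.tsv", sep="\t", index=False)
    truth.gene_links.to_csv(data / "truth_gene_links.tsv", sep="\t", index=False)
    with open(data / "guide.txt", "w") as fh:
        fh.write(f"{truth.guide_protospacer}\t{truth.guide_pam}\n")
    return {"n_elements": len(copies), "n_genes": len(genes)}


def _load_cohort(outdir: Path):
    data = outdir / "data"
    copies = lio.read_repeat_annotation(data / "repeats.bed", "bed6")
    genes = lio.read_gene_models(data / "genes.bed12")
    return copies, genes


def stage_guides(config: RunConfig, outdir: Path) -> Dict[str, int]:
    data = outdir / "data"
    genome = lio.read_fasta(data / "genome.fa")
    copies, _ = _load_cohort(outdir)
    family = config.cohort.get("target_family", "LTR12C")
    fam_copies = [c for c in copies if c.family == family]
    seqs = lio.extract_sequences(genome, fam_copies)
    anchor_ids = sorted(seqs, key=lambda k: -len(seqs[k]))[: config.consensus_max_copies]
    consensus = cns.build_consensus([seqs[k] for k in anchor_ids])
    guides = cns.enumerate_guides(consensus, tss_position=0)
    rows = []
    for g in guides:
        cns.score_guide_conservation(g, seqs, max_mm=config.max_mm)
        row = {
            "protospacer": g.protospacer,
            "pam": g.pam,
            "consensus_position": g.consensus_position,
            "strand": g.consensus_strand,
            "distance_to_tss": g.distance_to_tss,
        }
        row.update({f"f{k}": v for k, v in g.conservation.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "guides.tsv", sep="\t", index=False)
    ident_rows = []
    for cid, seq in seqs.items():
        prof = cns.percent_identity_profile(seq, consensus, config.identity_window)
        ident_rows.append({"copy_id": cid, "percent_identity": prof.overall})
    pd.DataFrame(ident_rows).to_csv(outdir / "identity_profile.tsv", sep="\t", index=False)
    return {"n_guides": len(rows), "consensus_length": len(consensus)}


def stage_diffexp(config: RunConfig, outdir: Path) -> Dict[str, int]:
    data = outdir / "data"
    copies, genes = _load_cohort(outdir)
    et = lio.read_counts(data / "counts_elements_treated.tsv")
    ec = lio.read_counts(data / "counts_elements_control.tsv")
    lib_path = data / "library_sizes.tsv"
    lib = (
        pd.read_csv(lib_path, sep="\t", index_col=0)["library_size"].to_dict()
        if lib_path.exists()
        else None
    )
    lengths = {c.copy_id: len(c.interval) for c in copies}
    families = {c.copy_id: c.family for c in copies}
    ediff = expr.call_differential(
        et, ec, lengths, families,
        test=config.test, fc_threshold=config.fc_threshold,
        alpha=config.alpha, pseudocount=config.pseudocount,
        library_sizes=lib,
    )
    ediff.to_csv(outdir / "elements_diff.tsv", sep="\t")
    gt = lio.read_counts(data / "counts_genes_treated.tsv")
    gc = lio.read_counts(data / "counts_genes_control.tsv")
    glens = {g.gene_id: g.exonic_length for g in genes}
    gdiff = expr.call_differential(
        gt, gc, glens, {g.gene_id: "gene" for g in genes},
        test=config.test, fc_threshold=config.fc_threshold,
        alpha=config.alpha, pseudocount=config.pseudocount,
        library_sizes=lib,
    )
    gdiff.to_csv(outdir / "genes_diff.tsv", sep="\t")
    comp = expr.family_composition(ediff)
    comp.to_csv(outdir / "family_composition.tsv", sep="\t", index=False)
    return {
        "n_upregulated_elements": int(ediff["upregulated"].sum()),
        "n_upregulated_genes": int(gdiff["upregulated"].sum()),
    }


def _chrom_sizes(outdir: Path) -> Dict[str, int]:
    genome = lio.read_fasta(outdir / "data" / "genome.fa")
    return {k: len(v) for k, v in genome.items()}


def stage_epistate(config: RunConfig, outdir: Path) -> Dict[str, int]:
    data = outdir / "data"
    copies, genes = _load_cohort(outdir)
    sizes = _chrom_sizes(outdir)
    k4 = lio.read_signal_track(data / "track_k4.bedgraph", 1e6, sizes)
    k27 = lio.read_signal_track(data / "track_k27.bedgraph", 1e6, sizes)
    ha_peaks = lio.read_peaks(data / "ha_peaks.bed")
    ediff = pd.read_csv(outdir / "elements_diff.tsv", sep="\t", index_col=0)
    family = config.cohort.get("target_family", "LTR12C")
    up_ids = set(ediff.index[ediff["upregulated"]])
    up_elements = [c for c in copies if c.copy_id in up_ids]
    transactivated = [c for c in up_elements if c.family == family]
    exclude = [c.interval for c in copies] + [g.interval for g in genes]
    params = epi.EpiParams(
        k27_window=config.k27_window,
        k4_window=config.k4_window,
        enrich_fold=config.enrich_fold,
        min_rpm=config.min_rpm,
    )
    states = epi.classify_epistate(
        k4, k27, ha_peaks, transactivated, params, background_exclude=exclude
    )
    states.to_csv(outdir / "epistate.tsv", sep="\t")
    _, specificity = epi.binding_specificity(ha_peaks, up_elements, family)
    pd.DataFrame(
        [{"target_family": family, "specificity": specificity}]
    ).to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    cpg = lio.read_cpg_table(data / "cpg.tsv")
    meth = epi.aggregate_methylation(cpg, [c.interval for c in transactivated])
    meth_named = pd.Series(
        meth.to_numpy(), index=[c.copy_id for c in transactivated], name="mean_methylation"
    )
    meth_named.rename_axis("element_id").to_csv(outdir / "methylation.tsv", sep="\t")
    counts = states["epi_class"].value_counts()
    return {
        "n_co_marked": int(counts.get("co_marked", 0)),
        "n_single_marked": int(counts.get("single_marked", 0)),
        "n_unmarked": int(counts.get("unmarked", 0)),
    }


def stage_link(config: RunConfig, outdir: Path) -> Dict[str, int]:
    data = outdir / "data"
    copies, genes = _load_cohort(outdir)
    sizes = _chrom_sizes(outdir)
    genome = lio.read_fasta(data / "genome.fa")
    rna = lio.read_signal_track(data / "track_rna.bedgraph", 1e6, sizes)
    tr_t = {
        "k4": lio.read_signal_track(data / "track_k4.bedgraph", 1e6, sizes),
        "k27": lio.read_signal_track(data / "track_k27.bedgraph", 1e6, sizes),
    }
    tr_c = {
        "k4": lio.read_signal_track(data / "track_k4_control.bedgraph", 1e6, sizes),
        "k27": lio.read_signal_track(data / "track_k27_control.bedgraph", 1e6, sizes),
    }
    ediff = pd.read_csv(outdir / "elements_diff.tsv", sep="\t", index_col=0)
    gdiff = pd.read_csv(outdir / "genes_diff.tsv", sep="\t", index_col=0)
    states = pd.read_csv(outdir / "epistate.tsv", sep="\t", index_col=0)
    family = config.cohort.get("target_family", "LTR12C")
    by_id = {c.copy_id: c for c in copies}
    up_ids = set(ediff.index[ediff["upregulated"]])
    sources = [by_id[i] for i in up_ids if by_id[i].family == family]
    gene_ivs = [g.interval for g in genes]
    nontarget_up = [
        by_id[i]
        for i in up_ids
        if by_id[i].family != family
        and not any(by_id[i].interval.overlaps(gv) for gv in gene_ivs)
    ]
    calls, frac = lnk.attribute_readthrough(
        nontarget_up, sources, rna, genome,
        max_distance=config.max_distance, min_ratio=config.min_ratio,
        min_covered_fraction=config.min_covered_fraction,
    )
    calls.to_csv(outdir / "readthrough.tsv", sep="\t", index=False)
    classes = states["epi_class"].to_dict()
    gene_up = gdiff["upregulated"].to_dict()
    links = lnk.link_genes(
        [by_id[i] for i in states.index if i in by_id],
        classes, genes, gene_up, tr_t, tr_c,
        max_gene_distance=config.max_gene_distance,
        promoter_fold=config.promoter_fold,
    )
    links.to_csv(outdir / "gene_links.tsv", sep="\t", index=False)
    groups = {}
    linked = links[links["linked"]]
    for cls in ("co_marked", "single_marked"):
        ids = linked.loc[linked["element_class"] == cls, "gene_id"]
        vals = gdiff.loc[[g for g in ids if g in gdiff.index], "mean_rpkm_treated"]
        if len(vals):
            groups[cls] = vals.to_list()
    if len(groups) >= 2:
        comparison = lnk.compare_group_expression(groups)
    else:
        comparison = pd.DataFrame(
            columns=["group_a", "group_b", "U", "p_value", "p_adjusted"]
        )
    comparison.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
    tads_path = data / "tads.bed"
    if tads_path.exists():
        tads = lio.read_tads(tads_path)
        unlinked_up = links[links["gene_upregulated"] & ~links["linked"]]["gene_id"]
        gene_by_id = {g.gene_id: g for g in genes}
        series, n_same = lnk.tad_comembership(
            [gene_by_id[g] for g in unlinked_up if g in gene_by_id],
            [by_id[i] for i in states.index if i in by_id],
            tads,
        )
        series.rename_axis("gene_id").to_csv(outdir / "tad_comembership.tsv", sep="\t")
    return {
        "n_attributed": int(calls["attributed"].sum()) if not calls.empty else 0,
        "n_linked": int(links["linked"].sum()) if not links.empty else 0,
    }


_STAGE_FN = {
    "generate": stage_generate,
    "guides": stage_guides,
    "diffexp": stage_diffexp,
    "epistate": stage_epistate,
    "link": stage_link,
}


def run_pipeline(config: RunConfig) -> Dict:
    """Run the requested stages in dependency order; returns the manifest
    (also written to <outdir>/manifest.json). Identical config + seed
    give byte-identical outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _preflight(config, outdir)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    manifest: Dict = {
        "tool": "ltrscope",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": dataclasses.asdict(config),
        "counts": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        manifest["counts"][stage] = _STAGE_FN[stage](config, outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
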
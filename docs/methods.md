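# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open on the forward genome
strand; 1-based dialects (RepeatMasker `.out`, GTF) are converted at the
I/O boundary, and RepeatMasker's `C` strand maps to `-`. The TSS of a
repeat copy is defined as its strand-aware 5′ terminus (`start` on `+`,
`end − 1` on `-`). "Upstream"/"downstream" windows, summit offsets,
read-through direction and gene proximity are all measured on the
element's own strand under this convention. An optional
merge-adjacent-same-family mode handles annotations in which one element
is split across rows (off by default; no universally correct merge rule
exists).

## Consensus and percent identity

The family consensus is a **star alignment**: every copy is globally
aligned (affine gaps: match +2, mismatch −2, gap open −5, gap extend −1,
via `Bio.Align.PairwiseAligner`) to the longest copy, and each anchor
column takes a plurality vote over the aligned residues; columns where
the gap vote strictly exceeds every base are dropped, and base ties break
in the fixed order A < C < G < T, making the build deterministic. A star
alignment is used instead of a full multiple alignment because at
family-divergence levels of a few percent it recovers the ancestor
essentially perfectly (validated by the ancestor-recovery test: ≥ 99%
identity from 50 copies at 5% substitution divergence) at a fraction of
the cost, and nothing downstream depends on fine alignment detail.

**Percent identity** of a copy against the consensus is
100 × matches / alignment columns, with every gapped column counted as a
non-match; windowed profiles tile the consensus, charge insertions to the
window of the consensus position at their left, and mark windows with no
aligned copy residue as gaps. A copy at substitution rate μ (to one of
the three other bases) therefore has expected identity 100 (1 − μ).

## Guide design and conservation

Guides are all 20-nt protospacers immediately 5′ of an NGG PAM on either
consensus strand (SpCas9 geometry; the PAM's N is never counted as a
mismatch, and mismatches are plain Hamming distance — no seed-region
weighting). Per-copy conservation is the minimum Hamming distance over
every PAM-adjacent window on both strands of the copy (∞ when the copy
has no NGG site); f(k) is the fraction of copies at ≤ k mismatches and is
non-decreasing in k by construction. The genome-wide scan uses the same
vectorised window comparison; its correctness is established against an
exhaustive per-window brute-force oracle, exactly, in the test suite.
Degenerate bases count as mismatches (with a logged warning).

## Differential expression

RPKM = count / (length/10³) / (library/10⁶). **Library sizes are an
explicit input**: the denominators must be total uniquely mapped reads,
which a count table restricted to one repeat family cannot provide — and
deriving them from the family table's own column sums lets strongly
activated copies cancel their own fold change. Fold change is computed
on mean RPKM per condition with a pseudocount equal to the RPKM
equivalent of one read at the mean library size, so zero-count controls
give finite values; both thresholds of the joint call are strict
(FC > 2, p < 0.05), so a fold change of exactly 2 is *not* upregulated.

The per-copy **Wilcoxon signed-rank** test enumerates the exact null
(all 2ⁿ sign assignments of the mid-ranks) for n ≤ 15 informative pairs
and switches to a normal approximation with tie and continuity
corrections beyond; all-zero differences return p = 1 with a warning.
The implementation is cross-checked in the tests against an independent
sign-flip enumeration oracle and against `scipy.stats.wilcoxon` in the
tie-free regime. With 3 replicate pairs a signed-rank test cannot reach
p < 0.05, so two replication units are supported: (a) pairs = biological
replicates (the default; the per-record `test_mode` field records it),
and (b) pairs = positional coverage bins along the element
(`wilcoxon_from_bins`) for designs with few replicates. Fold changes are
computed on RPKM, not raw counts. No multiple-testing correction is
applied to per-copy calls (the joint FC gate is the specificity
control); group comparisons use Mann–Whitney U with Holm step-down
(`scipy` / `statsmodels`).

## Epi-state classification

Window geometry (defaults, configurable): H3K27ac over [−400, +100) bp
and H3K4me3 over [0, +2000) bp around the strand-aware TSS — the 400 bp
upstream region is the family's promoter/enhancer region, and H3K4me3 on
activated copies sits characteristically *downstream* of the TSS. A mark
is enriched when its window mean RPM is ≥ `enrich_fold` (default 2) times
the genome background and above a small absolute floor (`min_rpm`,
default 0.05 RPM). Background is the bp-weighted 5%-trimmed mean of the
track over the genome excluding annotated repeat/gene windows — robust to
the small fraction of enriched bins without requiring a control track.
Classes: co-marked (both), single-marked (H3K27ac only), unmarked.
H3K4me3 without H3K27ac fits neither marked class and is reported as
unmarked (it did not occur in the data this models; the class invariant
keeps every element in exactly one class).

The H3K4me3 **summit offset** is the argmax of the 150 bp moving-average
signal over [−2000, +4000] bp around the TSS, sign positive downstream;
the extraction window is padded by the kernel width so smoothing has no
edge artifact, ties resolve to the smallest |offset| (downstream
preferred on exact ± ties), and a flat profile is undefined (warning).

dCas9 binding uses ≥ 1 bp peak–element overlap; specificity = bound
target-family elements / all bound upregulated elements, which is
invariant to fragmenting a peak into abutting pieces. Methylation:
duplicate CpG records at one site are pooled (summed reads) *before* the
per-site ratio, then regions take the unweighted mean of site ratios
(regions with no covered CpG are NA; zero-coverage sites are skipped with
a warning). Profile matrices are strand-oriented per-element RPM rows on
a symmetric bin grid around the TSS; column means give the metaplot, and
rows order by descending per-element signal (e.g. RNA RPM) by default.
No plotting is bundled — the matrices serialise to TSV and feed any
heatmap tool.

## Read-through attribution and gene linkage

An upregulated non-family, intergenic element is attributed to
read-through when the **nearest upstream** (element-strand-aware)
transactivated family copy on the **same strand** lies within
`max_distance` (default 20 kb) and RNA coverage continues across the gap:
gap mean RPM ≥ `min_ratio` (default 0.2) of the source element's mean RPM
*and* at least `min_covered_fraction` (default 0.8) of gap bases
individually reach that level. The continuity condition is this package's
operationalisation of "directly downstream" read-through: a true
read-through isoform covers the whole gap at its retention level, whereas
unrelated transcribed elements inside a long gap can raise the *mean*
while leaving most of the gap uncovered, which inflates false
attributions at dense loci. Poly(A) signals are AATAAA/ATTAAA hexamers
read on the source strand; the number traversed in the gap is reported.
Attribution is deterministic and monotone in `max_distance`.

Gene linkage: an upregulated gene links to the nearest co-/single-marked
transactivated copy whose 3′ end lies ≤ `max_gene_distance` (default
50 kb) upstream of the gene TSS on the copy's strand (a symmetric mode
exists for enhancer-style linking), provided neither H3K4me3 nor H3K27ac
at the gene's own promoter (±500 bp) changed by ≥ `promoter_fold`
(default 1.5) between conditions — the alternative-promoter reading
requires the canonical promoter to be unchanged. Genes upregulated with
no proximal marked copy are reported separately and can be tested for TAD
co-membership with transactivated copies (TADs consumed as plain
non-overlapping intervals, half-open containment of the TSS).

## Synthetic cohort

The generator plants every structure the analysis assumes, and records it
in a `SyntheticTruth` object:

* one ancestral consensus (default 1500 bp) with an embedded
  protospacer+NGG site; each family copy is an independent descendant
  (substitutions at μ = 0.05 to one of the other three bases, single-base
  indels at ι = 0.005). A `fraction_targetable` = 0.64 subset keeps the
  guide site at ≤ 1 mismatch (of which `frac_exact_guide` = 0.375 exact,
  so ≈ 24% of all copies match exactly and ≈ 64% at ≤ 1 mismatch); the
  rest have the site disrupted. Targetable copies are the transactivated
  set.
* class labels are planted by **stratified exact counts**
  (round(frac × n) copies, placed at random) rather than per-copy
  Bernoulli draws: the planted co-marked fraction (default 0.20),
  targetable fraction and read-through fraction then carry no binomial
  noise of their own, so recovery tests measure the analysis, not the
  plant.
* counts are negative binomial with var = m + α m² (α =
  `nb_dispersion` = 0.1; Poisson at α = 0), control means lognormal
  around `base_mean` = 50, treated mean = `effect_size` (= 4) × control
  for transactivated copies, read-through targets, independently
  activated decoys and linked genes (co-marked-linked genes get 2×
  `effect_size`, reproducing their higher expression). Default
  `n_replicates` = 8 per condition: an NB power calculation at effect 4 /
  dispersion 0.1 gives per-replicate P(treated > control) ≈ 0.99, hence
  ≈ 0.96 per-copy sensitivity under the exact signed-rank test at n = 8
  (≈ 0.93 at n = 6, uncomfortably close to the 90% recovery target).
  Per-sample library sizes add a constant `background_library` = 10⁶
  reads mapped outside the tables.
* tracks are emitted at 25 bp bins (library_scale 10⁶, so values are
  RPM) over a gamma(1, 0.2) background: H3K27ac rectangles over the
  [−400, +100) TSS window of every transactivated copy at 10× background;
  for co-marked copies a Gaussian (σ = 300 bp) H3K4me3 bump with summit
  planted uniformly 500–1500 bp downstream; dCas9-HA Gaussians (σ =
  100 bp) at the guide site of every targeted copy, with matching planted
  peak intervals; RNA coverage from the TSS to the first planted poly(A)
  hexamer, extended past it at a geometric retention factor (0.5) into
  the downstream element for read-through events; gene promoters carry
  identical H3K4me3/H3K27ac bumps in treated and control tracks (except
  "confounder" genes, upregulated with a treated-only promoter gain, which
  the promoter-unchanged filter must reject). Per-copy CpG methylation is
  Beta(2,2)-distributed and identical across conditions (activation does
  not change DNA methylation in this model).
* layout: units (copy + poly(A) + optional ERV9-like internal segment +
  optional read-through decoy + optional downstream gene at 4.6–15 kb)
  are shuffled along one chromosome (default 3 Mb) with 0.8–2 kb gaps;
  gene-bearing units get 16–20 kb spacers on both sides so the planted
  element is always its gene's nearest marked element. Minus-strand units
  are built on a local forward canvas and reverse-complemented whole, so
  every planted motif and mark is strand-consistent by construction.
  All randomness flows from a single mandatory seed through named
  substreams (genome / counts / tracks), making every output
  byte-reproducible.

**What the generator does not emulate** — mappability and multi-mapping
artifacts (the central practical difficulty of real repeat quantification),
read-level noise, fragment-size effects, diploidy, cross-copy sequence
exchange, and genome-scale heterogeneity of background signal. Passing
recovery tests therefore demonstrate that the statistical and geometric
logic of each stage is correct under the stated noise model, not that the
pipeline is robust to alignment ambiguity in real data.

## Problem sizes and numerical choices

Recovery checks run on a 120-copy / 3 Mb cohort (≈ 77 transactivated
copies), calibration on a 1000-element null cohort with 6+6 replicates,
and scanner oracle-equivalence on a 1 Mb genome with 50 copies — sizes at
which every planted quantity is estimated with comfortable margins while
the whole suite stays desk-scale. Exact signed-rank enumeration is capped
at n = 15 (2¹⁵ sign vectors); bedGraph track values are rounded to 5
decimals on write; floating-point ties in summit detection resolve by
`np.isclose` against the maximum.

## Known limitations

* The consensus is rebuilt from the copies at hand, not taken from a
  curated repeat library, so conservation fractions depend on the input
  annotation.
* Percent identity depends on the (deterministic) choice among co-optimal
  alignments; strand symmetry of identity is therefore approximate at the
  sub-percent level, while mismatch counts and all calls are exactly
  symmetric.
* The numeric criterion separating co- from single-marked elements, the
  distance defining a "proximal" gene and the read-through rule are
  operational choices (exposed as parameters), not published definitions;
  absolute class counts from real data will depend on them.
* Splice-junction evidence for LTR-to-gene fusion transcripts is accepted
  as an optional input table, never computed from alignments.
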
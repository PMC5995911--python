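# Methods

This note documents the models, conventions, parameter defaults and design
decisions behind each stage of the package, and what the synthetic-data
tests do and do not establish about real data.

## Coordinates and tags

All genomic spans are 0-based half-open (BED convention); a tag at exactly
a window's end coordinate is outside it. Tags are single-base points. When
real BED records are loaded, stranded records are reduced to their 5′ base
shifted +100 bp toward 3′ (a fixed half-fragment shift standing in for a
fragment model); unstranded records use the interval midpoint. Identical
(chrom, position) tags collapse to one before any counting (clonal-read
removal), and the depth-normalization factor uses the post-deduplication
total, so the factor and the counts it scales are self-consistent.

## Occupancy quantification

Promoters are 2 kb windows centered at the TSS, symmetric regardless of
strand, clipped at position 0 and (when a chromosome-sizes table is given)
at the chromosome end; clipped windows are flagged. Occupancy is the
deduplicated tag count in the window multiplied by `target / N_tags` with
`target = 20,000,000` by default, so samples of different depth are
directly comparable. The default reports the summed normalized count; a
`per_bp` option divides by window length for users who prefer an average
density — the two differ only by a constant for fixed-width windows.

Anchor matrices cover TSS ±5 kb in 50 bp bins (200 columns). The flank and
the per-bin assignment `floor((pos − (anchor − flank)) / bin)` are exact
integer arithmetic; rows of minus-strand anchors are reversed so the
upstream direction is always on the left. 50 bp is a display-resolution
choice; column sums are invariant to it. Δ matrices are elementwise KD −
control on an identical row/bin grid, and profiles are plain column means
(no smoothing).

## Peak calling

The built-in caller is deliberately minimal: one genome-wide Poisson rate
λ = N·w/G (N deduplicated tags, w = 300 bp window, G genome length),
windows slid at 100 bp steps, a window significant when the exact upper
tail P(X ≥ k; λ) ≤ 10⁻⁸, and overlapping/touching significant windows
merged into one peak scored by the best window's −log₁₀ p (capped at 1000
in BED output) with that window's center as the summit. It has no local
background, no input subtraction, no fragment-model shifting and no
broad-peak mode; it exists so the downstream consensus/overlap/
classification machinery can be exercised end-to-end. Peaks from a real
caller can be supplied as BED6/narrowPeak and bypass it.

## Consensus overlap

For overlap statistics, peaks of both (or all three) sets are merged —
touching intervals coalesce — into disjoint consensus regions. A peak
counts as overlapped when it shares strictly more than 500 bp with a
consensus region that also receives strictly more than 500 bp from a peak
of the other set (an exact 500 bp overlap fails). The published wording of
this rule is ambiguous between peak-vs-consensus and peak-vs-peak
comparison; the consensus interpretation is the default and a `pairwise`
mode provides the direct peak-vs-peak >500 bp alternative. Venn
compartments use the same per-set claim rule on consensus regions; regions
claimed by no set (possible when every peak in them is short) are reported
under `none` so compartment counts always sum to the number of consensus
regions.

## Bivalent classification and split

A promoter has a mark when it intersects the mark's peak union by at least
1 bp; `min_frac` optionally demands a covered fraction instead. The 1 bp
rule is the simplest testable reading of "enrichment of both marks" —
the underlying study may have used a score cutoff, which is why the
sensitivity knob is exposed rather than hidden. States: bivalent (both
marks), active (H3K4me3 only), neither (otherwise).

Bivalent genes are split against the knockdown expression table at
log₂FC ≥ 1 and FDR ≤ 0.05 (both inclusive, exactly as printed) into Up,
Down (≤ −1, ≤ 0.05) and No Change; Down and No Change together form
"Other". Bivalent genes absent from the table are counted as No Change and
logged.

## Enrichment statistic

Genes are ranked by a metric (the knockdown log₂FC by default, matching
the direction of the expression contrast). Walking down the ranked list,
the running sum rises by |r|^w / Σ_hits |r|^w at signature genes (weight
w = 1 by default) and falls by 1/(N − N_h) elsewhere; ES is the signed
extremum. Degenerate rules, stated rather than implicit: a signature
covering the whole list has no misses and scores ES = 1; an all-zero hit
metric falls back to uniform increments 1/N_h. The null is gene-label
permutation (sample permutation is impossible without replicate-level
signal data): n_perm (default 1000) random hit sets of the same size from
a seeded stream. NES divides ES by the mean |null ES| of the same sign,
and p is the add-one-corrected fraction of same-sign nulls at least as
extreme — so the attainable minimum is 1/(1 + n_same-sign), roughly
2/n_perm for a sign-balanced null. The same-sign convention keeps the
null p approximately uniform, which the calibration tests verify.

## Reporting statistics

- Comparative CT: 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per sample,
  assuming ideal two-fold amplification per cycle.
- t test: pooled-variance Student form by default (the form named in
  figure-legend conventions), Welch via `equal_var=False`. Two samples
  with zero variance and equal means return (0, 1); n < 2 is an error.
- Wilcoxon rank-sum: midranks for ties. For combined n ≤ 12 the two-sided
  p comes from exact enumeration of all C(n, n_a) rank assignments — a
  permutation test that stays valid with ties, which also yields the
  symmetric p = 1 for identical samples. Above 12, a normal approximation
  with tie and continuity corrections. The switch point is configurable.
- Benjamini–Hochberg step-up adjustment for all FDR columns.
- AP staining categorization: the control sample's 10th and 40th
  linear-interpolation percentiles become the low/intermediate/high
  cutoffs (bottom 10% low, next 30% intermediate, top 60% high); boundary
  values fall into the lower category, so a degenerate all-equal control
  maps to "low". Cutoffs derived from the control are applied unchanged to
  every sample. The quantile convention is declared here, not inferred
  from any source.

## Synthetic data generator

The generator emulates the promoter chromatin structure the analysis
assumes, at a desk-scale size: by default 431 active, 97 other-bivalent,
22 up-bivalent and 30 silent genes (the mESC census of 8618 active and
2389 bivalent promoters, 435 of them derepressed, scaled down 20-fold,
plus a small silent class) laid out evenly on 2 × 10 Mb chromosomes with
alternating strands and archetype labels shuffled by a seeded stream.

Tags per (mark, condition) sample are a uniform genomic background at
5×10⁻⁴ tags/bp plus, per gene, Poisson-many tags uniform over the 2 kb
promoter window with expectation density × width × multiplier. Default
control densities (tags/bp) follow the qualitative ordering of real
promoter classes — e.g. H3K4me3 0.05 at active vs 0.025 at up-bivalent;
H3K27me3 0.05 at up-bivalent vs 0.03 at other-bivalent vs 0 at active;
H2A.Z and GAS41 strong (0.07–0.08) at all non-silent promoters. The
knockdown multiplies densities only at the up-bivalent archetype: H2A.Z
×0.5, H3K27me3 ×0.6, H3K4me3 ×1.1. These effect sizes are configuration,
not biological claims: the real data constrain directions (both
repressive-axis marks down, the active mark slightly up), not magnitudes.
Each (mark, condition) sample draws from its own RNG stream keyed by a
CRC of its labels under the master seed, so adding a mark never perturbs
the draws of another.

Two readings of "sequencing depth" are reconciled explicitly: by default
(`depth=None`) totals are Poisson around the expectation implied by the
densities and the bookkeeping identity *expected count = density × width ×
multiplier* holds exactly; setting `depth` rescales all rates per sample
so each sample's total is Poisson(depth) (the per-sample scale factor is
recorded in the ground truth). `depth=0` yields empty collections with
ground truth still emitted.

The expression table draws 2 conditions × 3 replicates per gene from a
negative binomial (gamma–Poisson) with variance m + φm², φ = 10⁻⁴ by
default, knockdown mean = baseline × 2^true_log2FC (true log₂FC 3 at
up-bivalent genes, 0 elsewhere; baselines 2000/1000/600/50 for
active/other-bivalent/up-bivalent/silent, echoing the lower basal
expression of derepressed bivalent genes). Each gene gets a two-sided
Welch t on log₂(count+1) and a BH-adjusted FDR. Three replicates rather
than two is a deliberate design choice: with n = 2 the Welch–Satterthwaite
degrees of freedom land in [1, 2] and the resulting t-tails are so heavy
that even enormous effects rarely clear a multiple-testing threshold —
the planted-effect recovery this generator exists to support is
statistically impossible at n = 2, and n = 3 restores near-complete power
at these settings.

**What passing tests show — and don't.** The generator and the quantifier
agree by construction on the tag model (points, uniform promoter signal,
no fragment-length structure, no mappability or GC bias, no copy-number
variation, no input/IgG background structure, single-TSS genes, no
enhancers unless supplied as custom anchor sets). Recovery results
therefore validate the correctness of the pipeline's bookkeeping,
thresholds and statistics — not the robustness of any step to the biases
of real ChIP-seq libraries.

## Pipeline driver

The `run` driver chains load → quantify → call peaks → overlap → classify
→ split → Δ profiles (with rank-sum tests at the Up-bivalent set) →
enrichment, writing TSV/BED/JSON artifacts whose header comments name the
coordinate convention and normalization target, plus a manifest with the
tool version, a hash of the analytic configuration (output location
excluded), input checksums, seed and per-stage row counts. Identical
inputs and seed reproduce byte-identical tables; only manifest timestamps
differ. The configuration file is flat YAML key-value with dynamic
`tags_<mark>_<condition>` / `peaks_<mark>_<condition>` keys; unknown keys
are errors so typos cannot silently fall back to defaults. All stages are
vectorised single-threaded numpy; the `--threads` flag is accepted for
interface compatibility and results are independent of it.

## Problem sizes

The default simulation (580 genes, 6 marks × 2 conditions ≈ 7×10⁵ tags,
20 Mb genome) runs the full pipeline in a few seconds; the test suite's
calibration checks use 20 expression replica runs and 200 enrichment runs
at n_perm = 200. These sizes were chosen so every distributional claim is
testable interactively; all of them are configuration, and the same code
paths handle genome-scale inputs (interval and counting operations are
sort/searchsorted-based, linear-logarithmic in tags and windows).

## Known limitations

- The Poisson caller's single global λ over-calls in high-background
  samples and under-calls broad domains; it is a stand-in, not a
  contribution.
- One TSS per gene; isoform-level promoters are out of scope.
- The enrichment module reports ES/NES/p for a single signature per call;
  multi-signature FDR across a collection reduces to BH over their p's.
- No bigWig/plotting output; tables are written for external plotters.
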
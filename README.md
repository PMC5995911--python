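# poised

Promoter chromatin-state analysis for ChIP-seq tag data: bivalent-domain
classification, histone-variant occupancy quantification, peak consensus
overlap, knockdown delta profiling, and gene-set enrichment — together with
a seeded synthetic-data generator that provides ground truth for every
stage.

## The problem

In mouse embryonic stem cells, promoters of many developmental genes carry
both the active H3K4me3 and the repressive H3K27me3 mark — a *bivalent
domain* that keeps the gene poised. The histone variant H2A.Z is deposited
at these promoters by chromatin remodeling complexes whose recruitment
depends on readers of histone acetylation (H3K27ac, H3K14ac). Knocking
down such a reader reduces H2A.Z and H3K27me3 at a subset of bivalent
promoters and derepresses those genes.

Testing that chain of events from sequencing data requires a set of small,
well-defined computational steps that this package implements as a
reusable, fully tested pipeline:

- **Occupancy**: tags are deduplicated, counted in 2 kb promoter windows
  centered at the TSS, and scaled to a common depth of 2×10⁷ tags, so
  `occ(g) = (target / N_tags) · #{tags ∈ [tss−1kb, tss+1kb)}`.
- **Peaks**: a stand-in Poisson caller tests 300 bp sliding windows
  against a uniform background rate λ = N·w/G at `P(X ≥ k) ≤ 10⁻⁸`;
  externally called peaks can be supplied instead.
- **Overlap**: peaks of all marks are merged into consensus regions; a
  peak is *overlapped* when it shares **> 500 bp** with a consensus region
  that also receives > 500 bp from the other set. Two- and three-way Venn
  compartments use the same rule.
- **Bivalent split**: promoters intersecting both H3K4me3 and H3K27me3
  peaks are bivalent; bivalent genes with knockdown log₂FC ≥ 1 and
  FDR ≤ 0.05 form the "Up" set, the rest "Other".
- **Delta profiles**: TSS ±5 kb occupancy matrices (50 bp bins,
  minus-strand rows flipped) are differenced (Δ = KD − control) and
  compared with a two-tailed unpaired Wilcoxon rank-sum test.
- **Enrichment**: the weighted running-sum (GSEA-style) statistic
  `ES = extremum of Σ_hits |r|^w/Σ|r|^w − Σ_miss 1/(N−N_h)` with a
  gene-label permutation null, NES and nominal p.
- **Reporting statistics**: comparative-CT (2^−ΔΔCt) expression, pooled
  Student and Welch t tests, exact/approximate Wilcoxon, Benjamini–
  Hochberg FDR, and quantile-based (60/30/10) staining categorization.

The synthetic generator emulates the mESC promoter landscape — archetypes
`active`, `bivalent_other`, `bivalent_up`, `silent` with per-mark tag
densities for H3K4me3, H3K27me3, H2A.Z, H3K27ac, H3K14ac and GAS41 under
control and knockdown conditions — and emits tag BEDs, a TSS table, an
expression table with replicate counts and FDR, and the full ground truth.

## Worked example

```python
import poised as ps

cfg = ps.SimulationConfig(seed=1)          # ~580 genes, 6 marks, 2 conditions
tags, truth = ps.simulate_tags(cfg)
de = ps.simulate_expression(truth, cfg)

# classify promoters from called peaks
proms = ps.promoter_windows(truth.gene_models(), 2000, cfg.chrom_sizes)
k4 = ps.call_peaks_poisson(tags[("H3K4me3", "control")], cfg.chrom_sizes)
k27 = ps.call_peaks_poisson(tags[("H3K27me3", "control")], cfg.chrom_sizes)
states = ps.classify_promoters(proms, k4, k27)
print(states["state"].value_counts().to_dict())

split = ps.split_bivalent(states, de)
print(len(split.up), "Up-bivalent,", len(split.other), "Other bivalent")

# knockdown reduces H2A.Z at the Up-bivalent promoters
up = proms[proms.gene_id.isin(split.up)]
c = ps.window_occupancy(tags[("H2A.Z", "control")], up)
k = ps.window_occupancy(tags[("H2A.Z", "kd")], up)
print("H2A.Z KD/control ratio:", round(k.sum() / c.sum(), 3))
```

Output:

```
{'active': 431, 'bivalent': 112, 'neither': 37}
20 Up-bivalent, 92 Other bivalent
H2A.Z KD/control ratio: 0.52
```

431 promoters are called active (H3K4me3 only) and 112 bivalent; of the
bivalent genes, 20 pass the Up thresholds (the generator planted 22, of
which the caller classifies 20 as bivalent — the remaining Up genes have
weak H3K4me3 signal near the calling threshold). The H2A.Z knockdown/control
occupancy ratio at those promoters recovers the planted multiplier 0.5.

The same stages are available from the shell:

```bash
poised simulate --seed 1 --outdir sim
poised run --config pipeline.yaml --seed 1 --outdir out
poised overlap --peaks-a gas41.bed --peaks-b h2az.bed
```

`poised run` writes occupancy tables, peak BEDs, the overlap report, the
promoter states and bivalent split, Δ profiles with Wilcoxon statistics,
the enrichment result, and a run manifest (config hash, input checksums,
row counts); re-running with the same inputs and seed reproduces
byte-identical tables.

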
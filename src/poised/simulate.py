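"""Synthetic multi-mark ChIP tag data with known ground truth.

The generator emulates the promoter chromatin structure of mouse ESCs that
the downstream analysis assumes: genes fall into archetypes (``active``,
``bivalent_other``, ``bivalent_up``, ``silent``) with characteristic
promoter tag densities for six marks (H3K4me3, H3K27me3, H2A.Z, H3K27ac,
H3K14ac, GAS41) under two conditions (control vs knockdown).  The knockdown
perturbs only the designated Up-bivalent subset: H2A.Z and H3K27me3 are
reduced, H3K4me3 slightly increased, and expression is derepressed with a
known true log2 fold change.  Tags are single-base points: a uniform genomic
background plus a uniform signal over each 2 kb promoter window.  A matched
expression table with negative-binomial replicate counts, a Welch test on
log2 counts and Benjamini–Hochberg FDR completes the inputs the pipeline
consumes.  Every draw flows from one master seed through per-(mark,
condition) streams, so adding a mark never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneModel, IntervalSet
from .io import (write_chrom_sizes, write_de_table, write_tss_table)
from .signal import TagCollection
from .stats import benjamini_hochberg, t_test_unpaired

__all__ = [
    "MARKS",
    "CONDITIONS",
    "ArchetypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_archetypes",
    "simulate_tags",
    "simulate_expression",
    "write_simulation",
]

MARKS = ("H3K4me3", "H3K27me3", "H2A.Z", "H3K27ac", "H3K14ac", "GAS41")
CONDITIONS = ("control", "kd")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Promoter chromatin archetype: per-mark densities and knockdown effects.

    ``densities`` are control-condition promoter tag densities in tags/bp;
    ``kd_multipliers`` scale them in the knockdown (marks not listed keep
    multiplier 1); ``true_log2fc`` is the planted expression response;
    ``baseline_expression`` the control-condition mean count.
    """

    name: str
    densities: dict[str, float]
    kd_multipliers: dict[str, float] = field(default_factory=dict)
    true_log2fc: float = 0.0
    baseline_expression: float = 100.0

    def __post_init__(self) -> None:
        for mark, d in self.densities.items():
            if d < 0:
                raise ValueError(f"{self.name}: negative density for {mark}")
        for mark, m in self.kd_multipliers.items():
            if m < 0:
                raise ValueError(f"{self.name}: negative multiplier for {mark}")
        if self.baseline_expression < 0:
            raise ValueError("baseline_expression must be >= 0")

    def density(self, mark: str) -> float:
        return self.densities.get(mark, 0.0)

    def multiplier(self, mark: str) -> float:
        return self.kd_multipliers.get(mark, 1.0)


def default_archetypes() -> list[ArchetypeSpec]:
    """The default mESC-like archetype panel.

    Densities follow the qualitative ordering seen at real promoters: active
    genes carry strong H3K4me3 and acetylation with no H3K27me3; bivalent
    genes carry both methyl marks with stronger H2A.Z; Up-bivalent genes
    (the subset derepressed by knockdown) have higher H3K27me3, lower
    H3K4me3/H3K27ac and lower basal expression than other bivalent genes;
    silent genes are background.  Knockdown effects (H2A.Z x0.5,
    H3K27me3 x0.6, H3K4me3 x1.1, expression +3 log2 units at Up-bivalent
    promoters only) set the effect directions the analysis must recover.
    """
    return [
        ArchetypeSpec(
            "active",
            densities={"H3K4me3": 0.05, "H3K27me3": 0.0, "H2A.Z": 0.07,
                       "H3K27ac": 0.05, "H3K14ac": 0.02, "GAS41": 0.07},
            baseline_expression=2000.0,
        ),
        ArchetypeSpec(
            "bivalent_other",
            densities={"H3K4me3": 0.03, "H3K27me3": 0.03, "H2A.Z": 0.08,
                       "H3K27ac": 0.01, "H3K14ac": 0.02, "GAS41": 0.07},
            baseline_expression=1000.0,
        ),
        ArchetypeSpec(
            "bivalent_up",
            densities={"H3K4me3": 0.025, "H3K27me3": 0.05, "H2A.Z": 0.07,
                       "H3K27ac": 0.005, "H3K14ac": 0.025, "GAS41": 0.075},
            kd_multipliers={"H2A.Z": 0.5, "H3K27me3": 0.6, "H3K4me3": 1.1},
            true_log2fc=3.0,
            baseline_expression=600.0,
        ),
        ArchetypeSpec(
            "silent",
            densities={m: 0.0 for m in MARKS},
            baseline_expression=50.0,
        ),
    ]


# Default archetype mix: the mESC census of 8618 active and 2389 bivalent
# promoters (435 of them Up-bivalent) scaled down 20-fold, plus a small
# silent background class.
DEFAULT_N_GENES = {"active": 431, "bivalent_other": 97, "bivalent_up": 22,
                   "silent": 30}


@dataclass
class SimulationConfig:
    n_genes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_GENES))
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    background_density: float = 5e-4  # tags/bp, genome-wide
    depth: int | None = None  # per-sample total tags; None = implied by densities
    seed: int = 0
    signal_width: int = 2000
    dispersion: float = 1e-4  # NB dispersion of replicate counts
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_genes.values()):
            raise ValueError("n_genes entries must be positive")
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chroms and chrom_length must be positive")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.signal_width <= 0 or self.signal_width % 2:
            raise ValueError("signal_width must be positive and even")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length


@dataclass
class GroundTruth:
    """The simulator's oracle: gene layout, expected occupancies, true peaks.

    ``genes`` has one row per simulated gene (gene_id, archetype, chrom,
    strand, tss, promoter bounds, true_log2fc, baseline).  ``occupancy``
    records, per gene and mark, the expected promoter tag count in each
    condition and the knockdown multiplier (the bookkeeping identity
    expected = density x width x multiplier x scale).  ``true_peaks`` lists
    the promoter signal intervals per (mark, condition);
    ``scale_factors`` the per-sample depth rescaling (1.0 unless a target
    depth was configured).
    """

    genes: pd.DataFrame
    occupancy: pd.DataFrame
    true_peaks: dict[tuple[str, str], IntervalSet]
    scale_factors: dict[tuple[str, str], float]

    def gene_models(self) -> list[GeneModel]:
        return [GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss))
                for r in self.genes.itertuples(index=False)]

    def genes_of(self, archetype: str) -> list[str]:
        return self.genes.loc[self.genes["archetype"] == archetype, "gene_id"].tolist()


def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent, label-keyed RNG stream derived from the master seed."""
    key = [seed] + [zlib.crc32(lab.encode()) & 0x7FFFFFFF for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


def _lay_out_genes(config: SimulationConfig,
                   archetypes: list[ArchetypeSpec]) -> pd.DataFrame:
    """Place genes evenly along the chromosomes with shuffled archetypes."""
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("archetype names must be unique")
    unknown = set(config.n_genes) - set(names)
    if unknown:
        raise ValueError(f"n_genes refers to unknown archetypes: {sorted(unknown)}")
    by_name = {a.name: a for a in archetypes}
    labels = [name for name in config.n_genes for _ in range(config.n_genes[name])]
    rng = _stream(config.seed, "layout")
    labels = list(np.array(labels)[rng.permutation(len(labels))])

    n_total = len(labels)
    per_chrom = int(np.ceil(n_total / config.n_chroms))
    margin = 20_000  # keep promoters and ±5 kb flanks clear of chrom ends
    usable = config.chrom_length - 2 * margin
    spacing = usable // per_chrom
    half = config.signal_width // 2
    rows = []
    for i, name in enumerate(labels):
        chrom_i, slot = divmod(i, per_chrom)
        tss = margin + slot * spacing + spacing // 2
        arch = by_name[name]
        rows.append((
            f"gene_{i + 1:04d}", name, f"chr{chrom_i + 1}",
            "+" if i % 2 == 0 else "-", tss, tss - half, tss + half,
            arch.true_log2fc, arch.baseline_expression,
        ))
    return pd.DataFrame(rows, columns=[
        "gene_id", "archetype", "chrom", "strand", "tss",
        "promoter_start", "promoter_end", "true_log2fc", "baseline",
    ])


def simulate_tags(
    config: SimulationConfig,
    archetypes: list[ArchetypeSpec] | None = None,
) -> tuple[dict[tuple[str, str], TagCollection], GroundTruth]:
    """Draw per-(mark, condition) tag collections plus their ground truth.

    Background tags are uniform over each chromosome at
    ``background_density``; each gene adds Poisson-many tags uniform over
    its promoter window with expectation ``density x width x multiplier``.
    With a configured ``depth`` all rates are rescaled per sample so the
    sample total is Poisson(depth); ``depth=0`` yields empty collections
    (ground truth is still returned).
    """
    if archetypes is None:
        archetypes = default_archetypes()
    by_name = {a.name: a for a in archetypes}
    genes = _lay_out_genes(config, archetypes)
    width = config.signal_width

    occ_rows = []
    collections: dict[tuple[str, str], TagCollection] = {}
    true_peaks: dict[tuple[str, str], IntervalSet] = {}
    scale_factors: dict[tuple[str, str], float] = {}

    for mark in MARKS:
        dens = genes["archetype"].map(lambda a: by_name[a].density(mark)).to_numpy()
        mult = genes["archetype"].map(lambda a: by_name[a].multiplier(mark)).to_numpy()
        for cond in CONDITIONS:
            eff = dens * (mult if cond == "kd" else 1.0)
            mu_genes = eff * width
            expected_bg = config.background_density * config.genome_length
            expected_total = expected_bg + mu_genes.sum()
            if config.depth is None:
                scale = 1.0
            elif config.depth == 0:
                scale = 0.0
            else:
                scale = config.depth / expected_total
            scale_factors[(mark, cond)] = scale

            rng = _stream(config.seed, mark, cond)
            positions: dict[str, list[np.ndarray]] = {c: [] for c in config.chrom_sizes}
            if scale > 0:
                for chrom, size in config.chrom_sizes.items():
                    n_bg = rng.poisson(config.background_density * size * scale)
                    positions[chrom].append(rng.integers(0, size, n_bg, dtype=np.int64))
                counts = rng.poisson(mu_genes * scale)
                for row, k in zip(genes.itertuples(index=False), counts):
                    if k:
                        positions[row.chrom].append(
                            rng.integers(row.promoter_start, row.promoter_end,
                                         k, dtype=np.int64)
                        )
            merged = {c: (np.concatenate(v) if v else np.empty(0, dtype=np.int64))
                      for c, v in positions.items()}
            collections[(mark, cond)] = TagCollection(
                sample_id=f"{mark}_{cond}", mark=mark, condition=cond,
                positions=merged,
            )
            signal = genes[mu_genes * (scale if scale else 1.0) > 0]
            true_peaks[(mark, cond)] = IntervalSet(
                signal[["chrom", "promoter_start", "promoter_end"]]
                .rename(columns={"promoter_start": "start", "promoter_end": "end"})
            )
        for row, d, m in zip(genes.itertuples(index=False), dens, mult):
            occ_rows.append((row.gene_id, mark, d * width,
                             d * width * m, m))

    occupancy = pd.DataFrame(
        occ_rows,
        columns=["gene_id", "mark", "expected_control", "expected_kd", "multiplier"],
    )
    truth = GroundTruth(genes, occupancy, true_peaks, scale_factors)
    return collections, truth


def simulate_expression(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Replicate counts, Welch test and BH adjustment for every gene.

    Counts for 2 conditions x ``n_replicates`` replicates (default 3) come from a
    negative binomial (gamma-Poisson) with control mean = baseline, knockdown
    mean = baseline x 2^true_log2fc, and variance ``m + dispersion * m^2``.
    The per-gene two-sided test is a Welch t on log2(count + 1); the FDR
    column is the Benjamini–Hochberg adjustment across genes.  Columns:
    gene_id, log2fc (observed), fdr, baseline (observed control mean).
    """
    if len(truth.genes) == 0:
        raise ValueError("ground truth holds no genes")
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    rng = _stream(config.seed, "expression")

    def draw(mean: float, n: int) -> np.ndarray:
        if mean == 0:
            return np.zeros(n, dtype=np.int64)
        if config.dispersion == 0:
            return rng.poisson(mean, n)
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape, n)
        return rng.poisson(lam)

    rows = []
    pvals = []
    for row in truth.genes.itertuples(index=False):
        ctrl = draw(row.baseline, config.n_replicates)
        kd = draw(row.baseline * 2.0 ** row.true_log2fc, config.n_replicates)
        log_ctrl = np.log2(ctrl + 1.0)
        log_kd = np.log2(kd + 1.0)
        _, p = t_test_unpaired(log_kd, log_ctrl, equal_var=False)
        rows.append((row.gene_id, float(log_kd.mean() - log_ctrl.mean()),
                     float(ctrl.mean())))
        pvals.append(p)
    fdr = benjamini_hochberg(pvals)
    de = pd.DataFrame(rows, columns=["gene_id", "log2fc", "baseline"])
    de["fdr"] = fdr
    return de[["gene_id", "log2fc", "fdr", "baseline"]]


def write_simulation(
    outdir: str | Path,
    tags: dict[tuple[str, str], TagCollection],
    truth: GroundTruth,
    de: pd.DataFrame,
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write BED per (mark, condition), TSS/chrom-sizes/ground-truth TSVs and
    the DE table.  Returns the path of every file written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for (mark, cond), coll in tags.items():
        safe = mark.replace(".", "")
        path = outdir / f"tags_{safe}_{cond}.bed"
        coll.to_frame().to_csv(path, sep="\t", header=False, index=False)
        written[f"tags_{mark}_{cond}"] = path

    tss_path = outdir / "tss.tsv"
    write_tss_table(truth.gene_models(), tss_path)
    written["tss"] = tss_path

    sizes_path = outdir / "chrom.sizes"
    write_chrom_sizes(config.chrom_sizes, sizes_path)
    written["chrom_sizes"] = sizes_path

    truth_path = outdir / "ground_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("# simulated ground truth; coordinates 0-based half-open\n")
        truth.genes.to_csv(fh, sep="\t", index=False)
    written["ground_truth"] = truth_path

    occ_path = outdir / "ground_truth_occupancy.tsv"
    with open(occ_path, "w") as fh:
        fh.write("# expected promoter tag counts per gene/mark/condition\n")
        truth.occupancy.to_csv(fh, sep="\t", index=False)
    written["ground_truth_occupancy"] = occ_path

    de_path = outdir / "expression.tsv"
    write_de_table(de, de_path)
    written["expression"] = de_path
    return written
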
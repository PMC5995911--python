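"""Poisson window peak calling, consensus regions, and overlap statistics.

The caller is a deliberately simple stand-in: a single genome-wide Poisson
background rate, fixed sliding windows, and an upper-tail test at
``P <= 1e-8``.  It has no local background, input subtraction or fragment
model; externally called peaks (BED/narrowPeak) can be supplied instead and
flow through the same overlap machinery.

Overlap follows the consensus rule: peaks from all sets are merged into
disjoint consensus regions, and a peak counts as overlapped only when it
shares strictly more than ``min_overlap`` bp (default 500) with a consensus
region that also receives strictly more than ``min_overlap`` bp from a peak
of the other set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, merge_intervals, overlap_length
from .io import read_bed, write_bed
from .signal import TagCollection

__all__ = [
    "Peak",
    "OverlapResult",
    "call_peaks_poisson",
    "consensus_overlap",
    "venn_counts",
    "read_peaks",
    "write_peaks",
]

MAX_SCORE = 1000.0  # −log10 p cap for BED score column


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0  # −log10 p-value
    summit: int | None = None  # offset from interval start

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score (−log10 p) must be >= 0")


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_a_overlapping: int
    min_overlap: int
    mode: str = "consensus"

    @property
    def fraction_a(self) -> float:
        return self.n_a_overlapping / self.n_a

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_a_overlapping": self.n_a_overlapping,
            "fraction_a": self.fraction_a,
            "min_overlap": self.min_overlap,
            "mode": self.mode,
        }


def call_peaks_poisson(
    tags: TagCollection,
    chrom_sizes: Mapping[str, int],
    window: int = 300,
    step: int = 100,
    p_threshold: float = 1e-8,
) -> list[Peak]:
    """Call peaks as runs of Poisson-significant sliding windows.

    The background rate is uniform: ``lambda = total_tags * window /
    genome_length``.  A window with ``k`` deduplicated tags is significant
    when the upper tail ``P(X >= k; lambda)`` is at or below
    ``p_threshold``.  Overlapping or touching significant windows merge into
    one peak whose score is the max ``-log10 p`` over its windows and whose
    summit is the center of its best window.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    genome_length = int(sum(chrom_sizes.values()))
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    tags = tags.dedup()
    total = tags.total_count
    if total == 0:
        return []
    lam = total * window / genome_length

    peaks: list[Peak] = []
    for chrom in sorted(chrom_sizes):
        pos = tags.positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        size = int(chrom_sizes[chrom])
        starts = np.arange(0, max(size - window, 0) + 1, step, dtype=np.int64)
        ends = starts + window
        k = np.searchsorted(pos, ends, side="left") - np.searchsorted(pos, starts, side="left")
        # upper tail P(X >= k) = sf(k - 1)
        pvals = stats.poisson.sf(k - 1, lam)
        sig = np.flatnonzero(pvals <= p_threshold)
        if len(sig) == 0:
            continue
        with np.errstate(divide="ignore"):
            scores = np.minimum(-np.log10(pvals[sig]), MAX_SCORE)
        # merge runs of overlapping/touching significant windows
        breaks = np.flatnonzero(starts[sig][1:] > ends[sig][:-1])
        bounds = np.concatenate([[0], breaks + 1, [len(sig)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            idx = sig[lo:hi]
            best = lo + int(np.argmax(scores[lo:hi]))
            p_start = int(starts[idx[0]])
            p_end = int(min(ends[idx[-1]], size))
            summit = int(starts[sig[best]] + window // 2 - p_start)
            peaks.append(
                Peak(GenomicInterval(chrom, p_start, p_end),
                     score=float(scores[best]), summit=summit)
            )
    return peaks


def _consensus_flags(
    sets: Sequence[Sequence[Peak]], min_overlap: int
) -> tuple[IntervalSet, np.ndarray]:
    """Merge all peaks; flag, per consensus region, which sets claim it.

    A set claims a region when one of its peaks shares > ``min_overlap`` bp
    with that region.
    """
    every = IntervalSet.from_intervals(p.interval for s in sets for p in s)
    consensus = merge_intervals(every)
    regions = list(consensus)
    flags = np.zeros((len(regions), len(sets)), dtype=bool)
    for si, peak_list in enumerate(sets):
        for peak in peak_list:
            for ri, region in enumerate(regions):
                if overlap_length(peak.interval, region) > min_overlap:
                    flags[ri, si] = True
    return consensus, flags


def consensus_overlap(
    set_a: Sequence[Peak],
    set_b: Sequence[Peak],
    min_overlap: int = 500,
    pairwise: bool = False,
) -> OverlapResult:
    """Fraction of A peaks overlapping B under the >``min_overlap`` bp rule.

    Consensus mode (default): an A peak is overlapped iff some consensus
    region receives > ``min_overlap`` bp from it and > ``min_overlap`` bp
    from some B peak.  Pairwise mode tests direct peak-vs-peak overlap
    instead.  The threshold is strict: an overlap of exactly
    ``min_overlap`` bp does not count.
    """
    if len(set_a) == 0:
        raise ValueError("set A is empty; overlap fraction undefined")
    if pairwise:
        n_over = 0
        for a in set_a:
            if any(overlap_length(a.interval, b.interval) > min_overlap for b in set_b):
                n_over += 1
        return OverlapResult(len(set_a), len(set_b), n_over, min_overlap, "pairwise")

    consensus, flags = _consensus_flags([set_a, set_b], min_overlap)
    regions = list(consensus)
    b_claimed = flags[:, 1]
    n_over = 0
    for a in set_a:
        for ri, region in enumerate(regions):
            if b_claimed[ri] and overlap_length(a.interval, region) > min_overlap:
                n_over += 1
                break
    return OverlapResult(len(set_a), len(set_b), n_over, min_overlap, "consensus")


def venn_counts(
    sets: Mapping[str, Sequence[Peak]], min_overlap: int = 500
) -> dict[str, int]:
    """Venn compartment counts over consensus regions for 2 or 3 peak sets.

    Each consensus region is assigned to the compartment of the sets that
    claim it (> ``min_overlap`` bp from one of their peaks); regions claimed
    by no set land in ``"none"``.  Compartment counts sum to the number of
    consensus regions.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts takes 2 or 3 named peak sets")
    _, flags = _consensus_flags([sets[n] for n in names], min_overlap)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(range(len(names)), r):
            key = "&".join(names[i] for i in combo)
            member = np.ones(len(flags), dtype=bool)
            for i in range(len(names)):
                member &= flags[:, i] if i in combo else ~flags[:, i]
            counts[key] = int(member.sum())
    counts["none"] = int((~flags.any(axis=1)).sum()) if len(flags) else 0
    return counts


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks from BED6 or narrowPeak (columns beyond 6 are ignored,
    except a narrowPeak summit in column 10)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        score = float(row[4]) if len(row) > 4 else 0.0
        summit = None
        if len(row) >= 10:  # narrowPeak: col 10 is summit offset (-1 = none)
            s = int(row[9])
            summit = s if s >= 0 else None
        peaks.append(Peak(GenomicInterval(chrom, start, end), max(score, 0.0), summit))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = [
        (p.interval.chrom, p.interval.start, p.interval.end,
         f"peak_{i + 1}", min(p.score, MAX_SCORE), ".")
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.interval.chrom,
                                                           p.interval.start)))
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    write_bed(df, path, header="coordinates: 0-based half-open (BED); score = -log10 p (capped at 1000)")
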
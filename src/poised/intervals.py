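"""Genomic coordinate conventions, gene models, promoter windows and interval algebra.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end - 1``.  Every downstream stage
(peak calling, occupancy quantification, overlap statistics) works in this
convention, and every file written by the package states it in its header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "IntervalSet",
    "promoter_window",
    "promoter_windows",
    "merge_intervals",
    "overlap_length",
]

_VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).  The span itself
    is strand-agnostic; strand only matters for orientation-sensitive
    consumers (anchor matrices reverse bin order for minus-strand genes).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        return overlap_length(self, other)


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site (TSS).

    One TSS per gene; when an annotation carries several transcripts the
    first listed one wins (the GTF reader logs this collapse).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def promoter_window(
    gene: GeneModel,
    width: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Promoter of a gene: the ``width`` bp window centered at its TSS.

    The window is symmetric about the TSS regardless of strand and is
    clipped at position 0 and, when ``chrom_sizes`` is given, at the
    chromosome end.  Default width 2000 bp (2 kb promoters).
    """
    if width <= 0 or width % 2 != 0:
        raise ValueError(f"width must be a positive even integer, got {width}")
    half = width // 2
    start = max(0, gene.tss - half)
    end = gene.tss + half
    if chrom_sizes is not None and gene.chrom in chrom_sizes:
        end = min(end, int(chrom_sizes[gene.chrom]))
    if end <= start:
        raise ValueError(
            f"promoter window for {gene.gene_id} is empty after clipping"
        )
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def promoter_windows(
    genes: Iterable[GeneModel],
    width: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Promoter windows for many genes as a table.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand,
    clipped`` (``clipped`` flags windows truncated at a chromosome
    boundary).  Raises on duplicate gene ids.
    """
    rows = []
    for g in genes:
        w = promoter_window(g, width=width, chrom_sizes=chrom_sizes)
        rows.append(
            (g.gene_id, w.chrom, w.start, w.end, g.strand, len(w) != width)
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "clipped"]
    )
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    return df


@dataclass
class IntervalSet:
    """An ordered collection of intervals, grouped and sorted by chromosome.

    Iteration order is (chrom, start, end) lexicographic.  Members may
    overlap unless ``merged`` is True (the result of :meth:`merge`).
    """

    df: pd.DataFrame = field(default_factory=lambda: _empty_frame())
    merged: bool = False

    def __post_init__(self) -> None:
        df = self.df
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"IntervalSet frame needs columns {required}")
        if len(df) and ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError("all intervals must satisfy 0 <= start < end")
        self.df = (
            df.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        if not rows:
            df = _empty_frame()
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        has_strand = "strand" in self.df.columns
        for row in self.df.itertuples(index=False):
            strand = getattr(row, "strand", ".") if has_strand else "."
            if strand not in _VALID_STRANDS:
                strand = "."
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), strand)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def by_chrom(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) rows on one chromosome, sorted."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)

    def merge(self) -> "IntervalSet":
        """Merge overlapping and touching intervals into a flat set.

        Touching intervals (``end == start``) are merged, so the result is a
        set of disjoint, non-adjacent spans covering exactly the same bases.
        Idempotent.
        """
        out = []
        for chrom in self.chroms:
            arr = self.by_chrom(chrom)
            for start, end in _merge_sorted(arr):
                out.append((chrom, start, end))
        df = pd.DataFrame(out, columns=["chrom", "start", "end"])
        if not out:
            df = _empty_frame()
        return IntervalSet(df, merged=True)

    def total_coverage(self) -> int:
        """Number of distinct bases covered by the set."""
        m = self.merge().df
        return int((m["end"] - m["start"]).sum()) if len(m) else 0


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str),
         "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64)}
    )


def _merge_sorted(arr: np.ndarray) -> list[tuple[int, int]]:
    # arr sorted by (start, end); touching spans coalesce
    merged: list[tuple[int, int]] = []
    for start, end in arr:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], int(end)))
        else:
            merged.append((int(start), int(end)))
    return merged


def merge_intervals(intervals: IntervalSet | Iterable[GenomicInterval]) -> IntervalSet:
    """Union of intervals as disjoint consensus regions (touching spans merge)."""
    if not isinstance(intervals, IntervalSet):
        intervals = IntervalSet.from_intervals(intervals)
    return intervals.merge()
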
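"""Depth normalization, promoter occupancy, anchor matrices, profiles, deltas.

Tags are single-base points.  Occupancy is a deduplicated tag count inside a
window, scaled so every sample is comparable at a common depth target
(20,000,000 tags by default).  Anchor matrices bin tags around TSSs
(±5 kb, 50 bp bins by default) with minus-strand rows reversed so upstream
is always on the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, IntervalSet
from .io import read_bed

__all__ = [
    "TagCollection",
    "OccupancyMatrix",
    "Profile",
    "normalization_factor",
    "window_occupancy",
    "anchor_matrix",
    "delta_matrix",
    "average_profile",
]

NORMALIZATION_TARGET = 20_000_000


@dataclass
class TagCollection:
    """Point tags for one sample (one mark in one condition).

    ``positions`` maps chromosome name to a sorted int64 array of 0-based
    tag positions.  ``total_count`` is the number of stored tags; after
    :meth:`dedup` it is the post-deduplication count, which is what the
    normalization factor uses.
    """

    sample_id: str
    mark: str
    condition: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    deduplicated: bool = False

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if len(arr) and arr.min() < 0:
                raise ValueError("tag positions must be >= 0")
            clean[chrom] = np.sort(arr)
        self.positions = clean

    @property
    def total_count(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def dedup(self) -> "TagCollection":
        """Collapse identical (chrom, position) tags to one (clonal removal)."""
        if self.deduplicated:
            return self
        pos = {c: np.unique(p) for c, p in self.positions.items()}
        return replace(self, positions=pos, deduplicated=True)

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        sample_id: str,
        mark: str = "",
        condition: str = "",
        shift: int = 100,
    ) -> "TagCollection":
        """Load tags from BED, reducing each record to a point.

        Stranded records are reduced to the 5' base shifted ``shift`` bp
        toward 3' (a fixed half-fragment shift); unstranded records use the
        interval midpoint.
        """
        df = read_bed(path)
        if "strand" in df.columns:
            plus = df["strand"] == "+"
            minus = df["strand"] == "-"
            point = np.where(
                plus, df["start"] + shift,
                np.where(minus, df["end"] - 1 - shift,
                         (df["start"] + df["end"]) // 2),
            )
        else:
            point = ((df["start"] + df["end"]) // 2).to_numpy()
        point = np.maximum(np.asarray(point, dtype=np.int64), 0)
        positions = {
            chrom: point[(df["chrom"] == chrom).to_numpy()]
            for chrom in df["chrom"].unique()
        }
        return cls(sample_id, mark, condition, positions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + 1})
            for chrom, pos in sorted(self.positions.items())
        ]
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)


def normalization_factor(tags: TagCollection, target: int = NORMALIZATION_TARGET) -> float:
    """Scale factor bringing a sample to the common depth target.

    All per-window and per-bin counts downstream are multiplied by
    ``target / total_count``.  The total is the post-deduplication count
    when the collection has been deduplicated.
    """
    total = tags.total_count
    if total == 0:
        raise ValueError(
            f"cannot normalize empty tag collection {tags.sample_id!r}"
        )
    return target / total


def window_occupancy(
    tags: TagCollection,
    windows: IntervalSet | pd.DataFrame,
    scale: float = 1.0,
) -> pd.Series:
    """Normalized deduplicated tag count per window.

    ``windows`` may be an :class:`IntervalSet` or a frame with
    ``chrom/start/end`` (and optionally ``gene_id``, used as the index).
    Counting is half-open: a tag at exactly ``end`` is outside.  Duplicate
    tag positions collapse to one before counting.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    df = windows.df if isinstance(windows, IntervalSet) else windows
    df = df.reset_index(drop=True)
    tags = tags.dedup()
    counts = np.zeros(len(df), dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = tags.positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        counts[sub.index.to_numpy()] = hi - lo
    index = df["gene_id"] if "gene_id" in df.columns else df.index
    return pd.Series(counts * float(scale), index=np.asarray(index), name=tags.sample_id)


@dataclass
class OccupancyMatrix:
    """Genes × bins normalized signal around anchors.

    Rows follow the anchor order; columns are ``2*flank/bin_size`` bins from
    ``-flank`` (upstream, leftmost) to ``+flank``.  Minus-strand anchors have
    already been flipped, so column direction is transcriptional.
    """

    values: np.ndarray
    row_ids: list[str]
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = 2 * self.flank // self.bin_size
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"matrix must have {expected} columns, got shape {self.values.shape}"
            )
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length must match number of rows")
        if len(self.values) and not np.isfinite(self.values).all():
            raise ValueError("matrix values must be finite")

    @property
    def bin_centers(self) -> np.ndarray:
        """bp offset of each bin center from the anchor (negative = upstream)."""
        edges = np.arange(-self.flank, self.flank, self.bin_size)
        return edges + self.bin_size / 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.bin_centers)


@dataclass
class Profile:
    """Per-bin mean occupancy across a matrix's rows (a metagene profile)."""

    offsets: np.ndarray
    values: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_occupancy": self.values})


def anchor_matrix(
    tags: TagCollection,
    anchors: Sequence[GeneModel] | Sequence[tuple[str, str, int, str]],
    flank: int = 5000,
    bin_size: int = 50,
    scale: float = 1.0,
) -> OccupancyMatrix:
    """Bin tags into a genes × bins matrix around anchor points.

    Each anchor (a :class:`GeneModel` or ``(id, chrom, position, strand)``
    tuple) contributes one row covering ``[anchor - flank, anchor + flank)``.
    Tag ``p`` lands in bin ``floor((p - (anchor - flank)) / bin_size)``.
    Rows of minus-strand anchors are reversed so upstream is on the left for
    every gene.  Values are multiplied by ``scale``.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    tags = tags.dedup()
    rows, ids = [], []
    for anchor in anchors:
        if isinstance(anchor, GeneModel):
            aid, chrom, center, strand = anchor.gene_id, anchor.chrom, anchor.tss, anchor.strand
        else:
            aid, chrom, center, strand = anchor
        pos = tags.positions.get(chrom)
        row = np.zeros(n_bins)
        if pos is not None and len(pos):
            lo = np.searchsorted(pos, center - flank, side="left")
            hi = np.searchsorted(pos, center + flank, side="left")
            local = pos[lo:hi] - (center - flank)
            if len(local):
                row = np.bincount(local // bin_size, minlength=n_bins).astype(float)
        if strand == "-":
            row = row[::-1]
        rows.append(row * float(scale))
        ids.append(aid)
    values = np.vstack(rows) if rows else np.empty((0, n_bins))
    return OccupancyMatrix(values, ids, flank, bin_size)


def delta_matrix(kd: OccupancyMatrix, nt: OccupancyMatrix) -> OccupancyMatrix:
    """Elementwise knockdown-minus-control difference (Δ = shKD − shNT)."""
    if kd.row_ids != nt.row_ids or kd.flank != nt.flank or kd.bin_size != nt.bin_size:
        raise ValueError("matrices must share row ids, flank and bin size")
    return OccupancyMatrix(kd.values - nt.values, list(kd.row_ids), kd.flank, kd.bin_size)


def average_profile(matrix: OccupancyMatrix) -> Profile:
    """Column means of an occupancy matrix (average TSS profile)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot average an empty matrix")
    return Profile(matrix.bin_centers, matrix.values.mean(axis=0),
                   matrix.values.shape[0])
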
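"""Bivalent-domain classification and its integration with expression.

A promoter is *bivalent* when it carries both the active H3K4me3 and the
repressive H3K27me3 mark, *active* when it carries H3K4me3 only, and
*neither* otherwise.  Bivalent genes are split against a knockdown
differential-expression table into "Up" (log2FC >= 1 and FDR <= 0.05,
inclusive) and "Other" (Down at log2FC <= -1 & FDR <= 0.05, plus No
Change).  A differentiation gene signature is built by thresholding a
differentiation-vs-ESC contrast (log2FC >= 5 by default), and enrichment of
a signature in a ranked list is scored with the weighted running-sum
(GSEA-style) statistic with a gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals
from .peaks import Peak
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterState",
    "BivalentSplit",
    "GeneSignature",
    "EnrichmentResult",
    "classify_promoters",
    "split_bivalent",
    "build_signature",
    "enrichment_score",
]


@dataclass(frozen=True)
class PromoterState:
    gene_id: str
    has_k4me3: bool
    has_k27me3: bool

    @property
    def state(self) -> str:
        if self.has_k4me3 and self.has_k27me3:
            return "bivalent"
        if self.has_k4me3:
            return "active"
        return "neither"


@dataclass
class BivalentSplit:
    """Partition of the bivalent gene set against knockdown expression."""

    up: set[str]
    down: set[str]
    no_change: set[str]
    lfc: float = 1.0
    fdr: float = 0.05

    @property
    def other(self) -> set[str]:
        """Down and No-Change combined ("Other Bivalent")."""
        return self.down | self.no_change

    def __post_init__(self) -> None:
        if (self.up & self.down) or (self.up & self.no_change) or (self.down & self.no_change):
            raise ValueError("up/down/no_change must be disjoint")


@dataclass(frozen=True)
class GeneSignature:
    name: str
    members: frozenset[str]
    rule: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    fdr: float
    n_perm: int
    seed: int
    n_hits: int
    n_null_same_sign: int = 0  # permutations whose ES shares the observed sign

    def to_dict(self) -> dict:
        return {
            "es": self.es, "nes": self.nes, "p": self.p, "fdr": self.fdr,
            "n_perm": self.n_perm, "seed": self.seed, "n_hits": self.n_hits,
            "n_null_same_sign": self.n_null_same_sign,
        }


def _coverage_bp(promoters: pd.DataFrame, peaks: Sequence[Peak]) -> np.ndarray:
    """bp of each promoter covered by the union of a mark's peaks."""
    merged = merge_intervals(IntervalSet.from_intervals(p.interval for p in peaks))
    cov = np.zeros(len(promoters), dtype=np.int64)
    for chrom, sub in promoters.groupby("chrom", sort=False):
        arr = merged.by_chrom(chrom)
        if len(arr) == 0:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        for i, s, e in zip(sub.index.to_numpy(),
                           sub["start"].to_numpy(), sub["end"].to_numpy()):
            lo = np.searchsorted(ends, s, side="right")
            hi = np.searchsorted(starts, e, side="left")
            if hi > lo:
                cov[i] = np.maximum(
                    0, np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
                ).sum()
    return cov


def classify_promoters(
    promoters: pd.DataFrame,
    k4_peaks: Sequence[Peak],
    k27_peaks: Sequence[Peak],
    min_frac: float = 0.0,
) -> pd.DataFrame:
    """Assign each promoter a chromatin state from H3K4me3/H3K27me3 peaks.

    ``promoters`` is the frame from :func:`poised.intervals.promoter_windows`
    (gene_id, chrom, start, end).  A mark is present when the promoter
    intersects that mark's peak union by at least 1 bp, or — when
    ``min_frac`` > 0 — when at least that fraction of the promoter is
    covered.  Returns the frame with ``has_k4me3``, ``has_k27me3`` and
    ``state`` columns added.
    """
    if promoters["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in promoter table")
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    promoters = promoters.reset_index(drop=True)
    width = (promoters["end"] - promoters["start"]).to_numpy()
    out = promoters.copy()
    for col, peaks in (("has_k4me3", k4_peaks), ("has_k27me3", k27_peaks)):
        cov = _coverage_bp(promoters, peaks)
        if min_frac > 0:
            out[col] = cov >= min_frac * width
        else:
            out[col] = cov >= 1
    out["state"] = np.where(
        out["has_k4me3"] & out["has_k27me3"], "bivalent",
        np.where(out["has_k4me3"], "active", "neither"),
    )
    return out


def split_bivalent(
    states: pd.DataFrame | Sequence[PromoterState],
    de: pd.DataFrame,
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> BivalentSplit:
    """Split bivalent genes by knockdown response at the printed thresholds.

    Up: log2FC >= ``lfc`` and FDR <= ``fdr`` (both inclusive); Down:
    log2FC <= -``lfc`` and FDR <= ``fdr``; everything else is No Change.
    Bivalent genes missing from the expression table are counted as No
    Change (logged).
    """
    if isinstance(states, pd.DataFrame):
        bivalent = set(states.loc[states["state"] == "bivalent", "gene_id"])
    else:
        bivalent = {s.gene_id for s in states if s.state == "bivalent"}
    table = de.set_index("gene_id")
    missing = bivalent - set(table.index)
    if missing:
        logger.info("split_bivalent: %d bivalent genes absent from the DE table, "
                    "counted as no-change", len(missing))
    up, down, no_change = set(), set(), set()
    for g in bivalent:
        if g in missing:
            no_change.add(g)
            continue
        row = table.loc[g]
        if row["log2fc"] >= lfc and row["fdr"] <= fdr:
            up.add(g)
        elif row["log2fc"] <= -lfc and row["fdr"] <= fdr:
            down.add(g)
        else:
            no_change.add(g)
    return BivalentSplit(up, down, no_change, lfc, fdr)


def build_signature(
    de_differentiation: pd.DataFrame,
    lfc_min: float = 5.0,
    name: str = "differentiation_signature",
) -> GeneSignature:
    """Signature of genes strongly upregulated in a differentiation contrast.

    Members are genes with log2FC >= ``lfc_min`` (inclusive).  Raises when
    no gene passes.
    """
    members = frozenset(
        de_differentiation.loc[de_differentiation["log2fc"] >= lfc_min, "gene_id"]
    )
    if not members:
        raise ValueError(f"no genes at log2FC >= {lfc_min}; signature would be empty")
    return GeneSignature(name, members, rule=f"log2FC >= {lfc_min}")


def _running_sum_extremum(metric_sorted: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Signed extremum of the weighted running sum over a ranked list."""
    n = len(metric_sorted)
    n_hits = int(hit.sum())
    if n_hits == n:
        return 1.0  # degenerate: no misses to decrement against
    w = np.abs(metric_sorted) ** weight
    hit_mass = w * hit
    denom = hit_mass.sum()
    if denom == 0:  # all hit metrics zero: fall back to unweighted increments
        steps = hit / n_hits
    else:
        steps = hit_mass / denom
    steps = steps - (~hit.astype(bool)) / (n - n_hits)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def enrichment_score(
    ranked: pd.Series | Mapping[str, float],
    signature: GeneSignature,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted running-sum enrichment of a gene signature in a ranked list.

    Genes are ranked by the metric in descending order (ties keep input
    order).  Walking down the list, the running sum rises by
    ``|metric|^weight / sum_hits |metric|^weight`` at signature genes and
    falls by ``1/(N - N_hits)`` elsewhere; ES is the signed extremum.  The
    null is ``n_perm`` gene-label permutations from a seeded stream; NES
    divides ES by the mean |null ES| of the same sign, and the nominal p is
    the add-one-corrected fraction of same-sign nulls at least as extreme.
    Signature genes absent from the list are dropped (logged).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    series = pd.Series(ranked, dtype=float)
    order = np.argsort(-series.to_numpy(), kind="stable")
    genes = series.index.to_numpy()[order]
    metric = series.to_numpy()[order]
    present = signature.members & set(genes)
    dropped = signature.members - present
    if dropped:
        logger.info("enrichment_score: %d signature genes not in ranked list, dropped",
                    len(dropped))
    if not present:
        raise ValueError("signature has no genes in the ranked list")
    hit = np.isin(genes, list(present)).astype(float)
    n_hits = int(hit.sum())
    es = _running_sum_extremum(metric, hit, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = len(genes)
    for i in range(n_perm):
        perm_hit = np.zeros(n)
        perm_hit[rng.choice(n, size=n_hits, replace=False)] = 1.0
        null[i] = _running_sum_extremum(metric, perm_hit, weight)

    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same_sign):
        p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + len(same_sign))
        mean_null = np.abs(same_sign).mean()
        nes = es / mean_null if mean_null > 0 else np.sign(es) * np.inf
    else:
        p, nes = 1.0 / (1 + n_perm), np.sign(es) * np.inf
    fdr = float(benjamini_hochberg([p])[0])
    return EnrichmentResult(es, float(nes), float(p), fdr, n_perm, seed,
                            n_hits, int(len(same_sign)))
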
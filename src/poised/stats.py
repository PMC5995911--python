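"""Small statistical procedures used across the analysis and its reporting.

Comparative-CT relative expression, the two-sample tests used for occupancy
and expression comparisons, Benjamini–Hochberg adjustment, and quantile
categorization of alkaline-phosphatase (AP) staining intensities.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CtMeasurement",
    "IntensityRecord",
    "comparative_ct",
    "t_test_unpaired",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "ap_categorize",
]


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR measurement: target and reference (Actb-role) cycle thresholds."""

    sample_id: str
    target_ct: float
    reference_ct: float
    group: str = "test"  # "test" or "calibrator"

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class IntensityRecord:
    """AP staining intensity of one colony."""

    colony_id: str
    field_id: str
    intensity: float
    sample: str

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


def comparative_ct(test: CtMeasurement, calibrator: CtMeasurement) -> float:
    """Relative expression by the comparative CT (2^-ddCt) method.

    dCt = Ct_target - Ct_reference within each sample; ddCt = dCt_test -
    dCt_calibrator; returns 2^-ddCt, so the calibrator itself maps to 1.
    Assumes ideal (2-fold per cycle) amplification efficiency.
    """
    d_test = test.target_ct - test.reference_ct
    d_cal = calibrator.target_ct - calibrator.reference_ct
    return float(2.0 ** (-(d_test - d_cal)))


def t_test_unpaired(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-tailed unpaired t test; pooled-variance Student form by default.

    ``equal_var=False`` gives the Welch form.  Degenerate case: when both
    samples have zero variance and equal means the test is uninformative and
    returns ``(0.0, 1.0)``; zero variance with unequal means returns
    ``(±inf, 0.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    with warnings.catch_warnings():
        # near-identical samples trigger a precision warning; the degenerate
        # exact-equality cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _rank_sum_exact_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided permutation p for the rank sum of the first ``n_a`` ranks.

    Enumerates all C(n, n_a) assignments of the (mid)ranks to group A and
    counts those whose rank sum is at least as far from its null mean as the
    observed one.  Valid with ties because midranks are permuted as-is.
    """
    n = len(ranks)
    w_obs = ranks[:n_a].sum()
    mu = ranks.sum() * n_a / n
    d_obs = abs(w_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-tailed unpaired Wilcoxon (Mann–Whitney) rank-sum test.

    Returns ``(U, p)`` where ``U`` is the Mann–Whitney statistic of sample
    ``a``.  Ties get midranks.  For combined ``n <= exact_max_n`` the p-value
    is an exact permutation enumeration over all rank assignments; above
    that, a normal approximation with tie correction and continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)  # midranks for ties
    w_a = ranks[:n_a].sum()
    u = w_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= exact_max_n:
        p = _rank_sum_exact_p(ranks, n_a)
        return float(u), float(p)

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:  # all values identical
        return float(u), 1.0
    d = abs(u - mu)
    z = max(d - 0.5, 0.0) / math.sqrt(sigma2)  # continuity correction
    p = 2.0 * sps.norm.sf(z)
    return float(u), float(min(p, 1.0))


def benjamini_hochberg(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ap_categorize(
    control: Sequence[float] | Sequence[IntensityRecord],
    samples: Mapping[str, Sequence[float] | Sequence[IntensityRecord]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorize colony staining intensities against control-derived cutoffs.

    The control sample defines the scale: its bottom 10% of intensities are
    "low", the next 30% "intermediate", and the top 60% "high".  Cutoffs are
    therefore the control's 10th and 40th percentiles (linear-interpolation
    quantiles) and are applied unchanged to every sample.  Boundary values
    fall into the lower category (``<=``).

    Returns ``(per_colony, fractions)``: one row per colony with its
    category, and per-sample stacked fractions of low/intermediate/high.
    """
    ctrl = _intensities(control)
    if len(ctrl) == 0:
        raise ValueError("control sample must be non-empty")
    q10, q40 = np.quantile(ctrl, [0.10, 0.40])  # linear interpolation

    rows = []
    for sample_name, values in samples.items():
        for i, v in enumerate(_intensities(values)):
            if v <= q10:
                cat = "low"
            elif v <= q40:
                cat = "intermediate"
            else:
                cat = "high"
            rows.append((sample_name, i, float(v), cat))
    per_colony = pd.DataFrame(rows, columns=["sample", "colony", "intensity", "category"])
    fractions = (
        per_colony.groupby("sample")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["low", "intermediate", "high"], fill_value=0.0)
    )
    fractions.attrs["cutoffs"] = (float(q10), float(q40))
    return per_colony, fractions


def _intensities(values) -> np.ndarray:
    vals = [v.intensity if isinstance(v, IntensityRecord) else float(v) for v in values]
    arr = np.asarray(vals, dtype=float)
    if len(arr) and (arr < 0).any():
        raise ValueError("intensities must be >= 0")
    return arr
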
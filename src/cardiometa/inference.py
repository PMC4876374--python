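"""Cohort-level inference: paired contrasts, correlations, dependent-correlation
comparison, and rank-based group tests.

The dependent-correlation comparison is Williams' t (as recommended by Steiger,
1980) for two correlations that share one variable in the same sample — the
statistic behind the common online calculators for this test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("cardiometa")

__all__ = [
    "PairedContrast",
    "DependentCorrTest",
    "paired_t",
    "correlate",
    "steiger_test",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class PairedContrast:
    """Paired t test with Cohen's d = mean(diff) / sd(diff)."""

    n: int
    mean_x: float
    mean_y: float
    t: float
    p: float
    cohens_d: float
    degenerate: bool = False


@dataclass(frozen=True)
class DependentCorrTest:
    """Williams/Steiger t for two dependent correlations sharing variable 1."""

    r12: float
    r13: float
    r23: float
    n: int
    t: float
    p: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedContrast:
    """Classical paired t (df = n-1) with Cohen's d from the difference scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedContrast(
            n=n, mean_x=float(x.mean()), mean_y=float(y.mean()),
            t=0.0 if d.mean() == 0 else math.inf, p=float(d.mean() == 0),
            cohens_d=0.0 if d.mean() == 0 else math.inf, degenerate=True,
        )
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return PairedContrast(
        n=n, mean_x=float(x.mean()), mean_y=float(y.mean()),
        t=t, p=p, cohens_d=float(d.mean() / sd),
    )


def correlate(
    a: Sequence[float], b: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("a and b must have equal length")
    if a.size < 4:
        raise ValueError("need at least 4 observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def steiger_test(r12: float, r13: float, r23: float, n: int) -> DependentCorrTest:
    """Compare two dependent correlations r12 vs r13 sharing variable 1.

    Williams' t with df = n - 3, two-sided p; antisymmetric in (r12, r13) and
    exactly zero when they are equal.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError(
            f"correlation triple (r12={r12}, r13={r13}, r23={r23}) is not "
            "positive definite"
        )
    rbar = 0.5 * (r12 + r13)
    num = (r12 - r13) * math.sqrt((n - 1) * (1 + r23))
    den = math.sqrt(
        2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    )
    t = num / den
    p = float(2 * stats.t.sf(abs(t), n - 3))
    return DependentCorrTest(r12=r12, r13=r13, r23=r23, n=n, t=float(t), p=p)


def kruskal_wallis(
    values_by_group: Mapping[object, Sequence[float]]
) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction; returns (H, df, p).

    Empty groups are dropped with a warning.
    """
    groups = []
    for label, vals in values_by_group.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            logger.warning("group %s is empty; dropped from Kruskal-Wallis", label)
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):  # scipy raises on all-identical data
        return 0.0, df, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), df, float(p)
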
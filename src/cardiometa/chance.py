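"""Exact binomial chance model and three-way subject classification.

Subjects answering a balanced two-alternative forced-choice task are classified
against an exact Binomial(n, 1/2) chance model: SELF if they score at or above
the smallest count whose point probability drops to the significance level,
OTHER if at or below its mirror image, NON_DISCRIMINATOR otherwise.  For the
study design (n = 30, alpha = .05) the bounds are 20 and 10 correct trials.

Group-frequency distributions are compared with chi-square goodness-of-fit
tests, with Cohen's omega = sqrt(chi2 / N) as the effect size.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger("cardiometa")

__all__ = [
    "GroupLabel",
    "ChanceModel",
    "GofResult",
    "binom_pmf",
    "build_chance_model",
    "classify_subject",
    "gof_chi2",
    "posthoc_pairwise",
]


class GroupLabel(enum.Enum):
    SELF = "SELF"
    NON_DISCRIMINATOR = "NON_DISCRIMINATOR"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ChanceModel:
    """Binomial chance model with two-sided classification bounds.

    ``k_upper`` is the smallest correct-count significantly above chance,
    ``k_lower`` the largest significantly below; at p0 = 1/2 they satisfy
    ``k_upper + k_lower = n`` by symmetry.
    """

    n: int
    p0: float
    k_upper: int
    k_lower: int
    alpha: float


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit result with Cohen's omega effect size."""

    chi2: float
    df: int
    p: float
    omega: float
    N: int
    labels: tuple[str, ...] = ()


def binom_pmf(k: int, n: int, p: float = 0.5) -> float:
    """Exact binomial point probability C(n,k) p^k (1-p)^(n-k).

    Computed through log-gamma for numerical stability at large n.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range [0, {n}]")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p={p} must lie strictly inside (0, 1)")
    # group the symmetric gammaln terms so pmf(k, n, 1/2) == pmf(n-k, n, 1/2)
    # holds exactly in floating point
    log_coeff = gammaln(n + 1) - (gammaln(k + 1) + gammaln(n - k + 1))
    if p == 0.5:
        log_kernel = n * math.log(0.5)
    else:
        log_kernel = k * math.log(p) + (n - k) * math.log1p(-p)
    return float(np.exp(log_coeff + log_kernel))


def build_chance_model(n: int, p0: float = 0.5, alpha: float = 0.05) -> ChanceModel:
    """Find the classification bounds of the Binomial(n, p0) chance model.

    ``k_upper`` is the smallest k above the chance expectation n*p0 whose point
    probability is <= alpha; ``k_lower`` mirrors it (n - k_upper at p0 = 1/2,
    otherwise the largest k below expectation with pmf <= alpha).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k_upper = None
    for k in range(int(math.floor(n * p0)) + 1, n + 1):
        if k > n * p0 and binom_pmf(k, n, p0) <= alpha:
            k_upper = k
            break
    if k_upper is None:
        raise ValueError(
            f"no count in 0..{n} is significant at alpha={alpha}; "
            "increase n or alpha"
        )
    if p0 == 0.5:
        k_lower = n - k_upper
    else:
        k_lower = -1
        for k in range(int(math.ceil(n * p0)) - 1, -1, -1):
            if k < n * p0 and binom_pmf(k, n, p0) <= alpha:
                k_lower = k
                break
        if k_lower < 0:
            raise ValueError(
                f"no below-chance count is significant at alpha={alpha}"
            )
    return ChanceModel(n=n, p0=p0, k_upper=k_upper, k_lower=k_lower, alpha=alpha)


def classify_subject(n_correct: int, model: ChanceModel) -> GroupLabel:
    """Assign SELF / NON_DISCRIMINATOR / OTHER from a correct-trial count.

    The three labels partition 0..n into contiguous bands; classification is
    monotone in ``n_correct``.
    """
    if not 0 <= n_correct <= model.n:
        raise ValueError(f"n_correct={n_correct} out of range [0, {model.n}]")
    if n_correct >= model.k_upper:
        return GroupLabel.SELF
    if n_correct <= model.k_lower:
        return GroupLabel.OTHER
    return GroupLabel.NON_DISCRIMINATOR


def gof_chi2(
    observed: Sequence[float],
    expected: Sequence[float] | str = "equal",
    labels: Sequence[str] = (),
) -> GofResult:
    """Pearson chi-square goodness-of-fit with Cohen's omega = sqrt(chi2/N)."""
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 cells")
    N = float(obs.sum())
    if isinstance(expected, str):
        if expected != "equal":
            raise ValueError(f"unknown expected spec {expected!r}")
        exp = np.full(obs.size, N / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.size != obs.size:
            raise ValueError("observed and expected differ in length")
        # rescale expected counts to the observed total
        exp = exp * (N / exp.sum())
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be > 0")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    omega = math.sqrt(chi2 / N)
    return GofResult(chi2=chi2, df=df, p=p, omega=omega, N=int(round(N)),
                     labels=tuple(labels))


def posthoc_pairwise(counts_by_group: Mapping[object, int]) -> list[GofResult]:
    """Two-cell equal-expected chi-square for every unordered group pair.

    No multiple-testing adjustment is applied. Pairs with zero total count are
    skipped with a warning.
    """
    items = list(counts_by_group.items())
    if len(items) < 2:
        raise ValueError("need at least 2 groups")
    results = []
    for (la, ca), (lb, cb) in itertools.combinations(items, 2):
        if ca + cb == 0:
            logger.warning("pair (%s, %s) has zero total count; skipped", la, lb)
            continue
        name_a = la.value if isinstance(la, GroupLabel) else str(la)
        name_b = lb.value if isinstance(lb, GroupLabel) else str(lb)
        results.append(gof_chi2([ca, cb], "equal", labels=(name_a, name_b)))
    return results
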
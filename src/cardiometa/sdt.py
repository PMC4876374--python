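"""Type-1 and type-2 signal detection: d', criterion, and meta-d' by SSE fit.

Type-1 model
------------
The forced-choice decision is modelled as an equal-variance Gaussian observer:
the decision variable is Normal(+d'/2, 1) on own-heart trials and
Normal(-d'/2, 1) on other-heart trials, and the subject answers "self" when it
exceeds the criterion c.  Sensitivity is d' = z(HR) - z(FAR) and the criterion
c = -(z(HR) + z(FAR))/2, with a rate correction (log-linear by default) keeping
rates strictly inside (0, 1).

Type-2 model (meta-d')
----------------------
Confidence ratings are reduced to K ordered levels and cross-tabulated by
response side and stimulus truth.  meta-d' is the type-1 sensitivity that an
SDT-ideal metacognitive observer would need in order to produce the observed
confidence data: under a candidate meta-d', with the type-1 criterion locked at
the subject's *relative* criterion (meta-c = c/d' * meta-d') and K-1 ordered
type-2 criteria on each response side, the model's conditional probabilities of
high confidence given (stimulus, response) are truncated-normal tail ratios.
The fit minimizes the sum of squared differences between observed and model
cumulative type-2 hit/false-alarm rates over meta-d' and the criteria, using a
derivative-free simplex search with random restarts, criterion monotonicity
being enforced by optimizing log-increments.  meta-d' = d' is metacognitively
optimal; meta-d' < d' indicates confidence carries less information than the
decision itself.  M-ratio = meta-d'/d' is the normalized efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from .io_model import RateCorrection, Response, Stimulus, TrialRecord

logger = logging.getLogger("cardiometa")

__all__ = [
    "Type1Stats",
    "RatingScheme",
    "Type2Counts",
    "MetaFit",
    "FitError",
    "type1_stats",
    "bin_confidence",
    "type2_counts",
    "fit_meta_d",
    "meta_contrast",
]

META_D_BOUND = 5.0


class FitError(RuntimeError):
    """meta-d' optimization failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, best: "MetaFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class Type1Stats:
    """First-order performance: counts, corrected rates, d', criterion."""

    n_signal: int
    n_noise: int
    hits: int
    false_alarms: int
    HR: float
    FAR: float
    d_prime: float
    c: float

    @property
    def c_rel(self) -> float:
        """Relative criterion c' = c / d' (undefined at d' = 0)."""
        if self.d_prime == 0:
            raise ZeroDivisionError("c_rel undefined when d' = 0")
        return self.c / self.d_prime


@dataclass(frozen=True)
class RatingScheme:
    """K ordered confidence levels defined by K-1 strictly increasing cut points."""

    K: int
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != self.K - 1:
            raise ValueError("need K-1 edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    def level_of(self, confidence: float) -> int:
        """Map a confidence in [0, 100] to a level 1..K (boundaries go low)."""
        return int(np.searchsorted(self.edges, confidence, side="left")) + 1


@dataclass(frozen=True)
class Type2Counts:
    """Confidence-level counts per response side x stimulus truth.

    Each array has shape (2, K): row 0 is own-heart stimuli, row 1 other-heart.
    ``padded`` flags response sides where the 1/(2K) zero-cell padding was
    applied (a side containing any empty cell gets the constant added to every
    one of its cells, keeping cumulative rates inside (0, 1)).
    """

    says_self: np.ndarray
    says_other: np.ndarray
    K: int
    padded: tuple[bool, bool] = (False, False)

    @property
    def n_trials(self) -> float:
        return float(self.says_self.sum() + self.says_other.sum())


@dataclass(frozen=True)
class MetaFit:
    """Result of the meta-d' sum-square-error fit."""

    meta_d: float
    meta_c: float
    t2_criteria_self: tuple[float, ...]
    t2_criteria_other: tuple[float, ...]
    sse: float
    m_ratio: float
    converged: bool
    n_restarts_used: int


def type1_stats(
    trials: Sequence[TrialRecord],
    correction: RateCorrection = RateCorrection.LOGLIN,
) -> Type1Stats:
    """Hit/false-alarm counts and corrected-rate d' and criterion.

    Own-heart stimuli are "signal": a hit is answering "self" to one's own
    heart, a false alarm answering "self" to the other heart.
    """
    n_signal = sum(t.stimulus is Stimulus.SELF_HEART for t in trials)
    n_noise = len(trials) - n_signal
    if n_signal == 0 or n_noise == 0:
        raise ValueError("both stimulus classes must be present")
    hits = sum(
        t.stimulus is Stimulus.SELF_HEART and t.response is Response.SAYS_SELF
        for t in trials
    )
    fas = sum(
        t.stimulus is Stimulus.OTHER_HEART and t.response is Response.SAYS_SELF
        for t in trials
    )
    if correction is RateCorrection.LOGLIN:
        HR = (hits + 0.5) / (n_signal + 1)
        FAR = (fas + 0.5) / (n_noise + 1)
    elif correction is RateCorrection.HALF_COUNT:
        HR = hits / n_signal
        FAR = fas / n_noise
        HR = min(max(HR, 1 / (2 * n_signal)), 1 - 1 / (2 * n_signal))
        FAR = min(max(FAR, 1 / (2 * n_noise)), 1 - 1 / (2 * n_noise))
    elif correction is RateCorrection.NONE:
        HR = hits / n_signal
        FAR = fas / n_noise
        if HR in (0.0, 1.0) or FAR in (0.0, 1.0):
            raise ValueError(
                "extreme rate with correction=NONE; choose LOGLIN or HALF_COUNT"
            )
    else:  # pragma: no cover
        raise ValueError(correction)
    zH, zF = ndtri(HR), ndtri(FAR)
    return Type1Stats(
        n_signal=n_signal,
        n_noise=n_noise,
        hits=hits,
        false_alarms=fas,
        HR=HR,
        FAR=FAR,
        d_prime=float(zH - zF),
        c=float(-0.5 * (zH + zF)),
    )


def bin_confidence(
    trials: Sequence[TrialRecord], K: int = 4
) -> tuple[RatingScheme, list[tuple[TrialRecord, int]]]:
    """Reduce continuous 0-100 confidence to K levels by within-subject quantiles.

    Edges sit at the j/K empirical quantiles; a confidence equal to an edge is
    assigned to the lower level. Deterministic given the data.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    conf = np.array([t.confidence for t in trials], dtype=float)
    if np.unique(conf).size < K:
        raise ValueError(
            f"only {np.unique(conf).size} distinct confidence values; "
            f"cannot form K={K} levels — use a smaller K"
        )
    edges = np.quantile(conf, [j / K for j in range(1, K)])
    # collapse ties between quantiles by nudging into a strictly increasing grid
    for i in range(1, len(edges)):
        if edges[i] <= edges[i - 1]:
            edges[i] = np.nextafter(edges[i - 1], np.inf)
    scheme = RatingScheme(K=K, edges=tuple(float(e) for e in edges))
    return scheme, [(t, scheme.level_of(t.confidence)) for t in trials]


def type2_counts(
    binned: Sequence[tuple[TrialRecord, int]], K: int | None = None
) -> Type2Counts:
    """Cross-tabulate confidence levels by response side and stimulus truth.

    ``K`` defaults to the largest level present; pass the rating scheme's K
    explicitly when the top level might be unused.
    """
    if not binned:
        raise ValueError("no trials")
    if K is None:
        K = max(level for _, level in binned)
    K = max(K, 2)
    tables = {
        Response.SAYS_SELF: np.zeros((2, K)),
        Response.SAYS_OTHER: np.zeros((2, K)),
    }
    for t, level in binned:
        row = 0 if t.stimulus is Stimulus.SELF_HEART else 1
        tables[t.response][row, level - 1] += 1
    padded = []
    for resp in (Response.SAYS_SELF, Response.SAYS_OTHER):
        need = bool((tables[resp] == 0).any())
        if need:
            tables[resp] = tables[resp] + 1.0 / (2 * K)
            logger.debug("zero-cell padding applied to %s side", resp.name)
        padded.append(need)
    return Type2Counts(
        says_self=tables[Response.SAYS_SELF],
        says_other=tables[Response.SAYS_OTHER],
        K=K,
        padded=tuple(padded),
    )


def _observed_type2_rates(counts: Type2Counts) -> np.ndarray:
    """Observed cumulative P(conf >= level j+1 | stimulus, response).

    Returns shape (4, K-1): rows are (self-resp/self-stim, self-resp/other-stim,
    other-resp/other-stim, other-resp/self-stim) — i.e. type-2 HR then FAR for
    each response side.
    """
    K = counts.K
    rows = []
    for table, correct_row in ((counts.says_self, 0), (counts.says_other, 1)):
        for row in (correct_row, 1 - correct_row):
            cell = table[row]
            total = cell.sum()
            # reversed cumulative sums: P(level >= j+1) for j = 1..K-1
            tail = np.cumsum(cell[::-1])[::-1]
            rows.append(tail[1:] / total)
    return np.vstack(rows)


def _model_type2_rates(
    meta_d: float, meta_c: float, crit_self: np.ndarray, crit_other: np.ndarray
) -> np.ndarray:
    """Model cumulative type-2 rates, same layout as ``_observed_type2_rates``.

    Truncated-normal tail ratios under the equal-variance observer with
    stimulus means +/- meta_d/2 and type-1 criterion meta_c.
    """
    mu_self, mu_other = meta_d / 2.0, -meta_d / 2.0
    eps = 1e-12
    out = []
    for mu in (mu_self, mu_other):  # SAYS_SELF side: HR row then FAR row
        denom = max(1.0 - ndtr(meta_c - mu), eps)
        out.append((1.0 - ndtr(crit_self - mu)) / denom)
    for mu in (mu_other, mu_self):  # SAYS_OTHER side
        denom = max(ndtr(meta_c - mu), eps)
        out.append(ndtr(crit_other - mu) / denom)
    return np.vstack(out)


def _unpack_params(theta: np.ndarray, c_rel: float, K: int):
    meta_d = float(np.clip(theta[0], -META_D_BOUND, META_D_BOUND))
    meta_c = c_rel * meta_d
    inc = np.exp(np.clip(theta[1:], -20.0, 5.0))
    crit_self = meta_c + np.cumsum(inc[: K - 1])
    crit_other = meta_c - np.cumsum(inc[K - 1 :])
    return meta_d, meta_c, crit_self, crit_other


def _sse_objective(theta: np.ndarray, observed: np.ndarray, c_rel: float, K: int) -> float:
    meta_d, meta_c, crit_self, crit_other = _unpack_params(theta, c_rel, K)
    model = _model_type2_rates(meta_d, meta_c, crit_self, crit_other)
    return float(((observed - model) ** 2).sum())


def fit_meta_d(
    counts: Type2Counts,
    t1: Type1Stats,
    n_restarts: int = 8,
    seed: int | None = 0,
    tol: float = 1e-6,
) -> MetaFit:
    """Estimate meta-d' by minimizing the sum of squared rate differences.

    The type-1 criterion of the metacognitive observer is locked to the
    subject's relative criterion (meta_c = c/d' * meta_d), so meta-d' stays on
    the d' scale; the 2(K-1) type-2 criteria are free up to their ordering
    constraint.  Multiple Nelder-Mead restarts guard against ridges in the SSE
    surface; raises :class:`FitError` (with best-so-far diagnostics) if no
    restart converges.
    """
    if t1.d_prime == 0:
        raise ValueError("|d'| must be > 0 to anchor the relative criterion")
    K = counts.K
    observed = _observed_type2_rates(counts)
    c_rel = t1.c_rel
    rng = np.random.default_rng(seed)

    best: optimize.OptimizeResult | None = None
    any_converged = False
    n_params = 1 + 2 * (K - 1)
    for restart in range(n_restarts):
        theta0 = np.empty(n_params)
        if restart == 0:
            theta0[0] = np.clip(t1.d_prime, -META_D_BOUND, META_D_BOUND)
            theta0[1:] = np.log(0.5)
        else:
            theta0[0] = np.clip(
                t1.d_prime + rng.normal(scale=1.0), -META_D_BOUND, META_D_BOUND
            )
            theta0[1:] = np.log(0.5) + rng.normal(scale=0.7, size=n_params - 1)
        res = optimize.minimize(
            _sse_objective,
            theta0,
            args=(observed, c_rel, K),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 4000, "maxfev": 4000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < tol and any_converged:
            break

    meta_d, meta_c, crit_self, crit_other = _unpack_params(best.x, c_rel, K)
    fit = MetaFit(
        meta_d=meta_d,
        meta_c=meta_c,
        t2_criteria_self=tuple(float(x) for x in crit_self),
        t2_criteria_other=tuple(float(x) for x in crit_other),
        sse=float(best.fun),
        m_ratio=meta_d / t1.d_prime,
        converged=any_converged,
        n_restarts_used=restart + 1,
    )
    if not any_converged:
        raise FitError(
            f"meta-d' fit did not converge after {n_restarts} restarts "
            f"(best SSE {best.fun:.3g})",
            best=fit,
        )
    return fit


def meta_contrast(t1: Type1Stats, fit: MetaFit) -> dict:
    """meta-d' - d' difference and M-ratio; flags the degenerate d' = 0 case."""
    if t1.d_prime == 0:
        return {"diff": fit.meta_d, "m_ratio": None, "degenerate": True}
    return {
        "diff": fit.meta_d - t1.d_prime,
        "m_ratio": fit.meta_d / t1.d_prime,
        "degenerate": False,
    }
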
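"""Generative models for trial-level datasets with the structure the analysis
assumes, plus deterministic fixtures reproducing the published group counts.

The trial generator is an equal-variance Gaussian SDT observer: on each of 30
trials (15 own-heart, 15 other-heart) a decision variable x ~ Normal(+-d'/2, 1)
is compared against the criterion c; the type-2 (confidence) evidence is
x2 = x + Normal(0, sigma_meta), so sigma_meta = 0 is a metacognitively ideal
observer (meta-d' = d' in the large-sample limit) and larger sigma_meta
degrades confidence resolution without touching first-order accuracy.
Confidence is a deterministic monotone squashing of |x2 - c| onto the 0-100
visual-analogue scale.

The heartbeat-counting generator draws a per-subject counting error rate and
produces counted = round(recorded * (1 - e)) per interval, keeping the
tracking index in [0, 1] by construction.  In cohorts the counting score is
coupled to metacognitive efficiency through a Gaussian copula so that
recovery of the published metacognition-interoception correlation can be
tested against latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_model import (
    CountingRecord,
    Response,
    Stimulus,
    SubjectDataset,
    TaskTag,
    TrialRecord,
)

__all__ = [
    "SimConfig",
    "CohortHeterogeneity",
    "simulate_subject",
    "simulate_cohort",
    "make_table1_cohort",
    "make_control_cohort",
]

COUNTING_INTERVALS_S = (25.0, 35.0, 45.0, 100.0)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for a simulated observer / cohort.

    Defaults mirror the study conditions: 30 trials split 15/15 between
    own- and other-heart stimuli, cohort-level sensitivity around d' = 0.8,
    counting accuracy around 0.75, and a 0.4 coupling between metacognitive
    efficiency and counting accuracy.
    """

    n_subjects: int = 27
    n_trials: int = 30
    d_prime_gen: float = 0.8
    c_gen: float = 0.0
    sigma_meta: float = 1.0
    conf_scale: float = 1.0
    iacc_mean: float = 0.75
    iacc_sd: float = 0.17
    rho_meta_iacc: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_meta < 0:
            raise ValueError("sigma_meta must be >= 0")
        if not -1.0 <= self.rho_meta_iacc <= 1.0:
            raise ValueError("rho_meta_iacc must lie in [-1, 1]")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even (balanced 50/50 design)")
        if self.n_trials < 2 or self.n_subjects < 1:
            raise ValueError("need n_trials >= 2 and n_subjects >= 1")


@dataclass(frozen=True)
class CohortHeterogeneity:
    """Between-subject spread of the latent observer parameters."""

    d_prime_sd: float = 0.35
    d_prime_min: float = 0.05
    c_sd: float = 0.3
    sigma_meta_spread: float = 0.6  # log-scale spread driven by the efficiency latent


def _confidence_from_evidence(x2: np.ndarray, c: float, scale: float) -> np.ndarray:
    """Monotone squashing of type-2 evidence distance onto the 0-100 VAS."""
    return 100.0 * (2.0 * ndtr(scale * np.abs(x2 - c)) - 1.0)


def simulate_subject(
    cfg: SimConfig,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "sim01",
    d_prime: float | None = None,
    c: float | None = None,
    sigma_meta: float | None = None,
    iacc: float | None = None,
    with_counting: bool = True,
    task_tag: TaskTag = TaskTag.HEART_SOUND,
) -> SubjectDataset:
    """Simulate one observer's trial (and optionally counting) records.

    Per-subject parameter overrides fall back to the config values; the
    output is reproducible given ``subject_seed``.
    """
    rng = np.random.default_rng(subject_seed)
    d = cfg.d_prime_gen if d_prime is None else d_prime
    crit = cfg.c_gen if c is None else c
    sm = cfg.sigma_meta if sigma_meta is None else sigma_meta

    half = cfg.n_trials // 2
    stimuli = np.array([1] * half + [-1] * half)  # +1 own heart, -1 other
    rng.shuffle(stimuli)
    x = rng.normal(loc=stimuli * d / 2.0, scale=1.0)
    says_self = x > crit
    x2 = x + rng.normal(scale=sm, size=cfg.n_trials) if sm > 0 else x
    conf = _confidence_from_evidence(x2, crit, cfg.conf_scale)

    trials = [
        TrialRecord(
            subject_id=subject_id,
            trial_index=i + 1,
            stimulus=Stimulus.SELF_HEART if stimuli[i] == 1 else Stimulus.OTHER_HEART,
            response=Response.SAYS_SELF if says_self[i] else Response.SAYS_OTHER,
            confidence=float(conf[i]),
        )
        for i in range(cfg.n_trials)
    ]

    counting: list[CountingRecord] = []
    if with_counting:
        target = cfg.iacc_mean if iacc is None else iacc
        target = float(np.clip(target, 0.0, 1.0))
        hr_bpm = rng.normal(70.0, 8.0)
        for interval in COUNTING_INTERVALS_S:
            recorded = max(1, int(round(hr_bpm / 60.0 * interval)))
            counted = int(round(recorded * target))
            counting.append(
                CountingRecord(
                    subject_id=subject_id,
                    interval_s=interval,
                    counted=counted,
                    recorded=recorded,
                )
            )
    return SubjectDataset(subject_id, trials, counting, task_tag=task_tag)


def simulate_cohort(
    cfg: SimConfig,
    heterogeneity: CohortHeterogeneity | None = None,
) -> tuple[list[SubjectDataset], pd.DataFrame]:
    """Simulate a cohort with between-subject heterogeneity and latent truth.

    Per subject, (d', c) are drawn from truncated/plain normals around the
    config values; a standard-normal efficiency latent z_eff scales the
    metacognitive noise multiplicatively (sigma_i = sigma_meta *
    exp(-spread * z_eff)), and the counting score shares a Gaussian copula
    with z_eff at correlation ``rho_meta_iacc``.  Returns the datasets and a
    per-subject latent-truth table for recovery tests.
    """
    het = heterogeneity or CohortHeterogeneity()
    root = np.random.SeedSequence(cfg.seed)
    latent_ss, *subject_ss = root.spawn(cfg.n_subjects + 1)
    rng = np.random.default_rng(latent_ss)

    n = cfg.n_subjects
    d = cfg.d_prime_gen + het.d_prime_sd * rng.standard_normal(n)
    d = np.maximum(d, het.d_prime_min)
    c = cfg.c_gen + het.c_sd * rng.standard_normal(n)
    z_eff = rng.standard_normal(n)
    z_ind = rng.standard_normal(n)
    rho = cfg.rho_meta_iacc
    z_iacc = rho * z_eff + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
    iacc = np.clip(cfg.iacc_mean + cfg.iacc_sd * z_iacc, 0.0, 1.0)
    if cfg.sigma_meta > 0:
        sigma = cfg.sigma_meta * np.exp(-het.sigma_meta_spread * z_eff)
    else:
        sigma = np.zeros(n)

    datasets = []
    rows = []
    for i in range(n):
        sid = f"sim{i + 1:03d}"
        datasets.append(
            simulate_subject(
                cfg,
                subject_ss[i],
                subject_id=sid,
                d_prime=float(d[i]),
                c=float(c[i]),
                sigma_meta=float(sigma[i]),
                iacc=float(iacc[i]),
            )
        )
        rows.append(
            {
                "subject_id": sid,
                "d_prime": float(d[i]),
                "c": float(c[i]),
                "sigma_meta": float(sigma[i]),
                "z_eff": float(z_eff[i]),
                "iacc": float(iacc[i]),
            }
        )
    return datasets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic fixtures reproducing the published group counts


def _fixture_subject(
    subject_id: str, subj_idx: int, n_correct: int, task_tag: TaskTag
) -> SubjectDataset:
    """One deterministic 30-trial subject with exactly ``n_correct`` correct.

    Correct trials are split as evenly as possible across the two stimulus
    classes so the type-1 table is never degenerate; confidences follow a
    fixed 30-value lattice (plenty of distinct values for quantile binning).
    """
    n_trials, half = 30, 15
    correct_self = min(half, (n_correct + 1) // 2)
    correct_other = n_correct - correct_self
    if correct_other > half:  # rebalance when n_correct > 15 + 15
        correct_self += correct_other - half
        correct_other = half
    trials = []
    for i in range(n_trials):
        is_self = i % 2 == 0  # alternate stimulus classes
        within = i // 2  # 0..14 within the class
        correct = within < (correct_self if is_self else correct_other)
        stim = Stimulus.SELF_HEART if is_self else Stimulus.OTHER_HEART
        match = Response.SAYS_SELF if is_self else Response.SAYS_OTHER
        flip = Response.SAYS_OTHER if is_self else Response.SAYS_SELF
        conf = 5.0 + 3.0 * ((i * 7 + subj_idx * 11) % 30)  # fixed lattice in [5, 92]
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=i + 1,
                stimulus=stim,
                response=match if correct else flip,
                confidence=conf,
            )
        )
    return SubjectDataset(subject_id, trials, task_tag=task_tag)


def make_table1_cohort() -> list[SubjectDataset]:
    """27 deterministic heart-sound subjects realizing group counts (17, 7, 3).

    17 subjects score 23/30 (above-chance SELF), 7 score 15/30 (chance),
    3 score 7/30 (below-chance OTHER).
    """
    counts = [23] * 17 + [15] * 7 + [7] * 3
    return [
        _fixture_subject(f"hb{i + 1:02d}", i, k, TaskTag.HEART_SOUND)
        for i, k in enumerate(counts)
    ]


def make_control_cohort() -> list[SubjectDataset]:
    """16 deterministic beep-control subjects realizing group counts (3, 11, 2).

    3 subjects score 26/30, 11 score 15/30, 2 score 4/30.
    """
    counts = [26] * 3 + [15] * 11 + [4] * 2
    return [
        _fixture_subject(f"bp{i + 1:02d}", i, k, TaskTag.BEEP_CONTROL)
        for i, k in enumerate(counts)
    ]
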
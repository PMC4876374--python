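"""End-to-end orchestration: read -> classify -> IAcc -> SDT/meta-d' -> inference.

``run_pipeline`` is the single entry point reproducing the study's result
tables on any conforming dataset; ``analyze_cohort`` is the same computation
over in-memory datasets.  The output is a plain nested dict (JSON-ready via
:func:`cardiometa.io_model.write_report`): per-subject metrics, the group
table with counts and percentages, omnibus and post-hoc chi-squares, the
d' vs meta-d' paired contrast, correlations with counting accuracy, the
dependent-correlation comparison, and Kruskal-Wallis group comparisons.

Stages are independent: without a counting file the interoception metrics and
their correlations are simply omitted, everything else is computed.
"""

from __future__ import annotations

import logging
import time
import zlib
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .chance import (
    GroupLabel,
    build_chance_model,
    classify_subject,
    gof_chi2,
    posthoc_pairwise,
)
from .inference import correlate, kruskal_wallis, paired_t, steiger_test
from .interoception import schandry_index
from .io_model import (
    AnalysisConfig,
    CountingRecord,
    SubjectDataset,
    TaskTag,
    read_counting,
    read_trials,
)
from .sdt import FitError, bin_confidence, fit_meta_d, type1_stats, type2_counts

logger = logging.getLogger("cardiometa")

__all__ = ["run_pipeline", "analyze_cohort", "PipelineError"]

_GROUP_ORDER = (GroupLabel.SELF, GroupLabel.NON_DISCRIMINATOR, GroupLabel.OTHER)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""


def _subject_seed(base_seed: int, subject_id: str) -> np.random.SeedSequence:
    # stable per-subject seed: independent of cohort order and composition
    digest = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.SeedSequence(entropy=(base_seed, digest))


def _subject_metrics(ds: SubjectDataset, cfg: AnalysisConfig, models) -> dict:
    if ds.n_trials != cfg.n_trials_expected:
        logger.warning(
            "subject %s has %d trials (expected %d); chance model uses the "
            "actual count",
            ds.subject_id, ds.n_trials, cfg.n_trials_expected,
        )
    if ds.n_trials not in models:
        models[ds.n_trials] = build_chance_model(ds.n_trials, 0.5, cfg.alpha_chance)
    model = models[ds.n_trials]
    row: dict = {
        "subject_id": ds.subject_id,
        "n_trials": ds.n_trials,
        "n_correct": ds.n_correct,
        "accuracy": ds.accuracy,
        "mean_confidence": float(np.mean([t.confidence for t in ds.trials])),
        "group": classify_subject(ds.n_correct, model).value,
    }
    try:
        t1 = type1_stats(ds.trials, cfg.rate_correction)
    except ValueError as e:
        raise PipelineError(f"sdt stage, subject {ds.subject_id}: {e}") from e
    row.update(d_prime=t1.d_prime, c=t1.c, hits=t1.hits,
               false_alarms=t1.false_alarms)
    if t1.d_prime == 0:
        logger.warning(
            "subject %s has d' = 0; meta-d' undefined, skipped", ds.subject_id
        )
        row.update(meta_d=None, m_ratio=None, meta_sse=None, meta_converged=None)
        return row
    try:
        _, binned = bin_confidence(ds.trials, cfg.n_confidence_bins)
        counts = type2_counts(binned, K=cfg.n_confidence_bins)
        fit = fit_meta_d(
            counts, t1, n_restarts=cfg.n_restarts,
            seed=_subject_seed(cfg.seed, ds.subject_id),
        )
    except (ValueError, FitError) as e:
        raise PipelineError(f"meta-d' stage, subject {ds.subject_id}: {e}") from e
    row.update(
        meta_d=fit.meta_d, m_ratio=fit.m_ratio, meta_sse=fit.sse,
        meta_converged=fit.converged,
    )
    return row


def analyze_cohort(
    datasets: Sequence[SubjectDataset],
    cfg: AnalysisConfig | None = None,
    counting: Sequence[CountingRecord] | None = None,
    exclude: Sequence[str] = (),
) -> dict:
    """Run the full analysis over in-memory subject datasets."""
    cfg = cfg or AnalysisConfig()
    excluded = [sid for sid in exclude]
    datasets = [ds for ds in datasets if ds.subject_id not in excluded]
    if not datasets:
        raise PipelineError("classification stage: no subjects after exclusions")

    t0 = time.perf_counter()
    model = build_chance_model(cfg.n_trials_expected, 0.5, cfg.alpha_chance)
    models = {model.n: model}  # per-trial-count cache; subjects may deviate

    counting_by_subject: dict[str, list[CountingRecord]] = defaultdict(list)
    for ds in datasets:
        counting_by_subject[ds.subject_id].extend(ds.counting)
    for rec in counting or ():
        if rec.subject_id not in excluded:
            counting_by_subject[rec.subject_id].append(rec)

    per_subject = []
    for ds in datasets:
        row = _subject_metrics(ds, cfg, models)
        recs = counting_by_subject.get(ds.subject_id, [])
        row["iacc"] = schandry_index(recs).score if recs else None
        per_subject.append(row)

    # group table mirroring the published layout: counts and percentages
    counts = {g: sum(r["group"] == g.value for r in per_subject) for g in _GROUP_ORDER}
    n_subjects = len(per_subject)
    group_table = {
        g.value: {
            "count": counts[g],
            "pct": 100.0 * counts[g] / n_subjects,
        }
        for g in _GROUP_ORDER
    }

    omnibus = gof_chi2(
        [counts[g] for g in _GROUP_ORDER], "equal",
        labels=tuple(g.value for g in _GROUP_ORDER),
    )
    nonempty = {g: counts[g] for g in _GROUP_ORDER if counts[g] > 0}
    posthoc = posthoc_pairwise(nonempty) if len(nonempty) >= 2 else []

    result: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "task": datasets[0].task_tag.value,
        "excluded": excluded,
        "n_subjects": n_subjects,
        "chance_model": {
            "n": model.n, "p0": model.p0, "alpha": model.alpha,
            "k_upper": model.k_upper, "k_lower": model.k_lower,
            "p_at_k_upper": None,
        },
        "per_subject": per_subject,
        "group_table": group_table,
        "omnibus": _gof_dict(omnibus),
        "posthoc": [_gof_dict(g) for g in posthoc],
    }
    from .chance import binom_pmf  # local to avoid polluting module namespace

    result["chance_model"]["p_at_k_upper"] = binom_pmf(
        model.k_upper, model.n, model.p0
    )

    # cohort inference: d' vs meta-d'
    dvals = [r["d_prime"] for r in per_subject if r["meta_d"] is not None]
    mvals = [r["meta_d"] for r in per_subject if r["meta_d"] is not None]
    if len(dvals) >= 3:
        contrast = paired_t(dvals, mvals)
        result["meta_vs_d"] = {
            "n": contrast.n, "mean_d": contrast.mean_x, "mean_meta_d": contrast.mean_y,
            "t": contrast.t, "p": contrast.p, "cohens_d": contrast.cohens_d,
            "degenerate": contrast.degenerate,
        }

    # correlations with counting accuracy + dependent-correlation comparison
    triple = [
        (r["iacc"], r["meta_d"], r["d_prime"])
        for r in per_subject
        if r["iacc"] is not None and r["meta_d"] is not None
    ]
    if len(triple) >= 4:
        iacc_v, meta_v, d_v = map(list, zip(*triple))
        try:
            r_mi, p_mi = correlate(meta_v, iacc_v)
            r_di, p_di = correlate(d_v, iacc_v)
            r_md, _ = correlate(meta_v, d_v)
            result["correlations"] = {
                "n": len(triple),
                "meta_d_vs_iacc": {"r": r_mi, "p": p_mi},
                "d_prime_vs_iacc": {"r": r_di, "p": p_di},
                "meta_d_vs_d_prime": {"r": r_md},
            }
            st = steiger_test(r_mi, r_di, r_md, len(triple))
            result["steiger"] = {"t": st.t, "p": st.p, "df": st.n - 3}
        except ValueError as e:
            logger.warning("correlation stage skipped: %s", e)

    # Kruskal-Wallis comparisons across groups
    by_group_conf = defaultdict(list)
    by_group_iacc = defaultdict(list)
    for r in per_subject:
        by_group_conf[r["group"]].append(r["mean_confidence"])
        if r["iacc"] is not None:
            by_group_iacc[r["group"]].append(r["iacc"])
    kw = {}
    if sum(bool(v) for v in by_group_conf.values()) >= 2:
        H, df, p = kruskal_wallis(by_group_conf)
        kw["confidence"] = {"H": H, "df": df, "p": p}
    if sum(bool(v) for v in by_group_iacc.values()) >= 2:
        H, df, p = kruskal_wallis(by_group_iacc)
        kw["iacc"] = {"H": H, "df": df, "p": p}
    if kw:
        result["kruskal_wallis"] = kw

    logger.info(
        "analyzed %d subjects in %.2fs", n_subjects, time.perf_counter() - t0
    )
    return result


def _gof_dict(g) -> dict:
    return {
        "labels": list(g.labels), "chi2": g.chi2, "df": g.df,
        "p": g.p, "omega": g.omega, "N": g.N,
    }


def run_pipeline(
    trials_path: str | Path,
    counting_path: str | Path | None = None,
    cfg: AnalysisConfig | None = None,
    task_tag: TaskTag = TaskTag.HEART_SOUND,
    exclude: Sequence[str] = (),
) -> dict:
    """Read input files and run the full analysis; deterministic given config."""
    datasets = read_trials(trials_path, task_tag)
    counting = read_counting(counting_path) if counting_path else None
    return analyze_cohort(datasets, cfg, counting, exclude)
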
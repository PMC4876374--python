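import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from cardiometa import (
    RateCorrection,
    Response,
    SimConfig,
    Stimulus,
    TrialRecord,
    bin_confidence,
    fit_meta_d,
    meta_contrast,
    simulate_subject,
    type1_stats,
    type2_counts,
)
from cardiometa.sdt import (
    Type1Stats,
    Type2Counts,
    _model_type2_rates,
    _observed_type2_rates,
    _sse_objective,
)


def make_trials(hits, misses, fas, crs, conf=50.0):
    """Trial list with the given type-1 table and constant confidence."""
    trials = []
    idx = 1
    for n, stim, resp in [
        (hits, Stimulus.SELF_HEART, Response.SAYS_SELF),
        (misses, Stimulus.SELF_HEART, Response.SAYS_OTHER),
        (fas, Stimulus.OTHER_HEART, Response.SAYS_SELF),
        (crs, Stimulus.OTHER_HEART, Response.SAYS_OTHER),
    ]:
        for _ in range(n):
            trials.append(TrialRecord("s1", idx, stim, resp, conf))
            idx += 1
    return trials


def analytic_type2_counts(meta_d, c_rel, incs_self, incs_other, n_per_cell=1000.0):
    """Exact expected type-2 counts under the meta-d' observer model itself."""
    meta_c = c_rel * meta_d
    crit_self = meta_c + np.cumsum(incs_self)
    crit_other = meta_c - np.cumsum(incs_other)
    K = len(incs_self) + 1
    mus = (meta_d / 2.0, -meta_d / 2.0)

    def probs(mu, side):
        if side == "self":
            cuts = np.concatenate(([meta_c], crit_self, [np.inf]))
            tail = 1 - ndtr(cuts - mu)
            return -np.diff(tail)
        cuts = np.concatenate(([-np.inf], crit_other[::-1], [meta_c]))
        return np.diff(ndtr(cuts - mu))[::-1]

    says_self = np.vstack([probs(m, "self") for m in mus]) * n_per_cell
    says_other = np.vstack([probs(m, "other") for m in mus]) * n_per_cell
    counts = Type2Counts(says_self=says_self, says_other=says_other, K=K)
    return counts, crit_self, crit_other


class TestType1Stats:
    def test_hand_derived_loglin_example(self):
        # 15/15 design, 11 hits, 4 FAs: HR = 11.5/16, FAR = 4.5/16
        t1 = type1_stats(make_trials(11, 4, 4, 11), RateCorrection.LOGLIN)
        assert t1.HR == pytest.approx(11.5 / 16)
        assert t1.FAR == pytest.approx(4.5 / 16)
        assert t1.d_prime == pytest.approx(1.158, abs=1e-3)
        assert t1.c == pytest.approx(0.0, abs=1e-12)  # symmetric table

    def test_zero_when_rates_equal(self):
        t1 = type1_stats(make_trials(8, 7, 8, 7))
        assert t1.d_prime == 0.0

    def test_antisymmetry_under_count_swap(self):
        a = type1_stats(make_trials(11, 4, 4, 11))
        b = type1_stats(make_trials(4, 11, 11, 4))
        assert b.d_prime == pytest.approx(-a.d_prime)
        assert b.c == pytest.approx(-a.c)

    def test_half_count_correction_only_touches_extremes(self):
        t1 = type1_stats(make_trials(15, 0, 4, 11), RateCorrection.HALF_COUNT)
        assert t1.HR == pytest.approx(1 - 1 / 30)
        assert t1.FAR == pytest.approx(4 / 15)

    def test_missing_stimulus_class_rejected(self):
        with pytest.raises(ValueError):
            type1_stats(make_trials(10, 5, 0, 0))


class TestBinConfidence:
    def test_quantile_edges_on_uniform_sample(self, rng):
        confs = rng.uniform(0, 100, size=2000)
        trials = [
            TrialRecord("s1", i + 1,
                        Stimulus.SELF_HEART if i % 2 else Stimulus.OTHER_HEART,
                        Response.SAYS_SELF, float(c))
            for i, c in enumerate(confs)
        ]
        scheme, binned = bin_confidence(trials, 4)
        assert np.allclose(scheme.edges, (25, 50, 75), atol=4)
        levels = np.array([lv for _, lv in binned])
        # quantile binning gives near-equal masses
        assert np.all(np.abs(np.bincount(levels)[1:] - 500) <= 10)

    def test_identical_confidences_rejected(self):
        trials = make_trials(8, 7, 7, 8, conf=50.0)
        with pytest.raises(ValueError, match="distinct"):
            bin_confidence(trials, 4)

    def test_median_split_boundary_goes_to_lower_level(self):
        trials = [
            TrialRecord("s1", i + 1, Stimulus.SELF_HEART, Response.SAYS_SELF, c)
            for i, c in enumerate([10.0, 10.0, 50.0, 90.0])
        ]
        scheme, binned = bin_confidence(trials, 2)
        levels = {t.confidence: lv for t, lv in binned}
        assert levels[10.0] == 1
        assert scheme.level_of(scheme.edges[0]) == 1  # value on the edge stays low
        assert levels[90.0] == 2

    def test_deterministic_given_data(self):
        trials = [
            TrialRecord("s1", i + 1, Stimulus.SELF_HEART, Response.SAYS_SELF,
                        float(5 * i))
            for i in range(16)
        ]
        a = bin_confidence(trials, 4)
        b = bin_confidence(trials, 4)
        assert a[0] == b[0] and [lv for _, lv in a[1]] == [lv for _, lv in b[1]]


class TestType2Counts:
    def test_conservation_before_padding(self):
        cfg = SimConfig(n_trials=30, seed=0)
        ds = simulate_subject(cfg, 3, with_counting=False)
        _, binned = bin_confidence(ds.trials, 4)
        counts = type2_counts(binned, K=4)
        if not any(counts.padded):
            assert counts.n_trials == 30

    def test_one_sided_responses_pad_empty_side(self):
        trials = [
            TrialRecord("s1", i + 1,
                        Stimulus.SELF_HEART if i % 2 else Stimulus.OTHER_HEART,
                        Response.SAYS_SELF, float(i * 3 + 1))
            for i in range(30)
        ]
        _, binned = bin_confidence(trials, 4)
        counts = type2_counts(binned, K=4)
        assert counts.padded[1]  # SAYS_OTHER side was all zeros
        assert np.all(counts.says_other == 1 / 8)

    def test_large_sample_rates_match_generating_model(self):
        """Observed cumulative type-2 rates of a large-sample noiseless observer
        agree with the analytic truncated-normal values at its parameters."""
        d, c = 1.5, 0.2
        cfg = SimConfig(n_trials=50_000, d_prime_gen=d, c_gen=c,
                        sigma_meta=0.0, seed=21)
        ds = simulate_subject(cfg, 21, with_counting=False)
        scheme, binned = bin_confidence(ds.trials, 4)
        observed = _observed_type2_rates(type2_counts(binned, K=4))
        # invert the confidence squashing to evidence-space distances
        dist = ndtri((np.array(scheme.edges) / 100.0 + 1.0) / 2.0)
        crit_self, crit_other = c + dist, c - dist
        model = _model_type2_rates(d, c, crit_self, crit_other)
        assert np.max(np.abs(observed - model)) < 0.02


class TestFitMetaD:
    def test_recovers_generating_parameters_from_analytic_counts(self):
        counts, crit_self, _ = analytic_type2_counts(
            1.2, 0.25, [0.3, 0.4, 0.5], [0.3, 0.4, 0.5]
        )
        t1 = Type1Stats(500, 500, 0, 0, 0.7, 0.3, d_prime=1.2, c=0.3)
        fit = fit_meta_d(counts, t1, n_restarts=8, seed=0)
        assert fit.meta_d == pytest.approx(1.2, abs=1e-3)
        assert fit.sse < 1e-8
        assert np.allclose(fit.t2_criteria_self, crit_self, atol=1e-3)
        assert fit.converged

    def test_criteria_ordering_invariants(self):
        counts, _, _ = analytic_type2_counts(0.8, -0.3, [0.2, 0.6, 0.9],
                                             [0.5, 0.3, 0.4])
        t1 = Type1Stats(500, 500, 0, 0, 0.6, 0.4, d_prime=0.8, c=-0.24)
        fit = fit_meta_d(counts, t1, n_restarts=8, seed=0)
        cs, co = np.array(fit.t2_criteria_self), np.array(fit.t2_criteria_other)
        assert np.all(np.diff(cs) > 0) and np.all(cs >= fit.meta_c)
        assert np.all(np.diff(co) < 0) and np.all(co <= fit.meta_c)
        assert fit.m_ratio == pytest.approx(fit.meta_d / 0.8)

    def test_fitted_model_rates_monotone_in_level(self):
        cfg = SimConfig(n_trials=2000, d_prime_gen=1.0, sigma_meta=1.0, seed=4)
        ds = simulate_subject(cfg, 4, with_counting=False)
        t1 = type1_stats(ds.trials)
        _, binned = bin_confidence(ds.trials, 4)
        fit = fit_meta_d(type2_counts(binned, K=4), t1, n_restarts=4, seed=4)
        model = _model_type2_rates(
            fit.meta_d, fit.meta_c,
            np.array(fit.t2_criteria_self), np.array(fit.t2_criteria_other),
        )
        assert np.all(np.diff(model, axis=1) <= 1e-12)

    def test_optimum_dominates_random_feasible_draws(self, rng):
        """SSE at the fit optimum is below 200 random feasible parameter draws."""
        cfg = SimConfig(n_trials=3000, d_prime_gen=1.2, sigma_meta=0.8, seed=9)
        ds = simulate_subject(cfg, 9, with_counting=False)
        t1 = type1_stats(ds.trials)
        _, binned = bin_confidence(ds.trials, 4)
        counts = type2_counts(binned, K=4)
        fit = fit_meta_d(counts, t1, n_restarts=8, seed=9)
        observed = _observed_type2_rates(counts)
        draws = np.column_stack([
            rng.uniform(-5, 5, size=200),
            rng.normal(np.log(0.5), 1.0, size=(200, 6)).reshape(200, 6),
        ])
        sses = [_sse_objective(theta, observed, t1.c_rel, 4) for theta in draws]
        assert fit.sse <= min(sses) + 1e-9

    def test_requires_nonzero_d_prime(self):
        counts, _, _ = analytic_type2_counts(1.0, 0.0, [0.3, 0.3, 0.3],
                                             [0.3, 0.3, 0.3])
        t1 = Type1Stats(500, 500, 0, 0, 0.5, 0.5, d_prime=0.0, c=0.0)
        with pytest.raises(ValueError, match="d'"):
            fit_meta_d(counts, t1)


class TestMetaContrast:
    def test_optimal_observer_has_unit_ratio(self):
        t1 = Type1Stats(15, 15, 0, 0, 0.7, 0.3, d_prime=0.8, c=0.1)
        counts, _, _ = analytic_type2_counts(0.8, 0.125, [0.3, 0.3, 0.3],
                                             [0.3, 0.3, 0.3])
        fit = fit_meta_d(counts, t1, n_restarts=4, seed=0)
        out = meta_contrast(t1, fit)
        assert out["diff"] == pytest.approx(0.0, abs=2e-3)
        assert out["m_ratio"] == pytest.approx(1.0, abs=3e-3)

    def test_published_cohort_means_as_worked_example(self):
        # cohort means: meta-d' 0.30 vs d' 0.80 -> diff -0.50, M-ratio 0.375
        from cardiometa.sdt import MetaFit
        t1 = Type1Stats(15, 15, 0, 0, 0.7, 0.3, d_prime=0.80, c=0.0)
        fit = MetaFit(0.30, 0.0, (), (), 0.0, 0.30 / 0.80, True, 1)
        out = meta_contrast(t1, fit)
        assert out["diff"] == pytest.approx(-0.50)
        assert out["m_ratio"] == pytest.approx(0.375)

    def test_degenerate_zero_d_prime_flagged(self):
        from cardiometa.sdt import MetaFit
        t1 = Type1Stats(15, 15, 0, 0, 0.5, 0.5, d_prime=0.0, c=0.0)
        fit = MetaFit(0.2, 0.0, (), (), 0.0, float("nan"), True, 1)
        out = meta_contrast(t1, fit)
        assert out["degenerate"] and out["m_ratio"] is None
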
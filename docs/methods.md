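# Methods

This note documents the statistical models behind `cardiometa`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Chance model and classification

Forced-choice accuracy is referred to an exact Binomial(n, ½) null. The
above-chance bound `k_upper` is the smallest count k > n/2 whose *point*
probability C(n,k)/2ⁿ falls to the significance level α (default .05); the
below-chance bound is its mirror `n − k_upper`. For the canonical n = 30 this
gives bounds 20 and 10 and a criterion probability of 0.028. The point-mass
rule (rather than an upper-tail rule, which would give 0.049 at k = 20) is
deliberate: it is the convention this analysis line uses, and the two rules
give the same bound at n = 30 but can differ at other n (at n = 10 the
point rule yields k_upper = 8, the tail rule 9). Classification is monotone
in the correct count and partitions 0..n into three contiguous bands:
OTHER ≤ k_lower < NON-DISCRIMINATOR < k_upper ≤ SELF.

Group frequencies are compared with Pearson's χ² against equal expected
counts, df = cells − 1, and Cohen's ω = √(χ²/N) with N the table total; the
identity ω²·N = χ² holds to machine precision and is property-tested against
exact-rational arithmetic. Post-hoc comparisons are all unordered pairs of
non-empty groups as 2-cell equal-expected tests, with no multiplicity
adjustment (matching the analysis being reproduced). The pmf is computed
through log-gamma, with the symmetric terms grouped so that
pmf(k, n, ½) = pmf(n−k, n, ½) holds exactly in floating point.

One caveat is inherited from the source material: for the beep-control
tables, ω recomputed as √(χ²/N) does not reproduce the printed effect sizes
under any single N convention (e.g. (3, 11, 2) gives ω = 0.755, not 0.58),
although every χ² value does. The package reports ω as computed.

## Type-1 SDT

Own-heart trials are "signal". With hit rate HR and false-alarm rate FAR,
d′ = z(HR) − z(FAR) and c = −½[z(HR) + z(FAR)]. Because 30-trial counts
routinely produce empty cells, rates are corrected before the z-transform:

- `LOGLIN` (default): add 0.5 to all four type-1 cells, i.e.
  HR = (hits + 0.5)/(n_signal + 1). Symmetric, defined for every input.
- `HALF_COUNT`: replace only 0 by 1/(2N) and 1 by 1 − 1/(2N).
- `NONE`: raw rates; extreme counts raise an error.

A balanced design with exactly n/2 correct forces HR = FAR and hence d′ = 0
under the symmetric correction; such subjects are retained for
classification but flagged and excluded from the metacognition stage, where
the relative criterion c′ = c/d′ is undefined.

## Meta-d′ by sum-square-error fit

Confidence on the continuous 0–100 scale is reduced to K ordered levels
(default K = 4) by within-subject quantile cuts at j/K; values equal to a
cut go to the lower level, and fewer than K distinct values is an error
advising a smaller K. Quantile binning protects against idiosyncratic use of
the scale; K is a config knob because no canonical value exists for
continuous ratings, so per-subject estimates are comparable only within a
fixed K.

Binned trials are cross-tabulated by response side × stimulus truth × level.
A response side containing any empty cell has 1/(2K) added to each of its
cells, keeping the observed cumulative rates strictly inside (0, 1) with
minimal distortion.

The model: an equal-variance Gaussian observer with sensitivity meta-d′,
stimulus means ±meta-d′/2, type-1 criterion locked at
meta-c = c′ × meta-d′ (so meta-d′ stays on the d′ scale), and K−1 type-2
criteria per response side — increasing above meta-c on the "self" side,
decreasing below it on the "other" side. Conditional on stimulus s (mean
μ_s) and response "self", the modelled probability of confidence at or above
the level with criterion q is the truncated-normal tail ratio
[1 − Φ(q − μ_s)] / [1 − Φ(meta-c − μ_s)], and symmetrically with lower
tails on the "other" side. The objective is the summed squared difference
between observed and modelled cumulative type-2 hit and false-alarm rates
(both sides, K−1 levels each, 4(K−1) terms).

Numerics: Nelder–Mead over (meta-d′, log-increments of the criteria), which
enforces criterion ordering by construction; meta-d′ clipped to [−5, 5];
8 random restarts by default (first start at the type-1 d′ with equal
spacing), convergence tolerance 1e-6 on the SSE, denominators floored at
1e-12. The fit raises (with best-so-far diagnostics attached) if no restart
converges. Restart seeds in the pipeline derive from the config seed and a
CRC-32 of the subject id, so removing one subject never perturbs another's
estimate.

Validation: fitting counts generated analytically from the model recovers
meta-d′ to ~1e-3 with SSE ≈ 0; a simulated zero-meta-noise observer at
10,000 trials is recovered within 0.1 of its generating d′; criterion shifts
of 0.5 move the estimate by < 0.15 (response-bias robustness); and the
returned optimum dominates 200 random feasible parameter draws.

## Heartbeat-counting index

Per interval, accuracy is 1 − |recorded − counted|/recorded; the subject's
score is the unweighted mean over intervals (equal weighting across the
25/35/45/100-s intervals, the standard convention; duration weighting is not
offered). Overcounting beyond twice the recorded beats yields a negative
interval term, which is *kept* — clamping would silently alter data — and
logged as a warning.

## Cohort inference

- Paired t (df = n−1) for d′ vs meta-d′, with Cohen's d =
  mean(diff)/sd(diff) (n−1 denominator). Zero-variance differences are
  flagged degenerate rather than producing an infinite t silently.
- Correlations: Pearson by default (switchable to Spearman); two-sided p.
- Two dependent correlations sharing a variable are compared with Williams'
  t (the Steiger-recommended statistic behind the common online
  calculators), df = n−3, two-sided; the implied 3×3 correlation matrix must
  be positive definite. The statistic is exactly antisymmetric in
  (r12, r13) and exactly zero at r12 = r13. Monte-Carlo calibration under
  the null (2,000 replicates of n = 30 trivariate-normal samples) keeps the
  empirical type-I rate within 2 points of the nominal 5%.
- Kruskal–Wallis with tie correction for distribution comparisons across
  groups; all-identical data returns H = 0 rather than an error.

## Synthetic-data generator

`simulate_subject` draws a balanced 15/15 stimulus sequence; the decision
variable is x ~ N(±d′/2, 1), the response "self" iff x > c, and the type-2
evidence x₂ = x + N(0, σ_meta). Confidence is the deterministic monotone
squashing 100·[2Φ(s·|x₂ − c|) − 1], so higher type-2 evidence never yields
lower confidence. σ_meta = 0 is the ideal metacognitive observer (meta-d′ →
d′ in the large-sample limit — the sharp oracle the recovery tests rely on);
additive Gaussian type-2 noise is one of several published conventions and
was chosen for exactly that single-knob property. Counting records are
generated as counted = round(recorded · IAcc) at a heart rate drawn around
70 bpm, keeping the tracking index in [0, 1] by construction.

`simulate_cohort` adds between-subject heterogeneity: d′ ~ N(0.8, 0.35)
floored at 0.05 and c ~ N(0, 0.3) (centred on the cohort-level sensitivity
and unbiased criterion the task produces empirically); a standard-normal
efficiency latent z_eff scales the metacognitive noise as
σ_i = σ_meta·exp(−0.6·z_eff); and the counting score IAcc ~ N(0.75, 0.17)
clipped to [0, 1] shares a Gaussian copula with z_eff at the configured
correlation (default 0.4). The latent truth table is returned so recovery
tests can compare fitted metrics against generating values.

Deterministic fixtures (`make_table1_cohort`, `make_control_cohort`)
realize the published group counts exactly — 17/7/3 of 27 heart-sound
subjects at 23/15/7 correct of 30, and 3/11/2 of 16 beep-control subjects
at 26/15/4 — with correctness split across stimulus classes and a fixed
30-value confidence lattice, so the classification, chi-square and report
layers reproduce every printed count-derived statistic without random input.

What the generator does *not* emulate: serial dependence between trials,
drifting criteria, lapses and missed responses, non-Gaussian evidence,
duration-dependent counting error, or any audio-level structure. Passing
recovery tests therefore certify the estimators under the generating model's
assumptions, not the cognitive fidelity of that model to real listeners.

## Problem sizes

Stochastic checks use sizes chosen to keep Monte-Carlo error well inside the
asserted bands: single-observer recovery and robustness at 10,000 trials;
observed-vs-analytic type-2 rate agreement at 50,000 trials (at 10,000 the
0.02 band is within ~2 binomial SDs of the smallest conditional cell);
ideal-observer cohort mean at 12 subjects × 10,000 trials; the
efficiency–IAcc coupling recovery at 120 subjects × 800 trials (fewer trials
attenuate the fitted-metric correlation through estimation noise); 2,000
replicates for the dependent-correlation and Kruskal–Wallis calibrations.

## Known limitations

- Meta-d′ is fit per subject by least squares on cumulative rates; no
  maximum-likelihood or hierarchical variant is provided, and confidence
  intervals for meta-d′ are out of scope.
- Subjects at exact chance (d′ = 0) cannot enter the metacognition stage.
- The beep-control ω discrepancy described above is reported, not resolved.
- With strongly one-sided responding, the padded side's type-2 rates carry
  almost no information and the fitted criteria on that side are weakly
  identified (the meta-d′ estimate itself remains stable; see the
  response-bias robustness test).
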
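# cardiometa

Analysis pipeline for own-heart-sound recognition experiments: can people
recognize the sound of their own heartbeat, and do they *know* when they get
it right?

In the underlying paradigm, each participant hears 30 five-second heart-sound
samples — 15 recorded from their own heart, 15 from a heart-rate-matched other
person — and makes a forced-choice "my heart / not my heart" judgment followed
by a 0–100 confidence rating. A separate heartbeat-counting task (silently
counting one's heartbeats over 25 s, 35 s, 45 s and 100 s intervals) provides
a classical index of interoceptive accuracy. `cardiometa` implements the full
statistical analysis of such data for psychophysics and interoception
researchers:

- **Exact-binomial chance classification.** Each subject's correct-trial count
  is compared against Binomial(n, ½). With n = 30 and α = .05 the smallest
  significantly-above-chance count is 20 (point probability p = .028), so
  subjects are labelled SELF (≥ 20 correct), OTHER (≤ 10), or
  NON-DISCRIMINATOR. Group-frequency distributions are tested with chi-square
  goodness-of-fit plus Cohen's ω = √(χ²/N), omnibus and pairwise.
- **Type-1 signal detection.** Sensitivity d′ = z(HR) − z(FAR) and criterion
  c = −½[z(HR) + z(FAR)] under an equal-variance Gaussian observer, with
  selectable hit/false-alarm rate corrections (log-linear default).
- **Metacognition (meta-d′).** Confidence is reduced to K ordered levels
  (within-subject quantiles, K = 4 default) and meta-d′ is estimated by
  minimizing the sum of squared differences between observed and model
  cumulative type-2 hit/false-alarm rates, with the metacognitive observer's
  type-1 criterion locked to the subject's relative criterion c′ = c/d′.
  meta-d′ = d′ is metacognitively optimal; M-ratio = meta-d′/d′ measures
  efficiency.
- **Interoceptive accuracy.** The heartbeat-tracking index
  (1/T) Σ<sub>t</sub> [1 − |recorded − counted|/recorded].
- **Cohort inference.** Paired t with Cohen's d for d′ vs meta-d′; Pearson or
  Spearman correlations with counting accuracy; Williams/Steiger t for two
  dependent correlations sharing a variable; Kruskal–Wallis group comparisons.
- **Synthetic data.** A seeded Gaussian-observer simulator (decision variable
  x ~ N(±d′/2, 1), confidence from x + N(0, σ<sub>meta</sub>)) with
  per-subject heterogeneity and a Gaussian-copula coupling between
  metacognitive efficiency and counting accuracy, plus deterministic fixture
  cohorts that realize the published group counts — so every stage is testable
  without raw data.

## Worked example

Write the deterministic 27-subject fixture cohort and classify it:

```bash
$ cardiometa simulate --preset table1 --out fix
27 fixture subjects written to fix
$ cardiometa classify --trials fix/trials.csv
hb01    23/30   SELF
...
SELF    17/27   (63.0%)
NON_DISCRIMINATOR       7/27    (25.9%)
OTHER   3/27    (11.1%)
omnibus chi2=11.56 df=2 p=0.003096 omega=0.65
```

Seventeen of 27 subjects (63%) exceed the 20-of-30 binomial criterion; the
omnibus χ²(2) = 11.56 (ω = 0.65) says the three groups are far from equally
populated.

A simulated metacognitively *sub-optimal* cohort (σ<sub>meta</sub> = 1.5),
end to end:

```bash
$ cardiometa simulate --n-subjects 20 --d-prime 1.2 --sigma-meta 1.5 --seed 23 --out sim
$ cardiometa run --trials sim/trials.csv --counting sim/counting.csv --seed 23 --out out
group table: SELF=13 (65.0%)  NON_DISCRIMINATOR=7 (35.0%)  OTHER=0 (0.0%)
report written to out/report.json
```

`out/report.json` then contains, among the per-subject metrics and group
tests, the cohort contrast `mean d′ = 1.19` vs `mean meta-d′ = 0.23`
(paired t = 2.75, p = .014, Cohen's d = 0.65): confidence carries far less
information than the decisions themselves, exactly the signature the noisy
generator was asked to produce.

The same stages are available programmatically:

```python
from cardiometa import analyze_cohort, make_table1_cohort, AnalysisConfig

report = analyze_cohort(make_table1_cohort(), AnalysisConfig(seed=1))
report["group_table"]["SELF"]          # {'count': 17, 'pct': 62.96...}
report["omnibus"]["chi2"]              # 11.555...
```

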
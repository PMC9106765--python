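# Methods

This note documents the models and procedures implemented in `spartapace`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Data model

A course is an ordered list of checkpoint segments with strictly positive
lengths; distances are stored in km (as organisers publish them) and
converted to metres once at load, with all speeds in m/s.  The time limit
(36 h for the bundled Athens–Sparta course) is a course property, not a
constant.  Split times are integer seconds ("HH:MM:SS" or plain seconds on
input); storing integers makes telescoping sums of segment times exact, so
segment times are the exact inverse of cumulative summation and the
round-trip write → read → recompute preserves every metric bit for bit.

A results row enters the analysed cohort only if the runner finished,
recorded every split, has strictly increasing positive times and finishes
inside the limit.  Each excluded row is counted under exactly one reason
(`did_not_finish`, `missing_split`, `unparseable`, `non_monotone`,
`over_time_limit`), and rows in = included + excluded always holds.  A
missing age is not an exclusion: the runner drops out of the age ANOVA
only, with the dropped count reported in that table.

## Pacing metrics

Definitions are in the README.  Two consequences worth noting:

* Conservation: Σ<sub>j</sub> t<sub>ij</sub> v<sub>ij</sub> = D exactly, so
  the time-weighted mean of a runner's signed CCS is zero — CCS measures
  deviation around the runner's own race, not around the cohort.
* Scale invariance: multiplying all of a runner's times by a constant
  leaves CCS and ACCS unchanged; they are shape metrics, not speed metrics.

CCS is computed against the runner's own average race speed, not a cohort
mean; ACCS divides by the number of checkpoints N (10 for the bundled
course, generalised for others).

### Shape classification

Published pacing archetypes are verbal, so the classifier makes them
operational with one tunable: a tolerance band (default 2 % of the
profile's mean speed) inside which speeds count as equal.  Rules, applied
in order — *even*: all speeds within one band of the mean; *positive* /
*negative*: monotone within the band; *reverse-J*: first minimum at
checkpoint k\* ≥ ⌈N/2⌉ but not the last, non-increasing approach to it,
final speed more than one band above the minimum but not above the start;
*parabolic*: fast–slow–fast with the final speed above the start;
otherwise *other*.  The reverse-J/parabolic boundary (does the end rise
pass the starting speed?) follows the conventional definition of reverse-J
pacing as an end rise that does not exceed the early pace.  An *end spurt*
is a final segment more than one band faster than the previous one.

### Grouping

Age bins: <30, 30–34, …, 55–59, 60+ (open tail bins absorb sparse ages).
Performance groups are quartiles of average race speed, fastest first
(HL, MHL, MLL, LL); sizes differ from n/4 by at most one, ties and quartile
edges are resolved by a stable sort on runner id, so assignment is
deterministic and permutation-invariant.  Quartiles are formed over the
pooled cohort by default, with a within-sex option, since published
analyses are ambiguous on this point; neither choice is asserted as "the"
convention.

## The inferential battery

`PacingModel.fit()` runs, in order: an advisory KS normality check on ACCS
(one-sample, against a normal with the sample mean and SD — with estimated
parameters the test is anti-conservative, which is one reason it never
gates the pipeline); grouping; the split-plot ANOVA on |CCS| with its
post-hocs; and the two factorial ANOVAs on ACCS.  A stage that cannot run
(e.g. quartiles on three runners) is recorded and skipped without aborting
the rest.

### Split-plot engine

With one between factor (sex, g groups) and one complete within factor
(checkpoint, k levels), the weighted-means decomposition is used:

* between stratum: SS<sub>sex</sub> (group means around the grand mean,
  weighted by group size) and SS<sub>subjects-within-sex</sub>;
* within stratum: SS<sub>checkpoint</sub>, SS<sub>checkpoint×sex</sub>, and
  the checkpoint × subjects-within error.

Because every subject contributes a full row, the subject × checkpoint
layout has proportional cell frequencies even with unbalanced sexes, so
these five sums of squares add exactly to the total (asserted at 1e-8
relative).  F for sex uses the subjects-within mean square; checkpoint and
the interaction use the within error.  No sphericity correction is applied
by default (uncorrected df are the convention this battery follows);
Greenhouse–Geisser epsilon-adjusted p-values are available via
`gg_correction=True`.  Degenerate zero-variance strata yield flagged NaN F
values, never division errors.

### Factorial engine

The two-way ANOVAs use Type III sums of squares computed from first
principles: sum-to-zero (deviation) coding, each effect's SS = increase in
residual SS when its columns leave the full model, df from matrix ranks
(so empty cells reduce the interaction df and attach an estimability
warning rather than crashing).  Type III was chosen because the cohorts of
interest are heavily unbalanced (≈87 % men); note Type III SS are not
additive under unbalance, so the additivity invariant is tracked by an
`additive` flag that holds on balanced designs.  Both engines are verified
in the test suite against brute-force enumeration oracles (direct summation
over the defining formulas for all shapes up to 3×4 cells × 5 replicates)
and against independent implementations (pingouin's mixed ANOVA,
statsmodels' Type III `anova_lm`) to 1e-8.

Effect size is classical η² = SS/SS<sub>total</sub> (labels: negligible
< 0.01 ≤ small < 0.06 ≤ medium < 0.14 ≤ large, cutoffs inclusive at the
lower edge); partial η² is reported alongside because mixed-design
conventions differ.  Bonferroni adjustment is p·m capped at 1, with
explicit family definitions: the 10 per-checkpoint sex comparisons, the 45
checkpoint pairs (paired t), and the 6 performance-group pairs within each
sex (pooled-variance t).  α = 0.05 throughout.

## Synthetic cohort generator

The generator draws, per runner: sex (Bernoulli, default 86.8 % male), an
age bin (weights proportional to the published cohort's age table, then a
uniform integer age within the bin; a small mass of missing ages), and a
mean race speed from a sex-specific normal (defaults 2.22 ± 0.32 m/s men,
2.21 ± 0.28 m/s women — the published values).  Expected checkpoint speeds
are v<sub>ij</sub> = s<sub>i</sub> · m<sub>j</sub><sup>γ<sub>i</sub></sup> ·
c<sub>ij</sub> · exp(ε<sub>ij</sub>) where

* m<sub>j</sub> is the base profile — the published men's mean checkpoint
  speeds normalised by the men's average speed, a reverse-J with its
  minimum at checkpoint 7 (the climb to the Sangas pass);
* γ<sub>i</sub> is a pacing-amplitude exponent and ε a log-normal noise
  term (below);
* c<sub>ij</sub> applies the sex contrast: women's multipliers are scaled
  by (1 − δ<sub>j</sub>/100), with δ the men-minus-women signed CCS gap per
  checkpoint derived from the published per-sex speed tables.  Anchoring
  the base profile on the men's table and shifting women (rather than
  shifting men on top of a men-derived profile) avoids double-counting the
  contrast.  The derived δ is positive at checkpoints 1–2 (men start
  relatively faster) and positive but small (+0.93 points) at checkpoint
  10, where both sexes' CCS is negative and women's is more negative —
  i.e. women show the larger final-checkpoint |CCS|, which is the reported
  pattern.

Segment times d<sub>j</sub>/v<sub>ij</sub> are rounded to whole seconds, so
synthetic files are indistinguishable in format from real ones.  Runners
whose finish would exceed the course limit have their noise redrawn
(bounded retries) rather than truncated; mean speeds are drawn above the
feasibility floor the limit implies.  All randomness flows from the single
config seed through one `numpy` generator; a fixed seed reproduces the
splits file byte for byte.

### Performance-dependent variability

Published results show pacing variability highest in the two middle
performance quartiles.  The generator imposes this through two inverted-U
quadratics in the runner's (drawn-speed) percentile p:

* a noise SD curve σ(p) = 3.5 + 10p − 10p² (percent, log-speed), i.e.
  ~3.5 % for the fastest/slowest and ~6 % mid-pack;
* an amplitude curve γ(p) = 0.85 + 0.92p − 0.92p²: the fastest and slowest
  quartiles run a flattened version of the mean profile (γ ≈ 0.85–0.95),
  mid-pack runners an exaggerated one (γ up to ≈1.08).  The curve averages
  ≈1 over percentiles, so the cohort mean profile stays on the base
  profile.

The amplitude channel carries most of the quartile contrast.  Noise SD
alone was tried first and cannot do the job: raising it inflates
within-group ACCS dispersion as fast as the between-group signal (the
ordering margin saturates near z ≈ 1.7 regardless of amplitude), and the
extra noise also pushes high-noise runners down the realised-speed ranking,
mechanically inflating the slowest quartile's ACCS.  Amplitude modulation
is also the more physical story: mid-pack runners do not run "noisier"
segments so much as a more exaggerated fade-and-spurt.  With the default
curves the mid-vs-extreme ordering margin is ≈8 standard errors at
n = 2000, so structure recovery is reliable by construction, as intended
for a validation harness.

### Known calibration tensions

* The published mean ± SD of average speed (2.22 ± 0.32 m/s) is
  inconsistent with the 36 h limit, which implies a floor of 1.90 m/s (the
  published minima, 1.18/1.41 m/s, sit below it).  The generator keeps the
  published parameters and enforces the limit, so the realised simulated
  mean is the truncated-normal mean, ≈2.31 m/s for men.
* The profile-level ACCS of the published men's means is 17.30 % when
  normalised by the published average 2.22 m/s, but 17.14 % when normalised
  self-consistently by the harmonic (time-weighted) average the profile
  itself implies — the two published numbers are rounded independently.
  Zero-noise generated runners reproduce 17.14 %; the 17.30 % figure is
  what the published numbers give and is what the acceptance script
  reports.
* The sex contrast at the last checkpoint (+0.93 CCS points) is small;
  after the absolute-value transform it rarely reaches Bonferroni-adjusted
  significance at n = 2000 (it was borderline in the real cohort of 2598).
  The recovery harness therefore reports the early-checkpoint and
  last-checkpoint sex patterns separately and does not treat the
  last-checkpoint contrast as a power benchmark.

## Validation design and problem sizes

* **Engine exactness**: every SS matched against enumeration oracles and
  independent implementations (above).
* **Type-I control**: 20 zero-effect cohorts of n = 200 on an
  equal-segment course with no time limit; each of the nine battery F-tests
  must reject in at most 3/20 (upper 95 % binomial bound at α = 0.05).
  The equal-segment, no-limit null course matters: on the real uneven
  course the per-checkpoint CCS variance differs mechanically with segment
  length (the runner's average weights long segments more), so the
  "checkpoint" null would be false by construction; and the 36 h cut-off
  conditions accepted noise draws near the boundary.
* **Structure recovery**: 20 replicates of the default calibration at
  n = 2000; the reverse-J cohort profile, a significant "large" checkpoint
  effect, and the middle-quartile ACCS excess within each sex must each be
  recovered in at least 18/20.
* **Determinism / round-trip**: fixed-seed simulation twice gives
  byte-identical CSV and report.json; write → read preserves all metrics
  exactly.

These sizes keep the whole suite under a minute on one CPU while leaving
the binomial and recovery bounds meaningful.

## Limitations

The generator validates the *pipeline*, not the physiology: it contains no
terrain causality (the reverse-J is imposed through the base profile, not
derived from elevation), no weather, circadian, sleep or nutrition effects,
no drop-outs (DNF simulation beyond the validation path), and no herd
behaviour or within-race interaction between runners.  Real split data
also carry correlation structures (e.g. compressed between-runner spread
at early checkpoints) that the independent-noise model does not reproduce;
published per-checkpoint SDs are therefore not matched, only means,
composition and the direction/ordering of the reported contrasts.  Passing
the recovery tests shows the pipeline detects structure of the published
kind when present and stays quiet when absent — it does not certify any
new empirical claim about real races.  Published F statistics from the
original cohort are not reproducible here because the raw split times are
not deposited; their printed degrees of freedom are also not internally
consistent with the stated sample size, so textbook df are used throughout.
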
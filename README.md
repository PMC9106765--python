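# spartapace

Checkpoint-split pacing analysis for ultra-marathon cohorts, built around
the 246.8 km Athens–Sparta "Spartathlon" (10 timed checkpoints, 36 h limit)
but applicable to any checkpointed race.

It is written for sports scientists and race analysts who have a results
list with cumulative split times per finisher and want the standard pacing
battery: per-runner pacing metrics, pacing-shape classification, age and
performance stratification, and the mixed/two-way ANOVA machinery with
effect sizes and Bonferroni post-hocs — plus a calibrated synthetic cohort
generator so every stage of the pipeline can be exercised and validated
without access to raw race data.

## The metrics

For runner *i* on a course with segment lengths *d<sub>j</sub>* (m) and
segment times *t<sub>ij</sub>* (s):

- average race speed: v̄<sub>i</sub> = D / T<sub>i</sub> (total distance
  over net finish time);
- checkpoint speed: v<sub>ij</sub> = d<sub>j</sub> / t<sub>ij</sub>;
- change in checkpoint speed:
  CCS<sub>ij</sub> = 100 (v<sub>ij</sub> − v̄<sub>i</sub>) / v̄<sub>i</sub> (%);
- average change in checkpoint speed:
  ACCS<sub>i</sub> = mean<sub>j</sub> |CCS<sub>ij</sub>| (%), a scalar
  pacing-variability index (0 = perfectly even pacing).

Signed CCS is kept for description and plots; the absolute values feed the
statistics (mixed signs would cancel).  The inferential battery is:
a split-plot ANOVA on |CCS| (checkpoint within-subjects × sex
between-subjects, each effect tested against its own error stratum), and
two two-way Type III ANOVAs on ACCS (age group × sex; performance
quartile × sex), all with classical η² = SS<sub>effect</sub>/SS<sub>total</sub>
(0.01 / 0.06 / 0.14 = small / medium / large) and Bonferroni-adjusted
post-hoc t-tests at α = 0.05.  Performance groups HL/MHL/MLL/LL are
quartiles of average race speed, fastest first.

## Worked example

```python
import spartapace as sp

course = sp.spartathlon_course()                       # bundled 10-checkpoint course
cfg = sp.default_config(course, n_runners=500, seed=42)
cohort, meta = sp.generate(cfg, course)                # synthetic finisher cohort
results = sp.PacingModel(cohort).fit()                 # the full battery
print(results.summary())
```

prints (abridged):

```
Checkpoint pacing analysis
============================================================
course: Spartathlon (10 checkpoints, 246.8 km)
runners: 500  (alpha=0.05, grouping scope=overall)

Shape census: other=219, reverse_j=281
KS normality of ACCS: D=0.0355 p=0.5436 (advisory)

Split-plot ANOVA on |CCS| (checkpoint x sex)
--------------------------------------------
          source        ss   df        ms      F         p   eta_sq eta_label
             sex     27.38    1     27.38 0.5594    0.4548 2.95e-05 negligible
      checkpoint 7.883e+05    9 8.759e+04   3427         0   0.8492 large
checkpoint x sex     982.9    9     109.2  4.273 1.528e-05 0.001059 negligible

Two-way ANOVA on ACCS (performance group x sex)
-----------------------------------------------
                 source    ss  df    ms      F         p   eta_sq eta_label
      performance_group 288.4   3 96.13  25.37 2.823e-15   0.1182 medium
                    sex 3.028   1 3.028 0.7991    0.3718 0.001241 negligible
performance_group x sex 12.19   3 4.063  1.072    0.3604 0.004994 negligible
```

Read this as: the cohort slows checkpoint by checkpoint to a minimum at
checkpoint 7 and speeds up again (a reverse-J profile — the dominant effect,
η² = 0.85 here), sexes differ little overall, and pacing variability (ACCS)
differs strongly between performance quartiles.  `results.accs_by_group()`
shows the inverted U — the middle quartiles pace least evenly:

```
sex performance_group  mean  count
  M                HL 16.72    117
  M               MHL 18.83    108
  M               MLL 18.84    106
  M                LL 16.89    113
```

(At α = 0.05, roughly one null test in twenty will come out "significant"
in any single cohort; the type-I behaviour of the whole battery is itself
tested, see below.)

The same pipeline runs from the shell:

```
spartapace simulate --n 2000 --seed 42 --out splits.csv
spartapace analyze --splits splits.csv --out results/
spartapace summarize --splits splits.csv --out summary.csv
spartapace recover --n 2000 --replicates 20 --seed 42 --out recovery.json
```

`analyze` writes `metrics.csv` (one row per runner), `groups.csv`,
`report.json` (versioned schema, deterministic bytes for fixed inputs) and
`report.txt`.

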
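# cohermetrics

Simulation and analysis toolkit for **coherence-threshold psychophysics**:
the kind of study that asks how many signal elements a random-dot or bar
pattern needs before an observer can report its global motion direction or
global form orientation, and how those thresholds relate to reading
ability, gender and non-verbal IQ in adults across the dyslexia continuum.

The package re-implements a complete measurement-and-inference chain as
tested, reusable code:

* **Stimuli** — four coherence-parameterised stimulus classes as abstract
  geometric frame sequences (12° × 12° window, 18.75 Hz element updates,
  0.12° displacements): random-dot global motion (200 dots), spatially 1-D
  global motion (50 horizontal bars), static global form (superimposed
  frames → oriented streaks) and temporally-defined global form (a boundary
  carried only by asynchronous dot jitter).
* **Observers** — a Weibull psychometric observer anchored so that
  P(correct) = 0.793 exactly at its nominal threshold, and stimulus-driven
  ideal-observer decision rules that validate the generated stimuli carry
  the intended signal.
* **Staircase** — the transformed up-down (3-down/1-up) adaptive procedure
  in integer element units: initial step equal to the element count,
  halving at every reversal, termination after six reversals at the
  one-element step, threshold = mean of the last six reversal levels,
  sessions of ≥ 4 staircases.  The rule's equilibrium solves p³ = ½,
  i.e. it tracks the ~79.4%-correct level.
* **Synthetic cohort** — participant tables (N = 106; 64 female) with three
  correlated reading measures, a near-40% dyslexia rate at the
  standard-score-85 nonword-decoding cutoff, and per-task true thresholds
  from linear models calibrated to published summary statistics.
* **Analysis** — z-transform + correlation-matrix PCA reading composite;
  two-step hierarchical OLS (gender and non-verbal IQ at step 1, reading
  composite or reading group at step 2) with the R² change
  F-test, F = (ΔR²/1) / ((1 − R²)/(n − 4)), and local effect size
  Cohen's f² = ΔR² / (1 − R²); pooled two-sample t-tests from group
  summaries; cross-task Pearson correlations.

## Worked example

```python
from cohermetrics.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=7))
print(report.composite_report["variance_explained_pct"])
for task in ("rdk", "bar1d", "static_form", "temporal_form"):
    r = report.whole_sample[task]
    print(task, round(r["r2_full"], 3), round(r["delta_r2"], 3),
          round(r["p_change"], 4), round(r["f2_local"], 3))
```

prints (seed 7):

```
72.36
rdk 0.253 0.075 0.0018 0.101
bar1d 0.069 0.021 0.135 0.022
static_form 0.082 0.004 0.5112 0.004
temporal_form 0.166 0.039 0.0313 0.047
```

Read this as: the first principal component of the three reading measures
carries 72% of their variance in this draw (the generator's expectation is
~64%; single cohorts fluctuate).  After controlling for gender and
non-verbal IQ, the reading composite adds significant variance for the
random-dot motion task (ΔR² = 0.075, p = 0.002, f² = 0.10) and the
temporally-defined form task (p = 0.03), but nothing for static global
form (p = 0.51) — the qualitative signature the synthetic cohort is
calibrated to reproduce: poorer readers have higher thresholds on tasks
that require integrating information over *time*, not on purely spatial
form.

The same stages are scriptable from a shell:

```bash
cohermetrics cohort --seed 11 --out cohort.csv
cohermetrics composite --in cohort.csv --out cohort_pc.csv
cohermetrics analyze --in cohort_pc.csv --mode between-group --out report.json
cohermetrics staircase --task rdk --threshold 20 --seed 7 --out session.json
cohermetrics pipeline --seed 7 --out run/
```

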
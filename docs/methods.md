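# Methods

This note records the models implemented by cohermetrics, the parameter
choices that matter, and what the simulations can and cannot establish.

## Stimulus models

All four tasks live in an abstract 12° × 12° window with elements updated
at 18.75 Hz (every 4th frame of a 75 Hz display) and displaced 0.12° per
update; an 8-image sequence lasts 8/18.75 ≈ 0.4267 s (printed as 0.43 s).
The implied drift speed is 0.12° × 18.75 Hz = 2.25°/s; published accounts
of this class of stimulus print 2.26°/s, a 0.01°/s inconsistency we do not
attempt to resolve — the displacement and update rate are taken as exact.

Coherence is quantised to whole elements: the signal count is
round(C/100 · N), because the staircase steps in integer element units.

* **Random-dot motion** (200 dots): signal dots translate up or down;
  noise dots take 0.12° steps in directions drawn uniformly on [0, 2π),
  so signal and noise share one speed.  Signal/noise assignment is
  re-drawn on every update, limiting any dot's signal lifetime.  Positions
  wrap toroidally, conserving density.
* **1-D motion** (50 full-width horizontal bars): identical logic with a
  single degree of freedom; noise bars move up or down with probability ½.
  A noise bar therefore matches the signal direction half the time, which
  is why the empirical-coherence diagnostic returns ≈ 50 at C = 0.
* **Static form**: an 8-frame dot sequence whose signal/noise assignment
  is *fixed* for the whole sequence; each signal dot steps in a fixed
  (randomly + or −) direction along the common axis, so superimposing the
  frames leaves collinear 8-dot streaks of extent 7 × 0.12° = 0.84°,
  while noise dots leave random-walk trails.  Fixed assignment is forced
  by the task definition — per-update re-randomisation cannot produce
  streaks along a common axis.  Positions are *not* wrapped here: a
  toroidal wrap would cut edge streaks in two and destroy the oriented
  structure the task is defined by.
* **Temporal form** (200 dots): two populations of 100 jittered (one
  0.12° step, random direction) on strictly alternating updates, so every
  update moves exactly half the dots.  A fraction C/100 of dots have
  population membership dictated by their side of the midline; the rest
  are assigned randomly subject to the 100/100 split.  The jitter
  amplitude is never published for this stimulus class; we default it to
  the common 0.12° displacement for parameter parity across tasks.
  Initial placement is uniform but *quadrant-stratified* (50 dots per
  quadrant): both candidate splits then hold exactly half the dots, which
  (a) makes the 100/100 jitter split compatible with a fully coherent
  boundary and (b) removes a subtle bias in which the unbalanced
  orthogonal split showed a stochastically larger jitter-count difference
  and dragged zero-coherence accuracy below chance.

Elsewhere initial positions are uniform in the window — the null choice.

## Observers

The psychometric observer is a Weibull for a two-alternative task,

    P(c) = γ + (1 − γ − λ) · (1 − exp(−(c/α)^β)),

with guess rate γ = 0.5 and lapse rate λ = 0.01 by default.  The scale α
is solved so that P(threshold) = 0.793 *exactly*: thresholds are
parameterised at the level the staircase tracks, not at the conventional
Weibull α (~81.6% for γ = 0.5), so staircase recovery can be compared
directly to the observer's nominal threshold.  The non-zero lapse keeps
ceiling behaviour realistic for the near-ceiling temporal-form task.

The default slope is β = 2.0.  No slopes are published for these tasks;
shallow Weibull slopes (β ≈ 1.5–2.5) are typical of motion-coherence
discrimination, and within that range β = 2 makes the simulated
staircase's floor-step trial accuracy (~79.2%) agree with the procedure's
nominal 79.37% tracked level, whereas steeper functions bias the tracked
accuracy low (the asymmetric walk spends time below threshold, where a
steep function loses accuracy quickly).  Slope remains a free parameter
of every observer.

Stimulus-driven observers implement near-ideal decision rules on the
generated geometry: sign of summed vertical displacement (motion), the
axis with greater summed trail variance (static form), and the split —
left/right vs bottom/top — with the larger between-half difference in
per-dot jitter-event counts (temporal form).  Additive Gaussian
positional noise (`internal_noise_sd`, degrees) degrades them smoothly;
they exist to validate that the stimuli carry the intended signal, not to
model human vision.

## Staircase

3-down/1-up in integer signal-element units.  Initial level and initial
step both equal the total element count; an error raises the level
immediately, a third consecutive correct response lowers it.  A move
opposite to the previous movement direction is a reversal: the pre-move
level is recorded, the step halves (integer halving, floor one element)
and the reversing move uses the halved step.  Runs terminate at the sixth
reversal taken while the step is one element; the estimate is
100 · mean(last six reversal levels)/total.  Under the floor-termination
rule the last six reversals are exactly the floor-step reversals; an
`estimate_from="floor_only"` switch implements the alternative reading
explicitly.  Moves clamped at the 0/total boundaries count as reversals
only when the intended direction actually changed, preventing spurious
reversals at ceiling.  A 10,000-trial cap guards against non-termination
(a degenerate always-correct responder descends monotonically and never
reverses).  Sessions average ≥ 4 independent staircases.

The equilibrium of the rule solves p³ = ½, p ≈ 0.7937.  Simulated
recovery is essentially unbiased for mid-range thresholds (a 20%
observer is recovered within ~1 coherence point, session SD ≈ 2).

**Known limitation — ceiling thresholds.**  For thresholds near 100%
coherence (the temporal-form task sits near 91%), the procedure as
specified cannot track accurately: the halving schedule spends its step
budget crossing the range, the six floor-step reversals accumulate while
the level is still drifting upward, and session estimates terminate
compressed and noisy (mean ≈ 78, SD ≈ 8 for a true 91% threshold; even
implausibly steep observers only reach ≈ 88).  Both reversal-move
orderings behave the same.  Consequently `measure_cohort` reproduces true
thresholds faithfully for the three mid-range tasks (measured-vs-true
r > 0.9 over a 106-participant cohort) but only weakly for the
near-ceiling task; the default analysis pipeline therefore regresses true
thresholds, and simulated measurement is an explicit opt-in.

## Synthetic cohort

The generator emulates the *statistical structure* the analyses consume;
no participant-level data exist for the reference study, so defaults are
calibrated to its published summary tables (shipped in
`cohermetrics.calibration`).

* N = 106 with a deterministic 64/42 female/male split.
* Reading measures are correlated standard normals mapped affinely to
  each test's scale (irregular-word reading 26.7 ± 6.0 raw; sight-word
  efficiency 85.4 ± 12.0 and nonword decoding 88.5 ± 14.0 standard
  scores).  Pairwise correlations default to 0.35/0.45/0.60 — inside the
  published 0.27–0.61 range, chosen so the leading eigenvalue of the
  correlation matrix is ≈ 1.93 (64% variance) and the loading order
  reproduces the published ordering (decoding highest).  The individual
  correlations are assumptions: only their range was published.
* The nonword-decoding marginal is placed so that P(score ≤ 85) ≈ 0.405,
  matching the published 43/106 dyslexia rate; the reference sample was
  deliberately enriched with poor readers, so its published group tables
  (which describe the two tails) do not pin the population marginal.
* True thresholds: threshold = b0 + b_g·female + b_spm·SPM +
  b_read·composite + ε per task, with the slope coefficients taken from
  the published step-2 regression rows, intercepts back-solved from the
  published male cell means (including a numerical correction for
  truncation on the near-ceiling task), and residual SDs set to reproduce
  the published full-model R² given the predictor variances
  (8.1/10.5/3.9/5.1 for the four tasks).  The "true" composite used here
  is the unit-variance projection of the latent reading normals on the
  correlation matrix's leading eigenvector — the published standardized
  β values are consistent with unit-variance component scores, not
  raw eigen-projections.
* Thresholds are confined to (0, 100] by resampling ε, not clipping, so
  no point mass forms at the bounds.
* Group assignment: dyslexia ⇔ decoding score ≤ 85; good readers are the
  equally many top-ranked decoders among the remainder (balanced design);
  the rule depends only on that one column and is idempotent.  Group
  sizes are stochastic (≈ Binomial(106, 0.405)), not fixed at 43.

What the generator does **not** emulate: residual cross-task correlation
(thresholds co-vary only through shared predictors, ≈ 0.1–0.15 between
the motion tasks, versus the ~0.6 observed empirically between real
motion tasks — shared perceptual ability beyond IQ/gender/reading is not
modelled); non-normal threshold distributions and their skew; test–retest
structure; and any genotype subgrouping.  Passing tests therefore show
that the *inference machinery* behaves correctly under the calibrated
model, and that the published significance pattern (motion and
temporal-form effects present, static form null) is reproducible at the
published effect sizes — they do not validate the generator as a model of
real readers beyond the summary statistics it was calibrated to.

## Inference

Hierarchical fits are ordinary least squares at both steps via
statsmodels; the step-2 increment is judged by
F = (ΔR²/1)/((1 − R²_full)/(n − 4)) (equal to the squared t of the step-2
coefficient) and the local effect size f² = ΔR²/(1 − R²_full)
(0.02/0.15/0.35 small/medium/large).  Standardized β is B·SD_x/SD_y.
Gender is coded female = 1, reading group Good = 0/Dyslexia = 1, so
positive B means higher thresholds for females / the dyslexia group.
Group psychometric contrasts use the pooled-variance t (df = n₁+n₂−2),
which reproduces the published df subscript; Welch is available behind a
flag.  p values are two-tailed with no multiplicity correction, matching
the α = 0.05 per-test convention of the source analyses.  Designs with
condition number above 1e10 are rejected with a diagnostic.

Two published-table wrinkles are handled explicitly: feeding *rounded*
group summaries back through the pooled t can perturb the final printed
digit (the nonword-decoding row gives 14.3464 where 14.34 was computed
from unrounded raw scores), so identity tests allow one unit in the last
printed decimal; and the between-group temporal-form f² as printed (0.07)
is inconsistent with its own rounded ΔR²/(1 − R²) = 0.078, so that single
cell is excluded from identity checks.

## Numerical and reproducibility choices

z-scores use the sample (n − 1) SD.  PCA of the 3 × 3 correlation matrix
uses a dense symmetric eigendecomposition; the first component's sign is
fixed by positive loadings (tie broken by the first coordinate), and
loadings follow the factor-analytic convention (eigenvector × √λ), so
squared loadings sum to λ₁ and eigenvalues sum to 3.  Composite scores
are standardized to unit SD by default, with eigen-projection units
behind a flag.  All randomness flows from numpy `SeedSequence` roots;
the pipeline spawns one substream per stage, and identical configuration
plus seed reproduces every output file byte-for-byte (the manifest
records the config hash and seed).  Simulation sizes in the test suite
(200-replicate calibration checks, 400-replicate coverage, 1000-staircase
convergence runs) were chosen to keep Monte-Carlo error comfortably
inside the tested tolerances while the whole suite runs in well under a
minute.
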
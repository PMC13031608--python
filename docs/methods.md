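# Methods

`cfopt` implements an active-learning design-of-experiments pipeline
for maximizing the product titer of a multi-factor cell-free
biosynthesis reaction (the packaged reference tables concern
liquiritigenin synthesis from L-tyrosine by a five-enzyme cascade, but
nothing in the machinery is specific to that system).  This note
records the models, the numerical choices, and the limits of what the
synthetic test harness can demonstrate.

## Factor coding

Every stage works on *coded* factor values: a factor with low level
`L` and high level `H` (natural units: mg/mL enzyme, mM cofactor, µL,
°C, h, pH) maps to `x = 2(v − (L+H)/2)/(H − L)`, so the screening
levels sit at ±1 and heterogeneous units share one scale.  The map is
affine and invertible; values outside the levels code to values
outside ±1, which later optimization rounds use deliberately when they
explore a widened factor space.

## Two-level screening

Designs are built from the published cyclic generating rows for 8, 12,
16, 20 and 24 runs (first row = generator, next rows its cyclic
shifts, last row all-minus).  Each column is balanced and any two
columns orthogonal — asserted by brute force in the test suite.

The main effect of factor *i* is the split-sum estimator

    E_i = ( Σ y at x_i = +1  −  Σ y at x_i = −1 ) / N ,

with `N` the **total** run count.  The published form of this divisor
is ambiguous (total runs vs. runs per level); we use total runs
because it makes `E_i` coincide exactly with the ordinary
least-squares slope of the coded first-order model
`y = β + Σ E_i x_i` on any balanced orthogonal design, with the
intercept equal to the grand mean.  The half-difference-of-means
reading is exposed as `effect_halfdiff = 2 E_i` in reports.
Significance uses `t = coefficient / SE` on the residual degrees of
freedom `runs − factors − 1` (6 for the 20-run, 13-factor table) and a
two-sided Student-t p-value; responses are the replicate means (raw
triplicates are not available in the packaged tables).

**Known discrepancy in the packaged table.** Refitting the packaged
20-run table gives intercept 43.285 and coefficients that are each
exactly `43.285 / 38.54 ≈ 1.123` times the screening statistics that
ship alongside it — a single global response-scaling factor,
presumably introduced when the original analysis normalized its
responses.  Because t and p are invariant under response scaling, the
refit reproduces **all thirteen** shipped p-values at their printed
precision, and the same five factors (ZmPAL, GmCHS, MsCHR, pH,
volume) clear `p < 0.05`.  The package reports its computed
coefficients and keeps the shipped ones as read-only fixture data; no
attempt is made to force agreement.

## Steepest ascent

The ascent direction is the coefficient vector restricted to the
chosen factors, normalized to unit length in coded space; each
component keeps its coefficient's sign (negative = step that factor
down).  Trials are laid out affinely, `trial_i = center + i·step`,
with optional per-factor decimal rounding applied last — the packaged
5-trial path has manually rounded increments that cannot be
reverse-engineered from any single step rule, so natural-unit steps
are always user-suppliable.  The best trial is the response argmax,
ties to the lowest index.

## Surrogate zoo and nested cross-validation

Seven seeded regression families: random forest, RBF-kernel SVR, a
small multilayer perceptron (lbfgs solver), Gaussian-process
regression (constant × Matern-2.5 + white-noise kernel, normalized
targets), and three gradient-boosted-tree configurations (xgboost,
lightgbm, and scikit-learn's gradient boosting).  Hyperparameter grids
are deliberately small (2–6 combinations per family) and sized for
datasets of tens of runs; with ~25–75 points, larger grids mostly
select noise, and the whole zoo retrains each round inside the loop.

Generalization is estimated by nested cross-validation — outer 9-fold,
inner 3-fold grid search scored by Pearson correlation, both with
seeded shuffles — so hyperparameter selection never sees the held-out
fold (a metamorphic test corrupts held-out responses and asserts the
chosen hyperparameters do not move).  The surrogate is the family with
the best mean held-out correlation, refit on all data; R² is reported
alongside.  Three fusions of all seven families are fit on out-of-fold
base predictions and reported with their out-of-fold R²:

* **stacking** — ridge meta-learner, penalty chosen by internal CV;
* **averaging** — equal weights `1/k`;
* **non-negative least squares** — active-set NNLS, no sum-to-one
  constraint, so anticorrelated base models are clamped to zero.

## Batch proposal

Candidates are scored by the upper-confidence acquisition
`mean + κ·sd` with `κ = 1` by default.  The predictive sd comes from
the Gaussian-process posterior whenever a GP family is in the registry
— it shrinks near observed runs and saturates far from them, keeping
exploration bounded.  The spread across the seven base models was
evaluated as an alternative and rejected as the default: far from the
data it is dominated by perceptron extrapolation (sd ≈ 40 mg/L at the
corners of a 13-dimensional space vs. ≈ 13 for the GP prior), which
steers the search into corners with near-zero true yield.  The spread
proxy remains the fallback for GP-free registries.

The search spends its evaluation budget (default 2,000) as a seeded
scrambled-Sobol filling of the coded box for the first quarter, then
Gaussian perturbations (sd 0.15 coded units, clipped to bounds) around
anchors: the five best scorers so far plus the best *observed*
conditions, so refinement hill-climbs from real data as well as from
surrogate optimism.  The proposed batch is the top 12 scorers after a
greedy minimum-pairwise-distance filter (0.05 coded units) that keeps
the validated conditions distinct; a shortfall raises an error naming
how many candidates survived.  Identical (seed, surrogate, bounds)
yield identical batches.

## Shapley attribution

A prediction is decomposed relative to the mean prediction over a
background sample (the training set by default) under the
interventional value function `v(S) = E_b f(x_S, b_∖S)`.  Exact
enumeration over all `2^d` coalitions is used up to 12 features;
beyond that a permutation-sampling estimator with antithetic pairs
(each sampled permutation is evaluated together with its reversal)
estimates the same quantity, reporting ~2 standard errors as its
Monte-Carlo tolerance.  Efficiency, dummy and symmetry hold to 1e-9
on the exact path; the sampler is checked against enumeration at
three budgets.  Summary data rank features by mean |contribution| with
the feature-value/contribution correlation as the sign; waterfall data
walk the ordered cumulative sums from base value to prediction.

## The synthetic yield oracle

The wet-lab stand-in is a scaled Gaussian bump over the 13 factors:
`y(x) = Y_max · exp(zᵀMz) · inhibition(x)` with
`z_i = (x_i − opt_i)/half-range`, `M` negative definite (diagonal =
per-factor curvature, off-diagonal = pairwise interactions / 2,
checked by eigenvalue at construction), plus smoothstep collapse
factors for inhibition rules.  Defaults: maximum 160 mg/L at an
interior optimum (PAL enzyme 4 mg/mL, volume 108 µL, pH 7.5, 38 °C,
…), strong curvature on the five screening-significant factors and
mild curvature elsewhere, three pairwise interactions
(PAL×volume, CHS×CHR, pH×temperature), and substrate collapse above
6 mM tyrosine (97% loss).  These values were chosen once so that the
two-level screening region reproduces the qualitative single-factor
findings — more PAL enzyme and larger volume help, more CHS enzyme or
substrate hurt, interior pH/temperature optima, near-total product
loss at high substrate — and are not tuned thereafter.

Replicate noise is additive (sd 3 mg/L) plus multiplicative (5% CV)
on `n_reps = 3` draws, matching the magnitude of the packaged tables'
± values; responses clip at zero.  The noise stream is counter-based
(`default_rng([seed, query_index])`), so persisting the query counter
makes interrupted campaigns exactly resumable.

What the oracle does *not* emulate: mechanistic enzyme kinetics,
time-course behavior, non-stationary noise, batch effects between
extract preparations, or the true (unknown) interaction structure of
the real reaction.  Passing the recovery benchmark shows the loop can
climb a smooth, mildly interacting, noisy 13-dimensional landscape —
not that it would match wet-lab performance.

## The closed loop

Each round: train and select on the cumulative table → propose a
batch → obtain responses from the responder (oracle or lab-sheet
exchange) → append and update the best-so-far (kept monotone).
Convergence: the relative improvement of the best-so-far is at or
below 2% for 2 consecutive rounds (both configurable), or 10 rounds.
Synthetic-mode initialization mirrors the reference campaign: a
20-run screening design plus a 5-trial ascent path answered by the
oracle.  The ascent increment is 2.5 coded units per trial along the
unit direction (≈ 1 coded unit per chosen factor), the same order as
the packaged path's printed increments; timid steps leave the loop an
extra round of catching up.

Per-round seeds derive from (base seed, round index); round state
persists as JSON, and resuming from a persisted state reproduces the
uninterrupted run bit for bit.

## Benchmark sizes and observed behavior

The recovery benchmark runs ten seeded campaigns of 3 rounds ×
batch 12 × 2,000 search iterations starting from 25 synthetic points;
the acceptance harness asserts a median best measured yield ≥ 90% of
the true maximum.  Batch means rise from first to final round in all
ten seeds; strict round-over-round monotonicity is *not* asserted
because consecutive batch means differ by ~1–2 mg/L in several seeds
— within one standard error of a 12-condition batch mean under the
configured replicate noise — so the trend is tested first-to-final
round instead.

## Known limitations

* Coefficient magnitudes from the packaged screening table differ
  from the shipped printed statistics by the global scaling described
  above; only signs, t, p and the significant set are reproduced.
* The exact Shapley path is exponential in the feature count (capped
  at 12); the sampler's tolerance is Monte-Carlo, not a bound.
* The acquisition is a single-objective UCB; no cost, constraint or
  multi-objective handling.
* Hyperparameter grids are small by design; with hundreds of runs a
  practitioner should widen them.
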
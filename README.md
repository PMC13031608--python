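# cfopt

Machine-learning-driven optimization of multi-factor cell-free
biosynthesis reactions.

Cell-free enzyme cascades (here: liquiritigenin synthesis from
L-tyrosine via a five-enzyme P/TAL → 4CL → CHS → CHR → CHI pathway)
depend on a dozen or more coupled settings — enzyme loadings, cofactor
concentrations, substrate, pH, temperature, time, volume.  One-factor-
at-a-time optimization misses interactions, and full factorial designs
are unaffordable in the lab.  `cfopt` packages the standard modern
answer as a tested, reusable pipeline:

1. **Two-level screening** (Plackett–Burman): estimate the main effect
   of each factor `E_i = (Σy₊ − Σy₋)/N` from `N` runs, fit the coded
   first-order model `y = β + Σ E_i x_i`, and keep the factors with
   `p < 0.05`.
2. **Steepest ascent**: step along the unit direction of the
   coefficient vector until the response turns over.
3. **Surrogate ensemble**: seven regression families (random forest,
   kernel SVR, MLP, three gradient-boosted-tree configurations, and a
   Gaussian process) evaluated by nested cross-validation (inner
   3-fold tuning, outer 9-fold scoring by held-out Pearson
   correlation), plus stacking / averaging / NNLS fusions.
4. **Bayesian batch proposal**: upper-confidence search
   (`mean + κ·sd`, 2,000 evaluations, Sobol + local refinement) returns
   the top 12 distinct conditions to validate next.
5. **Shapley attribution**: exact (≤ 12 features) or
   permutation-sampled per-feature contributions, with summary- and
   waterfall-style outputs.
6. **Closed loop**: validate → append → retrain, until the best yield
   stabilizes.  A configurable **synthetic yield oracle** stands in
   for the wet lab so the whole loop runs and is testable end to end.

The reference screening (20 runs × 13 factors), ascent (5 trials) and
headline-yield tables ship as packaged, checksummed fixtures.

## Worked example

Screening statistics recomputed from the packaged 20-run table:

```python
import numpy as np, cfopt

space = cfopt.load_fixture("pb_factors")      # 13 factors with ±1 levels
runs  = cfopt.load_fixture("pb_runs")         # 20 measured runs (mg/L)
design = cfopt.PBDesign(np.round(runs.coded_matrix(space)), tuple(range(1, 21)))
fit = cfopt.fit_first_order(design, runs.responses, factor_names=space.names)
print("intercept", round(fit.intercept, 2))
print("significant:", cfopt.select_significant(fit, 0.05))
print("p(ZmPAL) =", round(fit.p_value("ZmPAL"), 3))
```

prints

```
intercept 43.28
significant: ['ZmPAL', 'GmCHS', 'MsCHR', 'pH', 'volume']
p(ZmPAL) = 0.027
```

i.e. the two pathway enzymes at the head of the cascade branch, the
reductase, pH and reaction volume are the five factors that matter at
95% confidence, and every recomputed p-value matches the shipped
screening statistics at printed precision (the shipped *coefficients*
differ from the refit by one global response-scaling factor; see
`docs/methods.md`).  The packaged ascent path then peaks at its third
trial:

```python
idx, best = cfopt.best_trial(cfopt.load_fixture("ascent_trials"))
# -> trial 3, 104.42 mg/L
```

A full synthetic closed-loop campaign from the command line:

```sh
cfopt loop --rounds 3 --seed 3 --outdir runs/
# best-so-far 158.76 mg/L after 3 rounds (99.2% of the true optimum)
```

which bootstraps a 20-run screening + 5-trial ascent from the synthetic
landscape (true maximum 160 mg/L), then runs three
train-propose-validate rounds of 12 conditions each, persisting
per-round state JSON and batch CSVs under `runs/`.

## Layout

| module | contents |
| --- | --- |
| `cfopt.factors` | factor specs, coded↔natural transforms |
| `cfopt.tables` | experiment tables, CSV I/O |
| `cfopt.fixtures` | packaged reference tables (checksummed) |
| `cfopt.screening` | PB design generation, effects, first-order fit |
| `cfopt.ascent` | ascent direction, path layout, best trial |
| `cfopt.surrogate` | model zoo, nested CV, stacking/averaging/NNLS |
| `cfopt.search` | UCB acquisition, Sobol + local batch proposal |
| `cfopt.attribution` | exact and sampled Shapley values |
| `cfopt.oracle` | synthetic yield landscape |
| `cfopt.loop` | closed loop, persistence, convergence |
| `cfopt.benchmark` | ten-seed recovery study |
| `cfopt.cli` | `cfopt` command-line entry point |
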
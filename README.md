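# pseudoabs

Pseudo-absence generation and habitat-model evaluation for animal telemetry
data.

Telemetry tracks are presence-only: tags record where animals went, never
where they did not. To fit a presence/absence habitat model (species
distribution model) to tracking data you must simulate "pseudo-absences",
and the way you simulate them quietly shapes everything the model reports.
`pseudoabs` is for movement ecologists and SDM practitioners who want to
generate pseudo-absences defensibly — and to measure, rather than assume,
what the choice of method does to their models.

The package implements:

- **Four pseudo-absence generators**, each emitting a 1:1 set of labeled,
  timestamped points inside the study domain:
  *background* (area-uniform over the domain), *buffer* (uniform on a
  geodesic disc around each presence, radius = mode empirical step length),
  *correlated random walk* (resampling paired step-length/turn-angle draws
  forward from the tagging location), and *reverse CRW* (backward in time
  from the last fix).
- **Movement statistics**: track regularization by linear interpolation in
  time with gap splitting, and the paired empirical (step length, turn
  angle) distribution that parameterizes the buffer radius and the CRWs.
- **Three habitat-model families** on a binomial response: linear logistic
  with ridge-shrunken per-animal intercepts (GLMM analogue), B-spline
  smooths with basis dimension 5 per covariate over the same backbone (GAMM
  analogue), and stochastic gradient-boosted trees (learning rate 0.005,
  bag fraction 0.75, depth 5, 2000 trees).
- **Evaluation**: rank-based AUC (ties ½), threshold-maximized True Skill
  Statistic, explained binomial deviance (R²), three cross-validation
  schemes (full-data, 75/25, leave-one-month-out), and the Bhattacharyya
  coefficient BC = Σᵢ√(p̂ᵢq̂ᵢ) over 50 shared histogram bins measuring the
  environmental separation between presences and pseudo-absences — plus the
  per-family OLS regression of AUC on BC that tests whether separation,
  rather than ecology, is driving apparent skill.
- **A synthetic world generator** producing gridded environments (gradients,
  correlated noise fields, distance-to-feature layers; static or monthly;
  optional missing data) and habitat-biased tracks via step selection with
  known coefficients, so the whole pipeline is testable end to end with no
  restricted data.

## Worked example

Generate a synthetic study whose animals prefer the east side of an
environmental gradient (selection coefficient β = 3 per SD), run all four
pseudo-absence methods through all three model families, and regress AUC on
the Bhattacharyya coefficient:

```python
import pseudoabs as pa

spec = pa.EnvironmentSpec(
    origin_lon=-125.0, origin_lat=45.0, cell_size=0.1, n_cols=80, n_rows=80,
    layers=(
        pa.LayerSpec("grad", kind="gradient", direction="east"),
        pa.LayerSpec("noise1", kind="smoothed-noise", correlation_length=4.0),
        pa.LayerSpec("noise2", kind="smoothed-noise", correlation_length=8.0),
    ),
    seed=1,
)
sel = pa.SelectionParams(coefficients={"grad": 3.0},
                         moves=pa.ParametricMoves(mean_step_km=8.0))
study = pa.generate_study(spec, sel, n_animals=10, n_steps=200, seed=1)
report = pa.evaluate_experiment(study, schemes=("full",), seed=1)
print(report.metrics[["method", "family", "r2", "auc", "tss"]].round(3))
print(report.regressions[["family", "slope", "p_value"]].round(4))
```

Output (2,010 presences; metrics on the full-data scheme):

```
     method family    r2   auc   tss
 background linear 0.023 0.591 0.161
 background smooth 0.041 0.628 0.207
 background  trees 0.301 0.900 0.658
     buffer linear 0.000 0.501 0.007
     buffer smooth 0.000 0.501 0.006
     buffer  trees 0.034 0.643 0.182
        crw linear 0.027 0.576 0.168
        crw smooth 0.075 0.635 0.209
        crw  trees 0.436 0.939 0.727
reverse_crw linear 0.010 0.545 0.099
reverse_crw smooth 0.038 0.589 0.135
reverse_crw  trees 0.374 0.923 0.682

family   slope  p_value
linear -1.8472   0.0097
smooth -3.2956   0.0010
 trees -7.8705   0.0003
```

Reading it: buffer sampling places pseudo-absences within one step length of
the presences, so presence and absence environments barely differ
(Bhattacharyya coefficient ≈ 1) and every model family scores near chance
(AUC ≈ 0.5). Methods that sample farther afield separate the environments
more and score higher — and the significantly negative slope of AUC on BC
in every family says that this environmental separation, not model quality,
is what moves the skill metrics. Boosted trees outscore smooths, which
outscore linear models, within every method.

## Command line

```bash
pseudoabs run-all --out results/demo          # full synthetic experiment
pseudoabs run-all --config my.yaml --out results/run1 --methods background,crw
pseudoabs plot --report results/demo --out results/figs
```

`run-all` writes tracks, pseudo-absence sets, model tables, skill metrics,
BC tables, the separation-skill regression, and prediction rasters
(NetCDF). All randomness flows from the config's single master seed, so
reruns are byte-identical. `simulate`, `moves`, `pseudoabs`, `extract`,
`fit`, and `evaluate` expose the individual stages.

## Layout

```
src/pseudoabs/
  geodesy.py          spherical distance / bearing / destination (authalic radius)
  movement.py         Track, Domain, regularization, empirical move distributions
  synthetic_world.py  environments + habitat-biased track simulation (known truth)
  pseudoabsence.py    the four generators
  covariates.py       gridded covariate stacks, extraction, model-table assembly
  models.py           linear / smooth / boosted-tree habitat models
  evaluation.py       AUC, TSS, deviance, Bhattacharyya, CV schemes, experiment loop
  cli.py              typer CLI and the run-all pipeline
docs/methods.md       the full methods note
```
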
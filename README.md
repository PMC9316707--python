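# postsel — selective inference for the (adaptive) Lasso

Variable selection and subsequent inference on the *same* data breaks
classical confidence intervals: once the Lasso has chosen a submodel
`M̂(y)`, the usual Wald interval for a refitted coefficient no longer
covers at its nominal level, because the hypothesis itself was picked by
looking at `y`.  `postsel` implements, for Gaussian linear models with
more observations than candidate predictors (the typical biomedical
regression setting), the three practical remedies and a simulation
harness to compare them:

* **Split** — select on one random half of the data, compute classical
  t-intervals on the other half;
* **SI** — exact post-selection inference conditional on the Lasso
  selection: at fixed penalty λ the event `{M̂ = M, signs = s}` is a
  polyhedron `{Ay ≤ b}`, so `η'y` follows a truncated Gaussian
  `N(η'β_M, σ²‖η‖²)` restricted to an interval `[V−, V+]`, and confidence
  limits invert that pivot;
* **PoSI** — universally valid simultaneous intervals
  `β̂_{j,M} ± K·σ̂(β̂_{j,M})`, where the constant `K` bounds
  `max_{M ⊆ M_F, j∈M} |t_{j,M}|` over *all* submodels (Monte-Carlo
  approximated), giving family-wise error control under any selection
  rule.

All three target the **submodel parameter**
`β_M = Σ_M⁻¹ Σ_{M,M_F} β` — the best linear approximation to the true
regression function using only the selected variables — rather than the
full-model β.  Selection itself is by the Lasso or the adaptive Lasso
(weights `w_j = 1/|β̂_j,full|^γ`), tuned by tenfold CV, AIC/BIC, or a
fixed universal-threshold penalty `λ = c·σ̂·√(2 log p / n)`.

The package is aimed at statisticians who want to study or teach the
frequentist behaviour of these intervals — selective coverage, power,
type-1 error, interval widths and stability, selection probabilities,
validation R² — on a configurable factorial simulation grid, and at
analysts who want to apply the interval constructions to a rectangular
dataset from the command line.

## Worked example

Generate one dataset from a toy scenario (4 standardized Gaussian
predictors, a correlated pair at ρ = 0.8, true β = (1, 0.5, 0, 0),
population R² = 0.5, n = 40), select with the CV-tuned Lasso, and compute
90% selective (SI) intervals:

```python
import numpy as np
from postsel import (simulate_scenario, toy_grid, lasso_fit,
                     estimate_sigma_full, si_ci, submodel_target)

scenario = next(s for s in toy_grid() if s.name == "toy-c1-b4-r0.5-m10")
data = simulate_scenario(scenario, seed=7)
X, y = data.X, data.y - data.y.mean()

fit = lasso_fit(X, y, tuning="cv", seed=7)
print(f"tuned lambda = {fit.lam:.4f}, selected = {fit.active_set}")

sigma2 = estimate_sigma_full(X, y)
ivs = si_ci(X, y, fit.lam, fit.active_set, fit.signs, sigma2, level=0.90)
target = submodel_target(data.Sigma_true, data.beta_true, fit.active_set)
for k, j in enumerate(ivs.indices):
    print(f"x{j}: estimate {ivs.estimate[k]:+.3f}, 90% CI "
          f"[{ivs.lower[k]:+.3f}, {ivs.upper[k]:+.3f}], target {target.values[k]:+.3f}")
```

Output:

```
tuned lambda = 0.1395, selected = (0, 1, 3)
x0: estimate +0.636, 90% CI [-0.424, +1.304], target +1.000
x1: estimate +1.130, 90% CI [+0.430, +2.026], target +0.500
x3: estimate +0.244, 90% CI [-1.615, +0.579], target +0.000
```

The Lasso kept a noise variable (`x3`); its submodel target is exactly 0
because it is uncorrelated with the true predictors, and the selective
interval — visibly asymmetric, as conditioning on selection makes them —
correctly covers 0.  The two true predictors' intervals cover their
submodel targets (1.0 and 0.5).  Each interval set also carries stability
flags (`infinite_limit`, `estimate_outside`) marking the unstable cases
this construction is known to produce.

Simulation grids are run via the orchestrator (or the CLI):

```python
from postsel import GridConfig, run_grid, desk_toy_scenarios

config = GridConfig(scenarios=desk_toy_scenarios(stride=10, n_iterations=200),
                    roster=("Full", "Lasso-CV-SI", "Lasso-CV-PoSI"),
                    n_iterations=200, master_seed=1)
summary = run_grid(config)   # one row per scenario x method
```

## Command line

```bash
postsel simulate --config grid.yaml --out results/     # scenario grid -> metrics.csv
postsel analyze  --data bodyfat.csv --outcome siri \
                 --methods Lasso-CV-SI,Lasso-CV-PoSI \
                 --subsamples 100 --out results/        # real-data workflow
postsel fixture  --scenario 3 --out fx/                 # dump one scenario's data
postsel path     --data table.csv --outcome y           # coefficient path CSV
```

`analyze` standardizes the covariates, centers the outcome, runs each
method once on the full table, estimates per-variable selection
frequencies on 100 subsampling resamples, and writes intervals on both
the standardized and original variable scales.  The classic body-fat
prediction dataset (Siri % body fat on 13 anthropometric candidate
predictors, one implausible observation removed, n = 251) is a good
end-to-end exercise; the file is not bundled, but any numeric CSV with a
header works as shown above.

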
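# monarchdd

Density-dependent intraspecific competition analysis for breeding monarch
butterflies (*Danaus plexippus*).

Eastern North American monarchs recolonise their breeding range over several
generations, so egg and larval densities on milkweed vary strongly across
regions and through the season. `monarchdd` is for population ecologists who
want to turn enclosure-experiment measurements of density-dependent vital
rates into spatially and temporally resolved estimates of how much those
effects reduce the number of adults a wild population produces.

It implements three connected analyses:

1. **Killing-value (k-value) statistics.** For egg laying,
   `k = log10(rate_ref / rate)` against adult density; for egg-to-eclosion
   survival, `k = -log10(n_eclosed / n_initial)` against starting egg
   density. The OLS slope β of k on log10(density) measures density
   dependence: β = 0 density independence, 0 < β < 1 undercompensating
   "contest" competition, β = 1 exact compensation, β > 1 overcompensating
   "scramble".
2. **A density-dependent survival curve.** A quasibinomial logistic GLM of
   eclosion counts on egg density d (eggs per plant),
   `logit S(d) = a + b d`, with dispersion φ = Pearson χ²/(n − 2) scaling
   the standard errors; `S(0)` is the density-independent survival rate. The
   curve can also be rebuilt from two published survival rates
   (`calibrate_two_point`). The reduction attributable to density dependence
   is `R(d) = 1 − S(d)/S(0)`.
3. **Monte Carlo propagation to field densities.** Percent population
   reduction per breeding region × phase stratum, per life-stage density
   definition (large larvae; eggs; eggs plus all larvae), pairing density
   draws `N(mean, SE)` (truncated at 0) with survival-slope draws — either
   at the stratum mean density or applied to each surveyed site's own
   density, where the convexity of R makes site-level estimates exceed
   mean-density ones (Jensen gap).

A synthetic-data module generates enclosure trials (binomial or
beta-binomial), egg-laying trials (gamma rates, mean 58/SD 29.9 eggs per
female), and zero-inflated right-skewed field surveys, so the full pipeline
is testable offline. See `docs/methods.md` for model details and
assumptions.

## Worked example

Rebuild the survival curve from the published endpoint survival rates
(73.4% density-independent survival; 50.8% at 5 eggs/plant) and estimate the
population reduction for the early-season southern site dataset under all
three density definitions:

```python
from monarchdd import (FieldDensitySummary, MonteCarloConfig,
                       calibrate_two_point, reduction_mean_density, report)

curve = calibrate_two_point(s0=0.734, s_max=0.508, d_max=5.0)
print("a, b =", round(curve.intercept_logit, 4), round(curve.slope, 4))
print("S(0.982) =", round(curve.survival_at(0.982), 4),
      " R(0.982) =", round(curve.reduction_at(0.982), 4))

cfg = MonteCarloConfig(n_draws=100, seed=1, slope_cv=0.35)
estimates = [
    reduction_mean_density(
        FieldDensitySummary("South", "early", stage_set, mean, se, 49),
        curve, cfg)
    for stage_set, mean, se in [("large_larvae", 0.202, 0.041),
                                ("eggs", 0.736, 0.120),
                                ("eggs_and_larvae", 0.982, 0.138)]
]
print(report(estimates))
```

Output:

```
a, b = 1.015 -0.1966
S(0.982) = 0.6947  R(0.982) = 0.0536
region    phase   stage set        mode             reduction (mean ± SE)
South     early   large_larvae     mean_density            1.08% ± 0.04%
South     early   eggs             mean_density            4.05% ± 0.15%
South     early   eggs_and_larvae  mean_density            5.48% ± 0.20%
```

The curve passes through logit(0.734) at d = 0 with slope −0.1966 per
egg/plant. At the combined eggs-plus-larvae mean density of 0.982/plant,
survival drops from 73.4% to 69.5%, a 5.4% reduction in expected eclosing
adults; the Monte Carlo rows add the density- and slope-uncertainty, showing
the reduction grows roughly five-fold as more life stages enter the density
definition (1.1% → 5.5%).

Fitting your own trials instead of calibrating:

```python
from monarchdd import DensitySurvivalModel, read_larval_trials
res = DensitySurvivalModel.from_trials(read_larval_trials("trials.csv")).fit()
print(res.summary())        # coefficients, dispersion, S(0)
curve = res.function
```

The same stages are exposed as a CLI (`monarchdd simulate-trials`,
`fit-survival`, `calibrate-survival`, `kvalue`, `reduce --config run.yaml`,
`report`); `reduce` writes a results TSV, the curve grid, k-value reports
and a manifest naming the seed and config hash, and re-running a manifest
reproduces every file byte-for-byte.

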
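# Methods

`monarchdd` quantifies density-dependent intraspecific competition in
breeding monarch butterflies (*Danaus plexippus*) and propagates it to field
densities. Three model layers are involved: killing-value regressions on the
experimental trials, a density-dependent egg-to-eclosion survival curve, and
a Monte Carlo engine that converts field density estimates into percent
population reduction.

## Killing values

For a vital rate measured at density d, the killing value is the log-scale
proportionate reduction relative to a baseline:

* larval survival: `k = -log10(n_eclosed / n_initial)`;
* per-capita egg laying: `k = log10(rate_ref / rate)`, with
  `rate_ref = 74` eggs per female — the observed rate at the lowest adult
  density, kept as a fixed constant (overridable) rather than re-estimated
  from the data, so k retains its interpretation as reduction relative to a
  competition-free baseline.

k is regressed on log10(density) by OLS; the F test (1, n − 2 df) decides
density dependence at α = 0.05, and the slope classifies the competition
type: < 1 undercompensating "contest", ≈ 1 exact compensation (± 0.05 band),
> 1 overcompensating "scramble". Base-10 logs are used throughout (the
conventional k-value scale); the slope is invariant to the base as long as k
and the density transform share it, which the test suite verifies.

Density units: the egg-laying regression uses adult females per enclosure
(1–16); the survival regression uses starting eggs per enclosure (1–50),
log10-transformed by default with an identity transform available.

Replicates with zero survivors (or a zero laying rate) have no finite k.
The default is to exclude them with a logged warning; a Haldane-style
continuity correction `(n + 0.5)/(N + 0.5)` is available behind a flag for
users who prefer to keep them.

## The survival curve

Replicate trials place 1, 5, 10, 20, 35 or 50 eggs on 10 potted milkweed
plants (0.1–5 eggs per plant, spanning published wild egg densities of
0–2.8/plant), six replicates per density. Eclosion counts are modelled as

    n_eclosed ~ quasibinomial(initial_eggs, S(d)),    logit S(d) = a + b d,

with d in eggs per plant (per-enclosure available). The fit is IRLS
(statsmodels GLM, binomial family) run to a relative deviance change below
1e-10 with a 100-iteration cap, started from an empirical-logit least-squares
fit. The dispersion φ = Pearson χ² / (n − 2) scales the standard errors;
coefficient tests use t on n − 2 df. (statsmodels' own `scale="X2"` option
interacts badly with two-column binomial endog in the version pinned here, so
φ is computed explicitly.) A saturated two-observation fit is permitted — it
reconstructs a curve exactly through two aggregated points — with φ
undefined. Complete separation and all-success/all-failure inputs are
rejected up front.

The logit-linear form in untransformed density is the default because it is
the only form consistent with the published curve endpoints and the
downstream reduction table; an identity-link variant is provided behind a
config switch for sensitivity analysis (its fitted values are clipped to
[0, 1]).

**Two-point calibration.** When replicate data are unavailable the curve is
rebuilt from two published survival rates: `a = logit(s0)`,
`b = (logit(s_max) − logit(s0)) / d_max`. The reference curve used throughout
the examples is calibrated to s0 = 0.734 (density-independent survival),
s_max = 0.508 at d_max = 5 eggs/plant, giving a ≈ 1.0150, b ≈ −0.1966.
Calibrated curves carry zero SEs; their slope uncertainty in Monte Carlo
draws comes from a relative SE (coefficient of variation) instead, default
0.35 — the SE-to-slope ratio of the experiment's published GLM coefficient
pair (0.0028/0.008). That published slope cannot be reconciled with the
published endpoint survival rates under any density unit we tried, so it is
used only to set this relative uncertainty, never as the curve itself.

**Reduction.** `R(d) = 1 − S(d)/S(0)` is the proportional population
reduction attributable to density dependence. For b < 0 it is increasing,
bounded in [0, 1), and convex over the experimental range (verified by
second differences on a 0.01 grid).

## Monte Carlo propagation to field densities

Inputs are either regional summaries (mean ± SE per-plant density for a
region × breeding-phase stratum) or per-site survey counts. Site density can
be defined three ways: large larvae (instars 3–5), eggs, or eggs plus all
larvae, each divided by milkweed plants examined. Sites with zero density
under the chosen definition are excluded first — they admit no
density-dependent effect.

* **mean_density mode** — 100 densities are drawn from
  normal(mean, sd = SE) and paired one-to-one with 100 slope draws from
  normal(b, sd); R is averaged over draws. "Mean and 95% CI" sampling is
  interpreted as sd = SE (the CI half-width divided by 1.96 is identical and
  available as an explicit option).
* **site_specific mode** — each of 100 replicates draws an independent slope
  per site (a shared-per-replicate option exists), evaluates R at every
  site's own density and averages across sites; replicate means are then
  averaged.

Negative density draws are rejected and redrawn (densities are
non-negative). Positive slope draws (a density benefit) would give negative
reductions; these are floored at zero, with the unfloored mean also reported.
The intercept is held fixed by default — it largely cancels in the
with/without ratio — with joint sampling behind a flag. Reported uncertainty
is SD(draws)/√n; the raw draw SD is also emitted since published "standard
errors" of this kind are ambiguous between the two.

All randomness flows from one root seed; stratified tables derive a child
seed per (region, phase, stage-set) cell from its position in the fixed
South/Midwest/Northeast × early/middle/late ordering, so input order cannot
change results and any run is bit-reproducible.

**Jensen gap and its limits.** Because R is convex, site-level averaging is
never below mean-density evaluation, and exceeds it whenever site densities
vary — mean-density estimates are conservative. The size of the gap under
this curve is, however, bounded: R(d)/d ranges only from ≈ 0.053 (near
d = 0.2) to ≈ 0.062 (at d = 5), so for a site set averaging ≈ 0.2/plant the
site/mean ratio cannot exceed ≈ 1.2 no matter how skewed the density
distribution is. Field reports of site-level estimates roughly twice the
mean-density estimate therefore cannot be explained by this curve's
convexity alone; the package reproduces the direction and existence of the
gap, not a 2× magnitude.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, so every stage is testable offline.

* **Larval trials** — binomial draws from a known curve at the 6 × 6
  experimental design; overdispersion φ > 1 switches to a beta-binomial with
  matching mean and variance inflation (directly comparable with the fitted
  quasibinomial φ; single-egg trials stay binomial, where no overdispersion
  is possible).
* **Egg-laying trials** — per-capita rates from a gamma distribution (mean
  58 eggs/female, SD 29.9, matching the enclosure experiment) at the
  1/4/8/16-female design with 7/5/4/4 replicates; a gamma rather than a
  truncated normal guarantees positivity while matching both moments. An
  optional k-scale density effect (k per decade of density) scales the mean.
* **Field sites** — a site is all-zero with probability 0.30 (surveys
  routinely find unoccupied sites; the source surveys do not publish their
  zero fraction, so a typical value was fixed once); otherwise per-plant
  intensity is lognormal(−0.25, 0.75) truncated at 2.8 individuals/plant
  (right-skewed, mean ≈ 0.95/plant among occupied sites, matching the
  published combined-stage mean of 0.982 and the 0–2.8 published range),
  apportioned over eggs and instars 1–5 by a stage mix derived from the
  published stage-set means (eggs 0.736/0.982, large larvae 0.202/0.982),
  and realised as independent Poisson counts over 1 + Poisson(49) plants.
  The default 49 sites matches the compiled site dataset's n.

What the generators do **not** emulate: spatial clustering of larvae among
plants within a site (counts are independent Poissons, not
negative-binomial), larval movement and egg cannibalism, milkweed phenology,
and any correlation between site density and plants examined. Passing tests
therefore show that the pipeline's statistics behave correctly under the
assumed sampling model, not that wild surveys satisfy that model.

## Problem sizes and numerical choices

The recovery study refits the GLM on 200 simulated 36-trial experiments;
overdispersion detection uses 100 seeds; null/power checks of the k
regression use 200 and 100 seeds; Monte Carlo checks use 100–10 000 draws.
These sizes give Monte Carlo SEs an order of magnitude below the tolerances
asserted, and the whole suite runs in a few seconds.

Degenerate inputs are handled exactly: constant draw vectors report an SD of
exactly zero so a zero-uncertainty Monte Carlo collapses to point evaluation
to machine precision; a perfectly flat k response reports F = 0, p = 1,
r² = 0 rather than 0/0.

## Known limitations

* The curve extrapolates linearly on the logit scale beyond 5 eggs/plant,
  the experimental maximum; field densities above that are outside support.
* Egg-to-eclosion survival is a single aggregate endpoint; stage-specific
  (instar-by-instar) key-factor decomposition is out of scope.
* Regional summaries are taken as given (mean ± SE per stratum); the package
  does not re-derive them from raw survey archives.
* Enclosure trials confine larvae with a fixed food supply; applying the
  fitted curve to wild densities assumes comparable competitive exposure,
  which field larvae can escape by dispersal.
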
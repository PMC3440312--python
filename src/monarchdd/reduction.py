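"""Monte Carlo estimation of density-dependent population reduction.

Field densities of immature monarchs — regional mean ± SE summaries, or
per-site survey counts — are combined with a fitted or calibrated survival
curve to estimate the percent of the population lost to density-dependent
larval competition.  Two sources of uncertainty are propagated: the field
density estimate (densities drawn from a normal with the summary mean and
SE, truncated at zero) and the experimental survival slope (drawn from a
normal with the coefficient estimate and its SE, or a relative-SE override).

Two aggregation modes are provided:

mean_density
    Each of ``n_draws`` iterations pairs one density draw with one slope
    draw; R(d) = 1 − S(d)/S(0) is averaged over draws.
site_specific
    Each of ``n_reps`` replicates applies an independently drawn slope to
    every observed site density and averages R across sites; the replicate
    means are then averaged.  Because R is convex in d where the curve bends,
    this mode is never smaller in expectation than evaluating at the mean
    density (Jensen's inequality) — site-level heterogeneity strengthens the
    apparent density dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import expit

from .survival import SurvivalFunction

logger = logging.getLogger(__name__)

REGIONS = ("South", "Midwest", "Northeast")
PHASES = ("early", "middle", "late")
STAGE_SETS = ("large_larvae", "eggs", "eggs_and_larvae")

StageSet = Literal["large_larvae", "eggs", "eggs_and_larvae"]
Mode = Literal["mean_density", "site_specific"]


@dataclass(frozen=True)
class SiteSurveyRecord:
    """Counts of monarch immatures and milkweed plants examined at one site."""

    site_id: str
    region: str
    phase: str
    n_plants: int
    n_eggs: int
    n_instar1: int
    n_instar2: int
    n_instar3: int
    n_instar4: int
    n_instar5: int

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError(f"{self.site_id}: n_plants must be >= 1")
        for name in ("n_eggs", "n_instar1", "n_instar2", "n_instar3",
                     "n_instar4", "n_instar5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.site_id}: {name} must be >= 0")


@dataclass(frozen=True)
class FieldDensitySummary:
    """Regional mean ± SE of per-plant density for one stratum."""

    region: str
    phase: str
    stage_set: str
    mean_density: float
    se_density: float
    n_sites: int | None = None

    def __post_init__(self) -> None:
        if not self.mean_density > 0:
            raise ValueError("mean_density must be > 0 (zero strata are excluded)")
        if self.se_density < 0:
            raise ValueError("se_density must be >= 0")


@dataclass(frozen=True)
class ReductionEstimate:
    """Monte Carlo percent population reduction for one stratum and mode.

    ``se_pct`` is SD(draws)/sqrt(n_draws); ``sd_pct`` is the raw draw SD.
    ``raw_mean_pct`` is the mean before flooring negative reductions (which
    arise from density-benefit slope draws) at zero.
    """

    mean_pct: float
    se_pct: float
    sd_pct: float
    n_draws: int
    mode: Mode
    seed: int
    stage_set: str
    region: str
    phase: str
    raw_mean_pct: float = float("nan")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Settings for the reduction Monte Carlo.

    slope_cv
        If set, slope draws use sd = |slope| * slope_cv instead of the
        curve's own slope SE (needed for calibrated curves, whose SE is 0).
    density_sd_is_ci_halfwidth
        Interpret the summary's ``se_density`` as a 95% CI half-width and
        divide by 1.96 before drawing (equivalent parameterisation).
    shared_slope_per_rep
        In site-specific mode, share one slope draw across sites within a
        replicate instead of drawing independently per site.
    sample_intercept
        Also draw the intercept (normal with its SE); off by default — the
        intercept largely cancels in the with/without ratio.
    """

    n_draws: int = 100
    n_reps: int = 100
    seed: int = 0
    slope_cv: float | None = None
    density_sd_is_ci_halfwidth: bool = False
    shared_slope_per_rep: bool = False
    sample_intercept: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1 or self.n_reps < 1:
            raise ValueError("n_draws and n_reps must be >= 1")
        if self.seed is None:
            raise ValueError("seed must be provided (no silent nondeterminism)")


def site_density(record: SiteSurveyRecord, stage_set: StageSet) -> float:
    """Per-plant density at one site under the chosen life-stage definition."""
    if stage_set == "large_larvae":
        count = record.n_instar3 + record.n_instar4 + record.n_instar5
    elif stage_set == "eggs":
        count = record.n_eggs
    elif stage_set == "eggs_and_larvae":
        count = (record.n_eggs + record.n_instar1 + record.n_instar2
                 + record.n_instar3 + record.n_instar4 + record.n_instar5)
    else:
        raise ValueError(f"unknown stage_set {stage_set!r}")
    return count / record.n_plants


def filter_nonzero(
    records: Iterable[SiteSurveyRecord], stage_set: StageSet
) -> list[SiteSurveyRecord]:
    """Drop sites with zero density under ``stage_set``.

    Zero-density sites admit no density-dependent effect and are excluded
    before any averaging or drawing.
    """
    records = list(records)
    kept = [r for r in records if site_density(r, stage_set) > 0]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_nonzero(%s): removed %d of %d sites",
                    stage_set, removed, len(records))
    return kept


def _unique_label(records: Sequence[SiteSurveyRecord], attr: str) -> str:
    labels = {getattr(r, attr) for r in records}
    return labels.pop() if len(labels) == 1 else "mixed"


def summarize_sites(
    records: Sequence[SiteSurveyRecord], stage_set: StageSet
) -> FieldDensitySummary:
    """Mean and standard error of per-plant density over non-zero sites."""
    if len(records) < 2:
        raise ValueError(f"need >= 2 records to summarise, got {len(records)}")
    d = np.asarray([site_density(r, stage_set) for r in records], dtype=float)
    return FieldDensitySummary(
        region=_unique_label(records, "region"),
        phase=_unique_label(records, "phase"),
        stage_set=stage_set,
        mean_density=float(d.mean()),
        se_density=float(d.std(ddof=1) / np.sqrt(d.size)),
        n_sites=int(d.size),
    )


def draw_densities(
    summary: FieldDensitySummary,
    n_draws: int,
    rng: np.random.Generator,
    sd: float | None = None,
) -> np.ndarray:
    """Draw non-negative densities from normal(mean, SE), rejecting negatives."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    sd = summary.se_density if sd is None else sd
    if sd < 0:
        raise ValueError("sd must be >= 0")
    out = rng.normal(summary.mean_density, sd, size=n_draws)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(summary.mean_density, sd, size=int(neg.sum()))


def draw_slope(
    fn: SurvivalFunction,
    rng: np.random.Generator,
    size: int | tuple[int, ...] | None = None,
    sd: float | None = None,
):
    """Draw survival-curve slopes from normal(b, slope SE)."""
    sd = fn.slope_se if sd is None else sd
    if sd < 0:
        raise ValueError("slope sd must be >= 0")
    draws = rng.normal(fn.slope, sd, size=size)
    return draws


def _slope_sd(fn: SurvivalFunction, cfg: MonteCarloConfig) -> float:
    if cfg.slope_cv is not None:
        return abs(fn.slope) * cfg.slope_cv
    return fn.slope_se


def _density_sd(summary: FieldDensitySummary, cfg: MonteCarloConfig) -> float:
    if cfg.density_sd_is_ci_halfwidth:
        return summary.se_density / 1.959963984540054
    return summary.se_density


def _exact_sd(values: np.ndarray) -> float:
    """Sample SD that is exactly 0 for constant draws (degenerate Monte
    Carlo must collapse to point evaluation without float fuzz)."""
    if values.size < 2 or np.all(values == values[0]):
        return 0.0
    return float(values.std(ddof=1))


def _reductions(
    fn: SurvivalFunction,
    d: np.ndarray,
    slopes: np.ndarray,
    intercepts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw reductions (floored at 0) and the raw unfloored values."""
    a = fn.intercept_logit if intercepts is None else intercepts
    if fn.link == "logit":
        s0 = expit(a)
        s = expit(a + slopes * d)
    else:
        s0 = np.clip(a, 1e-12, 1.0)
        s = np.clip(a + slopes * d, 0.0, 1.0)
    raw = 1.0 - s / s0
    return np.clip(raw, 0.0, None), raw


def reduction_mean_density(
    summary: FieldDensitySummary,
    fn: SurvivalFunction,
    cfg: MonteCarloConfig,
) -> ReductionEstimate:
    """Percent reduction from paired density/slope draws at the stratum mean.

    Each of ``cfg.n_draws`` iterations pairs one truncated-normal density
    draw with one slope draw and evaluates R(d); the estimate is the draw
    mean (as a percent) with SE = SD/sqrt(n_draws).
    """
    if not fn.survival_at(0.0) > 0:
        raise ValueError("survival at zero density must be > 0")
    rng = np.random.default_rng(cfg.seed)
    d = draw_densities(summary, cfg.n_draws, rng, sd=_density_sd(summary, cfg))
    slopes = draw_slope(fn, rng, size=cfg.n_draws, sd=_slope_sd(fn, cfg))
    intercepts = None
    if cfg.sample_intercept and fn.intercept_se > 0:
        intercepts = rng.normal(fn.intercept_logit, fn.intercept_se, size=cfg.n_draws)
    r, raw = _reductions(fn, d, slopes, intercepts)
    sd_r = _exact_sd(r)
    return ReductionEstimate(
        mean_pct=100.0 * float(r.mean()),
        se_pct=100.0 * sd_r / float(np.sqrt(cfg.n_draws)),
        sd_pct=100.0 * sd_r,
        n_draws=cfg.n_draws,
        mode="mean_density",
        seed=cfg.seed,
        stage_set=summary.stage_set,
        region=summary.region,
        phase=summary.phase,
        raw_mean_pct=100.0 * float(raw.mean()),
    )


def reduction_site_specific(
    records: Sequence[SiteSurveyRecord],
    fn: SurvivalFunction,
    cfg: MonteCarloConfig,
    stage_set: StageSet,
) -> ReductionEstimate:
    """Percent reduction applying slope draws to each site's own density.

    For each of ``cfg.n_reps`` replicates a slope is drawn per site
    (independently, unless ``shared_slope_per_rep``), R is evaluated at each
    site density and averaged across sites; the replicate means are then
    summarised as mean ± SD/sqrt(n_reps).
    """
    if not fn.survival_at(0.0) > 0:
        raise ValueError("survival at zero density must be > 0")
    kept = filter_nonzero(records, stage_set)
    if not kept:
        raise ValueError("no non-zero sites for stage set " + stage_set)
    d = np.asarray([site_density(r, stage_set) for r in kept], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    sd = _slope_sd(fn, cfg)
    n_sites = d.size
    rep_means = np.empty(cfg.n_reps)
    raw_rep_means = np.empty(cfg.n_reps)
    for i in range(cfg.n_reps):
        size = 1 if cfg.shared_slope_per_rep else n_sites
        slopes = draw_slope(fn, rng, size=size, sd=sd)
        if cfg.shared_slope_per_rep:
            slopes = np.full(n_sites, slopes[0])
        r, raw = _reductions(fn, d, slopes)
        rep_means[i] = r.mean()
        raw_rep_means[i] = raw.mean()
    sd_r = _exact_sd(rep_means)
    return ReductionEstimate(
        mean_pct=100.0 * float(rep_means.mean()),
        se_pct=100.0 * sd_r / float(np.sqrt(cfg.n_reps)),
        sd_pct=100.0 * sd_r,
        n_draws=cfg.n_reps,
        mode="site_specific",
        seed=cfg.seed,
        stage_set=stage_set,
        region=_unique_label(kept, "region"),
        phase=_unique_label(kept, "phase"),
        raw_mean_pct=100.0 * float(raw_rep_means.mean()),
    )


def _stratum_order_key(s: FieldDensitySummary) -> tuple[int, int, int]:
    ri = REGIONS.index(s.region) if s.region in REGIONS else len(REGIONS)
    pi = PHASES.index(s.phase) if s.phase in PHASES else len(PHASES)
    si = STAGE_SETS.index(s.stage_set) if s.stage_set in STAGE_SETS else len(STAGE_SETS)
    return ri, pi, si


def _stratum_seed(root_seed: int, key: tuple[int, int, int]) -> int:
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def region_phase_table(
    summaries: Sequence[FieldDensitySummary],
    fn: SurvivalFunction,
    cfg: MonteCarloConfig,
) -> list[ReductionEstimate]:
    """Mean-density reduction per (region, phase, stage-set) stratum.

    Output is ordered South/Midwest/Northeast × early/middle/late × stage
    set.  Each stratum draws from its own seed stream derived from the root
    seed and the stratum's position in that fixed ordering, so input order
    cannot change results.
    """
    keys = [(s.region, s.phase, s.stage_set) for s in summaries]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (region, phase, stage_set) strata")
    out = []
    for s in sorted(summaries, key=_stratum_order_key):
        child = _stratum_seed(cfg.seed, _stratum_order_key(s))
        out.append(reduction_mean_density(s, fn, replace(cfg, seed=child)))
    return out


def compare_modes(
    site_est: ReductionEstimate, mean_est: ReductionEstimate
) -> float:
    """Ratio of site-specific to mean-density percent reduction."""
    same = (
        site_est.stage_set == mean_est.stage_set
        and site_est.region == mean_est.region
        and site_est.phase == mean_est.phase
    )
    if not same:
        raise ValueError("estimates must describe the same stratum and stage set")
    if mean_est.mean_pct == 0:
        raise ZeroDivisionError("mean-density estimate is zero")
    return site_est.mean_pct / mean_est.mean_pct
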
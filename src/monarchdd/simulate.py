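"""Synthetic experimental trials and field surveys.

Generators that reproduce the statistical structure the analysis assumes, so
every stage of the pipeline can be exercised without external data:

* larval-survival enclosure trials — binomial (or beta-binomial, for
  overdispersion) eclosion counts from a known survival curve at the
  experimental design of 1, 5, 10, 20, 35 and 50 eggs on 10 plants with six
  replicates per density;
* adult egg-laying trials — gamma-distributed per-capita laying rates
  (mean 58 eggs/female, SD 29.9, matching the enclosure experiment) at adult
  densities of 1, 4, 8 and 16 females, optionally with an imposed k-scale
  density effect;
* field survey sites — zero-inflated, right-skewed per-plant densities
  (lognormal truncated at 2.8 individuals/plant, the upper end of published
  egg densities) apportioned over eggs and instars 1–5 and realised as
  Poisson counts per site.

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kvalue import EggLayingTrial
from .reduction import SiteSurveyRecord
from .survival import LarvalTrial, SurvivalFunction

STAGES = ("eggs", "i1", "i2", "i3", "i4", "i5")

#: Stage mix matching the published site-dataset means: eggs 0.736 and large
#: larvae 0.202 out of 0.982 total per plant, remainder split over instars
#: 1–2.
DEFAULT_STAGE_MIX = {
    "eggs": 0.736 / 0.982,
    "i1": 0.022 / 0.982,
    "i2": 0.022 / 0.982,
    "i3": 0.0673 / 0.982,
    "i4": 0.0673 / 0.982,
    "i5": 0.0674 / 0.982,
}


def _rng(seed, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("provide a seed or an rng (no silent nondeterminism)")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class FieldSimConfig:
    """Configuration of the field-survey generator.

    The positive-density component is lognormal(density_log_mean,
    density_log_sd) truncated (by rejection) at ``max_density``; a site is
    all-zero with probability ``zero_inflation``.  ``stage_mix`` apportions
    the per-plant intensity over eggs and instars 1–5 and must sum to 1.
    Plants examined per site are 1 + Poisson(plants_mean − 1).
    """

    n_sites: int = 49
    zero_inflation: float = 0.30
    density_log_mean: float = -0.25
    density_log_sd: float = 0.75
    max_density: float = 2.8
    stage_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MIX)
    )
    plants_mean: float = 50.0
    region: str = "South"
    phase: str = "early"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if not self.max_density > 0:
            raise ValueError("max_density must be > 0")
        if set(self.stage_mix) != set(STAGES):
            raise ValueError(f"stage_mix must have keys {STAGES}")
        total = sum(self.stage_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage_mix must sum to 1, got {total}")
        if self.plants_mean < 1:
            raise ValueError("plants_mean must be >= 1")


def gen_larval_trials(
    fn_true: SurvivalFunction,
    design: Sequence[int] = (1, 5, 10, 20, 35, 50),
    n_plants: int = 10,
    n_reps: int = 6,
    dispersion: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[LarvalTrial]:
    """Simulate enclosure survival trials from a known survival curve.

    Eclosion counts are binomial(initial_eggs, S(d)) with d the per-plant
    density; ``dispersion`` phi > 1 switches to a beta-binomial with the same
    mean and variance inflated by phi (for trials of a single egg no
    overdispersion is possible and the draw stays binomial).
    """
    if dispersion < 1.0:
        raise ValueError(f"dispersion must be >= 1, got {dispersion}")
    gen = _rng(seed, rng)
    trials = []
    for n_eggs in design:
        d = n_eggs / n_plants
        p = fn_true.survival_at(d)
        for rep in range(n_reps):
            if dispersion == 1.0 or n_eggs == 1 or p in (0.0, 1.0):
                n_ecl = int(gen.binomial(n_eggs, p))
            else:
                # Beta-binomial: var = n p q (1 + (n-1) rho), with rho set so
                # the inflation factor equals phi (capped below n).
                rho = min((dispersion - 1.0) / (n_eggs - 1.0), 1.0 - 1e-9)
                conc = (1.0 - rho) / rho
                p_i = gen.beta(p * conc, (1.0 - p) * conc)
                n_ecl = int(gen.binomial(n_eggs, p_i))
            trials.append(
                LarvalTrial(
                    replicate_id=f"d{n_eggs}_r{rep + 1}",
                    initial_eggs=n_eggs,
                    n_plants=n_plants,
                    n_eclosed=n_ecl,
                )
            )
    return trials


def gen_egg_trials(
    mu: float = 58.0,
    sd: float = 29.9,
    densities: Sequence[int] = (1, 4, 8, 16),
    reps: Sequence[int] = (7, 5, 4, 4),
    density_effect: float = 0.0,
    n_plants: int = 50,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EggLayingTrial]:
    """Simulate adult egg-laying trials with gamma per-capita rates.

    The per-capita rate at adult density D has mean mu * D**(-density_effect)
    (a k-scale effect of ``density_effect`` per decade of density) and the
    stated SD; a gamma keeps rates positive while matching both moments.
    Total eggs are the rounded rate times the number of females.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if len(densities) != len(reps):
        raise ValueError("densities and reps must align")
    gen = _rng(seed, rng)
    trials = []
    for n_females, n_rep in zip(densities, reps):
        mean_rate = mu * float(n_females) ** (-density_effect)
        shape = (mean_rate / sd) ** 2
        scale = sd**2 / mean_rate
        for rep in range(n_rep):
            rate = gen.gamma(shape, scale)
            trials.append(
                EggLayingTrial(
                    replicate_id=f"f{n_females}_r{rep + 1}",
                    n_females=n_females,
                    n_plants=n_plants,
                    total_eggs=int(round(rate * n_females)),
                )
            )
    return trials


def gen_field_sites(cfg: FieldSimConfig) -> list[SiteSurveyRecord]:
    """Simulate per-site survey records of eggs and instars 1–5.

    With probability ``zero_inflation`` a site is all-zero; otherwise the
    site's per-plant intensity is a truncated lognormal draw, split over
    stages by ``stage_mix``, and each stage count is
    Poisson(intensity * share * n_plants).
    """
    gen = np.random.default_rng(cfg.seed)
    shares = np.asarray([cfg.stage_mix[s] for s in STAGES], dtype=float)
    records = []
    for i in range(cfg.n_sites):
        n_plants = 1 + int(gen.poisson(cfg.plants_mean - 1.0))
        if gen.random() < cfg.zero_inflation:
            counts = np.zeros(len(STAGES), dtype=int)
        else:
            while True:
                dens = float(
                    gen.lognormal(cfg.density_log_mean, cfg.density_log_sd)
                )
                if dens <= cfg.max_density:
                    break
            counts = gen.poisson(dens * shares * n_plants)
        records.append(
            SiteSurveyRecord(
                site_id=f"site_{i + 1:03d}",
                region=cfg.region,
                phase=cfg.phase,
                n_plants=n_plants,
                n_eggs=int(counts[0]),
                n_instar1=int(counts[1]),
                n_instar2=int(counts[2]),
                n_instar3=int(counts[3]),
                n_instar4=int(counts[4]),
                n_instar5=int(counts[5]),
            )
        )
    return records
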
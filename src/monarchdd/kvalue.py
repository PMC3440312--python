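"""Killing-value (k-value) statistics for density-dependence analysis.

The killing value of Varley & Gradwell summarises proportionate mortality (or
proportionate reduction of a vital rate) on a log scale:

    k = log10(N_initial / N_final)

Regressing k on log10(density) measures the strength of density dependence:
a slope of 0 indicates density independence, slopes in (0, 1) indicate
undercompensating ("contest") competition, a slope of 1 exact compensation,
and slopes above 1 overcompensating ("scramble") competition.

This module provides the k transforms for two experiment types — per-capita
egg laying by adult females, and egg-to-eclosion survival of larvae — plus an
ordinary-least-squares k-versus-density regression and the competition-type
classification of its slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Reference per-capita egg-laying rate (eggs per female) at the lowest adult
#: density, the denominator-free baseline for egg-laying k-values.
DEFAULT_REFERENCE_RATE = 74.0

XTransform = Literal["log10", "ln", "identity"]

COMPETITION_LABELS = (
    "density_independent",
    "undercompensating_contest",
    "exact_compensation",
    "overcompensating_scramble",
)


class InvalidRecordError(ValueError):
    """A trial record violates a domain invariant."""


class UndefinedKValueError(ValueError):
    """The k-value is undefined (zero rate or zero survivors)."""


class SingularDesignError(ValueError):
    """The regression design is singular (no density variation)."""


@dataclass(frozen=True)
class EggLayingTrial:
    """One enclosure replicate of the adult-female egg-laying experiment.

    ``n_females`` adult females were enclosed with ``n_plants`` milkweed
    plants; ``total_eggs`` eggs were counted at the end of the trial.
    Cloud cover and mean adult age are recorded covariates; they are carried
    through IO but not modelled.
    """

    replicate_id: str
    n_females: int
    n_plants: int
    total_eggs: int
    cloud_cover_pct: float | None = None
    mean_age_days: float | None = None

    def __post_init__(self) -> None:
        if self.n_females < 1:
            raise InvalidRecordError(
                f"{self.replicate_id}: n_females must be >= 1, got {self.n_females}"
            )
        if self.n_plants < 1:
            raise InvalidRecordError(
                f"{self.replicate_id}: n_plants must be >= 1, got {self.n_plants}"
            )
        if self.total_eggs < 0:
            raise InvalidRecordError(
                f"{self.replicate_id}: total_eggs must be >= 0, got {self.total_eggs}"
            )
        if self.cloud_cover_pct is not None and not 0 <= self.cloud_cover_pct <= 100:
            raise InvalidRecordError(
                f"{self.replicate_id}: cloud_cover_pct outside [0, 100]"
            )


@dataclass(frozen=True)
class KPoint:
    """A (density, k) pair entering the k-versus-density regression."""

    density: float
    k: float

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise InvalidRecordError(f"density must be > 0, got {self.density}")
        if not math.isfinite(self.k):
            raise InvalidRecordError(f"k must be finite, got {self.k}")


@dataclass(frozen=True)
class KRegressionResult:
    """OLS fit of k on (transformed) density.

    ``slope`` is in k units per unit of transformed density (per decade of
    density under the default log10 transform).  The F test has
    (``df_num``, ``df_den``) = (1, n − 2) degrees of freedom.
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    f_stat: float
    p_value: float
    r_squared: float
    df_num: int
    df_den: int
    n_points: int
    x_transform: XTransform = "log10"

    def classification(self, alpha: float = 0.05, tol: float = 0.05) -> str:
        return classify_competition(self, alpha=alpha, tol=tol)

    def summary(self) -> str:
        lines = [
            "k-value regression (OLS)",
            f"  n points          {self.n_points}",
            f"  x transform       {self.x_transform}",
            f"  slope             {self.slope:.4f} (SE {self.slope_se:.4f})",
            f"  intercept         {self.intercept:.4f} (SE {self.intercept_se:.4f})",
            f"  F({self.df_num},{self.df_den})            {self.f_stat:.2f}",
            f"  P                 {self.p_value:.4g}",
            f"  r^2               {self.r_squared:.3f}",
            f"  competition type  {self.classification()}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "slope", "slope_se", "intercept", "intercept_se", "f_stat",
            "p_value", "r_squared", "df_num", "df_den", "n_points",
            "x_transform",
        )}
        d["classification"] = self.classification()
        return d


def per_capita_rate(trial: EggLayingTrial) -> float:
    """Mean per-capita egg-laying rate: total eggs divided by females."""
    return trial.total_eggs / trial.n_females


def egg_laying_k(rate: float, reference_rate: float = DEFAULT_REFERENCE_RATE) -> float:
    """k-value for an egg-laying rate relative to the low-density reference.

    k = log10(reference_rate / rate); negative when the observed rate exceeds
    the reference.  A zero rate has no finite k and raises
    :class:`UndefinedKValueError` — such replicates are flagged and excluded
    from the regression.
    """
    if reference_rate <= 0:
        raise InvalidRecordError(f"reference_rate must be > 0, got {reference_rate}")
    if rate <= 0:
        raise UndefinedKValueError(
            f"per-capita rate must be > 0 for a finite k, got {rate}"
        )
    return math.log10(reference_rate / rate)


def survival_k(
    n_initial: int,
    n_eclosed: int,
    continuity_correction: bool = False,
) -> float:
    """k-value for egg-to-eclosion survival: −log10(n_eclosed / n_initial).

    Zero survivors have no finite k; by default the replicate raises
    :class:`UndefinedKValueError` (callers flag and exclude it).  With
    ``continuity_correction`` a Haldane-style correction
    (n_eclosed + 0.5)/(n_initial + 0.5) keeps the k finite.
    """
    if n_initial < 1:
        raise InvalidRecordError(f"n_initial must be >= 1, got {n_initial}")
    if not 0 <= n_eclosed <= n_initial:
        raise InvalidRecordError(
            f"n_eclosed must lie in [0, n_initial], got {n_eclosed}/{n_initial}"
        )
    if continuity_correction:
        return -math.log10((n_eclosed + 0.5) / (n_initial + 0.5))
    if n_eclosed == 0:
        raise UndefinedKValueError("zero survivors: k is undefined")
    return -math.log10(n_eclosed / n_initial)


def egg_laying_kpoints(
    trials: Iterable[EggLayingTrial],
    reference_rate: float = DEFAULT_REFERENCE_RATE,
) -> tuple[list[KPoint], list[str]]:
    """(density, k) pairs for the egg-laying experiment.

    Density is the number of adult females per enclosure.  Returns the usable
    points and the replicate ids excluded for an undefined k (zero eggs).
    """
    points: list[KPoint] = []
    excluded: list[str] = []
    for t in trials:
        rate = per_capita_rate(t)
        try:
            k = egg_laying_k(rate, reference_rate)
        except UndefinedKValueError:
            logger.warning("excluding replicate %s: zero egg-laying rate", t.replicate_id)
            excluded.append(t.replicate_id)
            continue
        points.append(KPoint(density=float(t.n_females), k=k))
    return points, excluded


def survival_kpoints(
    trials: Iterable["LarvalTrial"],  # noqa: F821 - imported lazily to avoid a cycle
    continuity_correction: bool = False,
) -> tuple[list[KPoint], list[str]]:
    """(density, k) pairs for the larval-survival experiment.

    Density is the starting egg count per enclosure (the experimental
    treatment level).  Zero-survivor replicates are excluded with a warning
    unless ``continuity_correction`` is set.
    """
    points: list[KPoint] = []
    excluded: list[str] = []
    for t in trials:
        try:
            k = survival_k(t.initial_eggs, t.n_eclosed, continuity_correction)
        except UndefinedKValueError:
            logger.warning("excluding replicate %s: zero survivors", t.replicate_id)
            excluded.append(t.replicate_id)
            continue
        points.append(KPoint(density=float(t.initial_eggs), k=k))
    return points, excluded


def _transform_density(density: np.ndarray, x_transform: XTransform) -> np.ndarray:
    if x_transform == "log10":
        return np.log10(density)
    if x_transform == "ln":
        return np.log(density)
    if x_transform == "identity":
        return density
    raise ValueError(f"unknown x_transform {x_transform!r}")


class KValueRegression:
    """OLS model of k-values against (log-transformed) density.

    Parameters
    ----------
    points
        (density, k) pairs; at least 3 points over at least 2 distinct
        densities.
    x_transform
        How density enters the design: ``log10`` (default, the conventional
        k-value scale), ``ln``, or ``identity``.
    """

    def __init__(self, points: Sequence[KPoint], x_transform: XTransform = "log10"):
        if len(points) < 3:
            raise ValueError(f"need >= 3 points, got {len(points)}")
        self.points = list(points)
        self.x_transform = x_transform
        self._x = _transform_density(
            np.asarray([p.density for p in points], dtype=float), x_transform
        )
        self._y = np.asarray([p.k for p in points], dtype=float)
        if np.unique(self._x).size < 2:
            raise SingularDesignError("all densities identical: design is singular")

    def fit(self) -> KRegressionResult:
        exog = sm.add_constant(self._x)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(self._y, exog).fit()
            # A perfectly flat response gives F = 0/0; report 0 with p = 1.
            fval = float(res.fvalue)
            pval = float(res.f_pvalue)
            r2 = float(res.rsquared)
        n = self._y.size
        if not math.isfinite(fval):
            fval, pval = 0.0, 1.0
        if not math.isfinite(r2):
            r2 = 0.0
        return KRegressionResult(
            slope=float(res.params[1]),
            slope_se=float(res.bse[1]),
            intercept=float(res.params[0]),
            intercept_se=float(res.bse[0]),
            f_stat=fval,
            p_value=pval,
            r_squared=r2,
            df_num=1,
            df_den=n - 2,
            n_points=n,
            x_transform=self.x_transform,
        )


def fit_k_regression(
    points: Sequence[KPoint], x_transform: XTransform = "log10"
) -> KRegressionResult:
    """Fit the k-versus-density OLS regression (convenience wrapper)."""
    return KValueRegression(points, x_transform=x_transform).fit()


def classify_competition(
    result: KRegressionResult, alpha: float = 0.05, tol: float = 0.05
) -> str:
    """Classify the competition type implied by a k-regression slope.

    A non-significant regression (p >= alpha) is density-independent
    regardless of slope.  Otherwise the slope is compared to 1 (exact
    compensation) with a ``tol`` band: below → undercompensating contest,
    within → exact compensation, above → overcompensating scramble.
    """
    if result.p_value >= alpha:
        return "density_independent"
    if result.slope < 1 - tol:
        return "undercompensating_contest"
    if result.slope > 1 + tol:
        return "overcompensating_scramble"
    return "exact_compensation"
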
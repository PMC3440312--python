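"""Density-dependent egg-to-eclosion survival model.

The survival of monarch eggs through to adult eclosion declines with
conspecific egg density d (eggs per milkweed plant).  The model is a
binomial GLM with a logit link, linear in untransformed density,

    logit S(d) = a + b * d,

fitted to enclosure trials by iteratively reweighted least squares with a
quasibinomial dispersion: the variance-inflation factor phi is estimated from
the Pearson chi-square on n − 2 df and scales the coefficient standard
errors.  The back-transformed intercept S(0) = expit(a) is the
density-independent survival rate (mortality from host-plant toxicity, latex
miring, and similar causes that act regardless of density).

The proportional population reduction attributable to density dependence at
density d is

    R(d) = 1 − S(d) / S(0),

the complement of the ratio of predicted eclosing adults with and without
density dependence.  For b < 0, R is increasing and convex in d on the
experimental range — the property that makes site-level averaging of R exceed
R evaluated at the mean density (the Jensen gap exploited downstream).

Besides the GLM fit, a two-point calibration builds the same curve from a
published pair of survival rates (the density-independent rate and the rate
at the maximum experimental density), for use when the replicate-level trial
data are not available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy import stats

from .kvalue import InvalidRecordError

DensityScale = Literal["per_plant", "per_enclosure"]
Link = Literal["logit", "identity"]

#: Relative standard error of the experimental density slope (slope SE over
#: slope magnitude).  Used to set the width of Monte Carlo slope draws when a
#: curve comes from two-point calibration and therefore carries no SE of its
#: own.  The default 0.35 is the ratio observed in the enclosure experiment's
#: published GLM coefficient pair (0.0028 / 0.008).
DEFAULT_SLOPE_CV = 0.35


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: Sequence[float] = ()):  # pragma: no cover
        super().__init__(message)
        self.trace = list(trace)


class SeparationError(ValueError):
    """The data are completely separated (all-success/all-failure pattern)."""


@dataclass(frozen=True)
class LarvalTrial:
    """One enclosure replicate of the larval-density experiment.

    ``initial_eggs`` eggs were placed on ``n_plants`` milkweed plants
    (experimental design: 1, 5, 10, 20, 35 or 50 eggs on 10 plants, i.e.
    0.1–5 eggs per plant); ``n_eclosed`` adults emerged.
    """

    replicate_id: str
    initial_eggs: int
    n_plants: int
    n_eclosed: int

    def __post_init__(self) -> None:
        if self.initial_eggs < 1:
            raise InvalidRecordError(
                f"{self.replicate_id}: initial_eggs must be >= 1, got {self.initial_eggs}"
            )
        if self.n_plants < 1:
            raise InvalidRecordError(
                f"{self.replicate_id}: n_plants must be >= 1, got {self.n_plants}"
            )
        if not 0 <= self.n_eclosed <= self.initial_eggs:
            raise InvalidRecordError(
                f"{self.replicate_id}: n_eclosed must lie in [0, initial_eggs], "
                f"got {self.n_eclosed}/{self.initial_eggs}"
            )

    def density(self, scale: DensityScale = "per_plant") -> float:
        if scale == "per_plant":
            return self.initial_eggs / self.n_plants
        if scale == "per_enclosure":
            return float(self.initial_eggs)
        raise ValueError(f"unknown density scale {scale!r}")


@dataclass
class SurvivalFunction:
    """The density-dependent survival curve S(d).

    ``intercept_logit`` (a) and ``slope`` (b) are on the logit scale (for
    ``link='identity'`` they are on the probability scale instead); SEs may
    be zero for calibrated curves.  ``dispersion`` is the quasibinomial
    variance-inflation factor phi (NaN when not estimated).
    """

    intercept_logit: float
    slope: float
    intercept_se: float = 0.0
    slope_se: float = 0.0
    dispersion: float = math.nan
    n_fit: int = 0
    link: Link = "logit"
    density_scale: DensityScale = "per_plant"

    def survival_at(self, d):
        """Survival probability at density d (scalar or array, d >= 0)."""
        d_arr = np.asarray(d, dtype=float)
        if np.any(d_arr < 0):
            raise ValueError("density must be >= 0")
        eta = self.intercept_logit + self.slope * d_arr
        if self.link == "logit":
            s = expit(eta)
        elif self.link == "identity":
            s = np.clip(eta, 0.0, 1.0)
        else:
            raise ValueError(f"unknown link {self.link!r}")
        return float(s) if np.isscalar(d) or d_arr.ndim == 0 else s

    def reduction_at(self, d):
        """Proportional reduction R(d) = 1 − S(d)/S(0) due to density."""
        s0 = self.survival_at(0.0)
        if not s0 > 0:
            raise ValueError("survival at zero density must be > 0")
        s = self.survival_at(d)
        return 1.0 - s / s0

    def to_dict(self) -> dict:
        return {
            "intercept_logit": self.intercept_logit,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "dispersion": self.dispersion,
            "n_fit": self.n_fit,
            "link": self.link,
            "density_scale": self.density_scale,
        }


def survival_at(fn: SurvivalFunction, d):
    """Functional alias for :meth:`SurvivalFunction.survival_at`."""
    return fn.survival_at(d)


def reduction_at(fn: SurvivalFunction, d):
    """Functional alias for :meth:`SurvivalFunction.reduction_at`."""
    return fn.reduction_at(d)


def calibrate_two_point(
    s0: float, s_max: float, d_max: float, link: Link = "logit"
) -> SurvivalFunction:
    """Build a survival curve through two published survival rates.

    ``s0`` is the density-independent survival (at d = 0), ``s_max`` the
    survival at the maximum experimental density ``d_max`` (individuals per
    plant).  Under the logit link a = logit(s0) and
    b = (logit(s_max) − logit(s0)) / d_max; SEs are zero — downstream Monte
    Carlo uses a slope coefficient of variation instead
    (:data:`DEFAULT_SLOPE_CV`).
    """
    if not (0.0 < s0 < 1.0 and 0.0 < s_max < 1.0):
        raise ValueError("survival rates must lie strictly in (0, 1)")
    if s_max > s0:
        raise ValueError("s_max must not exceed s0 (survival declines with density)")
    if not d_max > 0:
        raise ValueError("d_max must be > 0")
    if link == "logit":
        a = float(logit(s0))
        b = float((logit(s_max) - logit(s0)) / d_max)
    elif link == "identity":
        a = float(s0)
        b = float((s_max - s0) / d_max)
    else:
        raise ValueError(f"unknown link {link!r}")
    return SurvivalFunction(intercept_logit=a, slope=b, link=link, n_fit=0)


def _check_separation(p: np.ndarray, d: np.ndarray) -> None:
    if np.all(p >= 1.0):
        raise SeparationError("all trials are complete successes")
    if np.all(p <= 0.0):
        raise SeparationError("all trials are complete failures")
    interior = (p > 0.0) & (p < 1.0)
    if not interior.any():
        # Only 0/1 proportions: separated unless successes and failures mix
        # at a common density.
        d_succ, d_fail = d[p >= 1.0], d[p <= 0.0]
        if d_succ.size and d_fail.size and (
            d_succ.min() > d_fail.max() or d_succ.max() < d_fail.min()
        ):
            raise SeparationError("complete separation in density")


class DensitySurvivalModel:
    """Quasibinomial logistic model of survival counts against density.

    Parameters
    ----------
    n_eclosed, n_initial
        Success and total counts per observation.
    density
        The density covariate for each observation (individuals per plant
        unless the trials were built ``per_enclosure``).
    link
        ``logit`` (default) or ``identity`` (sensitivity variant).
    """

    def __init__(
        self,
        n_eclosed: Sequence[int],
        n_initial: Sequence[int],
        density: Sequence[float],
        link: Link = "logit",
        density_scale: DensityScale = "per_plant",
    ):
        self.successes = np.asarray(n_eclosed, dtype=float)
        self.totals = np.asarray(n_initial, dtype=float)
        self.density = np.asarray(density, dtype=float)
        self.link = link
        self.density_scale: DensityScale = density_scale
        if not (self.successes.shape == self.totals.shape == self.density.shape):
            raise ValueError("n_eclosed, n_initial and density must align")
        # Two aggregated observations give a saturated (exactly-determined)
        # fit, useful for curve reconstruction from published rates.
        if self.totals.size < 2:
            raise ValueError(f"need >= 2 observations, got {self.totals.size}")
        if np.unique(self.density).size < 2:
            raise ValueError("need >= 2 distinct densities")
        if np.any(self.successes < 0) or np.any(self.successes > self.totals):
            raise InvalidRecordError("successes must lie in [0, total]")
        _check_separation(self.successes / self.totals, self.density)

    @classmethod
    def from_trials(
        cls,
        trials: Iterable[LarvalTrial],
        density_scale: DensityScale = "per_plant",
        link: Link = "logit",
    ) -> "DensitySurvivalModel":
        trials = list(trials)
        return cls(
            n_eclosed=[t.n_eclosed for t in trials],
            n_initial=[t.initial_eggs for t in trials],
            density=[t.density(density_scale) for t in trials],
            link=link,
            density_scale=density_scale,
        )

    def _start_params(self) -> np.ndarray:
        # Empirical-logit least squares: cheap, always finite.
        p_tilde = (self.successes + 0.5) / (self.totals + 1.0)
        y = np.log(p_tilde / (1.0 - p_tilde)) if self.link == "logit" else p_tilde
        X = np.column_stack([np.ones_like(self.density), self.density])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> "SurvivalResults":
        endog = np.column_stack([self.successes, self.totals - self.successes])
        exog = sm.add_constant(self.density)
        if self.link == "logit":
            family = sm.families.Binomial()
        else:
            family = sm.families.Binomial(link=sm.families.links.Identity())
        model = sm.GLM(endog, exog, family=family)
        with warnings.catch_warnings():
            # Saturated (two-point) fits trip statsmodels' near-zero-deviance
            # separation heuristic and a 0/0 scale; real separation is caught
            # by the explicit pre-check above.
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
                warnings.simplefilter("ignore", PerfectSeparationWarning)
            except ImportError:  # pragma: no cover
                pass
            res = model.fit(
                start_params=self._start_params(),
                maxiter=maxiter,
                tol=tol,
            )
        if not res.converged:
            raise ConvergenceError(
                f"IRLS did not converge in {maxiter} iterations",
                trace=getattr(res, "fit_history", {}).get("deviance", []),
            )
        if not np.all(np.isfinite(res.params)):
            raise SeparationError("non-finite coefficients: data are separated")
        return SurvivalResults(self, res)


class SurvivalResults:
    """Fitted quasibinomial survival model.

    Carries the coefficient estimates with dispersion-scaled standard errors,
    t statistics on n − 2 df, the Pearson dispersion phi, and the fitted
    :class:`SurvivalFunction` used by the Monte Carlo reduction engine.
    """

    def __init__(self, model: DensitySurvivalModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.nobs = int(model.totals.size)
        self.df_resid = self.nobs - 2
        self.params = np.asarray(sm_results.params, dtype=float)
        self.deviance = float(sm_results.deviance)
        self.pearson_chi2 = float(sm_results.pearson_chi2)
        # Quasibinomial dispersion: Pearson X2 on n - 2 df inflates the
        # binomial-model standard errors by sqrt(phi).  A saturated two-point
        # fit has no residual df; its dispersion is undefined and SEs stay on
        # the binomial scale.
        if self.df_resid > 0:
            self.dispersion = self.pearson_chi2 / self.df_resid
            self.bse = np.asarray(sm_results.bse, dtype=float) * math.sqrt(
                self.dispersion
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                self.tvalues = self.params / self.bse
            self.pvalues = 2.0 * stats.t.sf(np.abs(self.tvalues), df=self.df_resid)
        else:
            self.dispersion = math.nan
            self.bse = np.asarray(sm_results.bse, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                self.tvalues = self.params / self.bse
            self.pvalues = np.full_like(self.params, math.nan)

    @property
    def function(self) -> SurvivalFunction:
        return SurvivalFunction(
            intercept_logit=float(self.params[0]),
            slope=float(self.params[1]),
            intercept_se=float(self.bse[0]),
            slope_se=float(self.bse[1]),
            dispersion=self.dispersion,
            n_fit=self.nobs,
            link=self.model.link,
            density_scale=self.model.density_scale,
        )

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=self.df_resid)
        return np.column_stack(
            [self.params - tcrit * self.bse, self.params + tcrit * self.bse]
        )

    def summary(self) -> str:
        ci = self.conf_int()
        names = ["intercept", "density"]
        lines = [
            "Density-dependent survival model (quasibinomial, "
            f"{self.model.link} link, density {self.model.density_scale})",
            f"  n trials    {self.nobs}    df resid {self.df_resid}",
            f"  dispersion  {self.dispersion:.3f} (Pearson X2 {self.pearson_chi2:.2f})",
            f"  deviance    {self.deviance:.3f}",
            f"  {'term':<10}{'coef':>10}{'se':>10}{'t':>8}{'P>|t|':>10}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for i, name in enumerate(names):
            lines.append(
                f"  {name:<10}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.tvalues[i]:>8.2f}{self.pvalues[i]:>10.4g}"
                f"{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}"
            )
        s0 = self.function.survival_at(0.0)
        lines.append(f"  density-independent survival S(0) = {s0:.3f}")
        return "\n".join(lines)


def fit_survival_glm(
    trials: Iterable[LarvalTrial],
    density_scale: DensityScale = "per_plant",
    link: Link = "logit",
    tol: float = 1e-10,
    maxiter: int = 100,
) -> SurvivalFunction:
    """Fit the quasibinomial survival GLM and return the fitted curve."""
    model = DensitySurvivalModel.from_trials(trials, density_scale=density_scale, link=link)
    return model.fit(tol=tol, maxiter=maxiter).function


def curve_table(
    fn: SurvivalFunction,
    d_max: float = 5.0,
    step: float = 0.05,
) -> pd.DataFrame:
    """Tabulate S(d) and R(d) on a density grid (for plotting / export)."""
    d = np.arange(0.0, d_max + step / 2, step)
    return pd.DataFrame(
        {"density": d, "survival": fn.survival_at(d), "reduction": fn.reduction_at(d)}
    )
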
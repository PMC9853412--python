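"""Modified stretched exponential survival model with an age-dependent exponent.

The survival function is

    s(x) = exp[ -(x / alpha)^beta(x) ]

where ``alpha`` is the characteristic age, defined by ``s(alpha) = 1/e``
(identically, for every choice of exponent), and the stretched exponent
``beta(x)`` depends on age.  ``beta = 1`` recovers the simple exponential
with constant hazard ``1/alpha``; a constant ``beta != 1`` is the classical
stretched exponential (Weibull); larger ``beta`` means a more rectangular
survival curve.  At extreme ages (over 100 years) the exponent is well
described by a quadratic,

    beta(x) = b0 + b1*x + b2*x**2 ,

which is what this module fits.

A survival curve must be non-increasing.  Writing
``-ln s(x) = beta(x) * ln(x/alpha)``, the derivative ``ds/dx`` vanishes
exactly where

    beta(x) = gamma(x),      gamma(x) = -x * ln(x/alpha) * beta'(x) ,

so the smallest crossover of the fitted ``beta`` and ``gamma`` above
``alpha`` is the maximum mathematical lifespan ``omega``: beyond it the
fitted survival curve would (non-physically) increase.  ``solve_omega``
locates that crossover by sign-change bracketing plus bisection.

The Gompertz baseline ``mu(x) = a * exp(b*x)`` (log-linear hazard) is
provided as a diagnostic only — it is the model whose failure above age 100
motivates the age-dependent exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import overload

import numpy as np
from scipy.optimize import brentq

from .lifetable_io import SurvivalCurve

__all__ = [
    "E_INV",
    "StretchedExpFit",
    "GompertzFit",
    "BetaProfile",
    "OmegaEstimate",
    "ModelError",
    "NoCharacteristicAgeError",
    "InsufficientDataError",
    "UndefinedHazardError",
    "survival_at",
    "mortality_rate",
    "estimate_alpha",
    "extract_beta",
    "fit_beta_quadratic",
    "gamma_at",
    "solve_omega",
    "fit_gompertz",
    "rectangular_beta_approx",
]

#: The survival level defining the characteristic age: s(alpha) = 1/e.
E_INV = math.exp(-1.0)

#: |ln(x/alpha)| below this is treated as degenerate in beta extraction.
LOG_RATIO_TOL = 1e-6

#: s is usable for beta extraction only inside (S_LO_CLIP, 1 - S_HI_CLIP).
#: The upper margin is much wider than the lower one: near s = 1 the
#: inversion needs ln(-ln s), and float64 rounding of s destroys -ln s
#: when it is below ~1e-7 (the curve carries no exponent information there).
S_LO_CLIP = 1e-12
S_HI_CLIP = 1e-6


class ModelError(ValueError):
    """Invalid input to a model operation."""


class NoCharacteristicAgeError(ModelError):
    """The survival curve never crosses 1/e (no characteristic age)."""


class InsufficientDataError(ModelError):
    """Too few valid points for the requested fit."""


class UndefinedHazardError(ModelError):
    """Hazard undefined because survival is zero at an endpoint."""


@dataclass(frozen=True)
class StretchedExpFit:
    """Fitted stretched exponential: characteristic age plus quadratic exponent.

    Attributes
    ----------
    alpha : float
        Characteristic age in years, ``s(alpha) = 1/e``.
    b0, b1, b2 : float
        Quadratic exponent coefficients, ``beta(x) = b0 + b1*x + b2*x**2``
        (unitless, per-year, per-year**2).
    fit_window : (float, float)
        Half-open age window ``[x_lo, x_hi)`` over which the quadratic was
        fitted.
    n_points : int
        Number of ages used in the fit.
    residual_rms : float
        Root-mean-square residual of the quadratic fit (unitless).
    """

    alpha: float
    b0: float
    b1: float
    b2: float
    fit_window: tuple[float, float]
    n_points: int
    residual_rms: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ModelError(f"alpha must be positive, got {self.alpha}")
        x_lo, x_hi = self.fit_window
        if not x_lo < x_hi:
            raise ModelError(f"empty fit window {self.fit_window}")
        if self.n_points < 3:
            raise ModelError("a quadratic fit needs at least 3 points")
        xs = np.linspace(x_lo, x_hi, 64)
        if np.any(self.beta(xs) <= 0):
            raise ModelError("beta(x) must be positive over the fit window")

    def beta(self, x):
        """Quadratic exponent beta(x) = b0 + b1*x + b2*x**2."""
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * x * x

    def beta_prime(self, x):
        """d(beta)/dx = b1 + 2*b2*x."""
        x = np.asarray(x, dtype=float)
        return self.b1 + 2.0 * self.b2 * x


@dataclass(frozen=True)
class GompertzFit:
    """Gompertz hazard mu(x) = a*exp(b*x): baseline per-year hazard ``a`` and
    log-hazard slope ``b`` fitted over ``fit_window``."""

    a: float
    b: float
    fit_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ModelError(f"Gompertz baseline hazard a must be positive, got {self.a}")

    def hazard(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(self.b * x)


@dataclass
class BetaProfile:
    """Pointwise exponent values extracted from a survival curve.

    ``beta`` is defined (``valid_mask`` true) only where ``0 < s < 1`` away
    from the clip bounds and the age is not degenerate (``x`` near
    ``alpha``, where ``ln(x/alpha) = 0``, or ``x <= 0``).  Invalid entries
    hold 0.0, never NaN.
    """

    ages: np.ndarray
    beta: np.ndarray
    valid_mask: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not np.all(np.isfinite(self.beta[self.valid_mask])):
            raise ModelError("beta must be finite wherever valid")


@dataclass(frozen=True)
class OmegaEstimate:
    """Solved maximum mathematical lifespan for one fitted model.

    ``omega`` is NaN when the constraint ``beta = gamma`` has no root below
    ``search_bound`` (e.g. constant exponent: survival strictly decreasing
    everywhere) — an explicit outcome, not an error.
    """

    omega: float
    bracket: tuple[float, float] | None
    search_bound: float
    solver_tolerance: float
    residual: float

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.omega)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def survival_at(fit: StretchedExpFit, x):
    """Model survival s(x) = exp[-(x/alpha)^beta(x)] at age(s) ``x`` (years).

    ``survival_at(fit, fit.alpha)`` equals 1/e for every fit, since
    ``(alpha/alpha)^beta = 1`` regardless of the exponent.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ModelError("survival_at requires x > 0")
    out = np.exp(-((x / fit.alpha) ** fit.beta(x)))
    return float(out) if out.ndim == 0 else out


def mortality_rate(curve: SurvivalCurve | StretchedExpFit, x: float) -> float:
    """Hazard mu(x) = -d ln s / dx at age ``x``, per year.

    On a grid curve this is the forward difference
    ``-(ln s(x_next) - ln s(x)) / (x_next - x)``; for a fitted model it is
    the exact analytic derivative
    ``mu(x) = (x/alpha)^beta(x) * [beta'(x) ln(x/alpha) + beta(x)/x]``.
    """
    if isinstance(curve, StretchedExpFit):
        if x <= 0:
            raise ModelError("mortality_rate requires x > 0")
        fit = curve
        log_ratio = math.log(x / fit.alpha)
        power = (x / fit.alpha) ** float(fit.beta(x))
        return power * (float(fit.beta_prime(x)) * log_ratio + float(fit.beta(x)) / x)
    idx = np.nonzero(np.isclose(curve.ages, x))[0]
    if idx.size == 0 or idx[0] + 1 >= curve.ages.size:
        raise ModelError(f"age {x} (with a successor) not on the curve grid")
    i = int(idx[0])
    s0, s1 = curve.s[i], curve.s[i + 1]
    if s0 <= 0 or s1 <= 0:
        raise UndefinedHazardError(f"survival is zero at age {x} or its successor")
    return -(math.log(s1) - math.log(s0)) / (curve.ages[i + 1] - curve.ages[i])


# ---------------------------------------------------------------------------
# fitting: alpha, beta profile, quadratic exponent
# ---------------------------------------------------------------------------

def estimate_alpha(curve: SurvivalCurve) -> float:
    """Characteristic age: the crossover of s(x) with 1/e.

    Found by linear interpolation of s against age between the first grid
    pair bracketing 1/e.
    """
    s, ages = curve.s, curve.ages
    above = s[:-1] >= E_INV
    below = s[1:] <= E_INV
    hits = np.nonzero(above & below)[0]
    if hits.size == 0:
        raise NoCharacteristicAgeError(
            "survival curve does not cross 1/e: no characteristic age"
        )
    i = int(hits[0])
    drop = s[i] - s[i + 1]
    if drop == 0:  # flat exactly at 1/e
        return float(ages[i])
    return float(ages[i] + (s[i] - E_INV) / drop * (ages[i + 1] - ages[i]))


def extract_beta(curve: SurvivalCurve, alpha: float) -> BetaProfile:
    """Pointwise inversion beta(x) = ln(-ln s(x)) / ln(x/alpha).

    Ages where the inversion is degenerate — survival at 0 or 1 (within
    clip bounds), age at or below 0, or ``x`` so close to ``alpha`` that
    ``ln(x/alpha)`` vanishes — are masked invalid rather than propagated as
    NaN.
    """
    if alpha <= 0:
        raise ModelError(f"alpha must be positive, got {alpha}")
    ages, s = curve.ages, curve.s
    valid = (ages > 0) & (s > S_LO_CLIP) & (s < 1.0 - S_HI_CLIP)
    log_ratio = np.zeros_like(ages)
    np.log(ages / alpha, out=log_ratio, where=ages > 0)
    valid &= np.abs(log_ratio) > LOG_RATIO_TOL
    beta = np.zeros_like(ages)
    sv = s[valid]
    beta[valid] = np.log(-np.log(sv)) / log_ratio[valid]
    return BetaProfile(ages=ages, beta=beta, valid_mask=valid, alpha=alpha)


def fit_beta_quadratic(
    profile: BetaProfile,
    window: tuple[float, float] = (100.0, 110.0),
    weights: np.ndarray | None = None,
) -> StretchedExpFit:
    """Least-squares quadratic fit to the extracted exponent over a window.

    The window is half-open ``[x_lo, x_hi)`` so that with the default
    (100, 110) the open-interval row at age 110 — whose survival reflects a
    different exposure convention — is never used.  The fit is ordinary
    (unweighted) least squares unless ``weights`` is given.
    """
    x_lo, x_hi = window
    if not x_lo < x_hi:
        raise ModelError(f"empty fit window {window}")
    mask = profile.valid_mask & (profile.ages >= x_lo) & (profile.ages < x_hi)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"insufficient extreme-age data: {n} valid points in [{x_lo}, {x_hi})"
        )
    x = profile.ages[mask]
    y = profile.beta[mask]
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float)[mask])
    b0, b1, b2 = np.polynomial.polynomial.polyfit(x, y, 2, w=w)
    resid = y - (b0 + b1 * x + b2 * x * x)
    return StretchedExpFit(
        alpha=profile.alpha,
        b0=float(b0),
        b1=float(b1),
        b2=float(b2),
        fit_window=(float(x_lo), float(x_hi)),
        n_points=n,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# the monotonicity constraint and omega
# ---------------------------------------------------------------------------

def gamma_at(fit: StretchedExpFit, x):
    """Constraint function gamma(x) = -x * ln(x/alpha) * beta'(x).

    Survival decreases where ``beta(x) > gamma(x)``; ``ds/dx = 0`` exactly
    at ``beta = gamma``.  Identically zero for constant beta, and zero at
    ``x = alpha`` for any fit.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ModelError("gamma_at requires x > 0")
    out = -x * np.log(x / fit.alpha) * fit.beta_prime(x)
    return float(out) if out.ndim == 0 else out


def solve_omega(
    fit: StretchedExpFit,
    search_bound: float = 200.0,
    grid_step: float = 0.1,
    tolerance: float = 1e-6,
) -> OmegaEstimate:
    """Maximum mathematical lifespan: smallest root of beta(x) = gamma(x)
    above alpha.

    ``h(x) = beta(x) - gamma(x)`` is scanned on a grid of ``grid_step``
    years from just above ``alpha`` to ``search_bound``; the first sign
    change is refined by Brent bisection to ``tolerance`` years.  The
    smallest root is the physically meaningful one: survival monotonicity is
    violated from the first crossing onward.  No sign change up to the bound
    yields an explicit non-finite estimate (NaN omega), not an error.
    """
    if search_bound <= fit.alpha:
        raise ModelError(
            f"search_bound {search_bound} must exceed alpha {fit.alpha}"
        )

    def h(x):
        return fit.beta(x) - gamma_at(fit, x)

    xs = np.arange(fit.alpha + grid_step, search_bound + grid_step / 2, grid_step)
    xs = xs[xs <= search_bound]
    if xs.size < 2:
        xs = np.array([fit.alpha + tolerance, search_bound])
    hv = h(xs)
    sign_change = np.nonzero(hv[:-1] * hv[1:] <= 0)[0]
    if sign_change.size == 0:
        return OmegaEstimate(
            omega=math.nan,
            bracket=None,
            search_bound=search_bound,
            solver_tolerance=tolerance,
            residual=math.nan,
        )
    k = int(sign_change[0])
    lo, hi = float(xs[k]), float(xs[k + 1])
    if hv[k] == 0.0:
        omega = lo
    else:
        omega = float(brentq(h, lo, hi, xtol=tolerance))
    return OmegaEstimate(
        omega=omega,
        bracket=(lo, hi),
        search_bound=search_bound,
        solver_tolerance=tolerance,
        residual=float(h(omega)),
    )


# ---------------------------------------------------------------------------
# Gompertz baseline (diagnostic)
# ---------------------------------------------------------------------------

def fit_gompertz(
    curve: SurvivalCurve, window: tuple[float, float]
) -> GompertzFit:
    """Fit the Gompertz hazard mu(x) = a*exp(b*x) on a grid survival curve.

    Ordinary least squares of the log integrated hazard against age.  On a
    grid with spacing dx the forward difference gives the integrated hazard
    over [x, x+dx],  H(x) = (a/b) e^{bx} (e^{b dx} - 1),  whose log is
    exactly linear in x with slope b; the intercept is mapped back to ``a``
    through the (e^{b dx} - 1)/b factor, so exact Gompertz data are
    recovered to machine precision.  Diagnostic only: the log-linear hazard
    is the baseline whose failure above age 100 motivates the
    age-dependent-exponent model.
    """
    x_lo, x_hi = window
    ages, s = curve.ages, curve.s
    mask = (ages >= x_lo) & (ages < x_hi)
    idx = np.nonzero(mask[:-1])[0]  # need a successor on the grid
    usable = [i for i in idx if s[i] > 0 and s[i + 1] > 0]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"fewer than 2 usable hazard points in [{x_lo}, {x_hi})"
        )
    usable = np.array(usable)
    dxs = ages[usable + 1] - ages[usable]
    dx = float(dxs[0])
    if not np.allclose(dxs, dx):
        raise ModelError("Gompertz fit requires a uniformly spaced age grid")
    H = np.log(s[usable]) - np.log(s[usable + 1])  # integrated hazard
    if np.any(H <= 0):
        raise ModelError("non-positive integrated hazard in the fit window")
    slope, intercept = np.polyfit(ages[usable], np.log(H), 1)
    b = float(slope)
    if abs(b) < 1e-12:
        a = float(np.exp(intercept)) / dx
    else:
        a = float(np.exp(intercept)) * b / math.expm1(b * dx)
    return GompertzFit(a=a, b=b, fit_window=(float(x_lo), float(x_hi)))


def rectangular_beta_approx(x):
    """Rectangularity heuristic beta(x) ~ 7 / ln(x) — labelled diagnostic only.

    This closed form summarizes a fully rectangular curve (s ~ 1 below the
    characteristic age, ~ 0 above).  Its normalization is ambiguous — with
    x in plain years it gives beta ~ 1.5 near age 90, far below empirical
    extreme-age exponents — so it is exposed for plotting/inspection and is
    never used in fitting.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 1):
        raise ModelError("rectangular_beta_approx requires x > 1")
    out = 7.0 / np.log(x)
    return float(out) if out.ndim == 0 else out
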
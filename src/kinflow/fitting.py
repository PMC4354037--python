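"""Pre-steady-state kinetic analysis of product-formation data.

A rapid-quench experiment preincubates enzyme with primer/template, mixes in
nucleotide, quenches at a series of times and measures extended product.
Each concentration's time course is fit to a single exponential to obtain an
observed rate k_obs; the nucleotide-concentration dependence of k_obs follows
a hyperbola

    k_obs = k_max [S] / (K_d,app + [S])

yielding the maximal incorporation rate k_pol (= k_max) and the apparent
nucleotide dissociation constant K_d,app.  Mismatch incorporation cannot be
saturated experimentally, so its concentration dependence is fit to a line
whose slope is directly the specificity constant k_pol/K_d,app.  The ratio of
correct to mismatch specificity constants is the discrimination value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InputError

__all__ = [
    "ProductCurve",
    "ExpFit",
    "HyperbolicFit",
    "SpecificityResult",
    "fit_single_exponential",
    "fit_hyperbolic",
    "fit_linear_specificity",
    "specificity_and_discrimination",
]


@dataclass(frozen=True)
class ProductCurve:
    """Product (uM or fraction extended) versus time (s) at one nucleotide concentration."""

    times: np.ndarray
    product: np.ndarray
    nucleotide_conc: float = float("nan")
    label: Literal["correct", "mismatch"] = "correct"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.product, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "product", p)
        if t.ndim != 1 or t.shape != p.shape:
            raise InputError("times and product must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(p < 0):
            raise InputError("product must be >= 0")


@dataclass(frozen=True)
class ExpFit:
    amplitude: float
    rate: float
    offset: float
    residual_norm: float


@dataclass(frozen=True)
class HyperbolicFit:
    k_max: float
    kd_app: float
    k_max_se: float
    kd_app_se: float
    residual_norm: float


@dataclass(frozen=True)
class SpecificityResult:
    specificity_correct: float
    specificity_mismatch: float
    discrimination: float


def _rising_exp(t, A, k, C):
    return A * (1.0 - np.exp(-k * t)) + C


def _decaying_exp(t, A, k, C):
    return A * np.exp(-k * t) + C


def fit_single_exponential(
    curve: ProductCurve,
    *,
    form: Literal["rising", "decaying"] = "rising",
    n_starts: int = 12,
) -> ExpFit:
    """Least-squares single-exponential fit of a product time course.

    The default rising form ``A (1 - e^{-kt}) + C`` describes product
    accumulating to a plateau.  Initial rates are multi-started on a log grid
    spanning the sampled time scale; the rate is bounded positive.  A curve
    whose amplitude is negligible relative to its scale has no identifiable
    rate and raises :class:`FitError`.
    """
    t, y = curve.times, curve.product
    if t.size < 4:
        raise InputError("need at least 4 time points for an exponential fit")
    span = float(np.max(y) - np.min(y))
    scale = max(float(np.max(np.abs(y))), 1e-12)
    if span < 1e-9 * scale:
        raise FitError("amplitude ~ 0: exponential rate is unidentifiable on a constant curve")
    model = _rising_exp if form == "rising" else _decaying_exp
    t_pos = t[t > 0]
    k_lo, k_hi = 0.01 / t_pos[-1], 100.0 / t_pos[0]
    best = None
    for k0 in np.geomspace(k_lo, k_hi, n_starts):
        p0 = (span if form == "rising" else span, k0, float(y[0]) if form == "rising" else float(y[-1]))
        try:
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=p0,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(model(t, *popt) - y))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitError("single-exponential fit did not converge from any start")
    (A, k, C), resid = best
    if k <= 0:
        raise FitError(f"fitted rate is non-positive (k={k}); best residual {resid}")
    return ExpFit(amplitude=float(A), rate=float(k), offset=float(C), residual_norm=resid)


def fit_hyperbolic(
    concs: Sequence[float],
    rates: Sequence[float],
    *,
    n_starts: int = 8,
) -> HyperbolicFit:
    """Fit observed rates vs nucleotide concentration to k_max [S]/(K_d,app + [S]).

    Unweighted least squares with positivity bounds and multi-started K_d
    (log grid over the sampled concentration range).  Standard errors come
    from the covariance of the fit.
    """
    S = np.asarray(concs, dtype=float)
    k = np.asarray(rates, dtype=float)
    if S.shape != k.shape or S.ndim != 1:
        raise InputError("concs and rates must be 1-D arrays of equal length")
    if np.any(S <= 0):
        raise InputError("concentrations must be > 0")
    if np.unique(S).size < 3:
        raise InputError("need at least 3 distinct concentrations")
    if np.allclose(k, 0):
        raise FitError("all rates are zero; hyperbola is rank-deficient")

    def model(s, kmax, kd):
        return kmax * s / (kd + s)

    best = None
    for kd0 in np.geomspace(S.min() / 10.0, S.max() * 10.0, n_starts):
        try:
            popt, pcov = curve_fit(
                model,
                S,
                k,
                p0=(float(np.max(k)) or 1.0, kd0),
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(model(S, *popt) - k))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise FitError("hyperbolic fit did not converge from any start")
    (kmax, kd), pcov, resid = best
    if kmax <= 0 or kd <= 0:
        raise FitError(f"hyperbolic fit degenerate: k_max={kmax}, kd_app={kd}")
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return HyperbolicFit(
        k_max=float(kmax),
        kd_app=float(kd),
        k_max_se=float(se[0]),
        kd_app_se=float(se[1]),
        residual_norm=resid,
    )


def fit_linear_specificity(
    concs: Sequence[float],
    rates: Sequence[float],
) -> tuple[float, float]:
    """Ordinary least-squares line through (concentration, rate) points.

    Returns ``(slope, intercept)``; the slope is the specificity constant
    k_pol/K_d,app of a non-saturable (mismatch) incorporation, in 1/(uM s).
    """
    S = np.asarray(concs, dtype=float)
    k = np.asarray(rates, dtype=float)
    if S.shape != k.shape or S.ndim != 1:
        raise InputError("concs and rates must be 1-D arrays of equal length")
    if np.unique(S).size < 2:
        raise InputError("need at least 2 distinct concentrations for a slope")
    A = np.vstack([S, np.ones_like(S)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, k, rcond=None)
    return float(slope), float(intercept)


def specificity_and_discrimination(
    k_pol: float,
    kd_app: float,
    mismatch_slope: float,
) -> SpecificityResult:
    """Specificity constant k_pol/K_d,app and correct/mismatch discrimination."""
    if k_pol <= 0 or kd_app <= 0:
        raise InputError("k_pol and kd_app must be > 0")
    if mismatch_slope == 0:
        raise InputError("mismatch specificity is zero; discrimination undefined")
    spec_c = k_pol / kd_app
    return SpecificityResult(
        specificity_correct=spec_c,
        specificity_mismatch=mismatch_slope,
        discrimination=spec_c / mismatch_slope,
    )
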
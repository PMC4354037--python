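"""Mass-action model of polymerase/DNA-binding kinetics for base discrimination.

The sequencing chemistry modelled here reads out the *binding kinetics* of a
fluorescently labelled polymerase rather than labelled nucleotides.  The
minimal reaction scheme is

    E + Dn  <-- k1 / k-1 -->  E.Dn
    E.Dn + N  <-- k2 / k-2 -->  E.Dn.N
    E.Dn.N  -- k_pol -->  E.Dn+1
    E.Dn+1  -- k-1 -->  E + Dn+1

where ``E`` is free enzyme, ``Dn`` a primer/template with *n* bases
incorporated, ``N`` the flowed nucleotide and ``k_pol`` the committed
chemistry step.  Ground-state nucleotide binding and the induced-fit
conformational change are collapsed into one reversible step with an apparent
dissociation constant ``K_d,app = k-2 / k2``.  Post-chemistry steps
(translocation, PPi release) are treated as kinetically fast and omitted; the
post-chemistry complex dissociates at the DNA off-rate ``k-1``.

Every enzyme-bound species emits the same label signal, so the observable is
the *signal complex*

    SC = E.Dn + E.Dn.N + E.Dn+1

and ``%SC`` is the fraction of total enzyme residing in it.  A correct
nucleotide transiently stabilises SC through ternary-complex formation and
chemistry; a mismatch leaves SC at the two-state binding equilibrium.  At
high ionic strength (large ``k-1``) the two responses separate, which is the
physical basis of base calling.

Units throughout: concentrations in uM, time in s, first-order rates in 1/s,
second-order rates in 1/(uM s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DegenerateInputError, InputError, NumericalError, ParameterError

__all__ = [
    "RateConstants",
    "ReactionMix",
    "TimeCourse",
    "simulate_timecourse",
    "steady_state_percent_sc",
    "max_and_ss_amp",
    "parameter_scan",
    "fig2_rate_constants",
    "fig2_mix",
    "FIG2_FLUX",
]

#: Pseudo-first-order enzyme/DNA association flux (k1 * [Dn], 1/s) used for
#: the theory-figure regime.  Calibrated once so that the mismatch
#: steady-state %SC plateau equals 0.2 at k-1 = 500 1/s (0.2/0.8 * 500 = 125);
#: the underlying k1 and species concentrations are free parameters of the
#: model, only their product is constrained by the plateau.
FIG2_FLUX = 125.0

_REL_TOL_KD = 1e-9


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the minimal polymerase scheme.

    Parameters
    ----------
    k_on_dna : float
        Second-order polymerase/DNA association rate k1 (1/(uM s)).
    k_off_dna : float
        Polymerase/DNA dissociation rate k-1 (1/s).  Rises with ionic
        strength; the experimental tuning knob for base discrimination.
    k_on_nt : float
        Second-order nucleotide association rate k2 (1/(uM s)).
    k_off_nt : float
        Nucleotide dissociation rate k-2 (1/s).
    k_pol : float
        Committed incorporation (chemistry) rate (1/s).
    kd_app_nt : float
        Apparent nucleotide dissociation constant K_d,app = k-2/k2 (uM).
    """

    k_on_dna: float
    k_off_dna: float
    k_on_nt: float
    k_off_nt: float
    k_pol: float
    kd_app_nt: float

    def __post_init__(self) -> None:
        for name in ("k_on_dna", "k_off_dna", "k_on_nt", "k_off_nt", "k_pol", "kd_app_nt"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v!r}")
        expected = self.kd_app_nt * self.k_on_nt
        scale = max(abs(expected), abs(self.k_off_nt), 1e-300)
        if abs(expected - self.k_off_nt) > _REL_TOL_KD * scale:
            raise ParameterError(
                f"inconsistent nucleotide binding: kd_app_nt*k_on_nt={expected!r} "
                f"but k_off_nt={self.k_off_nt!r}"
            )

    @classmethod
    def from_kd(
        cls,
        *,
        k_on_dna: float,
        k_off_dna: float,
        k_pol: float,
        kd_app_nt: float,
        k_on_nt: float = 100.0,
    ) -> "RateConstants":
        """Build from K_d,app under the rapid-equilibrium convention.

        ``k_off_nt`` is derived as ``k_on_nt * kd_app_nt``.  The default
        ``k_on_nt = 100 1/(uM s)`` makes nucleotide-binding relaxation much
        faster than chemistry at the concentrations of interest, matching the
        collapsed one-step binding description.
        """
        return cls(
            k_on_dna=k_on_dna,
            k_off_dna=k_off_dna,
            k_on_nt=k_on_nt,
            k_off_nt=k_on_nt * kd_app_nt,
            k_pol=k_pol,
            kd_app_nt=kd_app_nt,
        )


@dataclass(frozen=True)
class ReactionMix:
    """Concentrations of the reaction, all in uM.

    ``is_correct`` tags whether the flowed nucleotide is the templated
    (correct) base; it selects which parameter set a caller pairs with the
    mix, and is carried through to outputs for bookkeeping.
    """

    enzyme_total: float
    dna_total: float
    nucleotide: float
    is_correct: bool = True

    def __post_init__(self) -> None:
        for name in ("enzyme_total", "dna_total", "nucleotide"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass
class TimeCourse:
    """Simulated species concentrations on a time grid.

    ``species`` maps names to concentration series (uM): ``"E"`` free enzyme,
    ``"D0".."Dn"`` free DNA with 0..n extra bases incorporated, ``"B0".."Bn"``
    binary complexes E.D_i (``Bn`` is the post-chemistry complex after the
    final incorporation), ``"T0".."Tn-1"`` ternary complexes E.D_i.N.
    ``sc_series`` is the summed signal complex and ``percent_sc_series`` its
    fraction of total enzyme.
    """

    time_grid: np.ndarray
    species: dict[str, np.ndarray]
    sc_series: np.ndarray
    percent_sc_series: np.ndarray
    n_incorporations: int
    rates: RateConstants
    mix: ReactionMix
    mode: str

    @property
    def free_enzyme(self) -> np.ndarray:
        return self.species["E"]

    @property
    def binary_complex(self) -> np.ndarray:
        """E.Dn (pre-incorporation binary complex)."""
        return self.species["B0"]

    @property
    def ternary_complex(self) -> np.ndarray:
        """E.Dn.N at the first incorporation stage."""
        return self.species["T0"]

    @property
    def post_chemistry_complex(self) -> np.ndarray:
        """E.Dn+k after the final chemistry step."""
        return self.species[f"B{self.n_incorporations}"]

    @property
    def released_product(self) -> np.ndarray:
        """Free, fully extended DNA."""
        return self.species[f"D{self.n_incorporations}"]

    @property
    def product_series(self) -> np.ndarray:
        """Total extended primer (at least one base incorporated), uM.

        This is the quantity a rapid-quench experiment measures: everything
        that is no longer the n-length substrate, bound or free.
        """
        unreacted = self.species["D0"] + self.species["B0"] + self.species["T0"]
        if self.mode == "clamped":
            raise DegenerateInputError("product is not tracked with clamped DNA")
        return self.mix.dna_total - unreacted


def _state_names(n: int) -> list[str]:
    return (
        ["E"]
        + [f"D{i}" for i in range(n + 1)]
        + [f"B{i}" for i in range(n + 1)]
        + [f"T{i}" for i in range(n)]
    )


def _build_system(
    rates: RateConstants,
    mix: ReactionMix,
    n: int,
    mode: str,
):
    """Return (rhs, jac, n_states) for the chain scheme with n incorporations.

    State vector: [E, D0..Dn, B0..Bn, T0..Tn-1].  Nucleotide is held at its
    total concentration (flowed in large excess over enzyme and templates).
    """
    k1, km1 = rates.k_on_dna, rates.k_off_dna
    kb = rates.k_on_nt * mix.nucleotide  # pseudo-first-order nt binding
    km2, kpol = rates.k_off_nt, rates.k_pol
    iE = 0
    iD = lambda i: 1 + i
    iB = lambda i: 2 + n + i
    iT = lambda i: 3 + 2 * n + i
    n_states = 3 + 3 * n
    if mode == "flow":
        bind_stages = list(range(n + 1))
    else:  # single_turnover / clamped: only unextended DNA associates
        bind_stages = [0]
    clamped = mode == "clamped"

    def rhs(_t, y):
        dy = np.zeros_like(y)
        E = y[iE]
        for i in range(n + 1):
            B = y[iB(i)]
            dy[iE] += km1 * B
            dy[iD(i)] += km1 * B
            dy[iB(i)] -= km1 * B
            if i in bind_stages:
                assoc = k1 * E * y[iD(i)]
                dy[iE] -= assoc
                dy[iD(i)] -= assoc
                dy[iB(i)] += assoc
            if i < n:
                T = y[iT(i)]
                f_on = kb * y[iB(i)]
                dy[iB(i)] += km2 * T - f_on
                dy[iT(i)] += f_on - (km2 + kpol) * T
                dy[iB(i + 1)] += kpol * T
        if clamped:
            dy[iD(0)] = 0.0
        return dy

    def jac(_t, y):
        J = np.zeros((n_states, n_states))
        E = y[iE]
        for i in range(n + 1):
            J[iE, iB(i)] += km1
            J[iD(i), iB(i)] += km1
            J[iB(i), iB(i)] -= km1
            if i in bind_stages:
                D = y[iD(i)]
                J[iE, iE] -= k1 * D
                J[iE, iD(i)] -= k1 * E
                J[iD(i), iE] -= k1 * D
                J[iD(i), iD(i)] -= k1 * E
                J[iB(i), iE] += k1 * D
                J[iB(i), iD(i)] += k1 * E
            if i < n:
                J[iB(i), iT(i)] += km2
                J[iB(i), iB(i)] -= kb
                J[iT(i), iB(i)] += kb
                J[iT(i), iT(i)] -= km2 + kpol
                J[iB(i + 1), iT(i)] += kpol
        if clamped:
            J[iD(0), :] = 0.0
        return J

    return rhs, jac, n_states


def simulate_timecourse(
    rates: RateConstants,
    mix: ReactionMix,
    t_grid: np.ndarray,
    *,
    n_incorporations: int = 1,
    mode: Literal["single_turnover", "flow", "clamped"] = "single_turnover",
    preincubated: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Integrate the reaction scheme and return species time courses.

    Parameters
    ----------
    rates, mix : parameter set and concentrations.
    t_grid : strictly increasing time grid starting at 0 (s).
    n_incorporations : number of chained chemistry stages; >1 models a
        homopolymer run where the enzyme incorporates the same base n times
        before the fully extended complex dissociates.
    mode : ``"single_turnover"`` forbids rebinding of (partially) extended
        DNA; ``"flow"`` allows the enzyme to rebind partially extended
        templates and to form a chemistry-dead binary complex on fully
        extended ones (the situation on a flow cell during one flow);
        ``"clamped"`` additionally holds free unextended DNA at its initial
        concentration (pseudo-first-order regime used for the theory figures
        and the analytic steady state).
    preincubated : start with the enzyme.DNA binary complex preformed
        (min(E, D) bound), as in a rapid-quench experiment where enzyme and
        DNA are mixed before the nucleotide.

    Notes
    -----
    The flowed nucleotide is assumed in excess and held constant, making the
    system linear whenever DNA is also effectively constant.  Integration is
    stiff-capable (BDF with analytic Jacobian).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise InputError("t_grid must be a 1-D array with at least two points")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise InputError("t_grid must start at 0 and be strictly increasing")
    if n_incorporations < 1:
        raise InputError("n_incorporations must be >= 1")
    n = int(n_incorporations)

    rhs, jac, n_states = _build_system(rates, mix, n, mode)
    y0 = np.zeros(n_states)
    if preincubated:
        bound = min(mix.enzyme_total, mix.dna_total)
        y0[0] = mix.enzyme_total - bound
        y0[1] = mix.dna_total - bound
        y0[2 + n] = bound
    else:
        y0[0] = mix.enzyme_total
        y0[1] = mix.dna_total

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method="BDF",
        jac=jac,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")

    names = _state_names(n)
    species = {name: sol.y[i] for i, name in enumerate(names)}
    sc = np.zeros_like(t_grid)
    for i in range(n + 1):
        sc = sc + species[f"B{i}"]
    for i in range(n):
        sc = sc + species[f"T{i}"]
    percent = sc / mix.enzyme_total if mix.enzyme_total > 0 else np.zeros_like(sc)
    return TimeCourse(
        time_grid=t_grid,
        species=species,
        sc_series=sc,
        percent_sc_series=percent,
        n_incorporations=n,
        rates=rates,
        mix=mix,
        mode=mode,
    )


def steady_state_percent_sc(rates: RateConstants, mix: ReactionMix) -> float:
    """Analytic long-time %SC in the pseudo-first-order (clamped-DNA) regime.

    With free DNA held at ``dna_total`` and nucleotide constant, the scheme is
    a linear four-state cycle whose stationary distribution has signal-complex
    odds

        SC/E = a (1 + r + k_pol r / k-1) / (k-1 + k_pol r),

    where ``a = k1 [Dn]`` is the association flux and
    ``r = k2 [N] / (k-2 + k_pol)`` the stationary ternary/binary ratio.  For
    a mismatch (k_pol ~ 0, weak nucleotide binding) this reduces to the
    two-state binding plateau a/(a + k-1).
    """
    if rates.k_off_dna <= 0:
        raise DegenerateInputError(
            "no steady state with free enzyme when k_off_dna == 0 (binding is absorbing)"
        )
    a = rates.k_on_dna * mix.dna_total
    denom_nt = rates.k_off_nt + rates.k_pol
    r = (rates.k_on_nt * mix.nucleotide / denom_nt) if denom_nt > 0 else 0.0
    odds = a * (1.0 + r + rates.k_pol * r / rates.k_off_dna) / (rates.k_off_dna + rates.k_pol * r)
    return odds / (1.0 + odds)


def max_and_ss_amp(
    series: np.ndarray,
    ss_window: int,
    *,
    smooth_window: int | None = None,
    eps: float = 1e-6,
) -> tuple[float, float, float]:
    """Maximum amplitude, steady-state amplitude and their ratio for a trace.

    ``ss_amp`` is operationalised as the mean over the trailing ``ss_window``
    samples (the tail of the flow, after the response has returned towards
    baseline); ``max_amp`` is the maximum of the series after an optional
    moving-average smoothing that suppresses shot noise.  The ratio uses an
    eps floor on ``ss_amp`` so that fully decayed traces yield a large but
    finite value.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InputError("empty series")
    if not (1 <= ss_window < series.size):
        raise InputError("require series length > ss_window >= 1")
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(int(smooth_window)) / float(smooth_window)
        smoothed = np.convolve(series, kernel, mode="same")
    else:
        smoothed = series
    max_amp = float(np.max(smoothed))
    ss_amp = float(np.mean(series[-ss_window:]))
    ratio = max_amp / max(ss_amp, eps)
    return max_amp, ss_amp, ratio


def fig2_rate_constants(
    k_off_dna: float = 500.0,
    *,
    k_pol: float = 9.0,
    kd_app_nt: float = 30.0,
    k_on_nt: float = 100.0,
    mismatch_kd_app_nt: float = 1e4,
    mismatch_specificity: float = 4.6e-6,
) -> tuple[RateConstants, RateConstants]:
    """Correct/mismatch parameter sets for the theory-figure regime.

    The correct nucleotide incorporates with ``k_pol = 9 1/s`` and
    ``K_d,app = 30 uM``; the mismatch binds non-saturably (large K_d,app) with
    an incorporation specificity constant (k_pol/K_d,app) of 4.6e-6 1/(uM s).
    Both share the DNA binding parameters; ``k_on_dna`` is chosen so that the
    association flux in :func:`fig2_mix` equals :data:`FIG2_FLUX`.
    """
    k_on_dna = FIG2_FLUX / _FIG2_DNA_TOTAL
    correct = RateConstants.from_kd(
        k_on_dna=k_on_dna,
        k_off_dna=k_off_dna,
        k_pol=k_pol,
        kd_app_nt=kd_app_nt,
        k_on_nt=k_on_nt,
    )
    mismatch = RateConstants.from_kd(
        k_on_dna=k_on_dna,
        k_off_dna=k_off_dna,
        k_pol=mismatch_specificity * mismatch_kd_app_nt,
        kd_app_nt=mismatch_kd_app_nt,
        k_on_nt=k_on_nt,
    )
    return correct, mismatch


_FIG2_DNA_TOTAL = 12.5  # uM; with k_on_dna above this sets the 125 1/s flux
_FIG2_ENZYME_TOTAL = 0.01  # uM; trace amounts keep the regime pseudo-first-order


def fig2_mix(nucleotide: float, *, is_correct: bool = True) -> ReactionMix:
    """Reaction mix for the theory-figure regime (clamped-DNA simulations)."""
    return ReactionMix(
        enzyme_total=_FIG2_ENZYME_TOTAL,
        dna_total=_FIG2_DNA_TOTAL,
        nucleotide=nucleotide,
        is_correct=is_correct,
    )


def _scan_t_grid(k_off_dna: float, n_points: int = 2000) -> np.ndarray:
    # long enough to reach steady state for the slowest mode of the regime
    t_end = 100.0 / k_off_dna + 2.0
    return np.linspace(0.0, t_end, n_points)


def parameter_scan(
    rates_correct: RateConstants,
    rates_mismatch: RateConstants,
    mix_base: ReactionMix,
    axis: Literal["k_off_dna", "nucleotide"],
    grid: np.ndarray,
    *,
    ss_window: int = 100,
) -> pd.DataFrame:
    """Scan %SC metrics over DNA off-rate or nucleotide concentration.

    Returns one row per grid value per nucleotide class with the maximum and
    steady-state %SC of the clamped-DNA time course and their ratio.  This
    reproduces the structure of the theory figures: at slow off-rates both
    classes saturate near 100% SC, while at fast off-rates the correct
    nucleotide sustains a much larger signal complex than the mismatch.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise InputError("grid must be non-empty and positive")
    if axis not in ("k_off_dna", "nucleotide"):
        raise InputError(f"unknown scan axis {axis!r}")
    rows = []
    for value in grid:
        for label, rates in (("correct", rates_correct), ("mismatch", rates_mismatch)):
            if axis == "k_off_dna":
                r = replace(rates, k_off_dna=float(value))
                mix = mix_base
            else:
                r = rates
                mix = replace(mix_base, nucleotide=float(value))
            tc = simulate_timecourse(r, mix, _scan_t_grid(r.k_off_dna), mode="clamped")
            max_amp, ss_amp, ratio = max_and_ss_amp(tc.percent_sc_series, ss_window)
            rows.append(
                {
                    "axis": axis,
                    "value": float(value),
                    "label": label,
                    "max_percent_sc": max_amp,
                    "steady_percent_sc": float(tc.percent_sc_series[-1]),
                    "ratio_max_ss": ratio,
                    "analytic_steady": steady_state_percent_sc(r, mix),
                }
            )
    return pd.DataFrame(rows)
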
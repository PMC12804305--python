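"""Whole-body decay kinetics and mother-daughter decay chains.

Two unrelated-but-neighbouring pieces of physics live here:

* **Effective half-life** — total activity retained in an animal versus time
  typically follows a one-phase or two-phase exponential. The effective decay
  rate combines physical decay and biological elimination
  (1/t_eff = 1/t_phys + 1/t_bio), so excreted tracers always show a shorter
  apparent half-life than the radionuclide's physical one.

* **Bateman ingrowth** — for alpha emitters whose gamma-quiet mother is
  quantified through a detectable daughter, the daughter activity follows

      A_d(t) = A_m(0) * lam_d/(lam_d - lam_m) * (exp(-lam_m t) - exp(-lam_d t)) * BR

  with the secular limit A_m(0) * (1 - exp(-lam_d t)) * BR when the mother is
  effectively stable, and transient equilibrium (parallel decay at ratio
  lam_d/(lam_d - lam_m) * BR) when the mother merely outlives the daughter.

Rates are per hour throughout this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitConvergenceError
from .nuclides import LN2, Nuclide, get_nuclide

#: AICc margin below which the simpler (one-phase) model is preferred
AICC_SIMPLER_MARGIN = 2.0

#: relative rate separation below which the degenerate Bateman limit is used
_DEGENERATE_EPS = 1e-12


# ---------------------------------------------------------------------------
# whole-body series and exponential fits


@dataclass
class WholeBodySeries:
    """Total-body activity of one animal versus time since injection."""

    animal_id: str
    t_hours: np.ndarray
    activity: np.ndarray  # MBq (or any consistent activity unit)

    def __post_init__(self) -> None:
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.t_hours.ndim != 1 or self.t_hours.shape != self.activity.shape:
            raise ValueError("t_hours and activity must be 1-D and equal length")
        if np.any(self.t_hours < 0):
            raise ValueError("times must be >= 0 h")
        if np.any(np.diff(self.t_hours) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activity < 0):
            raise ValueError("activities must be >= 0")


@dataclass
class DecayFitResult:
    """One- or two-phase exponential fit of a whole-body series."""

    model: str  # "one_phase" | "two_phase"
    amplitudes: tuple[float, ...]  # A0, or (A1, A2)
    rates: tuple[float, ...]  # 1/h; two-phase ordered fast, slow
    rss: float
    aicc: float
    t_half_biological: Optional[float] = None  # h

    @property
    def t_half_eff(self) -> tuple[float, ...]:
        """Effective half-life per phase, hours."""
        return tuple(LN2 / lam for lam in self.rates)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)  # exact fits: floor keeps the comparison finite
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _loglinear(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """log-linear regression init: returns (amplitude, rate)."""
    mask = a > 0
    if mask.sum() < 2:
        raise FitConvergenceError("need >= 2 positive activities to initialize")
    slope, intercept = np.polyfit(t[mask], np.log(a[mask]), 1)
    return float(np.exp(intercept)), float(max(-slope, 1e-9))


def _fit_one(t: np.ndarray, a: np.ndarray) -> DecayFitResult:
    a0, lam = _loglinear(t, a)
    popt, _ = curve_fit(
        lambda tt, A, l: A * np.exp(-l * tt), t, a, p0=[a0, lam],
        bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10000, xtol=1e-12,
        ftol=1e-14, gtol=1e-12)
    resid = a - popt[0] * np.exp(-popt[1] * t)
    rss = float(np.dot(resid, resid))
    return DecayFitResult(model="one_phase", amplitudes=(float(popt[0]),),
                          rates=(float(popt[1]),), rss=rss,
                          aicc=_aicc(rss, len(t), 2))


def _fit_two(t: np.ndarray, a: np.ndarray) -> DecayFitResult:
    # initialization by curve stripping: late points give the slow phase,
    # the early residual gives the fast phase
    mid = len(t) // 2
    a2, lam2 = _loglinear(t[mid:], a[mid:])
    early = a[:mid] - a2 * np.exp(-lam2 * t[:mid])
    try:
        a1, lam1 = _loglinear(t[:mid], np.clip(early, 1e-12, None))
    except FitConvergenceError:
        a1, lam1 = a2 * 0.5, lam2 * 10.0
    if lam1 <= lam2:
        lam1 = lam2 * 10.0

    def model(tt, A1, l1, A2, l2):
        return A1 * np.exp(-l1 * tt) + A2 * np.exp(-l2 * tt)

    popt, _ = curve_fit(model, t, a, p0=[a1, lam1, a2, lam2],
                        bounds=([0.0, 1e-12, 0.0, 1e-12],
                                [np.inf, np.inf, np.inf, np.inf]),
                        maxfev=20000, xtol=1e-12, ftol=1e-14, gtol=1e-12)
    A1, l1, A2, l2 = (float(v) for v in popt)
    if l1 < l2:  # order phases fast-first
        A1, l1, A2, l2 = A2, l2, A1, l1
    resid = a - model(t, A1, l1, A2, l2)
    rss = float(np.dot(resid, resid))
    return DecayFitResult(model="two_phase", amplitudes=(A1, A2),
                          rates=(l1, l2), rss=rss, aicc=_aicc(rss, len(t), 4))


def fit_effective_half_life(
    series: WholeBodySeries,
    model: str = "auto",
    nuclide: Optional[Nuclide | str] = None,
) -> DecayFitResult:
    """Fit a one- or two-phase exponential to a whole-body series.

    ``model="auto"`` fits both and keeps the two-phase model only when its
    AICc improves on the one-phase model by more than 2 units — in the
    absence of other evidence the simplest model is preferred. Supplying a
    ``nuclide`` adds the biological half-life via
    1/t_bio = 1/t_eff - 1/t_phys (terminal phase) when t_eff < t_phys.
    """
    t, a = series.t_hours, series.activity
    if model not in ("auto", "one_phase", "two_phase"):
        raise ValueError(f"unknown model {model!r}")
    if len(t) < 3:
        raise ValueError("one-phase fit needs >= 3 points")
    if model == "two_phase" and len(t) < 5:
        raise ValueError("two-phase fit needs >= 5 points")

    try:
        one = _fit_one(t, a)
    except (RuntimeError, FitConvergenceError) as exc:
        raise FitConvergenceError(
            f"one-phase fit failed to converge ({exc}); log-linear "
            "initialization may be degenerate") from exc

    result: DecayFitResult
    if model == "one_phase":
        result = one
    else:
        two = None
        if len(t) >= 5:
            try:
                two = _fit_two(t, a)
            except (RuntimeError, FitConvergenceError):
                two = None
        if model == "two_phase":
            if two is None:
                raise FitConvergenceError("two-phase fit failed to converge")
            result = two
        else:  # auto: simpler unless clearly better
            if two is not None and two.aicc < one.aicc - AICC_SIMPLER_MARGIN:
                result = two
            else:
                result = one

    if nuclide is not None:
        t_phys = get_nuclide(nuclide).half_life_hours
        t_eff = result.t_half_eff[-1]  # terminal phase
        if t_eff < t_phys:
            result.t_half_biological = 1.0 / (1.0 / t_eff - 1.0 / t_phys)
    return result


# ---------------------------------------------------------------------------
# Bateman mother-daughter chain


@dataclass
class BatemanSystem:
    """One mother-daughter pair: initial mother activity, rates, branching."""

    A_m0: float  # mother activity at t=0, any unit
    lambda_m: float  # 1/h
    lambda_d: float  # 1/h
    BR: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_d <= 0:
            raise ValueError("lambda_d must be positive")
        if self.lambda_m < 0:
            raise ValueError("lambda_m must be >= 0")
        if not (0.0 <= self.BR <= 1.0):
            raise ValueError("branching ratio must be in [0, 1]")

    @classmethod
    def from_nuclides(cls, mother: str | Nuclide, daughter: str | Nuclide,
                      A_m0: float = 1.0,
                      BR: Optional[float] = None) -> "BatemanSystem":
        """Build from database nuclides; BR defaults to the chain entry
        (effective BR 1.0 for a daughter reached through short-lived links)."""
        m = get_nuclide(mother)
        d = get_nuclide(daughter)
        if BR is None:
            BR = dict(m.daughters).get(d.id, 1.0)
        return cls(A_m0=A_m0, lambda_m=m.lam_per_hour,
                   lambda_d=d.lam_per_hour, BR=BR)

    def mother_activity(self, t: float) -> float:
        return self.A_m0 * math.exp(-self.lambda_m * t)


def bateman_daughter(sys: BatemanSystem, t: float | np.ndarray):
    """Daughter activity A_d(t) grown in from an initially pure mother.

    Near-degenerate rates (|lam_d - lam_m| < 1e-12 * lam_d) switch to the
    analytic limit A_m0 * lam * t * exp(-lam * t) * BR.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lm, ld = sys.lambda_m, sys.lambda_d
    if abs(ld - lm) < _DEGENERATE_EPS * ld:
        out = sys.A_m0 * ld * t * np.exp(-ld * t) * sys.BR
    else:
        out = (sys.A_m0 * ld / (ld - lm)
               * (np.exp(-lm * t) - np.exp(-ld * t)) * sys.BR)
    return float(out) if out.ndim == 0 else out


def secular_daughter(A_m0: float, lambda_d: float, BR: float,
                     t: float | np.ndarray):
    """Secular-equilibrium ingrowth: A_m0 * (1 - exp(-lam_d t)) * BR.

    Valid when the mother is so long-lived that lam_m ~ 0; the daughter
    reaches half the mother activity after one daughter half-life and
    asymptotes to A_m0 * BR (~equal after about five half-lives).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = A_m0 * (1.0 - np.exp(-lambda_d * t)) * BR
    return float(out) if out.ndim == 0 else out


def time_to_equilibrium(lambda_d: float, fraction: float = 0.99) -> float:
    """Time for the daughter to reach ``fraction`` of its secular asymptote."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if lambda_d <= 0:
        raise ValueError("lambda_d must be positive")
    return -math.log1p(-fraction) / lambda_d


def transient_ratio(lambda_m: float, lambda_d: float, BR: float = 1.0) -> float:
    """Asymptotic A_d/A_m under transient equilibrium: lam_d/(lam_d-lam_m)*BR."""
    if lambda_d <= lambda_m:
        raise ValueError(
            "transient equilibrium requires lambda_d > lambda_m "
            "(the mother must outlive the daughter)")
    if lambda_m < 0:
        raise ValueError("lambda_m must be >= 0")
    return lambda_d / (lambda_d - lambda_m) * BR


def daughter_peak_time(lambda_m: float, lambda_d: float) -> float:
    """Time of the daughter-activity maximum, ln(lam_d/lam_m)/(lam_d-lam_m)."""
    if not 0 < lambda_m < lambda_d:
        raise ValueError("requires 0 < lambda_m < lambda_d")
    return math.log(lambda_d / lambda_m) / (lambda_d - lambda_m)


def mother_from_daughter(A_d_measured: float, t_since_separation: float,
                         lambda_m: float, lambda_d: float,
                         BR: float = 1.0) -> float:
    """Invert the Bateman ingrowth: estimate A_m(0) from a daughter reading.

    At large ``t`` this reduces to dividing by the equilibrium ratio. Times so
    short that the predicted daughter response is below 1e-6 of its
    asymptote are rejected as ill-conditioned.
    """
    unit = BatemanSystem(A_m0=1.0, lambda_m=lambda_m, lambda_d=lambda_d, BR=BR)
    response = bateman_daughter(unit, t_since_separation)
    if response <= 1e-6 * BR:
        raise ValueError(
            f"t = {t_since_separation} h is too early: daughter ingrowth "
            f"({response:.3g} per unit mother) is ill-conditioned for inversion")
    return A_d_measured / response
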
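"""Weighed-standard calibration: CPM per gram of injected formulation.

The counting standard converts the injected *mass* of formulation into
counter units. One extra syringe is emptied into ~10 mL of water; aliquots
of that stock are gamma-counted next to the tissues. Each aliquot contains a
known mass fraction of the delivered standard, so its background-subtracted
CPM divided by its formulation mass gives a calibration factor in
CPM g^-1 of formulation at the shared counting reference time. When
dose-calibrator readings of the standard syringe exist, the factor is also
expressed in CPM MBq^-1 as a cross-check.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import CountingQualityWarning
from .nuclides import Nuclide, decay_correct
from .study import CountingSample, StandardStock, SyringeRecord, tissue_mass

#: replicate-scatter advisory threshold (percent CV across standard aliquots)
CV_WARN_PERCENT = 5.0


@dataclass
class CalibrationResult:
    """Calibration factor and its provenance.

    ``cf_mass`` is the mean over standard aliquots of
    ``(cpm_i - background) / formulation_mass_i`` in CPM per gram of injected
    formulation at the counting reference time. ``cf_activity`` (CPM MBq^-1)
    is present when the standard syringe carries dose-calibrator readings.
    """

    cf_mass: float
    per_standard_cf: list[float]
    cv: float  # percent
    background_cpm: float
    standard_mass_delivered: float  # g
    stock_total_mass: float  # g
    cf_activity: Optional[float] = None  # CPM / MBq
    activity_delivered_MBq: Optional[float] = None  # at t_ref

    def __post_init__(self) -> None:
        if self.cf_mass <= 0:
            raise ValueError("cf_mass must be positive")


def background_cpm(samples: Sequence[CountingSample] | Sequence[float],
                   method: str = "mean") -> float:
    """Aggregate background tubes to one CPM value (mean by default)."""
    values = [s.cpm if isinstance(s, CountingSample) else float(s)
              for s in samples]
    if not values:
        raise ValueError("no background samples")
    if len(values) < 3:
        warnings.warn(
            f"only {len(values)} background replicate(s); quadruplicate "
            "counting recommended", CountingQualityWarning, stacklevel=2)
    if method == "mean":
        return float(np.mean(values))
    if method == "median":
        return float(np.median(values))
    raise ValueError(f"unknown background policy {method!r}")


def standard_mass_delivered(std_syringe: SyringeRecord) -> float:
    """Formulation mass the standard syringe delivered into the stock, g."""
    if std_syringe.role != "standard":
        raise ValueError(
            f"syringe {std_syringe.syringe_id!r} has role "
            f"{std_syringe.role!r}, expected 'standard'")
    m = std_syringe.injected_mass
    if m <= 0:
        raise ValueError(
            f"syringe {std_syringe.syringe_id!r}: delivered mass {m} g <= 0")
    return m


def aliquot_formulation_mass(aliquot_mass: float, std_mass: float,
                             stock_total: float) -> float:
    """Formulation mass in one counted aliquot, by mass-fraction dilution."""
    if aliquot_mass <= 0:
        raise ValueError("aliquot mass must be positive")
    if aliquot_mass > stock_total:
        raise ValueError(
            f"aliquot mass {aliquot_mass} g exceeds stock total {stock_total} g")
    if not 0 < std_mass < stock_total:
        raise ValueError("standard mass must be in (0, stock_total)")
    return std_mass * aliquot_mass / stock_total


def calibration_factor(
    standards: Sequence[CountingSample],
    stock: StandardStock,
    std_syringe: SyringeRecord,
    background: float,
    nuclide: Optional[Nuclide] = None,
    t_ref: Optional[datetime] = None,
) -> CalibrationResult:
    """Compute the calibration factor from counted standard aliquots.

    All aliquot CPM values are assumed decay-corrected by the counter to the
    shared reference time. ``cf_activity`` is added when the standard
    syringe's before/after dose-calibrator readings, a nuclide, and ``t_ref``
    are all available; it is a cross-check on the mass-based factor, never a
    replacement.
    """
    if not standards:
        raise ValueError("no standard aliquots")
    if len(standards) < 4:
        warnings.warn(
            f"only {len(standards)} standard aliquot(s); at least 4 expected",
            CountingQualityWarning, stacklevel=2)

    std_mass = standard_mass_delivered(std_syringe)
    stock_total = stock.stock_total_mass
    per_cf = []
    for s in standards:
        aliquot = tissue_mass(s)
        f_mass = aliquot_formulation_mass(aliquot, std_mass, stock_total)
        net = s.cpm - background
        if net <= 0:
            raise ValueError(
                f"tube {s.tube_id!r}: background ({background:.1f} CPM) is not "
                f"below the standard counts ({s.cpm:.1f} CPM)")
        per_cf.append(net / f_mass)

    cf_mass = float(np.mean(per_cf))
    cv = (100.0 * statistics.stdev(per_cf) / cf_mass) if len(per_cf) > 1 else 0.0
    if cv > CV_WARN_PERCENT:
        warnings.warn(
            f"standard aliquot CV {cv:.1f}% exceeds {CV_WARN_PERCENT}% — check "
            "pipetting/weighing of the counting standards",
            CountingQualityWarning, stacklevel=2)

    cf_activity = None
    a_delivered = None
    if (nuclide is not None and t_ref is not None
            and std_syringe.activity_before is not None
            and std_syringe.activity_after is not None
            and std_syringe.t_activity_before is not None
            and std_syringe.t_activity_after is not None):
        a_before = decay_correct(std_syringe.activity_before,
                                 std_syringe.t_activity_before, t_ref, nuclide)
        a_after = decay_correct(std_syringe.activity_after,
                                std_syringe.t_activity_after, t_ref, nuclide)
        a_delivered = a_before - a_after
        if a_delivered > 0:
            cf_activity = cf_mass * std_mass / a_delivered

    return CalibrationResult(
        cf_mass=cf_mass, per_standard_cf=per_cf, cv=cv,
        background_cpm=background, standard_mass_delivered=std_mass,
        stock_total_mass=stock_total, cf_activity=cf_activity,
        activity_delivered_MBq=a_delivered)


@dataclass
class LinearityResult:
    slope: float
    relative_residuals: list[float]
    max_relative_deviation: float
    tolerance: float
    passed: bool


def linearity_check(
    dilution_series: Iterable[tuple[float, float]],
    tolerance: float = 0.05,
) -> LinearityResult:
    """Check counter linearity over a serial-dilution series.

    Fits a least-squares line through the origin to
    (expected relative activity, measured CPM) and reports each point's
    relative residual. Daily drift of counter calibration shows up here as
    curvature that would otherwise underestimate high-activity organs.
    """
    pts = [(float(x), float(y)) for x, y in dilution_series]
    if len(pts) < 3:
        raise ValueError("linearity check needs at least 3 dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(x <= 0):
        raise ValueError("expected relative activities must be positive")
    slope = float(np.dot(x, y) / np.dot(x, x))
    rel = ((y - slope * x) / (slope * x)).tolist()
    max_dev = float(np.max(np.abs(rel)))
    return LinearityResult(slope=slope, relative_residuals=rel,
                           max_relative_deviation=max_dev,
                           tolerance=tolerance, passed=max_dev <= tolerance)
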
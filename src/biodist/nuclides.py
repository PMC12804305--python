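"""Radionuclide constants and decay correction.

The package ships a versioned plain-text table of radionuclide half-lives,
principal gamma emissions and immediate decay-chain daughters. Labels are
normalized aggressively ("89Zr", "Zr-89" and "zr89" all resolve to the same
entry). Decay correction rescales any activity-like quantity (MBq, CPM, ...)
to a common reference time with the exponential decay law; it is unit-agnostic
and purely multiplicative.
"""

from __future__ import annotations

import csv
import difflib
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from functools import lru_cache
from importlib import resources

from ._time import elapsed_seconds
from .errors import DecayRangeError, NuclideLookupError

NUCLIDE_TABLE_VERSION = "2026.1"

LN2 = math.log(2.0)

_UNIT_SECONDS = {
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "d": 86400.0,
    "y": 365.25 * 86400.0,
}

# largest |lambda * dt| before exp() under/overflows a double
_EXP_GUARD = 700.0


@dataclass(frozen=True)
class Nuclide:
    """One radionuclide: half-life, gamma lines, immediate daughters.

    Attributes
    ----------
    id : canonical ``Element-MassNumber`` label, e.g. ``"Zr-89"``.
    half_life_value, half_life_unit : half-life as stored (unit preserved).
    emissions : tuple of ``(energy_keV, intensity_percent)``.
    daughters : tuple of ``(daughter_id, branching_ratio)``.
    """

    id: str
    half_life_value: float
    half_life_unit: str
    emissions: tuple[tuple[float, float], ...] = field(default=())
    daughters: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.half_life_value <= 0:
            raise ValueError(f"{self.id}: half-life must be positive")
        if self.half_life_unit not in _UNIT_SECONDS:
            raise ValueError(
                f"{self.id}: unknown half-life unit {self.half_life_unit!r}"
            )
        for energy, intensity in self.emissions:
            if not (0.0 <= intensity <= 100.0):
                raise ValueError(f"{self.id}: intensity {intensity} outside [0, 100]")
            if energy <= 0:
                raise ValueError(f"{self.id}: non-positive emission energy")
        for dau, br in self.daughters:
            if not (0.0 <= br <= 1.0):
                raise ValueError(f"{self.id}: branching ratio {br} outside [0, 1]")

    @property
    def half_life_seconds(self) -> float:
        return self.half_life_value * _UNIT_SECONDS[self.half_life_unit]

    @property
    def half_life_hours(self) -> float:
        return self.half_life_seconds / 3600.0

    @property
    def lam(self) -> float:
        """Decay constant ln2 / t_half, in 1/s."""
        return LN2 / self.half_life_seconds

    @property
    def lam_per_hour(self) -> float:
        return LN2 / self.half_life_hours


_LABEL_RE = re.compile(r"^\s*(?:([A-Za-z]{1,2})[-_ ]?(\d{1,3})(m?)|(\d{1,3})(m?)[-_ ]?([A-Za-z]{1,2}))\s*$")


def normalize_id(label: str) -> str:
    """Canonicalize a nuclide label to ``Element-MassNumber`` form.

    Accepts element-first ("Zr-89", "zr89") and mass-first ("89Zr") forms,
    with an optional metastable ``m`` suffix ("Tc-99m", "99mTc").
    """
    m = _LABEL_RE.match(str(label))
    if not m:
        raise NuclideLookupError(str(label))
    if m.group(1):
        elem, mass, meta = m.group(1), m.group(2), m.group(3)
    else:
        mass, meta, elem = m.group(4), m.group(5), m.group(6)
    return f"{elem.capitalize()}-{int(mass)}{meta.lower()}"


def _parse_pairs(cell: str, sep_item: str = ";", sep_kv: str = ":"):
    if not cell:
        return ()
    out = []
    for item in cell.split(sep_item):
        k, v = item.split(sep_kv)
        out.append((k.strip(), float(v)))
    return tuple(out)


@lru_cache(maxsize=1)
def _database() -> dict[str, Nuclide]:
    db: dict[str, Nuclide] = {}
    path = resources.files("biodist.data").joinpath("nuclides.csv")
    with path.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            emissions = tuple(
                (float(k), v) for k, v in _parse_pairs(row["emissions"])
            )
            daughters = _parse_pairs(row["daughters"])
            nuc = Nuclide(
                id=row["id"],
                half_life_value=float(row["half_life_value"]),
                half_life_unit=row["half_life_unit"],
                emissions=emissions,
                daughters=daughters,
            )
            db[nuc.id] = nuc
    return db


def list_nuclides() -> list[Nuclide]:
    """All database entries, sorted by label."""
    return sorted(_database().values(), key=lambda n: n.id)


def get_nuclide(label: str | Nuclide) -> Nuclide:
    """Look up a nuclide by label, normalizing common formats.

    Raises :class:`NuclideLookupError` naming the nearest known labels when
    the entry is absent.
    """
    if isinstance(label, Nuclide):
        return label
    db = _database()
    try:
        canon = normalize_id(label)
    except NuclideLookupError:
        canon = str(label)
    try:
        return db[canon]
    except KeyError:
        suggestions = tuple(difflib.get_close_matches(canon, db.keys(), n=3))
        raise NuclideLookupError(str(label), suggestions) from None


def decay_correct(
    value: float,
    t_meas: str | datetime,
    t_ref: str | datetime,
    nuclide: str | Nuclide,
) -> float:
    """Rescale an activity-like quantity measured at ``t_meas`` to ``t_ref``.

    Returns ``value * exp(-lambda * (t_ref - t_meas))``: forward correction
    (reference later than measurement) shrinks the value, back correction
    grows it. Unit-agnostic (MBq, CPM, ...).
    """
    if value < 0:
        raise ValueError(f"activity-like value must be >= 0, got {value}")
    nuc = get_nuclide(nuclide)
    dt = elapsed_seconds(t_ref, t_meas)
    if dt == 0.0:
        return value
    x = nuc.lam * dt
    if x > _EXP_GUARD:
        return 0.0  # decayed beyond double precision
    if x < -_EXP_GUARD:
        raise DecayRangeError(
            f"back-correction over {-x:.0f} mean-lives overflows ({nuc.id})"
        )
    return value * math.exp(-x)
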
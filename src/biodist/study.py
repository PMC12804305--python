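"""Study sheets: data model, readers/writers, validation.

A biodistribution study is captured in three delimited-text sheets plus a
JSON configuration:

* ``syringes.csv``   — one row per drawn syringe (animal doses and the
  counting standard): full/empty weighings with times, optional
  dose-calibrator readings before and after injection.
* ``injections.csv`` — one row per animal: which syringe, when, body weight,
  group, exclusion flag, optional manual injected-activity override.
* ``samples.csv``    — one row per gamma-counted tube (background, counting
  standard aliquots, tissues): tube weighings and counter CPM, all
  decay-corrected by the counter to the shared start of the counting protocol.

Validation is total: reading a malformed bundle produces a report listing
every violation found, never just the first.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd

from ._time import parse_timestamp
from .errors import BiodistWarning, StudyValidationError
from .nuclides import get_nuclide

#: Default controlled vocabulary of collected tissues (typical mouse panel,
#: in the recommended collection order).
DEFAULT_TISSUE_VOCABULARY = (
    "blood", "tumor", "gallbladder", "heart", "lung", "liver", "spleen",
    "pancreas", "stomach", "small intestine", "large intestine",
    "adrenal gland", "kidney", "fat", "urine", "muscle", "bone", "brain",
    "tail", "skin",
)

SYRINGE_COLUMNS = [
    "syringe_id", "role", "mass_full_g", "t_weigh_full", "mass_empty_g",
    "t_weigh_empty", "activity_before_MBq", "t_activity_before",
    "activity_after_MBq", "t_activity_after", "comment",
]
INJECTION_COLUMNS = [
    "animal_id", "syringe_id", "group", "t_injection", "body_weight_g",
    "exclusion_flag", "manual_injected_activity_override_MBq", "comment",
]
SAMPLE_COLUMNS = [
    "tube_id", "role", "animal_id", "tissue_name", "tube_empty_mass_g",
    "tube_full_mass_g", "cpm", "t_count_ref",
]


# ---------------------------------------------------------------------------
# records


@dataclass
class SyringeRecord:
    """Weighed-mass and activity bookkeeping for one drawn syringe."""

    syringe_id: str
    role: str  # "animal" | "standard"
    mass_full: float  # g, loaded syringe
    t_weigh_full: datetime
    mass_empty: float  # g, after injection (tare + residual)
    t_weigh_empty: datetime
    activity_before: Optional[float] = None  # MBq, dose calibrator
    t_activity_before: Optional[datetime] = None
    activity_after: Optional[float] = None  # MBq, residual
    t_activity_after: Optional[datetime] = None
    comment: str = ""

    @property
    def injected_mass(self) -> float:
        """Delivered formulation mass in g (full minus emptied weighing)."""
        return self.mass_full - self.mass_empty


@dataclass
class InjectionRecord:
    """One administered dose: animal, syringe, time, body weight, group."""

    animal_id: str
    syringe_id: str
    group: str
    t_injection: datetime
    body_weight: float  # g
    exclusion_flag: bool = False
    manual_injected_activity_override: Optional[float] = None  # MBq at t_ref
    comment: str = ""


@dataclass
class StandardStock:
    """The weighed-standard dilution: tube, ~10 mL water, spiked standard."""

    tube_empty: float  # g
    tube_plus_water: float  # g
    tube_plus_water_plus_standard: float  # g
    standard_syringe_id: str
    t_spike: datetime

    @property
    def water_mass(self) -> float:
        return self.tube_plus_water - self.tube_empty

    @property
    def stock_total_mass(self) -> float:
        """Total stock solution mass (water + delivered standard), g."""
        return self.tube_plus_water_plus_standard - self.tube_empty


@dataclass
class CountingSample:
    """One gamma-counted tube (background, standard aliquot, or tissue)."""

    tube_id: str
    role: str  # "background" | "standard" | "tissue"
    tube_empty_mass: float  # g, tube + cap
    tube_full_mass: float  # g
    cpm: float  # decay-corrected by the counter to t_count_ref
    t_count_ref: datetime
    animal_id: Optional[str] = None
    tissue_name: Optional[str] = None

    @property
    def content_mass(self) -> float:
        return self.tube_full_mass - self.tube_empty_mass


@dataclass
class StudyConfig:
    """Study-level configuration resolved once per analysis."""

    nuclide_id: str
    background_policy: str = "mean"  # "mean" | "median"
    negative_net_policy: str = "flag"  # "flag" | "clamp"
    tissue_vocabulary: tuple[str, ...] = DEFAULT_TISSUE_VOCABULARY
    molar_activity: Optional[float] = None  # GBq / umol
    counter_ceiling_cpm: Optional[float] = None  # linear-range ceiling
    spillover_fraction: float = 0.0  # user-supplied down-scatter fraction
    targets: tuple[str, ...] = ()
    backgrounds: tuple[str, ...] = ()
    stock: Optional[StandardStock] = None

    _POLICIES = {"background_policy": ("mean", "median"),
                 "negative_net_policy": ("flag", "clamp")}

    def validate(self) -> list[str]:
        problems = []
        try:
            get_nuclide(self.nuclide_id)
        except Exception as exc:
            problems.append(f"config: {exc}")
        for attr, allowed in self._POLICIES.items():
            if getattr(self, attr) not in allowed:
                problems.append(
                    f"config: {attr}={getattr(self, attr)!r} not in {allowed}")
        if not (0.0 <= self.spillover_fraction < 1.0):
            problems.append("config: spillover_fraction outside [0, 1)")
        return problems

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "nuclide": self.nuclide_id,
            "background_policy": self.background_policy,
            "negative_net_policy": self.negative_net_policy,
            "tissue_vocabulary": list(self.tissue_vocabulary),
            "molar_activity_GBq_per_umol": self.molar_activity,
            "counter_ceiling_cpm": self.counter_ceiling_cpm,
            "spillover_fraction": self.spillover_fraction,
            "targets": list(self.targets),
            "backgrounds": list(self.backgrounds),
        }
        if self.stock is not None:
            d["stock"] = {
                "tube_empty_g": self.stock.tube_empty,
                "tube_plus_water_g": self.stock.tube_plus_water,
                "tube_plus_water_plus_standard_g":
                    self.stock.tube_plus_water_plus_standard,
                "standard_syringe_id": self.stock.standard_syringe_id,
                "t_spike": self.stock.t_spike.isoformat(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        stock = None
        if d.get("stock"):
            s = d["stock"]
            stock = StandardStock(
                tube_empty=float(s["tube_empty_g"]),
                tube_plus_water=float(s["tube_plus_water_g"]),
                tube_plus_water_plus_standard=float(
                    s["tube_plus_water_plus_standard_g"]),
                standard_syringe_id=str(s["standard_syringe_id"]),
                t_spike=parse_timestamp(s["t_spike"]),
            )
        return cls(
            nuclide_id=d["nuclide"],
            background_policy=d.get("background_policy", "mean"),
            negative_net_policy=d.get("negative_net_policy", "flag"),
            tissue_vocabulary=tuple(
                d.get("tissue_vocabulary", DEFAULT_TISSUE_VOCABULARY)),
            molar_activity=d.get("molar_activity_GBq_per_umol"),
            counter_ceiling_cpm=d.get("counter_ceiling_cpm"),
            spillover_fraction=float(d.get("spillover_fraction", 0.0)),
            targets=tuple(d.get("targets", ())),
            backgrounds=tuple(d.get("backgrounds", ())),
            stock=stock,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# validation report


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity.upper()}] {self.code}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def error(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue("error", code, message))

    def warn(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue("warning", code, message))

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        if not self.issues:
            return "validation: clean"
        return "\n".join(str(i) for i in self.issues)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class StudyBundle:
    """All cross-linked records of one study plus its validation report."""

    config: StudyConfig
    syringes: dict[str, SyringeRecord]
    injections: list[InjectionRecord]
    samples: list[CountingSample]
    validation: ValidationReport = field(default_factory=ValidationReport)

    @property
    def t_count_ref(self) -> datetime:
        """Shared start of the gamma counting protocol."""
        return self.samples[0].t_count_ref

    def samples_by_role(self, role: str) -> list[CountingSample]:
        return [s for s in self.samples if s.role == role]

    def require_valid(self) -> "StudyBundle":
        if not self.validation.ok:
            raise StudyValidationError(self.validation)
        return self

    def write(self, directory: str | Path) -> None:
        write_sheets(self, directory)


# ---------------------------------------------------------------------------
# small operations


@dataclass(frozen=True)
class FormulationPlan:
    total_volume_ul: float
    n_syringes: int


def plan_formulation(n_animals: int, volume_per_dose_ul: float) -> FormulationPlan:
    """Dose-planning helper: prepare n+1 doses (the extra one becomes the
    counting standard). Returns total formulation volume and syringe count."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if volume_per_dose_ul <= 0:
        raise ValueError("volume_per_dose must be positive")
    n = int(n_animals) + 1
    return FormulationPlan(total_volume_ul=n * float(volume_per_dose_ul),
                           n_syringes=n)


def tissue_mass(sample: CountingSample) -> float:
    """Tissue (or aliquot) mass: filled tube minus pre-weighed empty tube."""
    if sample.role not in ("tissue", "standard"):
        raise ValueError(f"{sample.tube_id}: role {sample.role!r} has no content mass")
    m = sample.content_mass
    if m < 0:
        raise ValueError(
            f"{sample.tube_id}: tube_full < tube_empty "
            f"({sample.tube_full_mass} < {sample.tube_empty_mass} g) — weighing mix-up?")
    if m == 0:
        warnings.warn(f"{sample.tube_id}: empty tube (content mass 0 g)",
                      BiodistWarning, stacklevel=2)
    return m


# ---------------------------------------------------------------------------
# readers / writers


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_ts(v) -> Optional[datetime]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return parse_timestamp(v)


def _read_csv(path: Path, columns: list[str], report: ValidationReport):
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        report.error("missing_file", f"sheet not found: {path}")
        return None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        report.error("missing_column", f"{path.name}: missing columns {missing}")
        return None
    return df


def read_sheets(directory: str | Path, config: StudyConfig) -> StudyBundle:
    """Read and cross-validate the three study sheets in ``directory``.

    Every validation failure is collected into the bundle's report; call
    :meth:`StudyBundle.require_valid` (or the ``validate`` CLI) to enforce.
    """
    directory = Path(directory)
    report = ValidationReport()
    for msg in config.validate():
        report.error("config", msg)

    syr_df = _read_csv(directory / "syringes.csv", SYRINGE_COLUMNS, report)
    inj_df = _read_csv(directory / "injections.csv", INJECTION_COLUMNS, report)
    smp_df = _read_csv(directory / "samples.csv", SAMPLE_COLUMNS, report)

    syringes: dict[str, SyringeRecord] = {}
    injections: list[InjectionRecord] = []
    samples: list[CountingSample] = []

    if syr_df is not None:
        for _, row in syr_df.iterrows():
            sid = row["syringe_id"]
            try:
                rec = SyringeRecord(
                    syringe_id=sid,
                    role=row["role"],
                    mass_full=float(row["mass_full_g"]),
                    t_weigh_full=parse_timestamp(row["t_weigh_full"]),
                    mass_empty=float(row["mass_empty_g"]),
                    t_weigh_empty=parse_timestamp(row["t_weigh_empty"]),
                    activity_before=_opt_float(row["activity_before_MBq"]),
                    t_activity_before=_opt_ts(row["t_activity_before"]),
                    activity_after=_opt_float(row["activity_after_MBq"]),
                    t_activity_after=_opt_ts(row["t_activity_after"]),
                    comment=row["comment"],
                )
            except (ValueError, TypeError) as exc:
                report.error("syringe_parse", f"syringe {sid!r}: {exc}")
                continue
            if sid in syringes:
                report.error("duplicate_syringe", f"duplicate syringe_id {sid!r}")
            if rec.role not in ("animal", "standard"):
                report.error("syringe_role", f"syringe {sid!r}: role {rec.role!r}")
            if rec.mass_full <= rec.mass_empty:
                report.error(
                    "syringe_mass",
                    f"syringe {sid!r}: mass_full ({rec.mass_full} g) <= "
                    f"mass_empty ({rec.mass_empty} g)")
            for a in (rec.activity_before, rec.activity_after):
                if a is not None and a < 0:
                    report.error("syringe_activity",
                                 f"syringe {sid!r}: negative activity {a}")
            syringes[sid] = rec

    if inj_df is not None:
        seen_animals = set()
        for _, row in inj_df.iterrows():
            aid = row["animal_id"]
            try:
                rec = InjectionRecord(
                    animal_id=aid,
                    syringe_id=row["syringe_id"],
                    group=row["group"],
                    t_injection=parse_timestamp(row["t_injection"]),
                    body_weight=float(row["body_weight_g"]),
                    exclusion_flag=str(row["exclusion_flag"]).strip().lower()
                    in ("1", "true", "yes"),
                    manual_injected_activity_override=_opt_float(
                        row["manual_injected_activity_override_MBq"]),
                    comment=row["comment"],
                )
            except (ValueError, TypeError) as exc:
                report.error("injection_parse", f"animal {aid!r}: {exc}")
                continue
            if aid in seen_animals:
                report.error("duplicate_animal", f"duplicate animal_id {aid!r}")
            seen_animals.add(aid)
            if rec.body_weight <= 0:
                report.error("body_weight",
                             f"animal {aid!r}: body_weight {rec.body_weight} g <= 0")
            syr = syringes.get(rec.syringe_id)
            if syr is None:
                report.error("unresolved_syringe",
                             f"animal {aid!r}: syringe_id {rec.syringe_id!r} "
                             "not in syringes.csv")
            elif syr.role != "animal":
                report.error("syringe_role",
                             f"animal {aid!r}: syringe {rec.syringe_id!r} has "
                             f"role {syr.role!r}, expected 'animal'")
            injections.append(rec)

    if smp_df is not None:
        seen_tubes = set()
        t_refs = set()
        animal_ids = {i.animal_id for i in injections}
        for _, row in smp_df.iterrows():
            tid = row["tube_id"]
            try:
                rec = CountingSample(
                    tube_id=tid,
                    role=row["role"],
                    tube_empty_mass=float(row["tube_empty_mass_g"]),
                    tube_full_mass=float(row["tube_full_mass_g"]),
                    cpm=float(row["cpm"]),
                    t_count_ref=parse_timestamp(row["t_count_ref"]),
                    animal_id=row["animal_id"] or None,
                    tissue_name=row["tissue_name"] or None,
                )
            except (ValueError, TypeError) as exc:
                report.error("sample_parse", f"tube {tid!r}: {exc}")
                continue
            if tid in seen_tubes:
                report.error("duplicate_tube", f"duplicate tube_id {tid!r}")
            seen_tubes.add(tid)
            t_refs.add(rec.t_count_ref)
            if rec.role not in ("background", "standard", "tissue"):
                report.error("sample_role", f"tube {tid!r}: role {rec.role!r}")
            if rec.cpm < 0:
                report.error("negative_cpm", f"tube {tid!r}: cpm {rec.cpm} < 0")
            if rec.role != "background" and rec.tube_full_mass < rec.tube_empty_mass:
                report.error("tube_mass",
                             f"tube {tid!r}: tube_full_mass < tube_empty_mass")
            if rec.role == "tissue":
                if rec.animal_id not in animal_ids:
                    report.error("unresolved_animal",
                                 f"tube {tid!r}: animal_id {rec.animal_id!r} "
                                 "not in injections.csv")
                if rec.tissue_name is None:
                    report.error("missing_tissue", f"tube {tid!r}: no tissue_name")
                elif rec.tissue_name not in config.tissue_vocabulary:
                    report.warn("tissue_vocabulary",
                                f"tube {tid!r}: tissue {rec.tissue_name!r} not in "
                                "the controlled vocabulary (accepted)")
            if (config.counter_ceiling_cpm is not None
                    and rec.cpm > config.counter_ceiling_cpm):
                report.warn("saturation",
                            f"tube {tid!r}: cpm {rec.cpm:.0f} above the counter "
                            "linear-range ceiling — recount later recommended")
            samples.append(rec)
        if len(t_refs) > 1:
            report.error("t_count_ref",
                         "samples.csv carries more than one t_count_ref; all "
                         "tubes must share the counting-protocol start")
        n_bg = sum(1 for s in samples if s.role == "background")
        n_std = sum(1 for s in samples if s.role == "standard")
        if 0 < n_bg < 3:
            report.warn("few_backgrounds",
                        f"only {n_bg} background tubes (quadruplicate expected)")
        if 0 < n_std < 4:
            report.warn("few_standards",
                        f"only {n_std} standard aliquots (quadruplicate expected)")
        if n_bg == 0:
            report.error("no_background", "no background tubes in samples.csv")
        if n_std == 0 and any(s.role == "tissue" for s in samples):
            report.error("no_standard", "no counting-standard tubes in samples.csv")

    if config.stock is not None:
        st = config.stock
        if st.water_mass <= 0:
            report.error("stock_mass", "stock: tube_plus_water <= tube_empty")
        if st.tube_plus_water_plus_standard <= st.tube_plus_water:
            report.error("stock_mass",
                         "stock: no mass gained when spiking the standard")
        if st.standard_syringe_id not in syringes:
            report.error("unresolved_syringe",
                         f"stock: standard_syringe_id "
                         f"{st.standard_syringe_id!r} not in syringes.csv")
        elif syringes[st.standard_syringe_id].role != "standard":
            report.error("syringe_role",
                         f"stock: syringe {st.standard_syringe_id!r} is not "
                         "role 'standard'")

    return StudyBundle(config=config, syringes=syringes, injections=injections,
                       samples=samples, validation=report)


def _ts(v: Optional[datetime]) -> str:
    return v.isoformat() if v is not None else ""


def write_sheets(bundle: StudyBundle, directory: str | Path) -> None:
    """Write syringes/injections/samples CSVs and config.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    syr_rows = [{
        "syringe_id": s.syringe_id, "role": s.role,
        "mass_full_g": s.mass_full, "t_weigh_full": _ts(s.t_weigh_full),
        "mass_empty_g": s.mass_empty, "t_weigh_empty": _ts(s.t_weigh_empty),
        "activity_before_MBq": s.activity_before,
        "t_activity_before": _ts(s.t_activity_before),
        "activity_after_MBq": s.activity_after,
        "t_activity_after": _ts(s.t_activity_after),
        "comment": s.comment,
    } for s in bundle.syringes.values()]
    pd.DataFrame(syr_rows, columns=SYRINGE_COLUMNS).to_csv(
        directory / "syringes.csv", index=False)

    inj_rows = [{
        "animal_id": i.animal_id, "syringe_id": i.syringe_id, "group": i.group,
        "t_injection": _ts(i.t_injection), "body_weight_g": i.body_weight,
        "exclusion_flag": i.exclusion_flag,
        "manual_injected_activity_override_MBq":
            i.manual_injected_activity_override,
        "comment": i.comment,
    } for i in bundle.injections]
    pd.DataFrame(inj_rows, columns=INJECTION_COLUMNS).to_csv(
        directory / "injections.csv", index=False)

    smp_rows = [{
        "tube_id": s.tube_id, "role": s.role, "animal_id": s.animal_id or "",
        "tissue_name": s.tissue_name or "",
        "tube_empty_mass_g": s.tube_empty_mass,
        "tube_full_mass_g": s.tube_full_mass, "cpm": s.cpm,
        "t_count_ref": _ts(s.t_count_ref),
    } for s in bundle.samples]
    pd.DataFrame(smp_rows, columns=SAMPLE_COLUMNS).to_csv(
        directory / "samples.csv", index=False)

    bundle.config.to_json(directory / "config.json")
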
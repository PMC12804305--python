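"""Per-animal injected activity, %ID g^-1, %ID organ, SUV, contrast ratios,
and group summaries.

The injected activity of each animal is obtained from the *mass* it received
(full minus emptied syringe weighing) times the calibration factor in CPM per
gram of formulation, so injected dose and tissue counts live in the same
counter units and the radioactivity cancels out of the ratio:

    %ID g^-1 = 100 * (net_cpm / injected_cpm) / tissue_mass
    %ID organ = 100 * net_cpm / injected_cpm
    SUV       = %ID g^-1 * body_weight / 100

Dose-calibrator readings, when present, provide an independent injected
activity in MBq that is reported side-by-side with the mass-based value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .calibration import CalibrationResult, background_cpm, calibration_factor
from .errors import RecoveryWarning
from .nuclides import decay_correct, get_nuclide
from .study import (CountingSample, InjectionRecord, StudyBundle,
                    SyringeRecord)

#: summed-%ID recovery tolerance before the diagnostic warning fires
RECOVERY_TOLERANCE_PERCENT = 5.0


@dataclass
class InjectedDose:
    """Injected dose of one animal in counter units (and optionally MBq)."""

    animal_id: str
    injected_cpm: float  # CPM-equivalents at t_ref
    injected_mass: float  # g
    injected_mbq: Optional[float] = None  # dose-calibrator route, at t_ref
    relative_difference: Optional[float] = None  # (mass - calibrator)/calibrator
    override_used: bool = False


@dataclass
class TissueResult:
    animal_id: str
    tissue_name: str
    net_cpm: float
    mass: float  # g
    pct_id_per_g: Optional[float]
    pct_id_organ: float
    suv: Optional[float]
    flags: list[str] = field(default_factory=list)


def injected_activity(
    syringe: SyringeRecord,
    cf: CalibrationResult,
    override_mbq: Optional[float] = None,
    nuclide=None,
    t_ref=None,
) -> InjectedDose:
    """Injected dose in CPM-equivalents at the counting reference time.

    Mass route: ``cf_mass * (mass_full - mass_empty)``. When the syringe has
    dose-calibrator readings (and nuclide/t_ref are given), the calibrator
    route ``A_before(t_ref) - A_after(t_ref)`` is reported alongside with the
    relative difference. ``override_mbq`` (manual correction for failed or
    sticky injections, in MBq at t_ref) replaces the mass-based value and
    requires ``cf.cf_activity``.
    """
    if syringe.role != "animal":
        raise ValueError(
            f"syringe {syringe.syringe_id!r} has role {syringe.role!r}")
    injected_mass = syringe.injected_mass
    if injected_mass <= 0:
        raise ValueError(
            f"syringe {syringe.syringe_id!r}: injected mass {injected_mass} g <= 0")

    injected_cpm = cf.cf_mass * injected_mass
    override_used = False
    injected_mbq = None
    rel_diff = None

    if override_mbq is not None:
        if cf.cf_activity is None:
            raise ValueError(
                "manual injected-activity override requires a calibration "
                "factor in CPM/MBq (dose-calibrator data for the standard)")
        injected_cpm = override_mbq * cf.cf_activity
        injected_mbq = override_mbq
        override_used = True
    elif (nuclide is not None and t_ref is not None
          and syringe.activity_before is not None
          and syringe.activity_after is not None
          and syringe.t_activity_before is not None
          and syringe.t_activity_after is not None):
        a_before = decay_correct(syringe.activity_before,
                                 syringe.t_activity_before, t_ref, nuclide)
        a_after = decay_correct(syringe.activity_after,
                                syringe.t_activity_after, t_ref, nuclide)
        injected_mbq = a_before - a_after
        if injected_mbq > 0 and cf.cf_activity is not None:
            mass_based_mbq = injected_cpm / cf.cf_activity
            rel_diff = (mass_based_mbq - injected_mbq) / injected_mbq

    return InjectedDose(animal_id="", injected_cpm=injected_cpm,
                        injected_mass=injected_mass, injected_mbq=injected_mbq,
                        relative_difference=rel_diff, override_used=override_used)


def net_cpm(sample: CountingSample, background: float,
            policy: str = "flag") -> tuple[float, list[str]]:
    """Background-subtracted CPM with quality flags.

    Negative net counts are kept (policy ``"flag"``, default — keeps group
    means unbiased) or clamped to zero (policy ``"clamp"``); either way the
    ``negative_net`` flag is attached.
    """
    if sample.role != "tissue":
        raise ValueError(f"tube {sample.tube_id!r}: net_cpm expects a tissue tube")
    net = sample.cpm - background
    flags: list[str] = []
    if net < 0:
        flags.append("negative_net")
        if policy == "clamp":
            net = 0.0
        elif policy != "flag":
            raise ValueError(f"unknown negative-net policy {policy!r}")
    return net, flags


def pct_id_per_gram(net: float, mass: float, injected_cpm: float) -> float:
    """Percent of the injected dose per gram of tissue."""
    if injected_cpm <= 0:
        raise ValueError("injected_cpm must be positive")
    if mass <= 0:
        raise ValueError("tissue mass must be positive (zero-mass tubes are "
                         "reported as missing, not 0)")
    return 100.0 * (net / injected_cpm) / mass


def suv(pct_id_per_g: float, body_weight: float) -> float:
    """Standardized uptake value by body weight (dimensionless).

    Equals the tissue activity concentration divided by the injected activity
    per gram of body: a uniformly distributed tracer gives SUV = 1 everywhere.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    return pct_id_per_g * body_weight / 100.0


def _tissue_result(sample: CountingSample, background: float, policy: str,
                   injected: InjectedDose, body_weight: float,
                   saturation_ceiling: Optional[float]) -> TissueResult:
    net, flags = net_cpm(sample, background, policy)
    if saturation_ceiling is not None and sample.cpm > saturation_ceiling:
        flags.append("saturation")
    pct_organ = 100.0 * net / injected.injected_cpm
    mass = sample.content_mass
    if mass <= 0:
        flags.append("zero_mass")
        pidg = None
        s = None
    else:
        pidg = pct_id_per_gram(net, mass, injected.injected_cpm)
        s = suv(pidg, body_weight)
    return TissueResult(animal_id=sample.animal_id, tissue_name=sample.tissue_name,
                        net_cpm=net, mass=mass, pct_id_per_g=pidg,
                        pct_id_organ=pct_organ, suv=s, flags=flags)


@dataclass
class StudyResults:
    """All tables produced by one analysis run."""

    calibration: CalibrationResult
    injected: pd.DataFrame  # per animal
    per_animal: pd.DataFrame  # per animal x tissue
    group_summary: pd.DataFrame  # per group x tissue
    ratios: pd.DataFrame  # per group x (target, background)
    ratios_per_animal: pd.DataFrame

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_animal.to_csv(directory / "results_per_animal.csv",
                               index=False, float_format="%.6g")
        self.group_summary.to_csv(directory / "group_summary.csv",
                                  index=False, float_format="%.6g")
        self.ratios.to_csv(directory / "ratios.csv", index=False,
                           float_format="%.6g")
        self.ratios_per_animal.to_csv(directory / "ratios_per_animal.csv",
                                      index=False, float_format="%.6g")
        payload = {
            "calibration": {
                "cf_mass_cpm_per_g": self.calibration.cf_mass,
                "cv_percent": self.calibration.cv,
                "background_cpm": self.calibration.background_cpm,
                "cf_activity_cpm_per_MBq": self.calibration.cf_activity,
            },
            "injected": self.injected.to_dict(orient="records"),
            "per_animal": self.per_animal.to_dict(orient="records"),
            "group_summary": self.group_summary.to_dict(orient="records"),
            "ratios": self.ratios.to_dict(orient="records"),
            "ratios_per_animal": self.ratios_per_animal.to_dict(orient="records"),
        }
        import json

        def _clean(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [_clean(v) for v in o]
            return o

        (directory / "results.json").write_text(
            json.dumps(_clean(payload), indent=2, default=str) + "\n")


def contrast_ratios(
    results: pd.DataFrame,
    injections: Sequence[InjectionRecord],
    targets: Sequence[str],
    backgrounds: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target-to-background %ID g^-1 ratios, per animal then per group.

    Ratios are formed within each animal (preserving pairing) and then
    averaged within groups. A non-positive or missing background value makes
    that animal's ratio undefined (flagged, excluded from the mean).
    """
    group_of = {i.animal_id: i.group for i in injections
                if not i.exclusion_flag}
    per_animal_rows = []
    pidg = results.set_index(["animal_id", "tissue_name"])["pct_id_per_g"]
    for target in targets:
        for bg in backgrounds:
            for animal, group in group_of.items():
                t = pidg.get((animal, target))
                b = pidg.get((animal, bg))
                if t is None or b is None or (isinstance(t, float) and math.isnan(t)) \
                        or (isinstance(b, float) and math.isnan(b)):
                    warnings.warn(
                        f"animal {animal!r}: missing {target!r} or {bg!r}; "
                        "excluded from the ratio", RecoveryWarning, stacklevel=2)
                    continue
                if b <= 0:
                    per_animal_rows.append({
                        "animal_id": animal, "group": group, "target": target,
                        "background": bg, "ratio": math.nan,
                        "flag": "nonpositive_background"})
                    continue
                per_animal_rows.append({
                    "animal_id": animal, "group": group, "target": target,
                    "background": bg, "ratio": t / b, "flag": ""})
    per_animal = pd.DataFrame(
        per_animal_rows, columns=["animal_id", "group", "target", "background",
                                  "ratio", "flag"])
    if per_animal.empty:
        return per_animal, pd.DataFrame(
            columns=["group", "target", "background", "n", "mean", "sd"])
    grp = (per_animal.dropna(subset=["ratio"])
           .groupby(["group", "target", "background"])["ratio"]
           .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
           .reset_index())
    return per_animal, grp


def group_summary(results: pd.DataFrame,
                  injections: Sequence[InjectionRecord]) -> pd.DataFrame:
    """Per group x tissue: n, mean, sd (n-1), CV of %ID g^-1 and SUV.

    Animals with the exclusion flag are omitted. Summed %ID per animal is
    checked as a recovery diagnostic: totals above 100% + tolerance indicate
    a calibration or weighing problem.
    """
    included = {i.animal_id: i.group for i in injections if not i.exclusion_flag}
    if not included:
        raise ValueError("no non-excluded animals to summarize")
    df = results[results["animal_id"].isin(included)].copy()
    df["group"] = df["animal_id"].map(included)

    for animal, total in df.groupby("animal_id")["pct_id_organ"].sum().items():
        if total > 100.0 + RECOVERY_TOLERANCE_PERCENT:
            warnings.warn(
                f"animal {animal!r}: summed %ID over tissues is {total:.1f}% "
                f"(> {100 + RECOVERY_TOLERANCE_PERCENT:.0f}%) — check the "
                "calibration factor and weighings",
                RecoveryWarning, stacklevel=2)

    def _agg(v: pd.Series) -> pd.Series:
        v = v.dropna()
        n = len(v)
        mean = v.mean() if n else math.nan
        sd = v.std(ddof=1) if n > 1 else math.nan
        cv = 100.0 * sd / mean if n > 1 and mean > 0 else math.nan
        return pd.Series({"n": n, "mean": mean, "sd": sd, "cv": cv})

    out = []
    for (group, tissue), sub in df.groupby(["group", "tissue_name"], sort=True):
        row = {"group": group, "tissue_name": tissue}
        a = _agg(sub["pct_id_per_g"])
        row.update({"n": int(a["n"]), "pct_id_per_g_mean": a["mean"],
                    "pct_id_per_g_sd": a["sd"], "pct_id_per_g_cv": a["cv"]})
        b = _agg(sub["suv"])
        row.update({"suv_mean": b["mean"], "suv_sd": b["sd"],
                    "suv_cv": b["cv"]})
        if row["n"] == 1:
            row["flag"] = "n=1"
        else:
            row["flag"] = ""
        out.append(row)
    return pd.DataFrame(out)


def analyze_study(bundle: StudyBundle,
                  targets: Optional[Sequence[str]] = None,
                  backgrounds: Optional[Sequence[str]] = None) -> StudyResults:
    """Run the full quantification pipeline on a validated study bundle."""
    bundle.require_valid()
    config = bundle.config
    nuclide = get_nuclide(config.nuclide_id)
    t_ref = bundle.t_count_ref

    bg = background_cpm(bundle.samples_by_role("background"),
                        method=config.background_policy)
    if config.stock is None:
        raise ValueError("config carries no standard-stock block; cannot "
                         "compute the calibration factor")
    std_syringe = bundle.syringes[config.stock.standard_syringe_id]
    cf = calibration_factor(bundle.samples_by_role("standard"), config.stock,
                            std_syringe, bg, nuclide=nuclide, t_ref=t_ref)

    injected_rows = []
    doses: dict[str, InjectedDose] = {}
    body_weight: dict[str, float] = {}
    for inj in bundle.injections:
        dose = injected_activity(
            bundle.syringes[inj.syringe_id], cf,
            override_mbq=inj.manual_injected_activity_override,
            nuclide=nuclide, t_ref=t_ref)
        dose.animal_id = inj.animal_id
        doses[inj.animal_id] = dose
        body_weight[inj.animal_id] = inj.body_weight
        injected_rows.append({
            "animal_id": inj.animal_id, "group": inj.group,
            "excluded": inj.exclusion_flag,
            "injected_mass_g": dose.injected_mass,
            "injected_cpm": dose.injected_cpm,
            "injected_MBq_calibrator": dose.injected_mbq,
            "mass_vs_calibrator_rel_diff": dose.relative_difference,
            "override_used": dose.override_used,
        })

    tissue_rows = []
    for sample in bundle.samples_by_role("tissue"):
        res = _tissue_result(sample, bg, config.negative_net_policy,
                             doses[sample.animal_id],
                             body_weight[sample.animal_id],
                             config.counter_ceiling_cpm)
        tissue_rows.append({
            "animal_id": res.animal_id, "tissue_name": res.tissue_name,
            "mass_g": res.mass, "net_cpm": res.net_cpm,
            "pct_id_per_g": math.nan if res.pct_id_per_g is None else res.pct_id_per_g,
            "pct_id_organ": res.pct_id_organ,
            "suv": math.nan if res.suv is None else res.suv,
            "flags": ";".join(res.flags),
        })
    per_animal = pd.DataFrame(tissue_rows)

    summary = group_summary(per_animal, bundle.injections)
    targets = tuple(targets) if targets is not None else config.targets
    backgrounds = (tuple(backgrounds) if backgrounds is not None
                   else config.backgrounds)
    ratios_pa, ratios = contrast_ratios(per_animal, bundle.injections,
                                        targets, backgrounds)
    return StudyResults(calibration=cf, injected=pd.DataFrame(injected_rows),
                        per_animal=per_animal, group_summary=summary,
                        ratios=ratios, ratios_per_animal=ratios_pa)
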
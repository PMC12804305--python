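"""Seeded generator of complete virtual biodistribution studies.

The generator implements exactly the measurement model the analysis assumes:
weighed syringes with residual formulation, a weighed-standard dilution into
~10 mL of water, quadruplicate background and standard tubes, tissue tubes
with realistic masses, dose-calibrator readings consistent with the weighed
masses, physical decay across the counting queue undone by the simulated
counter's decay correction, and optional Poisson counting noise. Every sheet
it writes passes validation, and with noise disabled the analysis pipeline
recovers the generated ground truth exactly.

Balance readings are quantized to 4 decimal places (analytical-balance
resolution); the ground truth is derived from the quantized recordings, so
quantization is part of the truth rather than a noise source.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
import numpy as np

from .kinetics import WholeBodySeries
from .nuclides import LN2, get_nuclide
from .study import (DEFAULT_TISSUE_VOCABULARY, CountingSample,
                    InjectionRecord, StandardStock, StudyBundle, StudyConfig,
                    SyringeRecord)

#: default per-tissue truth: %ID g^-1 population mean and lognormal sigma
#: (typical pattern for a radiometal-labelled antibody ~24 h post injection)
DEFAULT_TRUE_PCT_ID_PER_G = {
    "blood": (10.0, 0.15),
    "tumor": (15.0, 0.25),
    "liver": (12.0, 0.15),
    "kidney": (8.0, 0.15),
    "spleen": (6.0, 0.20),
    "lung": (5.0, 0.15),
    "muscle": (1.2, 0.20),
    "bone": (3.0, 0.20),
}

#: default organ masses in g (mean, sd) — approximate adult-mouse values;
#: blood is the sampled aliquot, not total blood volume
DEFAULT_ORGAN_MASSES = {
    "blood": (0.20, 0.03),
    "tumor": (0.25, 0.05),
    "liver": (1.20, 0.10),
    "kidney": (0.35, 0.03),
    "spleen": (0.10, 0.02),
    "lung": (0.15, 0.02),
    "muscle": (0.12, 0.02),
    "bone": (0.08, 0.01),
}


def _round4(x: float) -> float:
    """Analytical-balance recording: 4 decimal places in grams."""
    return round(float(x), 4)


@dataclass
class SynthConfig:
    """Study conditions for one virtual biodistribution experiment."""

    nuclide_id: str = "Zr-89"
    groups: tuple[str, ...] = ("baseline",)
    n_animals: int = 4  # per group
    true_pct_id_per_g: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PCT_ID_PER_G))
    organ_mass_table: dict = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_MASSES))
    body_weight: tuple[float, float] = (22.0, 1.5)  # g
    syringe_fill: tuple[float, float] = (0.15, 0.01)  # g of formulation
    residual_fraction: tuple[float, float] = (0.08, 0.02)
    counts_per_gram_constant: float = 2.0e7  # CPM per g formulation at t_ref
    activity_per_gram_MBq: float = 8.0  # MBq per g formulation at t_ref
    background_cpm_mean: float = 30.0
    counting_interval_s: float = 60.0  # queue spacing between tubes
    noise: str = "none"  # "none" | "poisson"
    seed: int = 0
    start: datetime = field(
        default_factory=lambda: datetime(2026, 1, 5, 8, 0, 0))

    def validate(self) -> None:
        get_nuclide(self.nuclide_id)
        if self.n_animals < 1 or not self.groups:
            raise ValueError("need >= 1 group with >= 1 animal")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not (0.0 <= self.residual_fraction[0] < 0.5):
            raise ValueError("mean residual fraction must be in [0, 0.5)")
        for name, (mean, _) in {**self.true_pct_id_per_g}.items():
            if mean <= 0:
                raise ValueError(f"{name}: %ID/g mean must be positive")
            if name not in self.organ_mass_table:
                raise ValueError(f"{name}: no organ mass entry")
        for quantity in (self.counts_per_gram_constant,
                         self.activity_per_gram_MBq, self.syringe_fill[0],
                         self.body_weight[0]):
            if quantity <= 0:
                raise ValueError("all means must be positive")

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        d = json.loads(Path(path).read_text())
        if "start" in d:
            d["start"] = datetime.fromisoformat(d["start"])
        for key in ("groups",):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("body_weight", "syringe_fill", "residual_fraction"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("true_pct_id_per_g", "organ_mass_table"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually put into the sheets."""

    nuclide_id: str
    counts_per_gram: float  # CPM per g formulation at t_ref
    activity_per_gram: float  # MBq per g formulation at t_ref
    background_cpm: float
    cf_activity: float  # CPM per MBq
    animals: dict  # animal_id -> {group, body_weight, injected_*, tissues}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "nuclide_id": self.nuclide_id,
            "counts_per_gram": self.counts_per_gram,
            "activity_per_gram_MBq": self.activity_per_gram,
            "background_cpm": self.background_cpm,
            "cf_activity_cpm_per_MBq": self.cf_activity,
            "animals": self.animals,
        }, indent=2) + "\n")


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor: float) -> float:
    return float(max(mean + sd * rng.standard_normal(), floor))


def generate_study(config: SynthConfig) -> tuple[StudyBundle, GroundTruth]:
    """Generate one complete virtual study (sheets in memory + ground truth).

    The returned bundle can be written with ``bundle.write(dir)`` and re-read
    with :func:`biodist.study.read_sheets`; a fixed seed gives byte-identical
    files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nuc = get_nuclide(config.nuclide_id)
    lam_s = nuc.lam  # 1/s
    t0 = config.start
    t_ref = t0 + timedelta(hours=6)  # gamma counting protocol start

    tissues = list(config.true_pct_id_per_g)
    animal_ids = []
    groups_of = {}
    for gi, group in enumerate(config.groups):
        for ai in range(config.n_animals):
            aid = f"A{gi + 1}{ai + 1:02d}"
            animal_ids.append(aid)
            groups_of[aid] = group

    def activity_at(mbq_at_ref: float, t: datetime) -> float:
        """Dose-calibrator reading at t of a source worth mbq_at_ref at t_ref."""
        return mbq_at_ref * math.exp(lam_s * (t_ref - t).total_seconds())

    # --- syringes (animals + one counting standard) ------------------------
    syringes: dict[str, SyringeRecord] = {}
    injections: list[InjectionRecord] = []
    injected_mass_rec: dict[str, float] = {}
    apg = config.activity_per_gram_MBq

    def make_syringe(sid: str, role: str, idx: int) -> float:
        """Draw, weigh, inject, re-weigh one syringe; returns delivered mass."""
        tare = _round4(_positive_normal(rng, 2.5, 0.05, 2.0))
        content = _positive_normal(rng, *config.syringe_fill,
                                   0.2 * config.syringe_fill[0])
        resid = float(np.clip(
            config.residual_fraction[0]
            + config.residual_fraction[1] * rng.standard_normal(), 0.0, 0.45))
        mass_full = _round4(tare + content)
        mass_empty = _round4(tare + resid * content)
        t_full = t0 + timedelta(seconds=60.0 * idx)
        t_empty = t0 + timedelta(seconds=7200.0 + 60.0 * idx)
        content_rec = mass_full - tare
        residual_rec = mass_empty - tare
        syringes[sid] = SyringeRecord(
            syringe_id=sid, role=role,
            mass_full=mass_full, t_weigh_full=t_full,
            mass_empty=mass_empty, t_weigh_empty=t_empty,
            activity_before=activity_at(apg * content_rec, t_full),
            t_activity_before=t_full,
            activity_after=activity_at(apg * residual_rec, t_empty),
            t_activity_after=t_empty,
        )
        return mass_full - mass_empty

    for idx, aid in enumerate(animal_ids):
        sid = f"S{idx + 1:02d}"
        delivered = make_syringe(sid, "animal", idx)
        injected_mass_rec[aid] = delivered
        injections.append(InjectionRecord(
            animal_id=aid, syringe_id=sid, group=groups_of[aid],
            t_injection=t0 + timedelta(seconds=3600.0 + 120.0 * idx),
            body_weight=round(_positive_normal(rng, *config.body_weight, 10.0), 1),
        ))
    std_mass = make_syringe("STD", "standard", len(animal_ids))

    # --- weighed-standard stock (~10 mL water + the standard dose) ---------
    stock_tube_empty = _round4(_positive_normal(rng, 6.5, 0.05, 6.0))
    water = _positive_normal(rng, 10.0, 0.10, 9.0)
    tube_plus_water = _round4(stock_tube_empty + water)
    tube_pws = _round4(tube_plus_water + std_mass)
    stock = StandardStock(
        tube_empty=stock_tube_empty, tube_plus_water=tube_plus_water,
        tube_plus_water_plus_standard=tube_pws, standard_syringe_id="STD",
        t_spike=t0 + timedelta(seconds=3600.0 + 120.0 * len(animal_ids)))
    stock_total = tube_pws - stock_tube_empty

    # --- counting queue ----------------------------------------------------
    samples: list[CountingSample] = []
    poisson = config.noise == "poisson"
    bg_mean = config.background_cpm_mean
    cpg = config.counts_per_gram_constant

    def counted_cpm(signal_ref: float, position: int) -> float:
        """Simulated counter output for one tube at queue position.

        The sample signal decays while the tube waits its turn and the
        counter's decay correction restores it to the protocol start; the
        stationary ambient background passes through unchanged. With Poisson
        noise, signal and background counts are drawn separately (their sum
        is distributed as the gross-count draw).
        """
        if not poisson:
            return bg_mean + signal_ref
        delay = position * config.counting_interval_s
        decay = math.exp(-lam_s * delay)
        sig = rng.poisson(signal_ref * decay) / decay if signal_ref > 0 else 0.0
        return float(rng.poisson(bg_mean)) + float(sig)

    position = 0
    for i in range(4):  # background, in quadruplicate
        samples.append(CountingSample(
            tube_id=f"BG{i + 1}", role="background",
            tube_empty_mass=_round4(_positive_normal(rng, 2.0, 0.02, 1.8)),
            tube_full_mass=0.0, cpm=counted_cpm(0.0, position),
            t_count_ref=t_ref))
        samples[-1].tube_full_mass = samples[-1].tube_empty_mass
        position += 1

    aliquot_f_mass = []
    for i in range(4):  # counting standards, in quadruplicate
        tube_empty = _round4(_positive_normal(rng, 2.0, 0.02, 1.8))
        aliquot = _positive_normal(rng, 1.0, 0.01, 0.5)
        tube_full = _round4(tube_empty + aliquot)
        aliquot_rec = tube_full - tube_empty
        f_mass = std_mass * aliquot_rec / stock_total
        aliquot_f_mass.append(f_mass)
        samples.append(CountingSample(
            tube_id=f"ST{i + 1}", role="standard",
            tube_empty_mass=tube_empty, tube_full_mass=tube_full,
            cpm=counted_cpm(cpg * f_mass, position), t_count_ref=t_ref))
        position += 1

    truth_animals: dict = {}
    for inj in injections:
        aid = inj.animal_id
        injected_cpm = cpg * injected_mass_rec[aid]
        pct = {}
        masses = {}
        for name in tissues:
            mu, sigma = config.true_pct_id_per_g[name]
            # lognormal with population mean mu
            pct[name] = mu * math.exp(sigma * rng.standard_normal()
                                      - 0.5 * sigma * sigma)
            m_mean, m_sd = config.organ_mass_table[name]
            masses[name] = _positive_normal(rng, m_mean, m_sd, 0.02)
        tissue_truth = {}
        for name in tissues:
            tube_empty = _round4(_positive_normal(rng, 2.0, 0.02, 1.8))
            tube_full = _round4(tube_empty + masses[name])
            m_rec = _round4(tube_full - tube_empty)
            signal = injected_cpm * pct[name] * m_rec / 100.0
            samples.append(CountingSample(
                tube_id=f"T-{aid}-{name}", role="tissue",
                tube_empty_mass=tube_empty, tube_full_mass=tube_full,
                cpm=counted_cpm(signal, position), t_count_ref=t_ref,
                animal_id=aid, tissue_name=name))
            position += 1
            tissue_truth[name] = {
                "mass_g": m_rec,
                "pct_id_per_g": pct[name],
                "pct_id_organ": pct[name] * m_rec,
                "suv": pct[name] * inj.body_weight / 100.0,
            }
        total_pct = sum(v["pct_id_organ"] for v in tissue_truth.values())
        if total_pct > 100.0:
            raise RuntimeError(
                f"config puts {total_pct:.0f}% of the dose in the sampled "
                "tissues; reduce %ID/g means or organ masses")
        truth_animals[aid] = {
            "group": inj.group,
            "body_weight_g": inj.body_weight,
            "injected_mass_g": injected_mass_rec[aid],
            "injected_cpm": injected_cpm,
            "injected_MBq": apg * injected_mass_rec[aid],
            "tissues": tissue_truth,
        }

    targets = ("tumor",) if "tumor" in tissues else ()
    backgrounds = ("muscle",) if "muscle" in tissues else ()
    study_config = StudyConfig(
        nuclide_id=nuc.id, stock=stock, targets=targets,
        backgrounds=backgrounds,
        tissue_vocabulary=tuple(dict.fromkeys(
            list(tissues) + list(DEFAULT_TISSUE_VOCABULARY))))
    bundle = StudyBundle(config=study_config, syringes=syringes,
                         injections=injections, samples=samples)
    truth = GroundTruth(
        nuclide_id=nuc.id, counts_per_gram=cpg, activity_per_gram=apg,
        background_cpm=bg_mean, cf_activity=cpg / apg, animals=truth_animals)
    return bundle, truth


def write_study(bundle: StudyBundle, truth: GroundTruth, directory) -> None:
    """Write the sheets, config.json and ground_truth.json to a directory."""
    directory = Path(directory)
    bundle.write(directory)
    truth.to_json(directory / "ground_truth.json")


def generate_wholebody(
    t_half_phys: float,
    t_half_bio: float,
    n_points: int = 8,
    noise_cv: float = 0.0,
    seed: int = 0,
    a0: float = 10.0,
    animal_id: str = "A101",
) -> tuple[WholeBodySeries, dict]:
    """Whole-body retention series: physical decay x biological elimination.

    A(t) = a0 * exp(-(lam_phys + lam_bio) t) * (1 + eps) with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``. ``t_half_bio``
    may be ``math.inf`` for a tracer that is not excreted at all. Returns the
    series and the truth (lam_eff per hour, effective half-life).
    """
    if t_half_phys <= 0 or t_half_bio <= 0:
        raise ValueError("half-lives must be positive")
    lam_eff = LN2 / t_half_phys + (0.0 if math.isinf(t_half_bio)
                                   else LN2 / t_half_bio)
    t_half_eff = LN2 / lam_eff
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2.5 * t_half_eff, n_points)
    a = a0 * np.exp(-lam_eff * t)
    if noise_cv > 0:
        a = a * np.clip(1.0 + noise_cv * rng.standard_normal(n_points), 0.05,
                        None)
    series = WholeBodySeries(animal_id=animal_id, t_hours=t, activity=a)
    truth = {"lam_eff_per_h": lam_eff, "t_half_eff_h": t_half_eff, "a0": a0}
    return series, truth
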
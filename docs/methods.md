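# Methods

This note documents the measurement model, numerical choices and known
limitations of the `biodist` package.

## The gravimetric dose model

The package assumes the weighed-standard workflow: all syringes (animal
doses plus one standard) are drawn from one formulation, weighed full and
empty on a single analytical balance, and timed on a single clock. The
injected mass of animal *j* is `m_j = m_full,j − m_empty,j`; because both
weighings include the syringe tare and any residual formulation, the
difference is the delivered mass regardless of residual volume. The standard
syringe is emptied into a weighed ~10 mL water stock; aliquots of the stock
(~1 mL, weighed) are gamma-counted in quadruplicate next to the tissues.
Aliquot *i* contains formulation mass `m_std · m_aliquot,i / m_stock`
(mass-fraction dilution), giving per-aliquot calibration factors
`cf_i = (CPM_i − background) / m_formulation,i` whose mean is the study
calibration factor in CPM per gram of formulation. Background is the mean of
the background tubes (median available by configuration). A CV above 5%
across standard aliquots raises a warning — a pipetting/weighing quality
gate, configurable, not an error.

All tissue and standard CPM are assumed decay-corrected *by the counter* to
the start of the counting protocol; dose-calibrator readings (taken at
recorded times) are forward-corrected to the same reference with
`exp(−λΔt)`. Timestamps are ISO 8601; naive timestamps are taken to share
the study clock, and mixing naive with offset-aware timestamps is an error
rather than a guess.

Dose-calibrator readings never replace the mass route. When present they
produce a parallel injected activity in MBq and a CPM MBq⁻¹ factor
(`cf_activity = cf_mass · m_std / A_delivered(t_ref)`), reported side-by-side
with the relative difference — the intended use is detecting tracer sticking
to the syringe. A manual override (MBq at t_ref) exists for documented failed
injections and is converted through `cf_activity`.

## Quantities and conventions

* `%ID g⁻¹ = 100 · net_CPM / ID_cpm / m_tissue`; `%ID organ` omits the mass
  division; `SUV = %ID g⁻¹ · BW / 100` (body-weight SUV; lean-mass and
  body-surface variants are out of scope).
* Negative net counts are *flagged, not clamped* by default so group means
  stay unbiased; clamping to zero is available (`--clamp-negatives`).
* Zero-mass tubes yield a missing %ID g⁻¹ (flagged), never a zero.
* Group statistics use the sample standard deviation (n−1); CV is reported
  only for positive means; single-animal groups are flagged `n=1`.
* Contrast ratios are formed per animal (target %ID g⁻¹ / background
  %ID g⁻¹) and then averaged within groups — pairing is preserved; the
  ratio of group means is *not* used. Non-positive backgrounds make the
  animal's ratio undefined (flagged).
* A recovery diagnostic warns when an animal's summed %ID across tissues
  exceeds 105% — an arithmetic impossibility that indicates calibration or
  weighing errors.
* Excluded animals stay in the per-animal table but leave all summaries.

## Nuclide table

A versioned plain-text table (`biodist/data/nuclides.csv`, version 2026.1)
with 130 entries: half-life (value + unit, preserved as stored), principal
gamma lines (keV, % per decay; annihilation radiation is listed at the
positron yield so intensities stay within [0, 100]), and immediate
decay-chain daughters with branching ratios. Values are commonly tabulated
nuclear-data figures; they are lookup constants for decay correction, not a
dosimetry-grade evaluation. Labels normalize aggressively ("89Zr", "zr89",
"Zr-89", "99mTc"). Decay correction is unit-agnostic and multiplicative;
exponents beyond ±700 are guarded (forward → 0, backward → error).

## Kinetics

Whole-body fits use unweighted nonlinear least squares
(`scipy.optimize.curve_fit`) on `A0·e^(−λt)` or `A1·e^(−λ1 t) + A2·e^(−λ2 t)`
with non-negativity bounds. Initialization: log-linear regression for one
phase; curve stripping (late half → slow phase, early residual → fast phase)
for two. Phases are reported fast-first. `model="auto"` keeps the two-phase
fit only when its AICc beats the one-phase AICc by more than 2 units —
operationalizing the preference for the simplest defensible model; an exact
fit floors the RSS at 1e−300 so the comparison stays finite and the
extra-parameter penalty decides. The biological half-life uses
`1/t_bio = 1/t_eff − 1/t_phys` (terminal phase) when a nuclide is supplied
and `t_eff < t_phys`.

Bateman ingrowth is evaluated in closed form; within `1e−12` relative rate
separation it switches to the analytic limit `A_m0·λt·e^(−λt)·BR` to avoid
catastrophic cancellation. `mother_from_daughter` inverts the unit-response
and refuses times where the predicted ingrowth is below `1e−6` of the
asymptote (ill-conditioned). The down-scatter of ²¹³Bi photons into the
²²¹Fr window is *not* modelled — no general correction exists without a
counter-specific spillover measurement; `StudyConfig.spillover_fraction`
accepts a user-supplied fraction that is subtracted linearly.

## The synthetic-study generator

`synthgen.generate_study` emits the exact sheet set the readers consume,
plus a ground-truth record. Defaults describe a typical small-animal study:
one group of four ~22 g mice, ⁸⁹Zr, 0.15 g formulation per syringe with an
8% residual fraction, 2×10⁷ CPM g⁻¹ and 8 MBq g⁻¹ of formulation at the
counting reference time (i.e. 2.5×10⁶ CPM MBq⁻¹ counter response, ~1.1 MBq
injected), 30 CPM ambient background, and a radiometal-antibody-like uptake
pattern (tumor 15, liver 12, blood 10 … muscle 1.2 %ID g⁻¹) with per-animal
lognormal biological scatter parameterized so the stated value is the
population mean. Per-tissue organ masses are approximate adult-mouse values;
they are configuration, not claims.

Model details that matter for interpretation:

* **Balance quantization is part of the truth.** All masses are recorded to
  4 decimal places (analytical-balance resolution) and the ground truth is
  derived from the quantized recordings, so zero-noise analysis recovers the
  truth to machine precision. Dose-calibrator readings are kept at full
  float precision for the same reason.
* **Counting queue.** Tubes are counted one per interval (default 60 s);
  the sample signal decays while queued and the simulated counter's decay
  correction restores it to the protocol start. The stationary ambient
  background is not subjected to the correction — an idealization (a real
  counter corrects gross counts, inflating background by up to
  `e^(λ·queue) − 1`, ~0.3% of 30 CPM for ⁸⁹Zr here). Poisson noise draws
  signal and background counts separately; the sum of the two Poisson draws
  is distributed identically to a gross-count draw.
* **What it does not emulate:** tracer sticking, partial injections, organ
  cross-contamination, counter dead-time/saturation, energy-window spillover
  and daughter redistribution. Passing the round-trip tests therefore shows
  the *arithmetic chain* is faithful, not that real-data artifacts are
  handled — those surface as flags and warnings, not corrections.

`generate_wholebody` produces `A(t) = A0·e^(−(λ_phys+λ_bio)t)` with
multiplicative Gaussian noise on 8–10 points spanning ~2.5 effective
half-lives.

## Test problem sizes

The suite exercises the pipeline at deliberately compact sizes that keep
every check exact or statistically comfortable: round-trip studies of 1–2
groups × 3–4 animals × 8 tissues; Poisson-recovery coverage over 200
replicate studies at ≥10⁴ expected counts per tissue (group mean within 3
sample standard deviations of the population truth, per group × tissue
cell); fit recovery over 100 seeded noisy series; Bateman-vs-ODE agreement
over a 15-point rate grid including a near-degenerate pair.

## Known limitations

* Single mother–daughter Bateman pair (with effective branching ratio);
  longer chains must be composed by the user.
* No dead-time or saturation correction — tubes above a configured
  linear-range ceiling are flagged for recounting.
* Inferential statistics (t-tests, ANOVA) are intentionally absent; the CSV
  outputs are structured for direct import into statistics software.
* The spreadsheet-import shim is limited to CSV with documented headers;
  proprietary counter exports must be converted upstream.
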
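# biodist

Quantification toolkit for *ex vivo* biodistribution studies with
radiotracers in rodent models: from weighed syringes, counting standards and
gamma-counter CPM to decay-corrected **%ID g⁻¹**, **SUV** and
target-to-background **contrast ratios**, plus whole-body
**effective-half-life** fitting and **Bateman** decay-chain support for
alpha-emitter quantification.

## Who this is for

Radiochemistry and molecular-imaging labs that determine the injected dose
of each animal *gravimetrically*: every syringe is weighed full and empty on
an analytical balance, and one extra syringe (the counting standard) is
emptied into ~10 mL of water so that aliquots of the dilution can be counted
next to the tissues. This sidesteps dose-calibrator geometry errors at
sub-MBq activities and gamma-counter saturation of undiluted doses.

## The core arithmetic

With all CPM decay-corrected by the counter to the start of the counting
protocol (t_ref):

```
cf        = mean_i[ (CPM_i − background) / m_formulation,i ]   (CPM g⁻¹)
              where m_formulation,i = m_std · m_aliquot,i / m_stock
ID_cpm    = cf · (m_syringe,full − m_syringe,empty)
%ID g⁻¹   = 100 · (CPM_tissue − background) / ID_cpm / m_tissue
%ID organ = 100 · (CPM_tissue − background) / ID_cpm
SUV       = %ID g⁻¹ · BW / 100
```

Decay correction uses `A(t_ref) = A(t) · exp(−λ (t_ref − t))` with
`λ = ln 2 / t½` from a bundled table of 130 radionuclides. Whole-body
retention series are fitted with one- or two-phase exponentials (AICc model
selection, simplest model preferred); the effective half-life combines
physical decay and biological elimination via `1/t_eff = 1/t_phys + 1/t_bio`.
For gamma-quiet alpha emitters quantified through a detectable daughter, the
Bateman solution

```
A_d(t) = A_m(0) · λ_d/(λ_d − λ_m) · (e^(−λ_m t) − e^(−λ_d t)) · BR
```

and its secular limit `A_m(0)(1 − e^(−λ_d t))·BR` convert daughter counts to
mother activity (e.g. ²²⁵Ac via ²²¹Fr/²¹³Bi, ²²⁴Ra via ²¹²Pb).

## Worked example

Plan a five-animal study (one extra dose becomes the counting standard):

```
$ biodist plan -n 5 -v 100
total volume: 600 µL (6 syringes of 100 µL)
```

Generate a virtual ⁸⁹Zr study, validate it, and analyze it:

```
$ biodist simulate --out study/ --seed 11
wrote virtual study (4 animals, 40 tubes) to study/
$ biodist validate study/
OK: 4 injections, 40 counted tubes, no errors
$ biodist calibrate study/
{
  "cf_mass_cpm_per_g": 20000000.0,
  ...
}
$ biodist analyze study/ --out results/
wrote results to results/
```

`cf_mass_cpm_per_g` is the calibration factor: here every gram of the
injected formulation produces 2×10⁷ CPM at the counting reference time, so an
animal injected with 0.14 g received 2.8×10⁶ CPM-equivalents, and a tissue
tube's net CPM divided by that (and by the tissue mass, ×100) is its %ID g⁻¹.
`results/` contains `results_per_animal.csv` (per-tissue %ID g⁻¹, %ID organ,
SUV and quality flags), `group_summary.csv` (n, mean, sd, CV per group ×
tissue), `ratios.csv` (tumor-to-muscle contrast), `results.json` and a
`run_manifest.json` with input hashes for reproducibility.

Daughter ingrowth for ²²⁵Ac quantified through ²²¹Fr, 30 min after
separation:

```
$ biodist bateman --mother Ac-225 --daughter Fr-221 --time 0.5
{
  ...
  "A_mother_t": 0.9985453567764571,
  "A_daughter_t": 0.9857257830557746,
  "transient_ratio": 1.0003362045053366
}
```

After 0.5 h (≈6 daughter half-lives) the ²²¹Fr activity has grown to ~99% of
the mother's — counting any later reads the parent directly.

Effective half-life of an excreted tracer
(`wholebody.csv`: animal_id, t_hours, activity_MBq):

```
$ biodist halflife wholebody.csv --model auto --nuclide Zr-89
```

reports the fitted model, rate constants, effective half-life per phase, and
the biological half-life `1/t_bio = 1/t_eff − 1/t_phys`.

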
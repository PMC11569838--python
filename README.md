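# duplexkit

Biophysical analysis of short DNA duplexes carrying bulky lesions —
written for nucleic-acid chemists and DNA-repair labs who characterize
synthetic lesion analogs (here fluorescein-carbamoyl groups on a
propanediol backbone unit, with or without a hexanoyl linker) by how they
perturb duplex stability, geometry and repairability. The package turns
raw instrument tables into the standard comparative readouts:

* **Melting analysis** — fits the two-state hybridization model with
  sloping linear baselines to UV denaturation traces:
  A(T) = θ(T)·L_ds(T) + (1−θ(T))·L_ss(T), where θ solves the bimolecular
  mass-action equation K(T)·Ct·(1−θ)² = 2θ with
  K(T) = exp(−(ΔH° − T·ΔS°)/RT). Reports Tm (the θ = ½ temperature) and
  the hypochromic effect.
* **Van 't Hoff thermodynamics** — regresses 1/Tm on ln(Ct/4) across a
  strand-concentration ladder; ΔH° = R/slope, ΔS° = intercept·ΔH°,
  ΔG°₃₇ = ΔH° − 310.15·ΔS°, with delta-method uncertainties including the
  slope–intercept covariance, plus a consistency checker for published
  parameter tables.
* **Bend angles** — the cosine gel-mobility rule
  μ_mod/μ_unmod = cos(deflection/2), reported as the interior angle
  (180° = straight).
* **Titration metrics** — fluorophore-band (495 nm) hypochromic effect,
  fluorescence quenching and the 260-nm total-DNA trend across a
  complement-concentration series.
* **Excision kinetics** — background-corrected product-band time courses,
  per-time and time-averaged efficiency ratios between substrates with a
  replicate bootstrap interval.
* **Synthetic data** — a seeded generator emulating each instrument with
  known ground truth, so the whole pipeline is testable end to end.

See `docs/methods.md` for models, assumptions and design decisions.

## Worked example

Generate a synthetic bundle for the linkerless-lesion duplex (nFluS
scenario) and analyze it:

```bash
$ duplexkit simulate --scenario nFluS --seed 7 --out-dir sim
wrote synthetic bundle to sim/

$ duplexkit vanthoff sim/series.csv
dH = -108.6 +- 6.1 kcal/mol
dS = -311 +- 19 cal/(mol*K)
dG37 = -12.2 +- 0.3 kcal/mol
Tm(20 uM) = 50.9 degC  (r2 = 0.98747)
```

The six-point ladder (2.5–80 μM total strand, 0.3 °C Tm scatter) was
generated from ΔH° = −103.5 kcal/mol, ΔS° = −295 cal/(mol·K): the fit
recovers them within its own error bars, and shows the characteristic
pattern that ΔH/ΔS uncertainties are relatively large while the
anticorrelation of slope and intercept keeps ΔG°₃₇ tight (±0.3).

```bash
$ duplexkit melt-fit sim/melting.csv --ct-um 20
Tm = 51.18 degC
dH = -99.3 kcal/mol
dS = -282 cal/(mol*K)
hypochromicity = 14.44 %
ssr = 0.000815 AU^2; converged = True
```

A single noisy melt (σ = 0.002 AU) pins Tm to ~0.1 °C (truth: 51.04 °C at
20 μM) and the hypochromic effect to ~0.1% (truth: 14.3%); the
single-curve ΔH is soft, which is exactly why the ladder fit above exists.

```bash
$ duplexkit titrate sim/spectra_absorbance.csv
hypochromic effect at 495 nm: 39.9 %
monotone: True (direction -1)

$ duplexkit excision sim/bands.csv --n-boot 2000 --seed 7
  t = 5 min: ratio 1.901
  ...
  t = 60 min: ratio 1.498
summary ratio nFluS/nFluL = 1.791 [1.741, 1.844] (2000 bootstrap draws)
```

The fluorescein band loses 40% of its intensity at strand saturation
(the lesion's fluorophore stacking inside the duplex), and the excision
time courses show the linkerless lesion removed 1.5–2× more efficiently
than the linkered one across the whole incubation, summarized by the
time-averaged ratio with its replicate bootstrap interval.

Library use mirrors the CLI: each stage is a plain function over small
dataclasses (`fit_melting_curve`, `fit_vant_hoff`, `bend_angle`,
`hypochromic_effect`, `efficiency_ratio`, ...), and
`duplexkit pipeline run.cfg` chains stages from a flat key=value config.

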
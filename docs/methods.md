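# Methods

`duplexkit` analyzes the biophysics of short (here 16-bp) DNA duplexes in
which one strand carries a bulky fluorescein-carbamoyl lesion on a
propanediol backbone unit — with a hexanoyl linker (nFluL) or without
(nFluS) — alongside the unmodified duplex (NM). Five measurement types are
covered: UV melting, Tm-versus-concentration (van 't Hoff) ladders,
nondenaturing gel mobility, complement-titration spectra, and in-vitro
excision time courses. This note records the models, the parameters that
matter, and the design choices that were genuinely open.

## Two-state hybridization model

A non-self-complementary bimolecular equilibrium A + B ⇌ AB with equimolar
strands is assumed throughout: every strand is either fully duplexed or
fully single-stranded, with no populated intermediates. With
K(T) = exp(−(ΔH° − T·ΔS°)/(R·T)) and Ct the **total** single-strand
concentration (both strands summed — conventions differ by a factor of 2;
this one is the one under which the linearization coordinate is ln(Ct/4)),
the duplex fraction θ solves

    K(T) · Ct · (1 − θ)² = 2θ,

implemented in the cancellation-free closed form
θ = a/(a + 1 + √(2a+1)), a = K·Ct, with a large-`a` (log-space) branch so
no intermediate overflows. Setting θ = ½ gives

    Tm = ΔH° / (ΔS° + R·ln(Ct/4)).

Units: calories internally (R = 1.9872 cal·mol⁻¹·K⁻¹, matching the
calorie-unit reporting convention of the field's tables), kcal/mol and °C
at reporting boundaries, Kelvin inside. ΔH° < 0 and ΔS° < 0 are enforced at
construction — duplex formation is enthalpy-driven — and self-complementary
molecularity is out of scope. No nearest-neighbor prediction, salt
correction, or heat-capacity (ΔCp) term is included.

## Melting-curve fitting

An absorbance trace A(T) is modelled as
θ(T)·(b_ds + m_ds·T) + (1−θ(T))·(b_ss + m_ss·T): the two-state population
mixing two *linear* optical baselines (standard for short-duplex UV melts;
no published functional form dictates otherwise). Preprocessing subtracts
the 300-nm reference channel pointwise, sorts by temperature and averages
duplicates. Heating and cooling ramps are fitted separately; a merge helper
averages a pair after a hysteresis check (midpoint difference > 1 °C flags
the merged curve and warns — hysteresis is diagnostic, not an error).

The six parameters are estimated by derivative-free Nelder–Mead simplex
minimization of the residual sum of squares, in the better-conditioned
(Tm, ΔH) coordinates (ΔS follows from the Tm identity). Details:

* **Initialization.** Tm from the smoothed-derivative maximum
  (Savitzky–Golay, window 11, order 2, on a uniform resampled grid);
  baselines from straight-line fits to the outer 20% of the range; ΔH from
  the transition breadth via dθ/dT|Tm = ΔH/(6·R·Tm²), the bimolecular
  two-state relation.
* **Restarts.** 5 starts (first from the heuristic, rest jittered with a
  seeded generator: ±0.5 °C in Tm, ±10% in ΔH); each start chains simplex
  runs (re-initializing the simplex at the current best) until improvement
  falls below 10⁻¹² AU², capped at 10⁴ evaluations. Best SSR wins; ties
  break toward the derivative-Tm. `converged` is false when near-optimal
  restarts (SSR within 2× of best) disagree by > 0.5 °C in Tm.
* **Guards.** < 20 points or a span < 30 °C is an identifiability error; a
  trace with no interior derivative maximum is rejected as non-sigmoidal.

**Tm is defined as θ = ½ of the fitted model**, not the derivative
maximum: with sloping baselines and the asymmetric bimolecular θ(T), the
dA/dT peak sits systematically ~1 °C *above* the half-dissociation point
(for the nFluL-like parameter range), and the van 't Hoff relation
presumes the θ = ½ definition. `derivative_tm` is retained for
initialization and QC only.

**Hypochromicity** is reported as h = 100·(A_ss(Tm) − A_ds(Tm))/A_ss(Tm)
with both baselines extrapolated to the fitted Tm. The evaluation
temperature is this package's choice — the percentage is baseline-ratio
based and no convention fixes the temperature; evaluating at Tm makes h a
property of the fit rather than of the grid ends.

## Van 't Hoff concentration series

1/Tm (K⁻¹) is regressed on ln(Ct/4) by ordinary least squares (unweighted
by default, matching how such fits are usually described; inverse-variance
weighting by per-point Tm errors is available). Then ΔH° = R/slope,
ΔS° = intercept·ΔH°, and ΔG°₃₇ = ΔH° − 310.15·ΔS°. Uncertainties come from
the slope–intercept covariance by first-order (delta-method) propagation
**including the covariance term**: slope and intercept are strongly
anticorrelated, which is why ΔH/ΔS uncertainties of tens of percent
coexist with a ΔG°₃₇ uncertainty several-fold smaller (the synthetic
ladders reproduce this ~2× collapse). A ladder narrower than 8× in Ct is
flagged low-leverage. An instrument-resolution floor for the reported Tm
uncertainty can be supplied and is added in quadrature.

`check_row_consistency` cross-checks a published (ΔS°, ΔH°, ΔG°₃₇, Tm) row
against the closed forms. Tolerances (0.3 kcal/mol on ΔG°₃₇, 1.0 °C on Tm)
were set from printed-precision propagation — last-digit rounding of a
table's ΔH (±0.05 kcal) and ΔS (±0.5 cal) moves the closed-form Tm by
~0.5 °C and ΔG by ~0.2 kcal — so rounding passes while genuinely
inconsistent rows flag.

## Gel bend angles

The classical cosine mobility rule relates retarded nondenaturing-gel
migration of a bent duplex to the helix-axis deflection:
μ_mod/μ_unmod = cos(deflection/2), reported as the interior angle
180° − deflection (180° = straight). The rule is applied without any
gel-dependent calibration factor. A ratio > 1 (modified faster than
unmodified) is an anomalous-mobility error, not silently accepted.
Replicate lane ratios propagate to an angle uncertainty by first-order
expansion of arccos (singular at ratio 1, reported as infinite there).
Band calling from gel images is upstream and out of scope.

## Titration metrics

Band intensities are windowed maxima (±5 nm default) rather than single
grid points, robust to small environment-induced peak shifts on 1-nm
grids. The 495-nm (fluorescein-band) hypochromic effect is
100·(V_control − V_saturation)/V_control, compared directly against the
zero-complement control **without dilution correction**, valid because the
fluorophore-bearing strand is at fixed concentration in every sample (a
dilution-correction hook exists for other designs). Fluorescence quenching
is 1 − peak_i/peak_control over the scan range. The 260-nm trend is
diagnosed with a straight-line fit against total strand concentration;
with the default tight-binding design and complement ≤ modified strand,
the duplex amount is linear in complement, so a zero residual is the
expected outcome and curvature appears only with finite-Kd binding.
No binding-isotherm (Kd) fit is attempted: a 4-point series approaching
1:1 stoichiometry cannot constrain one, so the metrics stay descriptive.

## Excision kinetics

This module consumes band-intensity tables (densitometry is upstream).
Each replicate course is background-corrected by its time-zero point
(negatives clamp to zero with a warning); the efficiency contrast between
substrates is the **ratio of replicate-mean signals per time point** (not
the mean of per-replicate ratios, which is unstable at early low-signal
times), with time zero excluded, averaged over times for the summary. The
interval is a seeded percentile bootstrap resampling *replicates* (time
points within a course are not exchangeable). Swapping numerator and
denominator inverts every per-time ratio exactly. Replicate scatter uses
the sample SD with the n−1 denominator.

A caveat worth stating: with saturating signals the per-time signal ratio
is a time-dependent quantity — for equal plateaus and rates k and 2k it is
exactly 1 + e^(−k·t), i.e. near 2 at early times, decaying toward 1 — so
the time-averaged summary estimates the *signal* contrast over the sampled
window, not the underlying rate ratio. Percentile bootstrap intervals from
three replicates are additionally narrow in the small-sample regime
(coverage ≈ 0.77 for a mean-type statistic at n = 3); they should be read
as reproducibility bands, not calibrated 95% confidence sets.

## Synthetic-data generator

Every instrument is emulated with its statistical structure and its ground
truth returned alongside (and written to a manifest by the `simulate`
command), so recovery tests never re-derive truth from outputs. Same seed
and config give bit-identical results; the generators draw from
independent substreams, and files are written with 12 significant digits.

* **Scenario presets** carry the three duplexes' thermodynamics
  (NM −140.0 kcal/mol, −382 cal·mol⁻¹K⁻¹; nFluL −119.4, −339; nFluS
  −103.5, −295), melting hypochromicities (14.75/13.5/14.3%), 495-nm
  saturation effects (nFluL 20%, nFluS 40%), fluorescence quench depths
  (nFluL 0.05 — "virtually unchanged"; nFluS 0.50 — a marked, steady
  decrease) and the 2× excision-rate contrast.
* **Melting curves**: 5–95 °C at 0.5 °C steps, model truth plus i.i.d.
  Gaussian noise σ = 0.002 AU; the single-strand baseline is pinned to
  1.000 AU at Tm with slopes 3.0/1.5 × 10⁻⁴ AU/°C, and the duplex baseline
  offset realizes the preset hypochromicity at Tm.
* **Ladders**: closed-form Tm per concentration plus 0.3 °C Gaussian
  scatter (the instrument-resolution scale).
* **Titration**: modified strand fixed at 5.4 μM, complement
  {1.25, 2.7, 4.05, 5.4} μM (the interior grid points are a design choice;
  only the endpoints are externally fixed). Spectra are additive Gaussian
  bands: a 260-nm nucleobase band growing with total strand (damped by the
  duplex hypochromic term), a 495-nm fluorescein band scaled by
  (1 − effect·bound), and single fluorescence bands scaled by
  (1 − quench·bound). Bound fractions use the tight-binding
  (stoichiometric) limit — 16-mers at μM are orders of magnitude past Kd
  at room temperature — with an optional finite-Kd mass-action mode.
  Noise: 0.5% of the control peak.
* **Excision**: S(t) = A·(1 − e^(−k·t)) + background on a 0–60 min grid,
  equal plateaus, k_nFluL = ln 2/60 ≈ 0.0116 min⁻¹ and k_nFluS = 2×, three
  replicates, 5% multiplicative band noise, background 2% of plateau. The
  rate scale was chosen so that the slower substrate reaches half its
  plateau by the end of the window, making the per-time signal ratio span
  ≈1.9 → 1.5 across the course — the "1.5–2× throughout the experiment"
  regime this assay type reports — with a time-averaged summary ≈ 1.75.

What the generator does **not** emulate: sequence-dependent
(nearest-neighbor) thermodynamics, baseline curvature or drift,
wavelength-dependent noise, gel-image artifacts (smiles, streaks),
inter-day instrument effects, or partial-duplex intermediates. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise models, not robustness to every failure mode of real
instruments.

## Numerical choices and degenerate inputs

Simplex tolerances: SSR 10⁻¹² AU² absolute, 10⁴ evaluations per start.
Duplicate temperatures are averaged, not dropped. A constant-valued or
monotone trace raises a no-transition/fit-rejected error rather than
returning a boundary Tm. The bootstrap drops time points with zero
denominator mean before forming ratios and errors only when none remain.
Two-point van 't Hoff fits are allowed only when explicitly requested
(`min_points=2`) and report zero covariance. All file I/O is plain
delimited text with '#' comments, dot decimals, and headers; every writer
output round-trips through its own reader.

## Problem sizes used in checks

The bundled checks fit 50 seeded melting curves for the recovery
benchmark, use a 10³-combination grid against the bisection oracle,
6-point concentration ladders, 4-sample titration series, and 100 seeded
excision runs at 2,000 bootstrap draws — sizes at which all estimator
properties stated above are resolved.
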
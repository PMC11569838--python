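"""Spectral titration metrics for duplex formation.

A strand carrying a fluorophore-bearing lesion is held at fixed
concentration while the unmodified complement is titrated in; absorbance
or fluorescence spectra are recorded per sample together with a
zero-complement control.  Three descriptive readouts:

* the 260-nm band should grow roughly linearly with total strand
  concentration (it tracks total DNA), with a hypochromic deceleration
  from duplex formation;
* the fluorophore absorption band (fluorescein: 495 nm) loses intensity
  when the fluorophore stacks inside the duplex — the hypochromic effect
  at saturation is the headline number;
* fluorescence quenching across the series reports on fluorophore–base
  contacts in the duplex.

Band intensities use a windowed maximum (±5 nm default) rather than a
single grid point, so small environment-induced peak shifts do not bias
the metric.  No binding-isotherm fitting is attempted: with a handful of
points approaching 1:1 stoichiometry the series cannot constrain a Kd,
and the metrics stay descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FormatError, InsufficientDataError

_MODES = ("absorbance", "excitation", "emission")


@dataclass
class SpectrumSeries:
    """Spectra indexed by complement concentration, plus a control.

    ``intensities`` has shape (n_samples, n_wavelengths); ``control`` is
    the zero-complement spectrum on the same grid.  ``modified_conc`` is
    the fixed concentration of the lesion-bearing strand (mol/L).
    """

    wavelengths: np.ndarray
    complement_concs: np.ndarray  # mol/L, strictly increasing
    intensities: np.ndarray
    control: np.ndarray
    mode: str = "absorbance"
    modified_conc: float = 5.4e-6
    fixed_wavelength: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.complement_concs = np.asarray(self.complement_concs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.mode not in _MODES:
            raise FormatError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.intensities.shape != (
            len(self.complement_concs),
            len(self.wavelengths),
        ):
            raise FormatError("intensity matrix shape mismatch")
        if self.control.shape != self.wavelengths.shape:
            raise FormatError("control spectrum shape mismatch")
        if np.any(np.diff(self.complement_concs) <= 0):
            raise FormatError("complement concentrations must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.complement_concs)


@dataclass
class TitrationSummary:
    band_values: np.ndarray  # per sample, control excluded
    control_value: float
    hypochromic_effect_pct: float
    monotone_flag: bool
    direction: int  # -1 decreasing, +1 increasing, 0 flat/non-monotone


def _monotone_direction(values: np.ndarray) -> tuple[bool, int]:
    d = np.diff(values)
    if np.all(d <= 0) and np.any(d < 0):
        return True, -1
    if np.all(d >= 0) and np.any(d > 0):
        return True, 1
    if np.all(d == 0):
        return True, 0
    return False, 0


def band_value(
    series: SpectrumSeries, center: float, halfwidth: float = 5.0
) -> tuple[float, np.ndarray]:
    """Windowed-maximum intensity at a band for the control and each sample.

    The value is the maximum inside [center − halfwidth, center + halfwidth];
    the window must lie inside the recorded wavelength grid.
    """
    wl = series.wavelengths
    lo, hi = center - halfwidth, center + halfwidth
    if lo < wl.min() or hi > wl.max():
        raise DomainError(
            f"band window [{lo}, {hi}] nm outside the recorded grid "
            f"[{wl.min()}, {wl.max()}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    control_value = float(series.control[mask].max())
    sample_values = series.intensities[:, mask].max(axis=1)
    return control_value, sample_values


def hypochromic_effect(
    series: SpectrumSeries, center: float = 495.0, halfwidth: float = 5.0
) -> TitrationSummary:
    """Percent intensity loss at a band, saturation sample vs control.

    effect = 100·(V_control − V_last)/V_control with V the windowed band
    value and "last" the highest complement concentration.  Positive means
    hypochromism (intensity loss on duplex formation).  Comparing straight
    against the zero-complement control is valid when the band belongs to
    the fixed-concentration strand (no dilution correction needed).
    """
    if series.n_samples < 2:
        raise InsufficientDataError("need at least 2 titration samples")
    v_control, v_samples = band_value(series, center, halfwidth)
    if v_control <= 0:
        raise DomainError("control band value must be positive")
    effect = 100.0 * (v_control - v_samples[-1]) / v_control
    monotone, direction = _monotone_direction(
        np.concatenate([[v_control], v_samples])
    )
    return TitrationSummary(
        band_values=v_samples,
        control_value=v_control,
        hypochromic_effect_pct=float(effect),
        monotone_flag=monotone,
        direction=direction,
    )


@dataclass
class QuenchResult:
    fractions: np.ndarray  # per sample: 1 - peak_i / peak_control
    monotone_flag: bool
    direction: int


def quench_fraction(series: SpectrumSeries) -> QuenchResult:
    """Fractional loss of the fluorescence peak relative to the control.

    fraction_i = 1 − max(spectrum_i)/max(control), the peak searched over
    the full scan range.  Negative fractions mean enhancement.
    """
    if series.mode not in ("excitation", "emission"):
        raise FormatError("quench_fraction requires a fluorescence series")
    peak_control = float(series.control.max())
    if peak_control <= 0:
        raise DomainError("control fluorescence peak must be positive")
    peaks = series.intensities.max(axis=1)
    fractions = 1.0 - peaks / peak_control
    monotone, direction = _monotone_direction(np.concatenate([[0.0], fractions]))
    return QuenchResult(fractions=fractions, monotone_flag=monotone,
                        direction=direction)


@dataclass
class A260Trend:
    values: np.ndarray  # per sample, 260-nm band
    control_value: float
    total_concs: np.ndarray  # mol/L, modified + complement
    slope: float | None
    intercept: float | None
    rms_residual: float | None  # None when the line is undetermined


def a260_trend(series: SpectrumSeries, halfwidth: float = 5.0) -> A260Trend:
    """260-nm band values and a straight-line diagnostic vs total DNA.

    The nucleobase band grows with total strand concentration; the
    residual of a line fit against (modified + complement) concentration
    diagnoses whether the growth simply tracks total DNA or decelerates
    from duplex hypochromism.
    """
    if series.mode != "absorbance":
        raise FormatError("a260_trend requires an absorbance series")
    v_control, v_samples = band_value(series, 260.0, halfwidth)
    totals = series.modified_conc + series.complement_concs
    all_x = np.concatenate([[series.modified_conc], totals])
    all_y = np.concatenate([[v_control], v_samples])
    slope = intercept = rms = None
    if len(all_x) >= 3:
        coef = np.polyfit(all_x, all_y, 1)
        resid = all_y - np.polyval(coef, all_x)
        slope, intercept = float(coef[0]), float(coef[1])
        rms = float(np.sqrt(np.mean(resid**2)))
    return A260Trend(
        values=v_samples,
        control_value=v_control,
        total_concs=totals,
        slope=slope,
        intercept=intercept,
        rms_residual=rms,
    )
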
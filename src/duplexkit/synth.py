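"""Synthetic instrument data with known ground truth.

Every input the analysis stages consume can be generated here: UV melting
traces, Tm-versus-concentration ladders, titration spectra and excision
time courses.  Each generator draws from a seeded generator (same seed and
config give bit-identical output) and returns the ground truth alongside
the data, so parameter-recovery tests never re-derive truth from the
simulated output itself.

Scenario presets carry the three study duplexes: an unmodified 16-mer (NM)
and the same duplex with a fluorescein-carbamoyl lesion on a propanediol
backbone unit, either with a hexanoyl linker (nFluL) or without (nFluS).
The presets encode their van 't Hoff parameters, melting hypochromicities,
495-nm titration effects, fluorescence quench depths and relative excision
rates (nFluS excised twice as fast as nFluL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import thermo
from .errors import ConfigError, DomainError
from .excision import ExcisionTimecourse
from .meltfit import BaselinePair, MeltingCurve, model_absorbance
from .thermo import StrandConcentration, ThermoParams
from .titration import SpectrumSeries
from .vanthoff import ConcentrationSeries, SeriesPoint

#: Base excision rate of the slower substrate (min^-1).  ln(2)/60 puts the
#: slow substrate at half its plateau by the end of the 60-min window, so the
#: per-time signal ratio of the two substrates spans ~1.9 down to 1.5 — the
#: regime the assay actually samples.
K_EXCISION_SLOW = math.log(2.0) / 60.0


@dataclass(frozen=True)
class ScenarioPreset:
    """Ground-truth physical parameters of one duplex scenario."""

    name: str
    dH_kcal: float
    dS: float  # cal/(mol*K)
    hypochromicity_pct: float  # UV melting, at Tm
    effect495: float  # fractional 495-nm band loss at saturation
    quench: float  # fractional fluorescence loss at saturation
    excision_rate: float | None  # min^-1; None = not a repair substrate

    @property
    def params(self) -> ThermoParams:
        return ThermoParams.from_kcal(self.dH_kcal, self.dS)


SCENARIOS: dict[str, ScenarioPreset] = {
    "NM": ScenarioPreset(
        name="NM", dH_kcal=-140.0, dS=-382.0, hypochromicity_pct=14.75,
        effect495=0.0, quench=0.0, excision_rate=None,
    ),
    "nFluL": ScenarioPreset(
        name="nFluL", dH_kcal=-119.4, dS=-339.0, hypochromicity_pct=13.5,
        effect495=0.20, quench=0.05, excision_rate=K_EXCISION_SLOW,
    ),
    "nFluS": ScenarioPreset(
        name="nFluS", dH_kcal=-103.5, dS=-295.0, hypochromicity_pct=14.3,
        effect495=0.40, quench=0.50, excision_rate=2.0 * K_EXCISION_SLOW,
    ),
}

# Distinct stream tags so the generators consume independent substreams of
# the same seed.
_TAG_MELT, _TAG_SERIES, _TAG_TITRATION, _TAG_EXCISION = 11, 23, 37, 53


@dataclass
class GeneratorConfig:
    """Design of the simulated experiments.

    Noise defaults: 0.002 AU on melting absorbances, 0.5% of the control
    peak on spectra, 5% relative on gel bands, 0.3 °C on ladder Tm values.
    The temperature grid (5–95 °C, 0.5 °C steps) and the titration design
    (modified strand fixed at 5.4 μM, complement 1.25–5.4 μM) mirror the
    bench protocols this package analyzes.
    """

    seed: int = 0
    scenario: str = "nFluL"
    melting_sigma: float = 0.002  # AU
    spectrum_sigma_frac: float = 0.005  # of control peak
    band_sigma_frac: float = 0.05  # relative, gel bands
    tm_sigma: float = 0.3  # degC, concentration ladders
    t_min: float = 5.0  # degC
    t_max: float = 95.0
    t_step: float = 0.5
    titration_concs_uM: tuple = (1.25, 2.7, 4.05, 5.4)
    modified_conc_uM: float = 5.4
    excision_times: tuple = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)
    excision_replicates: int = 3
    excision_amplitude: float = 1000.0  # AU, plateau (equal across substrates)
    excision_background: float = 20.0  # AU
    titration_kd: float | None = None  # mol/L; None = tight-binding limit
    custom_preset: ScenarioPreset | None = None

    def preset(self) -> ScenarioPreset:
        if self.scenario == "custom":
            if self.custom_preset is None:
                raise ConfigError("scenario 'custom' requires custom_preset")
            return self.custom_preset
        try:
            return SCENARIOS[self.scenario]
        except KeyError:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; "
                f"choose from {sorted(SCENARIOS)} or 'custom'"
            ) from None

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def gen_melting_curve(
    cfg: GeneratorConfig, ct: StrandConcentration
) -> tuple[MeltingCurve, dict]:
    """Simulate one UV melting trace for the configured scenario.

    The noiseless truth is the two-state model with linear baselines whose
    separation at Tm reproduces the scenario's hypochromicity; i.i.d.
    Gaussian noise of ``melting_sigma`` AU is added on top.  Returns the
    curve and a ground-truth manifest.
    """
    preset = cfg.preset()
    params = preset.params
    tm = thermo.predict_tm(params, ct)
    # Single-strand baseline pinned to 1.000 AU at Tm; slopes typical of
    # short-duplex UV melts.
    m_ss, m_ds = 3.0e-4, 1.5e-4
    b_ss = 1.0 - m_ss * tm
    a_ds_tm = 1.0 - preset.hypochromicity_pct / 100.0
    b_ds = a_ds_tm - m_ds * tm
    baselines = BaselinePair(m_ds=m_ds, b_ds=b_ds, m_ss=m_ss, b_ss=b_ss)

    temps = np.arange(cfg.t_min, cfg.t_max + cfg.t_step / 2, cfg.t_step)
    clean = model_absorbance(params, baselines, ct, temps)
    noise = cfg.rng(_TAG_MELT).normal(0.0, cfg.melting_sigma, size=temps.shape)
    curve = MeltingCurve(
        temperatures=temps,
        absorbances=clean + (noise if cfg.melting_sigma > 0 else 0.0),
        ct=ct,
        wavelength=260.0,
        ramp="heating",
        label=f"{preset.name} synthetic",
    )
    truth = {
        "scenario": preset.name,
        "dH_kcal": preset.dH_kcal,
        "dS": preset.dS,
        "tm_C": tm,
        "hypochromicity_pct": preset.hypochromicity_pct,
        "baselines": baselines,
        "Ct": ct.Ct,
        "sigma_AU": cfg.melting_sigma,
    }
    return curve, truth


def gen_concentration_series(
    cfg: GeneratorConfig, ct_list_uM
) -> tuple[ConcentrationSeries, dict]:
    """Tm-versus-concentration ladder from the closed-form Tm plus noise."""
    preset = cfg.preset()
    params = preset.params
    rng = cfg.rng(_TAG_SERIES)
    points = []
    for ct_uM in ct_list_uM:
        ct = StrandConcentration.from_micromolar(ct_uM)
        tm = thermo.predict_tm(params, ct)
        if cfg.tm_sigma > 0:
            tm += rng.normal(0.0, cfg.tm_sigma)
        points.append(SeriesPoint(ct=ct.Ct, tm_C=tm, tm_err_C=cfg.tm_sigma or None))
    series = ConcentrationSeries(points=points, label=f"{preset.name} synthetic")
    truth = {
        "scenario": preset.name,
        "dH_kcal": preset.dH_kcal,
        "dS": preset.dS,
        "tm_sigma_C": cfg.tm_sigma,
    }
    return series, truth


def _bound_fraction(cfg: GeneratorConfig, comp: float, modified: float) -> float:
    """Fraction of the modified strand in duplex.

    Default is the tight-binding (stoichiometric) limit — μM strands far
    above Kd — with an optional finite-Kd mass-action mode for robustness
    studies.
    """
    if cfg.titration_kd is None:
        return min(comp, modified) / modified
    kd = cfg.titration_kd
    if kd <= 0:
        raise DomainError("titration_kd must be positive")
    s = comp + modified + kd
    dup = (s - math.sqrt(s * s - 4.0 * comp * modified)) / 2.0
    return dup / modified


def gen_titration_series(
    cfg: GeneratorConfig, mode: str = "absorbance"
) -> tuple[SpectrumSeries, dict]:
    """Simulate a complement-titration spectrum series plus control.

    Absorbance spectra carry a 260-nm nucleobase band that grows with total
    strand concentration (damped by a duplex hypochromic term) and a 495-nm
    fluorescein band scaled by (1 − effect·bound).  Fluorescence scans
    carry a single band scaled by (1 − quench·bound).  Noise is additive
    Gaussian, ``spectrum_sigma_frac`` of the control peak.
    """
    preset = cfg.preset()
    modified = cfg.modified_conc_uM * 1e-6
    concs = np.array(sorted(cfg.titration_concs_uM)) * 1e-6
    bound = np.array([_bound_fraction(cfg, c, modified) for c in concs])

    if mode == "absorbance":
        wl = np.arange(220.0, 600.0 + 0.5, 1.0)
        e260 = 0.15e6  # AU per mol/L of total strand
        e495 = 0.075e6  # AU per mol/L of fluorophore-bearing strand
        h260 = preset.hypochromicity_pct / 100.0

        def spectrum(comp: float, b: float) -> np.ndarray:
            total = modified + comp
            dup = b * modified
            frac_duplexed = 2.0 * dup / total
            a260 = e260 * total * (1.0 - h260 * frac_duplexed)
            a495 = e495 * modified * (1.0 - preset.effect495 * b)
            return a260 * _gaussian(wl, 260.0, 18.0) + a495 * _gaussian(wl, 495.0, 15.0)

        control = spectrum(0.0, 0.0)
        samples = np.array([spectrum(c, b) for c, b in zip(concs, bound)])
        fixed_wavelength = None
    elif mode in ("excitation", "emission"):
        if mode == "excitation":
            wl = np.arange(420.0, 520.0 + 0.5, 1.0)
            center, width, fixed_wavelength = 495.0, 22.0, 548.0
        else:
            wl = np.arange(500.0, 600.0 + 0.5, 1.0)
            center, width, fixed_wavelength = 520.0, 18.0, 533.0
        f0 = 1000.0  # counts at the control peak

        def fl_spectrum(b: float) -> np.ndarray:
            return f0 * (1.0 - preset.quench * b) * _gaussian(wl, center, width)

        control = fl_spectrum(0.0)
        samples = np.array([fl_spectrum(b) for b in bound])
    else:
        raise ConfigError(f"unknown titration mode {mode!r}")

    if cfg.spectrum_sigma_frac > 0:
        rng = cfg.rng(_TAG_TITRATION)
        sigma = cfg.spectrum_sigma_frac * control.max()
        control = control + rng.normal(0.0, sigma, size=control.shape)
        samples = samples + rng.normal(0.0, sigma, size=samples.shape)

    series = SpectrumSeries(
        wavelengths=wl,
        complement_concs=concs,
        intensities=samples,
        control=control,
        mode=mode,
        modified_conc=modified,
        fixed_wavelength=fixed_wavelength,
        label=f"{preset.name} synthetic {mode}",
    )
    truth = {
        "scenario": preset.name,
        "effect495": preset.effect495,
        "quench": preset.quench,
        "bound_fractions": bound,
        "saturation_effect_pct": 100.0 * preset.effect495 * bound[-1],
        "saturation_quench": preset.quench * bound[-1],
    }
    return series, truth


def gen_excision_timecourses(
    cfg: GeneratorConfig,
) -> tuple[dict[str, list[ExcisionTimecourse]], dict]:
    """Simulate replicate excision time courses for both lesion substrates.

    Signal model: S(t) = A·(1 − exp(−k·t)) + background with equal
    plateaus A across substrates and the nFluS:nFluL rate ratio of 2
    carried by the rates; multiplicative Gaussian noise of
    ``band_sigma_frac`` on every band.
    """
    rng = cfg.rng(_TAG_EXCISION)
    times = np.array(cfg.excision_times, dtype=float)
    out: dict[str, list[ExcisionTimecourse]] = {}
    rates = {}
    for name in ("nFluL", "nFluS"):
        k = SCENARIOS[name].excision_rate
        rates[name] = k
        clean = cfg.excision_amplitude * (1.0 - np.exp(-k * times)) + cfg.excision_background
        courses = []
        for rep in range(cfg.excision_replicates):
            noisy = clean * (
                1.0 + cfg.band_sigma_frac * rng.standard_normal(times.shape)
                if cfg.band_sigma_frac > 0
                else 1.0
            )
            courses.append(
                ExcisionTimecourse(
                    substrate=name,
                    times=times,
                    intensities=np.clip(noisy, 0.0, None),
                    replicate_id=str(rep + 1),
                )
            )
        out[name] = courses
    truth = {
        "rates_per_min": rates,
        "rate_ratio_nFluS_over_nFluL": rates["nFluS"] / rates["nFluL"],
        "amplitude": cfg.excision_amplitude,
        "background": cfg.excision_background,
        "band_sigma_frac": cfg.band_sigma_frac,
    }
    return out, truth


def truth_manifest_lines(truth: dict) -> list[str]:
    """Flatten a ground-truth dict into key=value text lines."""
    lines = []
    for key, val in truth.items():
        if isinstance(val, BaselinePair):
            for f in ("m_ds", "b_ds", "m_ss", "b_ss"):
                lines.append(f"{key}.{f}={getattr(val, f):.12g}")
        elif isinstance(val, dict):
            for k2, v2 in val.items():
                lines.append(f"{key}.{k2}={v2:.12g}")
        elif isinstance(val, np.ndarray):
            lines.append(f"{key}=" + ",".join(f"{v:.12g}" for v in val))
        elif isinstance(val, float):
            lines.append(f"{key}={val:.12g}")
        else:
            lines.append(f"{key}={val}")
    return lines
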
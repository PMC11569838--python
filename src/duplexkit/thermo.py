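"""Two-state bimolecular hybridization thermodynamics.

A short non-self-complementary duplex A + B ⇌ AB with equimolar strands is
described by a van 't Hoff enthalpy ΔH° and entropy ΔS° (both negative for
duplex formation).  With Ct the *total* single-strand concentration (both
strands summed), the equilibrium constant relates to the duplex fraction θ
through the mass-action equation

    K(T) · Ct · (1 − θ)² = 2 θ,

which puts the half-dissociation point (θ = 1/2) at K(Tm) = 4/Ct and gives
the closed-form melting temperature

    Tm = ΔH° / (ΔS° + R · ln(Ct/4)).

All enthalpies and entropies are kept in calorie units internally
(cal/mol and cal/(mol·K)); free energies are reported in kcal/mol and
temperatures in °C at the I/O boundaries, Kelvin internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: Gas constant in cal/(mol*K); every operation in the package uses this value.
R = 1.9872

#: 37 degC in Kelvin, the conventional reporting temperature for dG.
T37_K = 310.15

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class ThermoParams:
    """Van 't Hoff parameters of duplex formation.

    Parameters
    ----------
    dH : float
        Enthalpy change in cal/mol; must be negative (formation is
        enthalpy-driven).
    dS : float
        Entropy change in cal/(mol*K); must be negative.
    dH_err, dS_err : float, optional
        One-sigma uncertainties in the same units.
    """

    dH: float
    dS: float
    dH_err: float | None = None
    dS_err: float | None = None

    def __post_init__(self) -> None:
        if not (self.dH < 0 and self.dS < 0):
            raise DomainError(
                f"duplex formation requires dH < 0 and dS < 0, "
                f"got dH={self.dH}, dS={self.dS}"
            )

    @classmethod
    def from_kcal(
        cls,
        dH_kcal: float,
        dS: float,
        dH_err_kcal: float | None = None,
        dS_err: float | None = None,
    ) -> "ThermoParams":
        """Build from an enthalpy given in kcal/mol (the printed scale)."""
        return cls(
            dH=dH_kcal * 1000.0,
            dS=dS,
            dH_err=None if dH_err_kcal is None else dH_err_kcal * 1000.0,
            dS_err=dS_err,
        )

    @property
    def dH_kcal(self) -> float:
        return self.dH / 1000.0


@dataclass(frozen=True)
class StrandConcentration:
    """Total single-strand concentration Ct in mol/L.

    Ct sums BOTH strands of an equimolar duplex sample; this is the
    convention under which the van 't Hoff coordinate is ln(Ct/4).  Other
    conventions (per-duplex concentration) differ by a factor of 2.
    """

    Ct: float

    def __post_init__(self) -> None:
        if not self.Ct > 0:
            raise DomainError(f"Ct must be positive, got {self.Ct}")

    @classmethod
    def from_micromolar(cls, ct_uM: float) -> "StrandConcentration":
        return cls(ct_uM * 1e-6)

    @property
    def ln_ct_over_4(self) -> float:
        return math.log(self.Ct / 4.0)


def _check_temperature(T):
    if np.any(np.asarray(T) <= 0):
        raise DomainError("absolute temperature must be positive")


def equilibrium_constant(params: ThermoParams, T):
    """Equilibrium constant K(T) = exp(−ΔG°(T)/(R·T)) of duplex formation.

    ``T`` is in Kelvin and may be a scalar or array.  log K is affine in
    1/T (van 't Hoff behavior).
    """
    _check_temperature(T)
    T = np.asarray(T, dtype=float)
    exponent = -(params.dH - T * params.dS) / (R * T)
    with np.errstate(over="ignore"):
        out = np.exp(exponent)
    return out if out.ndim else float(out)


def fraction_duplex(params: ThermoParams, ct: StrandConcentration, T):
    """Fraction of strands in duplex form at temperature ``T`` (Kelvin).

    Solves K·Ct·(1−θ)² = 2θ for the root in [0, 1].  Written in the
    cancellation-free form θ = a / (a + 1 + sqrt(2a + 1)) with a = K·Ct,
    which is exact for both a → 0 and a → ∞.
    """
    _check_temperature(T)
    T_arr = np.asarray(T, dtype=float)
    scalar = T_arr.ndim == 0
    T_arr = np.atleast_1d(T_arr)
    # Work in log space so a = K*Ct never overflows before the final ratio.
    log_a = -(params.dH - T_arr * params.dS) / (R * T_arr) + math.log(ct.Ct)
    theta = np.empty_like(log_a)
    big = log_a > 600.0
    with np.errstate(over="ignore"):
        a = np.exp(np.where(big, 0.0, log_a))
    theta[~big] = a[~big] / (a[~big] + 1.0 + np.sqrt(2.0 * a[~big] + 1.0))
    # Large-a expansion: theta = 1 - sqrt(2/a) + O(1/a)
    theta[big] = 1.0 - np.sqrt(2.0) * np.exp(-log_a[big] / 2.0)
    return float(theta[0]) if scalar else theta


def delta_g(params: ThermoParams, T) -> float:
    """Free energy ΔG°(T) = ΔH° − T·ΔS° in kcal/mol (printed scale)."""
    _check_temperature(T)
    T = np.asarray(T, dtype=float)
    out = (params.dH - T * params.dS) / 1000.0
    return out if out.ndim else float(out)


def predict_tm(params: ThermoParams, ct: StrandConcentration) -> float:
    """Closed-form melting temperature in °C.

    Tm = ΔH° / (ΔS° + R·ln(Ct/4)); 1/Tm is affine in ln(Ct/4) with slope
    R/ΔH°, which is the linearization used for concentration-series fits.
    """
    denom = params.dS + R * ct.ln_ct_over_4
    if denom * params.dH <= 0:
        raise DomainError(
            "dS + R*ln(Ct/4) must share the sign of dH "
            f"(got denominator {denom:.4g} for dH {params.dH:.4g})"
        )
    tm_K = params.dH / denom
    return tm_K - CELSIUS_OFFSET
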
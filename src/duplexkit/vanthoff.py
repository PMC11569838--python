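"""Concentration-series (van 't Hoff) thermodynamics.

For a bimolecular non-self-complementary duplex the reciprocal melting
temperature is linear in the logarithm of the total strand concentration,

    1/Tm = ΔS°/ΔH° + (R/ΔH°) · ln(Ct/4),

so an ordinary least-squares line through (ln(Ct/4), 1/Tm) yields
ΔH° = R/slope and ΔS° = intercept·ΔH°.  Uncertainties are propagated to
ΔH°, ΔS° and ΔG°₃₇ by a first-order delta method from the full
slope–intercept covariance; the covariance term matters, because slope and
intercept are strongly anticorrelated and the individually huge ΔH/ΔS
errors collapse to a small ΔG°₃₇ error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, SignAnomalyError
from .thermo import (
    CELSIUS_OFFSET,
    R,
    T37_K,
    StrandConcentration,
    ThermoParams,
    delta_g,
    predict_tm,
)


@dataclass(frozen=True)
class SeriesPoint:
    ct: float  # mol/L, total single strand
    tm_C: float
    tm_err_C: float | None = None


@dataclass
class ConcentrationSeries:
    """Melting temperatures measured over a strand-concentration ladder."""

    points: list[SeriesPoint]
    label: str = ""
    low_leverage: bool = False

    def __post_init__(self) -> None:
        cts = [p.ct for p in self.points]
        if any(ct <= 0 for ct in cts):
            raise InsufficientDataError("all Ct values must be positive")
        if len(set(cts)) >= 2 and max(cts) / min(cts) < 8.0:
            # Narrow ladders fit, but the slope is poorly leveraged.
            self.low_leverage = True

    @property
    def ln_ct_over_4(self) -> np.ndarray:
        return np.log(np.array([p.ct for p in self.points]) / 4.0)

    @property
    def inv_tm(self) -> np.ndarray:
        return 1.0 / (np.array([p.tm_C for p in self.points]) + CELSIUS_OFFSET)


@dataclass
class VantHoffResult:
    params: ThermoParams  # carries dH_err/dS_err
    slope: float  # K^-1 per unit ln-concentration
    intercept: float  # K^-1
    r_squared: float
    dG37: float  # kcal/mol
    dG37_err: float  # kcal/mol
    covariance: np.ndarray  # 2x2 (slope, intercept)
    low_leverage: bool = False


def fit_vant_hoff(
    series: ConcentrationSeries,
    weighted: bool = False,
    min_points: int = 3,
) -> VantHoffResult:
    """Least-squares line through (ln(Ct/4), 1/Tm) and derived parameters.

    ``weighted=True`` applies inverse-variance weights from the per-point
    ``tm_err_C`` (default is the ordinary unweighted fit).  ``min_points``
    may be lowered to 2 for exact-interpolation checks.
    """
    n = len(series.points)
    if n < min_points or n < 2:
        raise InsufficientDataError(f"need at least {max(min_points, 2)} points, got {n}")
    x = series.ln_ct_over_4
    y = series.inv_tm
    if len(np.unique(x)) < 2:
        raise InsufficientDataError("need at least 2 distinct concentrations")

    w = None
    if weighted:
        errs = [p.tm_err_C for p in series.points]
        if any(e is None or e <= 0 for e in errs):
            raise InsufficientDataError("weighted fit requires positive tm_err_C")
        # sigma(1/Tm) = tm_err / Tm^2
        tm_K = np.array([p.tm_C for p in series.points]) + CELSIUS_OFFSET
        sigma_y = np.array(errs, dtype=float) / tm_K**2
        w = 1.0 / sigma_y

    if n > 2:
        coef, cov = np.polyfit(x, y, 1, w=w, cov="unscaled" if weighted else True)
    else:
        coef = np.polyfit(x, y, 1, w=w)
        cov = np.zeros((2, 2))
    slope, intercept = float(coef[0]), float(coef[1])
    if slope >= 0:
        raise SignAnomalyError(
            f"1/Tm vs ln(Ct/4) slope is {slope:.3g}; a forming duplex "
            "(dH < 0) requires a negative slope"
        )

    dH = R / slope
    dS = intercept * dH
    # Delta-method gradients w.r.t. (slope, intercept).
    g_dH = np.array([-R / slope**2, 0.0])
    g_dS = np.array([-intercept * R / slope**2, R / slope])
    g_dG = (g_dH - T37_K * g_dS) / 1000.0  # kcal/mol scale
    dH_err = float(math.sqrt(g_dH @ cov @ g_dH))
    dS_err = float(math.sqrt(g_dS @ cov @ g_dS))
    dG37_err = float(math.sqrt(g_dG @ cov @ g_dG))

    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    params = ThermoParams(dH=dH, dS=dS, dH_err=dH_err, dS_err=dS_err)
    return VantHoffResult(
        params=params,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        dG37=float(delta_g(params, T37_K)),
        dG37_err=dG37_err,
        covariance=np.asarray(cov, dtype=float),
        low_leverage=series.low_leverage,
    )


def tm_uncertainty(
    result: VantHoffResult,
    ct: StrandConcentration,
    instrument_err: float = 0.0,
) -> float:
    """1-sigma uncertainty of the predicted Tm at ``ct`` (°C).

    Propagated from the line's slope/intercept covariance; an optional
    instrument-resolution floor (°C) is added in quadrature.
    """
    L = ct.ln_ct_over_4
    inv_tm = result.intercept + result.slope * L
    g = np.array([L, 1.0])
    var_inv = float(g @ result.covariance @ g)
    tm_K = 1.0 / inv_tm
    err = tm_K**2 * math.sqrt(max(var_inv, 0.0))
    return math.hypot(err, instrument_err)


def summarize_duplex(
    result: VantHoffResult,
    ct_report: StrandConcentration,
    label: str = "",
    instrument_tm_err: float = 0.0,
) -> dict:
    """Tabular report row: ΔS°, ΔH° (kcal/mol), ΔG°₃₇ and Tm at ``ct_report``."""
    p = result.params
    return {
        "label": label,
        "dS_cal_per_mol_K": p.dS,
        "dS_err": p.dS_err,
        "dH_kcal_per_mol": p.dH_kcal,
        "dH_err_kcal": None if p.dH_err is None else p.dH_err / 1000.0,
        "dG37_kcal_per_mol": result.dG37,
        "dG37_err_kcal": result.dG37_err,
        "tm_C": predict_tm(p, ct_report),
        "tm_err_C": tm_uncertainty(result, ct_report, instrument_tm_err),
        "r_squared": result.r_squared,
    }


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of cross-checking a printed thermodynamic table row."""

    label: str
    dG37_printed: float
    dG37_computed: float
    tm_printed: float
    tm_computed: float
    dG37_consistent: bool
    tm_consistent: bool

    @property
    def consistent(self) -> bool:
        return self.dG37_consistent and self.tm_consistent


def check_row_consistency(
    dS: float,
    dH_kcal: float,
    dG37_printed: float,
    tm_printed_C: float,
    ct: StrandConcentration,
    label: str = "",
    dg_tol: float = 0.3,
    tm_tol: float = 1.0,
) -> ConsistencyReport:
    """Verify that a published (ΔS°, ΔH°, ΔG°₃₇, Tm) row is self-consistent.

    ΔG°₃₇ is recomputed as ΔH° − 310.15·ΔS° and Tm from the closed form at
    ``ct``; disagreement beyond ``dg_tol`` (kcal/mol) or ``tm_tol`` (°C)
    flags the row.  The tolerances absorb rounding of the printed ΔH°/ΔS°
    (last-digit rounding alone moves Tm by several tenths of a degree) but
    catch genuinely inconsistent rows.
    """
    params = ThermoParams.from_kcal(dH_kcal, dS)
    dg = float(delta_g(params, T37_K))
    tm = predict_tm(params, ct)
    return ConsistencyReport(
        label=label,
        dG37_printed=dG37_printed,
        dG37_computed=dg,
        tm_printed=tm_printed_C,
        tm_computed=tm,
        dG37_consistent=abs(dg - dG37_printed) <= dg_tol,
        tm_consistent=abs(tm - tm_printed_C) <= tm_tol,
    )
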
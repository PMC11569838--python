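"""Two-state fitting of optical thermal-denaturation traces.

An absorbance-versus-temperature trace of a short duplex is modelled as a
population-weighted mix of two linearly sloping optical baselines,

    A(T) = θ(T) · (b_ds + m_ds·T) + (1 − θ(T)) · (b_ss + m_ss·T),

with θ(T) the two-state duplex fraction from :mod:`duplexkit.thermo`.  The
six free parameters (ΔH°, ΔS° and the two baselines) are estimated by
derivative-free simplex minimization of the sum of squared residuals, with
multi-start restarts from jittered initial guesses.  Tm is reported as the
temperature where the fitted θ = 1/2 — not the derivative maximum, which
drifts when baselines slope — and the hypochromic effect is the fractional
absorbance drop between the two baselines extrapolated to Tm:

    h = 100 · (A_ss(Tm) − A_ds(Tm)) / A_ss(Tm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.signal import savgol_filter

from . import thermo
from .errors import (
    DomainError,
    FitRejectedError,
    FormatError,
    IdentifiabilityError,
    NoTransitionError,
)
from .thermo import CELSIUS_OFFSET, R, StrandConcentration, ThermoParams

#: Minimum points per free parameter before a fit is attempted.
_POINTS_PER_PARAM = 3
_N_PARAMS = 6


@dataclass
class MeltingCurve:
    """One thermal-denaturation trace with its metadata.

    ``temperatures`` are in °C, ``absorbances`` in AU.  The optional
    ``reference_absorbances`` channel (typically recorded at 300 nm, where
    nucleic acids do not absorb) is subtracted during preprocessing.
    """

    temperatures: np.ndarray
    absorbances: np.ndarray
    ct: StrandConcentration
    wavelength: float = 260.0
    reference_absorbances: np.ndarray | None = None
    ramp: str = "heating"
    label: str = ""
    hysteresis_flag: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.reference_absorbances is not None:
            self.reference_absorbances = np.asarray(
                self.reference_absorbances, dtype=float
            )
            if len(self.reference_absorbances) != len(self.temperatures):
                raise FormatError("reference channel length mismatch")
        if len(self.temperatures) != len(self.absorbances):
            raise FormatError("temperature/absorbance length mismatch")
        if self.ramp not in ("heating", "cooling"):
            raise FormatError(f"ramp must be heating or cooling, got {self.ramp!r}")

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def span(self) -> float:
        return float(self.temperatures.max() - self.temperatures.min())


@dataclass(frozen=True)
class BaselinePair:
    """Linear duplex-state and single-strand-state baselines (AU vs °C)."""

    m_ds: float
    b_ds: float
    m_ss: float
    b_ss: float

    def duplex(self, T):
        return self.b_ds + self.m_ds * np.asarray(T, dtype=float)

    def single_strand(self, T):
        return self.b_ss + self.m_ss * np.asarray(T, dtype=float)


@dataclass
class MeltFitResult:
    """Fitted two-state parameters for one melting curve."""

    params: ThermoParams
    baselines: BaselinePair
    tm: float  # degC, theta = 0.5 of the fitted model
    hypochromicity: float  # percent
    ssr: float  # AU^2
    converged: bool
    n_restarts_used: int
    ct: StrandConcentration
    restart_tms: list = field(default_factory=list)


def preprocess_curve(raw: MeltingCurve) -> MeltingCurve:
    """Reference-subtract, sort by temperature and average duplicates."""
    absorbances = raw.absorbances.copy()
    if raw.reference_absorbances is not None:
        absorbances = absorbances - raw.reference_absorbances
    order = np.argsort(raw.temperatures, kind="stable")
    temps = raw.temperatures[order]
    absorbances = absorbances[order]
    uniq, inverse = np.unique(temps, return_inverse=True)
    if len(uniq) != len(temps):
        summed = np.zeros(len(uniq))
        counts = np.zeros(len(uniq))
        np.add.at(summed, inverse, absorbances)
        np.add.at(counts, inverse, 1.0)
        temps, absorbances = uniq, summed / counts
    return replace(
        raw,
        temperatures=temps,
        absorbances=absorbances,
        reference_absorbances=None,
    )


def merge_ramps(
    heating: MeltingCurve, cooling: MeltingCurve, hysteresis_limit: float = 1.0
) -> MeltingCurve:
    """Average a heating/cooling pair onto the heating grid.

    If the model-free midpoints of the two ramps differ by more than
    ``hysteresis_limit`` (°C) the merged curve carries ``hysteresis_flag``
    and a warning is emitted; hysteresis is diagnostic of slow kinetics,
    not an error.
    """
    h = preprocess_curve(heating)
    c = preprocess_curve(cooling)
    flag = False
    try:
        delta = abs(derivative_tm(h) - derivative_tm(c))
        if delta > hysteresis_limit:
            warnings.warn(
                f"heating/cooling hysteresis {delta:.2f} degC exceeds "
                f"{hysteresis_limit} degC",
                stacklevel=2,
            )
            flag = True
    except NoTransitionError:
        pass
    interp = np.interp(h.temperatures, c.temperatures, c.absorbances)
    merged = (h.absorbances + interp) / 2.0
    return replace(h, absorbances=merged, ramp="heating", hysteresis_flag=flag,
                   label=(h.label + "+merged").lstrip("+"))


def model_absorbance(
    params: ThermoParams,
    baselines: BaselinePair,
    ct: StrandConcentration,
    T_celsius,
):
    """Two-state model absorbance at temperature(s) ``T_celsius`` (°C)."""
    T = np.asarray(T_celsius, dtype=float)
    theta = thermo.fraction_duplex(params, ct, T + CELSIUS_OFFSET)
    return theta * baselines.duplex(T) + (1.0 - theta) * baselines.single_strand(T)


def derivative_tm(curve: MeltingCurve, window: int = 11, polyorder: int = 2) -> float:
    """Model-free Tm: temperature of the maximum of a smoothed dA/dT.

    Uses a Savitzky–Golay local-polynomial derivative on a uniform
    temperature grid.  A maximum on (or within half a window of) the
    boundary means no interior transition and raises
    :class:`NoTransitionError`.  Intended for initialization and QC only.
    """
    if len(curve) < window:
        raise IdentifiabilityError(
            f"need at least {window} points for the derivative filter"
        )
    temps = curve.temperatures
    # Resample onto a uniform grid so the filter's delta is constant.
    grid = np.linspace(temps[0], temps[-1], len(temps))
    vals = np.interp(grid, temps, curve.absorbances)
    step = grid[1] - grid[0]
    dA = savgol_filter(vals, window_length=window, polyorder=polyorder,
                       deriv=1, delta=step)
    i = int(np.argmax(dA))
    guard = window // 2
    if i < guard or i >= len(grid) - guard:
        raise NoTransitionError("derivative maximum lies on the trace boundary")
    return float(grid[i])


def _initial_guess(curve: MeltingCurve) -> np.ndarray:
    """Heuristic start: baselines from the outer 20%, Tm from the smoothed
    derivative, ΔH from the two-state transition breadth.

    For a bimolecular non-self-complementary duplex dθ/dT at Tm equals
    ΔH/(6·R·Tm²), so the peak slope of the normalized trace gives a
    breadth-based enthalpy initializer.
    """
    temps, vals = curve.temperatures, curve.absorbances
    n_edge = max(3, int(0.2 * len(temps)))
    lo = np.polyfit(temps[:n_edge], vals[:n_edge], 1)
    hi = np.polyfit(temps[-n_edge:], vals[-n_edge:], 1)
    tm0 = derivative_tm(curve)
    # Normalized duplex fraction using the edge baselines.
    ds_line = np.polyval(lo, temps)
    ss_line = np.polyval(hi, temps)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = (ss_line - vals) / np.where(ss_line - ds_line == 0, np.nan,
                                            ss_line - ds_line)
    theta = np.clip(np.nan_to_num(theta, nan=0.5), 0.0, 1.0)
    win = min(11, len(theta) - (1 - len(theta) % 2))
    dtheta = savgol_filter(theta, window_length=win, polyorder=2, deriv=1,
                           delta=float(np.mean(np.diff(temps))))
    peak_slope = float(np.max(-dtheta))
    tm_K = tm0 + CELSIUS_OFFSET
    dH0_kcal = -6.0 * R * tm_K**2 * max(peak_slope, 1e-4) / 1000.0
    dH0_kcal = float(np.clip(dH0_kcal, -250.0, -40.0))
    return np.array([tm0, dH0_kcal, lo[0], lo[1], hi[0], hi[1]])


def _unpack(x: np.ndarray, ct: StrandConcentration):
    """(tm_C, dH_kcal, m_ds, b_ds, m_ss, b_ss) -> (ThermoParams, BaselinePair).

    The optimizer works in (Tm, ΔH) coordinates, which are far better
    conditioned than (ΔH, ΔS); ΔS follows from the Tm identity
    ΔS = ΔH/Tm − R·ln(Ct/4).
    """
    tm_C, dH_kcal, m_ds, b_ds, m_ss, b_ss = x
    dH = dH_kcal * 1000.0
    dS = dH / (tm_C + CELSIUS_OFFSET) - R * ct.ln_ct_over_4
    if dH >= 0 or dS >= 0:
        return None, None
    return ThermoParams(dH=dH, dS=dS), BaselinePair(m_ds, b_ds, m_ss, b_ss)


def fit_melting_curve(
    curve: MeltingCurve,
    init: np.ndarray | None = None,
    n_restarts: int = 5,
    max_fev: int = 10_000,
    ssr_tol: float = 1e-12,
    seed: int = 0,
) -> MeltFitResult:
    """Fit the two-state model with sloping linear baselines.

    Multi-start Nelder–Mead simplex over (Tm, ΔH, m_ds, b_ds, m_ss, b_ss);
    each start chains simplex runs until the SSR improvement drops below
    ``ssr_tol``.  Restarts are jittered from the heuristic initial guess
    with a seeded generator so the fit is reproducible.  ``init`` may carry
    a full parameter vector ``(tm_C, dH_kcal, m_ds, b_ds, m_ss, b_ss)`` to
    replace the heuristic.  ``converged`` is False when near-optimal
    restarts disagree by more than 0.5 °C in Tm.
    """
    if len(curve) < max(_POINTS_PER_PARAM * _N_PARAMS, 20):
        raise IdentifiabilityError(
            f"{len(curve)} points cannot constrain {_N_PARAMS} parameters"
        )
    if curve.span < 30.0:
        raise IdentifiabilityError(
            f"temperature span {curve.span:.1f} degC below the 30 degC floor"
        )
    try:
        tm_qc = derivative_tm(curve)
    except NoTransitionError as exc:
        raise FitRejectedError(f"trace is not sigmoidal: {exc}") from exc

    temps, vals = curve.temperatures, curve.absorbances
    tmin, tmax = float(temps.min()), float(temps.max())
    ct = curve.ct

    def objective(x: np.ndarray) -> float:
        params, baselines = _unpack(x, ct)
        if params is None or not tmin < x[0] < tmax:
            return 1e12
        resid = vals - model_absorbance(params, baselines, ct, temps)
        return float(resid @ resid)

    x0 = _initial_guess(curve) if init is None else np.asarray(init, dtype=float)
    rng = np.random.default_rng(seed)
    scale = np.array([0.5, 0.1, 0.0, 0.02, 0.0, 0.02])

    candidates: list[tuple[float, np.ndarray]] = []
    for k in range(n_restarts):
        if k == 0:
            start = x0.copy()
        else:
            start = x0.copy()
            start[0] += rng.normal(0.0, scale[0])
            start[1] *= 1.0 + rng.normal(0.0, scale[1])
            start[3] += rng.normal(0.0, scale[3]) * max(abs(x0[3]), 0.05)
            start[5] += rng.normal(0.0, scale[5]) * max(abs(x0[5]), 0.05)
        best_x, best_f = start, objective(start)
        fev_left = max_fev
        # Chained simplex runs: re-initializing the simplex at the current
        # best escapes the premature shrinkage Nelder-Mead is prone to.
        for _ in range(6):
            if fev_left <= 0:
                break
            res = minimize(
                objective,
                best_x,
                method="Nelder-Mead",
                options={
                    "maxfev": fev_left,
                    "xatol": 1e-10,
                    "fatol": 1e-15,
                    "adaptive": True,
                },
            )
            fev_left -= res.nfev
            if res.fun < best_f - ssr_tol:
                best_x, best_f = res.x, res.fun
            elif res.fun < best_f:
                best_x, best_f = res.x, res.fun
                break
            else:
                break
        candidates.append((best_f, best_x))

    best_ssr = min(f for f, _ in candidates)
    # Restarts that plausibly reached the same basin as the best one.
    good = [
        (f, x) for f, x in candidates if f <= best_ssr * 2.0 + 1e-12
    ]
    good.sort(key=lambda fx: (fx[0], abs(fx[1][0] - tm_qc)))
    ssr, x_best = good[0]
    restart_tms = [float(x[0]) for _, x in good]
    converged = (max(restart_tms) - min(restart_tms)) <= 0.5

    params, baselines = _unpack(x_best, ct)
    if params is None:
        raise FitRejectedError("optimizer terminated on unphysical parameters")
    result = MeltFitResult(
        params=params,
        baselines=baselines,
        tm=float(x_best[0]),
        hypochromicity=0.0,
        ssr=float(ssr),
        converged=converged,
        n_restarts_used=n_restarts,
        ct=ct,
        restart_tms=restart_tms,
    )
    result.hypochromicity = hypochromicity(result)
    return result


def hypochromicity(fit: MeltFitResult) -> float:
    """Hypochromic effect in percent at the fitted Tm.

    Both baselines are extrapolated to Tm:
    h = 100 · (A_ss(Tm) − A_ds(Tm)) / A_ss(Tm).
    """
    a_ss = float(fit.baselines.single_strand(fit.tm))
    a_ds = float(fit.baselines.duplex(fit.tm))
    if a_ss <= 0:
        raise DomainError(f"single-strand baseline at Tm is non-positive ({a_ss})")
    return 100.0 * (a_ss - a_ds) / a_ss
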
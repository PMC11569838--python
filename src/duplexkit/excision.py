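"""Quantification of lesion-excision time courses.

The readout of the in-vitro excision assay is the gel-band intensity of a
labeled excision product (here a 34-nt band) as a function of incubation
time with a repair-competent extract.  Densitometry is upstream: this
module consumes band-intensity tables.  Each time course is
background-corrected against its time-zero (or no-extract) point; the
efficiency contrast between two substrates is reported as the ratio of
replicate-mean signals per time point, averaged over times, with a
percentile bootstrap over replicates for the interval.  Resampling is
over replicates, not time points — time points within a course are not
exchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    EmptySignalError,
    FormatError,
    InputError,
    InsufficientDataError,
)


@dataclass
class ExcisionTimecourse:
    """Product-band signal of one replicate over incubation time (minutes)."""

    substrate: str
    times: np.ndarray
    intensities: np.ndarray
    replicate_id: str = "1"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.times) != len(self.intensities):
            raise FormatError("times/intensities length mismatch")
        if np.any(self.times < 0):
            raise FormatError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise FormatError("intensities must be non-negative")
        if self.times[0] != 0.0:
            raise FormatError(
                "a time-zero background point is required as the first row"
            )


def normalize_timecourse(
    tc: ExcisionTimecourse, rescale: bool = False
) -> ExcisionTimecourse:
    """Background-subtract (and optionally max-rescale) a time course.

    The time-zero intensity is the background; it is subtracted from every
    point, negatives are clamped to zero with a warning, and with
    ``rescale=True`` the course is divided by its maximum so the plateau
    is 1.  A course indistinguishable from background raises
    :class:`EmptySignalError`.
    """
    background = tc.intensities[0]
    corrected = tc.intensities - background
    if np.any(corrected < 0):
        warnings.warn(
            f"{tc.substrate}/{tc.replicate_id}: "
            f"{int(np.sum(corrected < 0))} point(s) below background clamped to 0",
            stacklevel=2,
        )
        corrected = np.clip(corrected, 0.0, None)
    if not np.any(corrected > 0):
        raise EmptySignalError(
            f"{tc.substrate}/{tc.replicate_id}: no signal above background"
        )
    if rescale:
        corrected = corrected / corrected.max()
    return replace(tc, intensities=corrected, normalized=True)


@dataclass
class EfficiencyRatioResult:
    times: np.ndarray
    ratio_per_time: np.ndarray
    summary_ratio: float
    ci_low: float
    ci_high: float
    n_boot: int


def _stack_common(
    courses: list[ExcisionTimecourse], common_times: np.ndarray
) -> np.ndarray:
    """(n_replicates, n_times) matrix of intensities at the common grid."""
    rows = []
    for tc in courses:
        idx = np.searchsorted(tc.times, common_times)
        rows.append(tc.intensities[idx])
    return np.array(rows)


def efficiency_ratio(
    numerator: list[ExcisionTimecourse],
    denominator: list[ExcisionTimecourse],
    n_boot: int = 2000,
    seed: int = 0,
) -> EfficiencyRatioResult:
    """Per-time and summary efficiency ratio of two substrates.

    At each shared time point (time zero excluded) the ratio of
    replicate-mean signals numerator/denominator is formed; the ratio of
    means — not the mean of per-replicate ratios — keeps early low-signal
    points from blowing up the estimate.  ``summary_ratio`` is the mean
    over time points, and the interval is a seeded percentile bootstrap
    (2.5/97.5) resampling replicates independently in each group.
    """
    if not numerator or not denominator:
        raise InsufficientDataError("need at least one replicate per substrate")
    if not all(tc.normalized for tc in numerator + denominator):
        raise InputError("normalize all time courses before forming ratios")
    t_num = set.intersection(*(set(tc.times[1:]) for tc in numerator))
    t_den = set.intersection(*(set(tc.times[1:]) for tc in denominator))
    common = np.array(sorted(t_num & t_den))
    if common.size == 0:
        raise InputError("no common post-zero time points")

    num = _stack_common(numerator, common)
    den = _stack_common(denominator, common)
    den_mean = den.mean(axis=0)
    keep = den_mean > 0
    if not np.any(keep):
        raise InputError("denominator signal is zero at every common time point")
    common = common[keep]
    num, den = num[:, keep], den[:, keep]

    ratio = num.mean(axis=0) / den.mean(axis=0)
    summary = float(ratio.mean())

    rng = np.random.default_rng(seed)
    n_n, n_d = num.shape[0], den.shape[0]
    idx_n = rng.integers(0, n_n, size=(n_boot, n_n))
    idx_d = rng.integers(0, n_d, size=(n_boot, n_d))
    boot_num = num[idx_n].mean(axis=1)  # (n_boot, n_times)
    boot_den = den[idx_d].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = boot_num / boot_den
    boot_summary = np.nanmean(np.where(np.isfinite(boot), boot, np.nan), axis=1)
    ci_low, ci_high = np.nanpercentile(boot_summary, [2.5, 97.5])
    return EfficiencyRatioResult(
        times=common,
        ratio_per_time=ratio,
        summary_ratio=summary,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
    )


def replicate_sd(values) -> float:
    """Sample standard deviation with the n−1 denominator."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("need at least 2 replicate values")
    return float(np.std(values, ddof=1))
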
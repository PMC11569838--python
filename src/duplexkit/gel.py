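"""Bend-angle estimation from nondenaturing gel mobility.

A static bend at a lesion makes a short duplex less compact and retards it
in a nondenaturing polyacrylamide gel.  The classical cosine mobility rule
relates the mobility ratio of the modified to the unmodified duplex to the
deflection of the helix axis:

    mu_mod / mu_unmod = cos(deflection / 2),

with the reported quantity being the interior angle 180° − deflection
(180° = straight helix).  A ratio of 1 therefore means no bend, and a
smaller ratio a stronger bend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import AnomalousMobilityError, DomainError, InputError


@dataclass(frozen=True)
class MobilityPair:
    """Migration distances (or mobilities) of a modified/unmodified pair.

    Units are arbitrary but must match; only the ratio enters the angle.
    """

    mu_mod: float
    mu_unmod: float

    def __post_init__(self) -> None:
        if self.mu_mod <= 0 or self.mu_unmod <= 0:
            raise DomainError("mobilities must be positive")

    @property
    def ratio(self) -> float:
        return self.mu_mod / self.mu_unmod


@dataclass(frozen=True)
class BendEstimate:
    interior_angle: float  # degrees; 180 = straight
    deflection: float  # degrees; 180 - interior_angle
    ratio: float
    interior_angle_err: float | None = None


def relative_mobility(
    lanes: Mapping[str, float], reference_lane: str
) -> dict[str, MobilityPair]:
    """Pair each lane's band position with the unmodified reference lane.

    ``lanes`` maps lane label to a single called band position (migration
    distance).  Returns one :class:`MobilityPair` per non-reference lane.
    """
    if reference_lane not in lanes:
        raise InputError(f"reference lane {reference_lane!r} not found in table")
    ref = lanes[reference_lane]
    if ref <= 0:
        raise DomainError(f"reference band position must be positive, got {ref}")
    out: dict[str, MobilityPair] = {}
    for label, pos in lanes.items():
        if label == reference_lane:
            continue
        if pos <= 0:
            raise DomainError(f"band position for lane {label!r} must be positive")
        out[label] = MobilityPair(mu_mod=pos, mu_unmod=ref)
    return out


def bend_angle(pair: MobilityPair, ratio_err: float | None = None) -> BendEstimate:
    """Interior bend angle from the cosine mobility rule.

    deflection = 2·arccos(mu_mod/mu_unmod); interior = 180° − deflection.
    An optional 1-sigma uncertainty on the ratio is propagated by
    first-order expansion of arccos (d(arccos r)/dr = −1/√(1−r²)).
    """
    r = pair.ratio
    if r > 1.0:
        raise AnomalousMobilityError(
            f"mobility ratio {r:.4f} > 1: modified duplex migrated faster "
            "than the unmodified reference"
        )
    if r <= 0.0:
        raise DomainError(f"mobility ratio must be positive, got {r}")
    interior = 180.0 - 2.0 * math.degrees(math.acos(r))
    deflection = 180.0 - interior  # stored so the pair is exactly complementary
    err = None
    if ratio_err is not None:
        if r == 1.0:
            err = float("inf")  # arccos derivative is singular at r = 1
        else:
            err = 2.0 * math.degrees(ratio_err / math.sqrt(1.0 - r * r))
    return BendEstimate(
        interior_angle=interior,
        deflection=deflection,
        ratio=r,
        interior_angle_err=err,
    )


def bend_angle_replicates(pairs: list[MobilityPair]) -> BendEstimate:
    """Bend estimate from replicate lane pairs.

    The mean mobility ratio is converted via the cosine rule; the
    replicate scatter of the ratio (sample SD of the mean) is propagated
    through arccos.
    """
    if not pairs:
        raise InputError("need at least one mobility pair")
    ratios = np.array([p.ratio for p in pairs])
    mean_r = float(np.mean(ratios))
    err = None
    if len(ratios) >= 2:
        err = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))
    mean_pair = MobilityPair(mu_mod=mean_r, mu_unmod=1.0)
    return bend_angle(mean_pair, ratio_err=err)


def ratio_for_interior_angle(interior_angle: float) -> float:
    """Inverse of :func:`bend_angle`: the mobility ratio that produces a
    given interior angle.  Useful for constructing synthetic lane tables."""
    if not 0.0 < interior_angle <= 180.0:
        raise DomainError("interior angle must be in (0, 180]")
    return math.cos(math.radians((180.0 - interior_angle) / 2.0))
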
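"""Geometric kernels: distances and the hydrogen-bond criterion.

A hydrogen bond is called present when the heavy-atom donor-acceptor distance
is at most ``d_max`` (default 3.5 Å) and the donor-hydrogen-acceptor angle,
measured at the hydrogen, is at least ``theta_min`` (default 135°). Both
cutoffs are inclusive so boundary geometries classify deterministically.
Donors and acceptors are named explicitly by the caller; no protonation or
chemistry inference happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory_io import Frame, PocketSpec

__all__ = [
    "HBondCriteria",
    "HBondObservation",
    "distance",
    "angle_at",
    "hbond",
    "clamp_distance",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Inclusive hydrogen-bond cutoffs (Å, degrees)."""

    d_max: float = 3.5
    theta_min: float = 135.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 < self.theta_min <= 180.0):
            raise ValueError("theta_min must lie in (0, 180]")


@dataclass(frozen=True)
class HBondObservation:
    donor: int
    hydrogen: int | None
    acceptor: int
    distance: float
    angle: float  # degrees; NaN when no hydrogen exists
    present: bool


def distance(frame: Frame, a: int, b: int) -> float:
    """Euclidean distance in Å between two atom handles."""
    return float(np.linalg.norm(frame.coords[a] - frame.coords[b]))


def angle_at(frame: Frame, a: int, vertex: int, b: int) -> float:
    """Angle a-vertex-b in degrees."""
    u = frame.coords[a] - frame.coords[vertex]
    v = frame.coords[b] - frame.coords[vertex]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return float("nan")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def hbond(
    frame: Frame,
    donor: int,
    hydrogen: int | None,
    acceptor: int,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondObservation:
    """Evaluate one donor-H...acceptor hydrogen bond.

    A missing hydrogen handle (e.g. cytidine N3, which has no proton) signals
    not-a-donor: the bond is reported absent with the heavy-atom distance
    still measured.
    """
    d = distance(frame, donor, acceptor)
    if hydrogen is None:
        return HBondObservation(donor, None, acceptor, d, float("nan"), False)
    theta = angle_at(frame, donor, hydrogen, acceptor)
    present = (d <= criteria.d_max) and (theta >= criteria.theta_min)
    return HBondObservation(donor, hydrogen, acceptor, d, theta, present)


def clamp_distance(frame: Frame, pocket: PocketSpec) -> float:
    """Width of the Trp215(CE3)-Phe230(CG) aromatic clamp in Å."""
    return distance(frame, pocket.clamp_a, pocket.clamp_b)
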
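"""Exact geometry of a sessile droplet modelled as a spherical cap.

A side-view droplet silhouette is the circular segment cut from a circle
(the sphere's meridian) by the horizontal substrate line ``y = a``.  From
the fitted circle and the baseline this module derives the two contact
points, the base chord (droplet diameter ``D``), the contact angle ``theta``
and, through the spherical-cap closed form

    V = (pi * D**3 / 24) * (2 - 3*cos(theta) + cos(theta)**3) / sin(theta)**3

the droplet volume in microlitres (with ``D`` in mm, 1 mm^3 == 1 uL).

All functions here operate in a y-up physical frame: the cap sits *above*
the baseline, and the contact angle is the tangent angle of that upper
segment at the contact line.  Conversion from the y-down pixel frame of an
image is the imaging module's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CalibrationError",
    "NoIntersectionError",
    "Calibration",
    "Circle",
    "Baseline",
    "DropletMeasurement",
    "calibrate",
    "circle_baseline_geometry",
    "cap_volume",
    "cap_height",
    "sphere_radius",
    "circle_from_cap",
]


class CalibrationError(ValueError):
    """Raised for non-positive calibration inputs."""


class NoIntersectionError(ValueError):
    """Raised when the baseline does not cut the circle."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale from an object of known physical length.

    Attributes
    ----------
    known_length_mm : float
        Physical length of the calibration object (mm), e.g. a micro ruler.
    span_px : float
        The same length measured in image pixels.
    mm_per_px : float
        Derived scale factor, ``known_length_mm / span_px``.
    """

    known_length_mm: float
    span_px: float
    mm_per_px: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.known_length_mm > 0):
            raise CalibrationError(
                f"known_length_mm must be > 0, got {self.known_length_mm}"
            )
        if not (self.span_px > 0):
            raise CalibrationError(f"span_px must be > 0, got {self.span_px}")
        object.__setattr__(
            self, "mm_per_px", self.known_length_mm / self.span_px
        )


@dataclass(frozen=True)
class Circle:
    """A circle with centre ``(cx, cy)`` and radius ``radius``.

    Units and frame (pixels y-down, or mm y-up) are the caller's contract;
    geometry functions require the y-up physical frame.
    """

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class Baseline:
    """The horizontal substrate line ``y = a`` (zero slope)."""

    a: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.a):
            raise ValueError(f"baseline coordinate must be finite, got {self.a}")


@dataclass(frozen=True)
class DropletMeasurement:
    """One droplet's derived quantities, all in physical units.

    ``diameter_mm`` is the base chord D between the contact points A and B,
    ``theta_deg`` the contact angle, ``height_mm`` the cap height h and
    ``volume_uL`` the spherical-cap volume.
    """

    diameter_mm: float
    theta_deg: float
    height_mm: float
    volume_uL: float
    contact_points: tuple[tuple[float, float], tuple[float, float]]


def calibrate(known_length_mm: float, span_px: float) -> Calibration:
    """Build a :class:`Calibration` from a known length and its pixel span.

    Examples
    --------
    >>> round(calibrate(10, 1028).mm_per_px, 6)
    0.009728
    """
    return Calibration(known_length_mm=known_length_mm, span_px=span_px)


def circle_baseline_geometry(
    circle: Circle, baseline: Baseline
) -> tuple[tuple[float, float], tuple[float, float], float, float]:
    """Intersect the droplet circle with the substrate line.

    Returns ``(A, B, chord_length, theta_deg)`` where A and B are the
    contact points (A on the left), the chord is the droplet base diameter
    and theta the contact angle of the cap lying above the baseline.

    With the circle centre at ``(cx, cy)`` and the line ``y = a``,

        A, B = (cx -/+ sqrt(r^2 - (a - cy)^2), a)
        theta = arccos((a - cy) / r)

    so a centre above the baseline (``cy > a``) yields theta > 90 deg — the
    hydrophobic branch.

    Raises
    ------
    NoIntersectionError
        If ``|a - cy| >= radius`` (line misses or merely grazes the circle).
    """
    m = baseline.a - circle.cy
    r = circle.radius
    if abs(m) >= r:
        raise NoIntersectionError(
            f"baseline y={baseline.a} does not cut circle "
            f"(cy={circle.cy}, r={r}): |a - cy| = {abs(m)} >= r"
        )
    half_chord = math.sqrt(r * r - m * m)
    a_pt = (circle.cx - half_chord, baseline.a)
    b_pt = (circle.cx + half_chord, baseline.a)
    theta_deg = math.degrees(math.acos(m / r))
    return a_pt, b_pt, 2.0 * half_chord, theta_deg


def cap_height(diameter_mm: float, theta_deg: float) -> float:
    """Cap height ``h = (D/2) (1 - cos theta) / sin theta`` in mm."""
    _check_cap_domain(diameter_mm, theta_deg)
    t = math.radians(theta_deg)
    return (diameter_mm / 2.0) * (1.0 - math.cos(t)) / math.sin(t)


def sphere_radius(diameter_mm: float, theta_deg: float) -> float:
    """Radius of the generating sphere, ``r_s = (D/2) / sin theta`` (mm)."""
    _check_cap_domain(diameter_mm, theta_deg)
    return (diameter_mm / 2.0) / math.sin(math.radians(theta_deg))


def cap_volume(diameter_mm: float, theta_deg: float) -> float:
    """Spherical-cap volume in uL from base diameter (mm) and contact angle.

        V = (pi D^3 / 24) * (2 - 3 cos theta + cos^3 theta) / sin^3 theta

    At theta = 90 deg this reduces to the hemisphere pi D^3 / 12.

    Raises
    ------
    ValueError
        If ``diameter_mm < 0`` or theta is outside (0, 180) degrees
        (``sin^3 theta`` vanishes at the endpoints).
    """
    if diameter_mm == 0:
        _check_theta(theta_deg)
        return 0.0
    _check_cap_domain(diameter_mm, theta_deg)
    t = math.radians(theta_deg)
    c = math.cos(t)
    s = math.sin(t)
    return (math.pi * diameter_mm**3 / 24.0) * (2.0 - 3.0 * c + c**3) / s**3


def circle_from_cap(
    diameter_mm: float, theta_deg: float, baseline_a: float = 0.0, cx: float = 0.0
) -> tuple[Circle, Baseline]:
    """Inverse construction: the circle/baseline whose upper segment is the
    cap with base diameter ``diameter_mm`` and contact angle ``theta_deg``.

    Useful for round-trip tests and for rendering ground-truth droplets.
    """
    _check_cap_domain(diameter_mm, theta_deg)
    t = math.radians(theta_deg)
    r = (diameter_mm / 2.0) / math.sin(t)
    # theta = arccos((a - cy)/r)  =>  cy = a - r cos(theta)
    cy = baseline_a - r * math.cos(t)
    return Circle(cx=cx, cy=cy, radius=r), Baseline(a=baseline_a)


def _check_theta(theta_deg: float) -> None:
    if not (0.0 < theta_deg < 180.0):
        raise ValueError(
            f"contact angle must lie strictly in (0, 180) deg, got {theta_deg}"
        )


def _check_cap_domain(diameter_mm: float, theta_deg: float) -> None:
    if not (diameter_mm > 0):
        raise ValueError(f"diameter_mm must be > 0, got {diameter_mm}")
    _check_theta(theta_deg)
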
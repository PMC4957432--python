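"""Spherical geometry of the nuclear surface.

The nuclear envelope is modelled as two concentric spherical surfaces of
common radius ``R``.  Channels, pores and measurement probes all live on
that sphere and are addressed by polar/azimuthal angles.  This module
provides the great-circle metric, deterministic and seeded point layouts,
and the equal-area Mollweide projection used for atlas snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, NumericalError

__all__ = [
    "SphericalPoint",
    "SphereGeometry",
    "great_circle_distance",
    "great_circle_distance_matrix",
    "unit_vectors",
    "points_from_unit_vectors",
    "golden_spiral_points",
    "random_uniform_points",
    "arc_queue_points",
    "mollweide_project",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SphericalPoint:
    """A position on the spherical surface.

    Parameters
    ----------
    theta:
        Polar angle in radians, measured from the north pole; in ``[0, pi]``.
    phi:
        Azimuthal angle in radians; normalised into ``[0, 2*pi)``.
    """

    theta: float
    phi: float

    def __post_init__(self) -> None:
        theta, phi = float(self.theta), float(self.phi)
        if not (math.isfinite(theta) and math.isfinite(phi)):
            raise InvalidInputError("spherical angles must be finite")
        if not 0.0 <= theta <= math.pi:
            raise InvalidInputError(f"theta={theta} outside [0, pi]")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "phi", phi % _TWO_PI)

    @property
    def unit_vector(self) -> np.ndarray:
        st = math.sin(self.theta)
        return np.array(
            [st * math.cos(self.phi), st * math.sin(self.phi), math.cos(self.theta)]
        )


@dataclass(frozen=True)
class SphereGeometry:
    """The sphere the two membranes share.  ``radius`` is in micrometres."""

    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise InvalidInputError(f"radius must be positive, got {self.radius}")

    @property
    def area(self) -> float:
        """Surface area in square micrometres."""
        return 4.0 * math.pi * self.radius**2


def great_circle_distance(
    a: SphericalPoint, b: SphericalPoint, geom: SphereGeometry
) -> float:
    """Length of the minor great-circle arc between two surface points.

    The arccos argument is clamped to ``[-1, 1]`` so that coincident or
    antipodal points do not trip on floating-point drift.
    """
    cosang = math.cos(a.theta) * math.cos(b.theta) + math.sin(a.theta) * math.sin(
        b.theta
    ) * math.cos(a.phi - b.phi)
    cosang = min(1.0, max(-1.0, cosang))
    return geom.radius * math.acos(cosang)


def unit_vectors(points: Sequence[SphericalPoint]) -> np.ndarray:
    """Stack points into an ``(n, 3)`` array of unit vectors."""
    if len(points) == 0:
        return np.empty((0, 3))
    return np.stack([p.unit_vector for p in points])


def points_from_unit_vectors(uv: np.ndarray) -> list[SphericalPoint]:
    uv = np.asarray(uv, dtype=float)
    theta = np.arccos(np.clip(uv[:, 2], -1.0, 1.0))
    phi = np.arctan2(uv[:, 1], uv[:, 0]) % _TWO_PI
    return [SphericalPoint(t, p) for t, p in zip(theta, phi)]


def great_circle_distance_matrix(
    a_uv: np.ndarray, b_uv: np.ndarray, geom: SphereGeometry
) -> np.ndarray:
    """Pairwise great-circle distances between two unit-vector stacks."""
    cosang = np.clip(a_uv @ b_uv.T, -1.0, 1.0)
    return geom.radius * np.arccos(cosang)


def golden_spiral_points(n: int, geom: SphereGeometry) -> list[SphericalPoint]:
    """Quasi-uniform deterministic layout by the golden-section spiral.

    Point ``k`` sits at ``cos(theta) = 1 - (2k+1)/n`` with azimuth advancing
    by the golden angle, which spreads any number of points evenly over the
    sphere.  The output is identical for identical ``n``.
    """
    if n < 1:
        raise InvalidInputError(f"need at least one point, got n={n}")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    phi = (k * golden_angle) % _TWO_PI
    return [SphericalPoint(t, p) for t, p in zip(theta, phi)]


def random_uniform_points(
    n: int, geom: SphereGeometry, seed: int
) -> list[SphericalPoint]:
    """Area-uniform random points: uniform azimuth, uniform ``cos(theta)``.

    Reproducible for a fixed seed.
    """
    if n < 0:
        raise InvalidInputError(f"negative count n={n}")
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, _TWO_PI, size=n)
    theta = np.arccos(z)
    return [SphericalPoint(t, p) for t, p in zip(theta, phi)]


def arc_queue_points(
    n: int,
    start: SphericalPoint,
    end: SphericalPoint,
    geom: SphereGeometry,
    spacing: float,
) -> list[SphericalPoint]:
    """Queue of ``n`` points along the minor great arc from ``start``.

    The first point sits one ``spacing`` from ``start``; each further point
    one more spacing along the arc towards ``end`` (pores queuing up from a
    channel towards a probe).  Raises if the queue would overrun the arc.
    """
    if spacing <= 0:
        raise InvalidInputError(f"spacing must be positive, got {spacing}")
    if n < 0:
        raise InvalidInputError(f"negative count n={n}")
    arc_len = great_circle_distance(start, end, geom)
    if n * spacing > arc_len + 1e-12:
        raise ConfigurationError(
            f"queue of {n} points at spacing {spacing} um needs "
            f"{n * spacing:.4f} um but the arc is only {arc_len:.4f} um long"
        )
    ua, ub = start.unit_vector, end.unit_vector
    omega = arc_len / geom.radius  # subtended angle
    if omega < 1e-15:
        raise ConfigurationError("start and end coincide; arc is degenerate")
    sin_omega = math.sin(omega)
    out = []
    for k in range(1, n + 1):
        f = k * spacing / arc_len  # fraction along the arc
        # spherical linear interpolation keeps the point on the great circle
        uv = (math.sin((1 - f) * omega) * ua + math.sin(f * omega) * ub) / sin_omega
        uv = uv / np.linalg.norm(uv)
        out.append(points_from_unit_vectors(uv[None, :])[0])
    return out


def mollweide_project(
    p: SphericalPoint,
    central_meridian: float = math.pi,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Forward equal-area Mollweide projection of a surface point.

    Returns planar coordinates on the unit sphere (multiply by the sphere
    radius for physical units); the ellipse then has the same total area as
    the sphere.  The equator point on the central meridian maps to the
    origin.  The auxiliary angle is found by Newton iteration of
    ``2a + sin(2a) = pi sin(lat)``.
    """
    lat = math.pi / 2.0 - p.theta
    lon = p.phi - central_meridian
    lon = (lon + math.pi) % _TWO_PI - math.pi  # wrap into [-pi, pi)
    if abs(abs(lat) - math.pi / 2.0) < 1e-12:
        alpha = math.copysign(math.pi / 2.0, lat)
    else:
        alpha = lat
        target = math.pi * math.sin(lat)
        for _ in range(max_iter):
            f = 2.0 * alpha + math.sin(2.0 * alpha) - target
            fp = 2.0 + 2.0 * math.cos(2.0 * alpha)
            if fp < 1e-14:
                alpha = math.copysign(math.pi / 2.0, lat)
                break
            step = f / fp
            alpha -= step
            if abs(step) < tol:
                break
        else:
            raise NumericalError(
                f"Mollweide auxiliary-angle iteration did not reach {tol} "
                f"within {max_iter} iterations for theta={p.theta}"
            )
    x = 2.0 * math.sqrt(2.0) / math.pi * lon * math.cos(alpha)
    y = math.sqrt(2.0) * math.sin(alpha)
    return (x, y)
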
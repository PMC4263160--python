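"""Particle geometry for parallel hard prolate spheroids.

All particles are identical prolate spheroids of revolution with short
semi-axis ``R`` and long semi-axis ``a = rho * R``, aligned with the external
field along +z.  Orientation is not a degree of freedom.  The field-induced
polarization of a particle is represented by a pair of opposite point charges
at ``(0, 0, +/-d)`` relative to the particle centre, with ``d`` chosen so that
the pair reproduces both the dipole and the octupole moment of a uniformly
polarized spheroid.

Lengths are expressed in units of ``R`` and energies in units of ``k_B T``
throughout the package; the charge magnitude never appears explicitly -- it is
absorbed into the coupling parameter ``Gamma`` (see
:mod:`tubuloid.electrostatics`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "SpheroidShape",
    "ChargePair",
    "Particle",
    "charge_offset",
    "charge_pair",
    "site_positions",
    "contact_function",
    "overlap",
    "discrete_charge_potential",
    "exact_polarized_potential",
]


@dataclass(frozen=True)
class SpheroidShape:
    """Prolate spheroid with short semi-axis ``R`` and aspect ratio ``rho``.

    ``R`` is the unit of length; ``rho >= 1`` is the ratio of the long to the
    short semi-axis, so the long semi-axis is ``a = rho * R``.
    """

    R: float = 1.0
    rho: float = 2.7

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"short semi-axis R must be positive, got {self.R}")
        if not self.rho >= 1:
            raise ValueError(f"aspect ratio rho must be >= 1, got {self.rho}")

    @property
    def a(self) -> float:
        """Long semi-axis ``rho * R``."""
        return self.rho * self.R

    @property
    def length(self) -> float:
        """End-to-end particle length ``2 rho R``."""
        return 2.0 * self.rho * self.R

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.rho * self.R**3

    @property
    def focal_half_length(self) -> float:
        """Half distance between foci, ``c = sqrt(a^2 - R^2)``."""
        return math.sqrt(self.a**2 - self.R**2)


@dataclass(frozen=True)
class ChargePair:
    """Discrete-charge representation of uniform polarization.

    Two point charges of opposite sign sit on the particle long axis at
    ``+/- d`` from the centre: ``+`` at ``+d`` and ``-`` at ``-d``.  The
    charge magnitude is absorbed into the coupling parameter, so only the
    offset ``d`` and the site signs remain.
    """

    d: float
    site_signs: tuple[int, int] = field(default=(+1, -1))

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"site offset d must be >= 0, got {self.d}")
        if sum(self.site_signs) != 0:
            raise ValueError("site signs must sum to zero (net-neutral particle)")

    @property
    def moment(self) -> float:
        """Dipole moment ``2 q d`` in units of ``q = 1``."""
        return 2.0 * self.d


@dataclass(frozen=True)
class Particle:
    """A particle: a centre plus the fixed +z orientation."""

    center: np.ndarray
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)


def charge_offset(shape: SpheroidShape) -> float:
    """Charge-site offset ``d`` matching dipole and octupole moments.

    A uniformly polarized prolate spheroid is exactly equivalent, outside its
    surface, to a line density of dipoles ``mu(z) ~ (1 - z^2/c^2)`` on the
    focal segment ``|z| <= c = sqrt(a^2 - R^2)``.  Its two lowest
    non-vanishing axial multipoles are the dipole ``p1 = int mu dz`` and the
    octupole ``p3 = 3 int mu z^2 dz``, with ratio ``p3/p1 = (3/5) c^2``.  For
    a +/-q pair at ``+/-d`` the same ratio is ``d^2``, hence

        d = R * sqrt(3 (rho^2 - 1) / 5).

    For ``rho = 1`` (a sphere) this gives ``d = 0``: a uniformly polarized
    sphere is a pure dipole.
    """
    if shape.rho < 1:
        raise ValueError("aspect ratio must be >= 1")
    return shape.R * math.sqrt(3.0 * (shape.rho**2 - 1.0) / 5.0)


def charge_pair(shape: SpheroidShape) -> ChargePair:
    """The moment-matched :class:`ChargePair` for ``shape``."""
    return ChargePair(d=charge_offset(shape))


def site_positions(center: np.ndarray, pair: ChargePair) -> np.ndarray:
    """(2, 3) array of charge-site positions: ``+`` site first."""
    center = np.asarray(center, dtype=float)
    off = np.array([[0.0, 0.0, pair.d], [0.0, 0.0, -pair.d]])
    return center[None, :] + off


def _center(p) -> np.ndarray:
    if isinstance(p, Particle):
        return np.asarray(p.center, dtype=float)
    return np.asarray(p, dtype=float)


def contact_function(p1, p2, shape: SpheroidShape, box=None) -> float:
    """Scaled squared separation of two parallel spheroids.

    Under the affine map ``z -> z/rho`` both spheroids become spheres of
    radius ``R``, so

        F = (dx^2 + dy^2 + (dz/rho)^2) / (2R)^2

    is exact for identical parallel particles: ``F < 1`` iff they overlap and
    ``F = 1`` at contact.  With ``box`` given, the minimum-image displacement
    is used.
    """
    delta = _center(p2) - _center(p1)
    if box is not None:
        box = np.asarray(box, dtype=float)
        delta = delta - box * np.round(delta / box)
    return float(
        (delta[0] ** 2 + delta[1] ** 2 + (delta[2] / shape.rho) ** 2)
        / (2.0 * shape.R) ** 2
    )


def overlap(p1, p2, shape: SpheroidShape, box=None) -> bool:
    """True iff the two parallel spheroids interpenetrate (contact is not overlap)."""
    return contact_function(p1, p2, shape, box=box) < 1.0


def discrete_charge_potential(point, shape: SpheroidShape, pair: ChargePair) -> float:
    """Dimensionless potential ``Phi*`` of the charge pair.

    ``Phi* = (R^2 / 2d) * (1/|r - r_+| - 1/|r - r_-|)`` with the sites at
    ``r_+/- = (0, 0, +/-d)``.  Normalized so that the on-axis far field is
    ``R^2 / z^2`` independent of ``d``.
    """
    p = np.asarray(point, dtype=float)
    rp = np.linalg.norm(p - np.array([0.0, 0.0, pair.d]))
    rm = np.linalg.norm(p - np.array([0.0, 0.0, -pair.d]))
    if rp == 0.0 or rm == 0.0:
        raise ZeroDivisionError("field point coincides with a charge site")
    if pair.d == 0.0:
        # moment-normalized limit: a pure point dipole
        r = np.linalg.norm(p)
        return float(shape.R**2 * p[2] / r**3)
    return float(shape.R**2 / (2.0 * pair.d) * (1.0 / rp - 1.0 / rm))


def exact_polarized_potential(point, shape: SpheroidShape) -> float:
    """Dimensionless exterior potential ``Phi*`` of a uniformly polarized spheroid.

    Computed by quadrature over the focal-segment dipole density
    ``mu(t) = A (1 - t^2/c^2)``, ``|t| <= c``, which reproduces the exterior
    field of uniform polarization exactly.  In the moment normalization the
    amplitude drops out:

        Phi*(r) = (3 R^2 / 4c) * int_{-c}^{c} (1 - t^2/c^2) (z - t)
                  / (s^2 + (z - t)^2)^{3/2} dt

    with ``s^2 = x^2 + y^2``.  Serves as the independent oracle for the
    discrete-charge representation.
    """
    p = np.asarray(point, dtype=float)
    x, y, z = p
    s2 = x * x + y * y
    if s2 / shape.R**2 + z * z / shape.a**2 < 1.0:
        raise ValueError("field point lies inside the spheroid")
    c = shape.focal_half_length
    if c == 0.0:
        r = np.linalg.norm(p)
        return float(shape.R**2 * z / r**3)

    def integrand(t: float) -> float:
        dz = z - t
        return (1.0 - (t / c) ** 2) * dz / (s2 + dz * dz) ** 1.5

    val, _ = integrate.quad(integrand, -c, c, limit=200)
    return float(3.0 * shape.R**2 / (4.0 * c) * val)
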
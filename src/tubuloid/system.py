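"""System state: particle centres in a periodic box, plus reduced-unit knobs.

The Monte Carlo state bundles the shared particle shape, the charge pair, the
coupling parameter ``Gamma``, the periodic box and the particle centres.  The
volume fraction is ``phi = N (4/3) pi rho R^3 / V``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ChargePair, SpheroidShape, charge_pair, contact_function

__all__ = ["SystemState", "minimum_image", "box_for_phi"]

#: interaction modes
CHARGE_PAIR = "charge_pair"
POINT_DIPOLE = "point_dipole"


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic periodic box."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def box_for_phi(n: int, shape: SpheroidShape, phi: float) -> np.ndarray:
    """Cubic box edge lengths giving volume fraction ``phi`` for ``n`` particles."""
    if not 0 < phi < 0.5:
        raise ValueError(f"volume fraction {phi} outside the sensible range (0, 0.5)")
    volume = n * shape.volume / phi
    edge = volume ** (1.0 / 3.0)
    return np.array([edge, edge, edge])


@dataclass
class SystemState:
    """Particles in a periodic box with electrostatic coupling ``gamma``.

    ``mode`` selects the interaction: ``"charge_pair"`` (the model) or
    ``"point_dipole"`` (the ideal-dipole negative control, an ideal z-dipole
    of moment ``2 q d`` at the particle centre).
    """

    shape: SpheroidShape
    pair: ChargePair
    gamma: float
    box: np.ndarray
    positions: np.ndarray
    mode: str = CHARGE_PAIR
    cached_energy: float | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.gamma < 0:
            raise ValueError("coupling parameter gamma must be >= 0")
        if self.mode not in (CHARGE_PAIR, POINT_DIPOLE):
            raise ValueError(f"unknown interaction mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def phi(self) -> float:
        return self.n * self.shape.volume / self.volume

    def wrapped(self) -> np.ndarray:
        """Positions folded into ``[0, L)`` per axis."""
        return np.mod(self.positions, self.box)

    def copy(self) -> "SystemState":
        return replace(self, positions=self.positions.copy())

    def has_overlap(self) -> bool:
        """Exhaustive minimum-image overlap check (testing/validation path)."""
        pos = self.positions
        rho = self.shape.rho
        lim = (2.0 * self.shape.R) ** 2
        for i in range(self.n - 1):
            d = pos[i + 1 :] - pos[i]
            d -= self.box * np.round(d / self.box)
            f = d[:, 0] ** 2 + d[:, 1] ** 2 + (d[:, 2] / rho) ** 2
            if np.any(f < lim * (1.0 - 1e-12)):
                return True
        return False


def make_state(
    positions,
    shape: SpheroidShape,
    box,
    gamma: float,
    mode: str = CHARGE_PAIR,
) -> SystemState:
    """Convenience constructor deriving the charge pair from the shape."""
    return SystemState(
        shape=shape,
        pair=charge_pair(shape),
        gamma=gamma,
        box=np.asarray(box, dtype=float),
        positions=np.asarray(positions, dtype=float),
        mode=mode,
    )
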
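"""Reduced-unit site-site electrostatics: direct sums, Ewald sums, controls.

The interaction energy of the model is

    U* = Gamma * sum_{inter-particle site pairs} Z_i Z_j / r*_ij,

with ``r* = r / 2R`` the site distance relative to the minimum centre-to-
centre distance of parallel spheroids (side-by-side contact, ``2R``) and
``Z = +/-1`` the site signs.  The coupling parameter
``Gamma = q^2 / (8 pi eps_m R k_B T)`` absorbs the charge magnitude and the
medium permittivity; all energies here are in units of ``k_B T`` and scale
exactly linearly in ``Gamma``.  No electrolyte screening enters the model.

Periodic systems use Ewald summation with the conducting ("tinfoil")
boundary; intra-particle site pairs are excluded consistently.  The
``point_dipole`` mode replaces each charge pair by an ideal z-dipole of the
same moment ``2 q d`` -- the negative control that does not form sheets or
tubes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import ChargePair, SpheroidShape
from .system import CHARGE_PAIR, SystemState, minimum_image

__all__ = [
    "EwaldParams",
    "direct_pair_energy",
    "total_energy_direct",
    "dipole_pair_energy",
    "ewald_energy",
    "move_energy_delta",
    "kvectors",
    "ewald_weights",
]


def energy_prefactor(gamma: float, shape: SpheroidShape) -> float:
    """``2 Gamma R``: converts a plain Coulomb site sum to reduced units."""
    return 2.0 * gamma * shape.R


def _site_terms(delta: np.ndarray, pair: ChargePair, box=None):
    """Distances and weights of the 4 inter-particle site pairs.

    For a centre displacement ``delta`` the site separations differ only in
    z: ``dz`` (weight +2, the ++ and -- pairs), ``dz - 2d`` and ``dz + 2d``
    (weight -1 each).  Minimum image is applied per site pair.
    """
    d = pair.d
    offsets = np.array([0.0, -2.0 * d, 2.0 * d])
    weights = np.array([2.0, -1.0, -1.0])
    vecs = np.tile(np.asarray(delta, dtype=float), (3, 1))
    vecs[:, 2] += offsets
    if box is not None:
        vecs = minimum_image(vecs, box)
    r = np.linalg.norm(vecs, axis=1)
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident charge sites")
    return r, weights


def direct_pair_energy(c1, c2, shape, pair, gamma, box=None) -> float:
    """Reduced energy of one particle pair by the direct 4-term site sum."""
    delta = np.asarray(c2, dtype=float) - np.asarray(c1, dtype=float)
    r, wts = _site_terms(delta, pair, box=box)
    return float(energy_prefactor(gamma, shape) * np.sum(wts / r))


def total_energy_direct(centers, shape, pair, gamma) -> float:
    """Reduced energy of a finite (non-periodic) aggregate; pairwise additive."""
    pos = np.atleast_2d(np.asarray(centers, dtype=float))
    n = pos.shape[0]
    if n < 2:
        return 0.0
    d = pair.d
    iu, ju = np.triu_indices(n, k=1)
    delta = pos[ju] - pos[iu]
    dxy2 = delta[:, 0] ** 2 + delta[:, 1] ** 2
    e = np.zeros(len(iu))
    for off, wt in ((0.0, 2.0), (-2.0 * d, -1.0), (2.0 * d, -1.0)):
        dz = delta[:, 2] + off
        e += wt / np.sqrt(dxy2 + dz * dz)
    return float(energy_prefactor(gamma, shape) * e.sum())


def dipole_pair_energy(c1, c2, shape, pair, gamma, box=None) -> float:
    """Ideal-dipole control: two parallel z-dipoles of moment ``2 q d``.

    ``U* = 2 Gamma R mu^2 (1 - 3 dz^2/r^2) / r^3`` -- the large-separation
    limit of :func:`direct_pair_energy`.  Repulsive side by side, attractive
    head to tail.
    """
    delta = np.asarray(c2, dtype=float) - np.asarray(c1, dtype=float)
    if box is not None:
        delta = minimum_image(delta, box)
    r2 = float(delta @ delta)
    if r2 == 0.0:
        raise ZeroDivisionError("coincident dipoles")
    r = math.sqrt(r2)
    mu2 = pair.moment**2
    return energy_prefactor(gamma, shape) * mu2 * (1.0 - 3.0 * delta[2] ** 2 / r2) / (
        r2 * r
    )


# ---------------------------------------------------------------------------
# Ewald summation


@dataclass(frozen=True)
class EwaldParams:
    """Splitting parameter and cutoffs for the Ewald sum.

    With ``s = sqrt(ln(1/accuracy))`` the choices ``alpha = s / r_cut`` and
    ``k_cut = 2 alpha s`` put both the real- and reciprocal-space truncation
    errors near ``accuracy``.  Results are invariant (to truncation level)
    under changes of ``alpha`` at fixed, generous cutoffs.
    """

    alpha: float
    r_cut: float
    k_cut: float

    @classmethod
    def from_box(cls, box, accuracy: float = 1e-5) -> "EwaldParams":
        box = np.asarray(box, dtype=float)
        s = math.sqrt(math.log(1.0 / accuracy))
        r_cut = float(box.min()) / 2.0
        alpha = s / r_cut
        return cls(alpha=alpha, r_cut=r_cut, k_cut=2.0 * alpha * s)

    def validate(self, box) -> None:
        if self.r_cut > float(np.min(box)) / 2.0 + 1e-12:
            raise ValueError(
                f"real-space cutoff {self.r_cut} exceeds half the shortest box edge"
            )


def kvectors(box, k_cut: float):
    """Half-space integer triples ``n`` and wavevectors ``k = 2 pi n / L``.

    Only one of each ``(k, -k)`` pair is kept (weights are doubled later);
    ``k = 0`` is excluded (tinfoil boundary, no surface term).
    """
    box = np.asarray(box, dtype=float)
    nmax = np.floor(k_cut * box / (2.0 * np.pi)).astype(int)
    ax = [np.arange(-m, m + 1) for m in nmax]
    nx, ny, nz = np.meshgrid(*ax, indexing="ij")
    n = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
    half = (n[:, 0] > 0) | ((n[:, 0] == 0) & (n[:, 1] > 0)) | (
        (n[:, 0] == 0) & (n[:, 1] == 0) & (n[:, 2] > 0)
    )
    n = n[half]
    k = 2.0 * np.pi * n / box[None, :]
    k2 = np.einsum("ij,ij->i", k, k)
    keep = k2 <= k_cut**2
    return n[keep], k[keep]


def ewald_weights(box, kvec, params: EwaldParams, mode: str, pair: ChargePair):
    """Reciprocal weights ``w(k)`` such that ``U_recip = sum_k w |T(k)|^2``.

    ``T(k) = sum_i exp(i k . c_i)`` runs over particle *centres*; the site
    structure enters through ``g(k) = 4 sin^2(k_z d)`` (charge pairs) or
    ``g(k) = mu^2 k_z^2`` (ideal dipoles).  The factor 2 accounts for the
    half k-space.
    """
    volume = float(np.prod(np.asarray(box, dtype=float)))
    k2 = np.einsum("ij,ij->i", kvec, kvec)
    kz = kvec[:, 2]
    coef = (2.0 * np.pi / volume) * np.exp(-k2 / (4.0 * params.alpha**2)) / k2
    if mode == CHARGE_PAIR:
        g = 4.0 * np.sin(kz * pair.d) ** 2
    else:
        g = pair.moment**2 * kz**2
    w = 2.0 * coef * g
    return w


def _constant_terms(state: SystemState, params: EwaldParams) -> float:
    """Self energy and intra-particle exclusion (configuration independent)."""
    n = state.n
    d = state.pair.d
    alpha = params.alpha
    if state.mode == CHARGE_PAIR:
        self_term = alpha / math.sqrt(math.pi) * 2.0 * n
        if d > 0:
            intra = n * math.erf(2.0 * alpha * d) / (2.0 * d)
        else:
            intra = n * 2.0 * alpha / math.sqrt(math.pi)
        const = -self_term + intra
    else:
        mu2 = state.pair.moment**2
        const = -2.0 * alpha**3 / (3.0 * math.sqrt(math.pi)) * n * mu2
    return energy_prefactor(state.gamma, state.shape) * const


def _mode_flag(state: SystemState) -> int:
    return 0 if state.mode == CHARGE_PAIR else 1


def ewald_energy(state: SystemState, params: EwaldParams | None = None) -> float:
    """Reduced periodic lattice-sum energy of a configuration.

    Reference (from-scratch) evaluation: real-space erfc sum over minimum
    images within ``r_cut``, reciprocal sum over the k-sphere, self and
    intra-particle corrections, conducting boundary.
    """
    if state.gamma == 0.0:
        return 0.0
    if params is None:
        params = EwaldParams.from_box(state.box)
    params.validate(state.box)
    mode = _mode_flag(state)
    mu2 = state.pair.moment**2
    real = _kernels.total_real_energy(
        state.positions,
        np.asarray(state.box, dtype=float),
        state.pair.d,
        mode,
        mu2,
        params.r_cut**2,
        params.alpha,
    )
    _, kvec = kvectors(state.box, params.k_cut)
    w = ewald_weights(state.box, kvec, params, state.mode, state.pair)
    phases = state.positions @ kvec.T
    T = np.exp(1j * phases).sum(axis=0)
    recip = float(np.sum(w * (T.real**2 + T.imag**2)))
    pref = energy_prefactor(state.gamma, state.shape)
    return pref * (real + recip) + _constant_terms(state, params)


def move_energy_delta(
    state: SystemState,
    index: int,
    new_position,
    params: EwaldParams | None = None,
) -> float:
    """Incremental ``Delta U*`` for moving one particle (no overlap assumed).

    Equals ``ewald_energy(after) - ewald_energy(before)`` to float precision;
    cost is O(N + K) instead of O(N^2 + K N).
    """
    if state.gamma == 0.0:
        return 0.0
    if params is None:
        params = EwaldParams.from_box(state.box)
    mode = _mode_flag(state)
    mu2 = state.pair.moment**2
    box = np.asarray(state.box, dtype=float)
    pos = state.positions
    old = pos[index]
    new = np.asarray(new_position, dtype=float)
    rc2 = params.r_cut**2
    e_old = _kernels.particle_real_energy(
        pos, index, old[0], old[1], old[2], box, state.pair.d, mode, mu2, rc2, params.alpha
    )
    e_new = _kernels.particle_real_energy(
        pos, index, new[0], new[1], new[2], box, state.pair.d, mode, mu2, rc2, params.alpha
    )
    _, kvec = kvectors(box, params.k_cut)
    w = ewald_weights(box, kvec, params, state.mode, state.pair)
    T = np.exp(1j * (pos @ kvec.T)).sum(axis=0)
    dp = np.exp(1j * (kvec @ new)) - np.exp(1j * (kvec @ old))
    drecip = float(np.sum(w * (2.0 * (T.real * dp.real + T.imag * dp.imag) + np.abs(dp) ** 2)))
    return energy_prefactor(state.gamma, state.shape) * (e_new - e_old + drecip)
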
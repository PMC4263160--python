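"""Numba kernels: real-space Ewald terms and the Metropolis MC inner loop.

Conventions shared with :mod:`tubuloid.electrostatics`:

* reduced energy ``U* = pref * sum_q q_i q_j / r_ij`` with ``pref = 2 Gamma R``
  (the factor ``2R`` converts site distances to the reduced distance
  ``r* = r / 2R``); kernels accumulate the *unscaled* sum, the prefactor is
  applied at the Metropolis decision and by the callers;
* charge-pair mode: each particle carries ``+1`` at ``center + d z`` and
  ``-1`` at ``center - d z``; intra-particle pairs are excluded;
* point-dipole mode: an ideal z-dipole of moment ``mu = 2 d`` at the centre;
* minimum image applied per site pair, orthorhombic box, tinfoil boundary;
* reciprocal space is tracked through ``T(k) = sum_i exp(i k . c_i)`` (one
  term per particle centre); mode-dependent site structure factors are folded
  into the weights ``w(k)`` built in :mod:`tubuloid.electrostatics`.
"""

from __future__ import annotations

import math

import numba
import numpy as np

SQRT_PI = math.sqrt(math.pi)


@numba.njit(inline="always")
def _min_image(x, L):
    return x - L * round(x / L)


@numba.njit(inline="always")
def _pair_real_charge(dx, dy, dz, d, bz, rc2, alpha):
    """Screened (erfc) sum over the 4 inter-particle site pairs.

    ``dx, dy`` are already minimum-imaged; the three distinct z separations
    ``dz``, ``dz - 2d``, ``dz + 2d`` carry weights ``+2, -1, -1``.
    """
    e = 0.0
    dxy2 = dx * dx + dy * dy
    for t in range(3):
        if t == 0:
            off = 0.0
            sgn = 2.0
        elif t == 1:
            off = -2.0 * d
            sgn = -1.0
        else:
            off = 2.0 * d
            sgn = -1.0
        dzz = _min_image(dz + off, bz)
        r2 = dxy2 + dzz * dzz
        if r2 < rc2:
            r = math.sqrt(r2)
            e += sgn * math.erfc(alpha * r) / r
    return e


@numba.njit(inline="always")
def _pair_real_dipole(dx, dy, dz, mu2, rc2, alpha):
    """Screened real-space interaction of two parallel ideal z-dipoles."""
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc2:
        return 0.0
    r = math.sqrt(r2)
    ar = alpha * r
    ex = math.exp(-ar * ar)
    erfc_ar = math.erfc(ar)
    b = (erfc_ar + 2.0 * ar / SQRT_PI * ex) / (r2 * r)
    c = (3.0 * erfc_ar + (2.0 * ar / SQRT_PI) * (3.0 + 2.0 * ar * ar) * ex) / (
        r2 * r2 * r
    )
    return mu2 * (b - dz * dz * c)


@numba.njit
def particle_real_energy(pos, i, xi, yi, zi, box, d, mode, mu2, rc2, alpha):
    """Real-space energy sum of a particle at (xi, yi, zi) with all others."""
    e = 0.0
    for j in range(pos.shape[0]):
        if j == i:
            continue
        dx = _min_image(pos[j, 0] - xi, box[0])
        dy = _min_image(pos[j, 1] - yi, box[1])
        dz = pos[j, 2] - zi
        if mode == 0:
            e += _pair_real_charge(dx, dy, dz, d, box[2], rc2, alpha)
        else:
            e += _pair_real_dipole(dx, dy, _min_image(dz, box[2]), mu2, rc2, alpha)
    return e


@numba.njit
def total_real_energy(pos, box, d, mode, mu2, rc2, alpha):
    e = 0.0
    n = pos.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[j, 0] - pos[i, 0], box[0])
            dy = _min_image(pos[j, 1] - pos[i, 1], box[1])
            dz = pos[j, 2] - pos[i, 2]
            if mode == 0:
                e += _pair_real_charge(dx, dy, dz, d, box[2], rc2, alpha)
            else:
                e += _pair_real_dipole(
                    dx, dy, _min_image(dz, box[2]), mu2, rc2, alpha
                )
    return e


@numba.njit
def compute_T(pos, kx, ky, kz):
    """Centre structure factor ``T(k) = sum_i exp(i k . c_i)``."""
    K = kx.shape[0]
    T = np.zeros(K, dtype=np.complex128)
    for i in range(pos.shape[0]):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        for t in range(K):
            ph = kx[t] * x + ky[t] * y + kz[t] * z
            T[t] += complex(math.cos(ph), math.sin(ph))
    return T


@numba.njit
def recip_energy(T, w):
    e = 0.0
    for t in range(T.shape[0]):
        e += w[t] * (T[t].real * T[t].real + T[t].imag * T[t].imag)
    return e


@numba.njit(inline="always")
def _fill_phase(x, L, nm, out):
    """out[nm + p] = exp(i 2 pi p x / L) for p in [-nm, nm]."""
    arg = 2.0 * math.pi * x / L
    base = complex(math.cos(arg), math.sin(arg))
    out[nm] = 1.0 + 0.0j
    acc = 1.0 + 0.0j
    for p in range(1, nm + 1):
        acc = acc * base
        out[nm + p] = acc
        out[nm - p] = acc.conjugate()


@numba.njit
def check_overlap(pos, i, xi, yi, zi, box, rho, four_r2):
    """True if a particle at (xi, yi, zi) overlaps any particle j != i."""
    for j in range(pos.shape[0]):
        if j == i:
            continue
        dx = _min_image(pos[j, 0] - xi, box[0])
        dy = _min_image(pos[j, 1] - yi, box[1])
        dz = _min_image(pos[j, 2] - zi, box[2])
        if dx * dx + dy * dy + (dz / rho) * (dz / rho) < four_r2:
            return True
    return False


@numba.njit
def mc_run(
    pos,
    box,
    rho,
    R,
    d,
    mode,
    mu2,
    pref,
    disp,
    n_cycles,
    seed,
    kx,
    ky,
    kz,
    w,
    nkx,
    nky,
    nkz,
    nmx,
    nmy,
    nmz,
    alpha,
    rc,
    T,
    u_var,
    snap_stride,
    snaps,
    snap_cycle,
    snap_u,
    counters,
):
    """Run ``n_cycles`` MC cycles in place; returns the final variable energy.

    One cycle = N attempted single-particle translations, each uniform in a
    cube of half-width ``disp``.  Hard-core overlap is tested first (cheap
    reject), then the Metropolis rule ``min(1, exp(-pref * delta))`` is
    applied to the incremental Ewald energy.  ``T`` (reciprocal structure
    factor) and ``u_var`` (real + reciprocal unscaled energy) are maintained
    incrementally; ``T`` is refreshed from scratch at every snapshot to keep
    floating-point drift at bay.

    counters: [attempts, accepted, overlap_rejects, energy_rejects]
    """
    np.random.seed(seed)
    n = pos.shape[0]
    K = kx.shape[0]
    four_r2 = (2.0 * R) ** 2
    rc2 = rc * rc
    exo = np.empty(2 * nmx + 1, dtype=np.complex128)
    eyo = np.empty(2 * nmy + 1, dtype=np.complex128)
    ezo = np.empty(2 * nmz + 1, dtype=np.complex128)
    exn = np.empty(2 * nmx + 1, dtype=np.complex128)
    eyn = np.empty(2 * nmy + 1, dtype=np.complex128)
    ezn = np.empty(2 * nmz + 1, dtype=np.complex128)
    dphase = np.empty(K, dtype=np.complex128)
    n_snap = 0

    for cyc in range(n_cycles):
        for _ in range(n):
            counters[0] += 1
            i = int(np.random.random() * n)
            if i == n:
                i = n - 1
            xo = pos[i, 0]
            yo = pos[i, 1]
            zo = pos[i, 2]
            xn = (xo + disp * (2.0 * np.random.random() - 1.0)) % box[0]
            yn = (yo + disp * (2.0 * np.random.random() - 1.0)) % box[1]
            zn = (zo + disp * (2.0 * np.random.random() - 1.0)) % box[2]
            if check_overlap(pos, i, xn, yn, zn, box, rho, four_r2):
                counters[2] += 1
                continue
            if pref != 0.0:
                e_old = particle_real_energy(
                    pos, i, xo, yo, zo, box, d, mode, mu2, rc2, alpha
                )
                e_new = particle_real_energy(
                    pos, i, xn, yn, zn, box, d, mode, mu2, rc2, alpha
                )
                delta = e_new - e_old
                _fill_phase(xo, box[0], nmx, exo)
                _fill_phase(yo, box[1], nmy, eyo)
                _fill_phase(zo, box[2], nmz, ezo)
                _fill_phase(xn, box[0], nmx, exn)
                _fill_phase(yn, box[1], nmy, eyn)
                _fill_phase(zn, box[2], nmz, ezn)
                for t in range(K):
                    po = exo[nkx[t] + nmx] * eyo[nky[t] + nmy] * ezo[nkz[t] + nmz]
                    pn = exn[nkx[t] + nmx] * eyn[nky[t] + nmy] * ezn[nkz[t] + nmz]
                    dp = pn - po
                    dphase[t] = dp
                    tt = T[t]
                    delta += w[t] * (
                        2.0 * (tt.real * dp.real + tt.imag * dp.imag)
                        + dp.real * dp.real
                        + dp.imag * dp.imag
                    )
                du = pref * delta
                if du > 0.0 and np.random.random() >= math.exp(-du):
                    counters[3] += 1
                    continue
                T += dphase
                u_var += delta
            pos[i, 0] = xn
            pos[i, 1] = yn
            pos[i, 2] = zn
            counters[1] += 1
        if snap_stride > 0 and (cyc + 1) % snap_stride == 0:
            if n_snap < snaps.shape[0]:
                snaps[n_snap] = pos
                snap_cycle[n_snap] = cyc + 1
                snap_u[n_snap] = u_var
                n_snap += 1
            if pref != 0.0:
                Tf = compute_T(pos, kx, ky, kz)
                for t in range(K):
                    T[t] = Tf[t]
    return u_var, n_snap
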
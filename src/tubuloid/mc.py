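"""Metropolis Monte Carlo of hard parallel spheroids with charge-pair coupling.

The move set is exactly single-particle translations: a trial displacement
uniform in a cube of half-width ``displacement`` (default one particle radius
``R``), hard-core rejection first, then the Metropolis rule on the
incremental Ewald energy.  One cycle is N attempted moves.  Trajectories are
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .electrostatics import (
    EwaldParams,
    _constant_terms,
    energy_prefactor,
    ewald_energy,
    ewald_weights,
    kvectors,
    move_energy_delta,
)
from .geometry import SpheroidShape, charge_pair, contact_function
from .system import CHARGE_PAIR, SystemState, box_for_phi

__all__ = [
    "MCParams",
    "Trajectory",
    "PackingError",
    "init_random_config",
    "mc_step",
    "run_mc",
    "run_until_plateau",
]


class PackingError(RuntimeError):
    """Random sequential insertion failed; lower phi or raise the attempt cap."""


@dataclass(frozen=True)
class MCParams:
    """Run parameters.  ``displacement=None`` means one particle radius ``R``."""

    cycles: int
    displacement: float | None = None
    seed: int = 0
    snapshot_stride: int = 1000
    ewald_accuracy: float = 1e-5


@dataclass
class Trajectory:
    """Snapshots plus bookkeeping of a single MC run (replayable from seed)."""

    cycles: np.ndarray
    energies: np.ndarray
    snapshots: np.ndarray
    acceptance: dict
    params: MCParams
    final_state: SystemState

    @property
    def n_frames(self) -> int:
        return self.snapshots.shape[0]

    def frame_state(self, i: int) -> SystemState:
        return replace(self.final_state, positions=self.snapshots[i].copy(),
                       cached_energy=float(self.energies[i]))


def init_random_config(
    n: int,
    shape: SpheroidShape,
    gamma: float,
    phi: float | None = None,
    box=None,
    seed: int = 0,
    mode: str = CHARGE_PAIR,
    max_attempts_per_particle: int = 20000,
) -> SystemState:
    """Random sequential insertion of ``n`` overlap-free aligned spheroids."""
    if box is None:
        if phi is None:
            raise ValueError("give either phi or box")
        box = box_for_phi(n, shape, phi)
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    rho = shape.rho
    lim = (2.0 * shape.R) ** 2
    pos = np.empty((n, 3))
    placed = 0
    attempts = 0
    cap = max_attempts_per_particle * n
    while placed < n:
        if attempts >= cap:
            raise PackingError(
                f"failed to insert particle {placed + 1}/{n} after {attempts} attempts; "
                "volume fraction too high for random insertion"
            )
        attempts += 1
        trial = rng.random(3) * box
        if placed:
            d = pos[:placed] - trial
            d -= box * np.round(d / box)
            f = d[:, 0] ** 2 + d[:, 1] ** 2 + (d[:, 2] / rho) ** 2
            if np.any(f < lim):
                continue
        pos[placed] = trial
        placed += 1
    return SystemState(
        shape=shape, pair=charge_pair(shape), gamma=gamma, box=box,
        positions=pos, mode=mode,
    )


def mc_step(state: SystemState, params: MCParams, rng: np.random.Generator):
    """One attempted single-particle move (clear reference path, not the fast loop).

    Returns ``(state, accepted)``; the state is updated in place on accept.
    """
    disp = params.displacement if params.displacement is not None else state.shape.R
    i = int(rng.integers(state.n))
    trial = state.positions[i] + disp * (2.0 * rng.random(3) - 1.0)
    trial = np.mod(trial, state.box)
    for j in range(state.n):
        if j != i and contact_function(trial, state.positions[j], state.shape,
                                       box=state.box) < 1.0:
            return state, False
    du = move_energy_delta(state, i, trial)
    if du > 0.0 and rng.random() >= math.exp(-du):
        return state, False
    state.positions[i] = trial
    if state.cached_energy is not None:
        state.cached_energy += du
    return state, True


def _kernel_inputs(state: SystemState, params: MCParams):
    box = np.asarray(state.box, dtype=float)
    pref = energy_prefactor(state.gamma, state.shape)
    mode = 0 if state.mode == CHARGE_PAIR else 1
    mu2 = state.pair.moment**2
    ew = EwaldParams.from_box(box, accuracy=params.ewald_accuracy)
    if pref != 0.0:
        nvec, kvec = kvectors(box, ew.k_cut)
        w = ewald_weights(box, kvec, ew, state.mode, state.pair)
        keep = w > (w.max() * 1e-14 if w.size else 0.0)
        nvec, kvec, w = nvec[keep], kvec[keep], w[keep]
    else:
        nvec = np.zeros((0, 3), dtype=int)
        kvec = np.zeros((0, 3))
        w = np.zeros(0)
    nmax = nvec.max(axis=0) if nvec.size else np.zeros(3, dtype=int)
    return box, pref, mode, mu2, ew, nvec, kvec, w, nmax


def run_mc(state: SystemState, params: MCParams) -> Trajectory:
    """Run ``params.cycles`` cycles with the compiled kernel; deterministic."""
    box, pref, mode, mu2, ew, nvec, kvec, w, nmax = _kernel_inputs(state, params)
    if state.has_overlap():
        raise ValueError("initial configuration contains overlapping particles")
    pos = np.mod(state.positions, box).copy()
    disp = params.displacement if params.displacement is not None else state.shape.R
    kx = np.ascontiguousarray(kvec[:, 0])
    ky = np.ascontiguousarray(kvec[:, 1])
    kz = np.ascontiguousarray(kvec[:, 2])
    nkx = np.ascontiguousarray(nvec[:, 0].astype(np.int64))
    nky = np.ascontiguousarray(nvec[:, 1].astype(np.int64))
    nkz = np.ascontiguousarray(nvec[:, 2].astype(np.int64))
    if pref != 0.0:
        T = _kernels.compute_T(pos, kx, ky, kz)
        u_var = _kernels.total_real_energy(
            pos, box, state.pair.d, mode, mu2, ew.r_cut**2, ew.alpha
        ) + _kernels.recip_energy(T, w)
        const = _constant_terms(state, ew)
    else:
        T = np.zeros(0, dtype=np.complex128)
        u_var = 0.0
        const = 0.0
    stride = max(int(params.snapshot_stride), 1)
    n_snap_max = params.cycles // stride
    snaps = np.empty((n_snap_max, state.n, 3))
    snap_cycle = np.zeros(n_snap_max, dtype=np.int64)
    snap_u = np.zeros(n_snap_max)
    counters = np.zeros(4, dtype=np.int64)
    u0 = pref * u_var + const
    u_final, n_snap = _kernels.mc_run(
        pos, box, state.shape.rho, state.shape.R, state.pair.d, mode, mu2, pref,
        disp, int(params.cycles), int(params.seed) % 2**31,
        kx, ky, kz, w, nkx, nky, nkz,
        int(nmax[0]), int(nmax[1]), int(nmax[2]),
        ew.alpha, ew.r_cut, T, u_var, stride,
        snaps, snap_cycle, snap_u, counters,
    )
    cycles = np.concatenate([[0], snap_cycle[:n_snap]])
    energies = np.concatenate([[u0], pref * snap_u[:n_snap] + const])
    frames = np.concatenate([state.positions[None, :, :], snaps[:n_snap]], axis=0)
    attempts = int(counters[0])
    acceptance = {
        "attempts": attempts,
        "accepted": int(counters[1]),
        "overlap_rejects": int(counters[2]),
        "energy_rejects": int(counters[3]),
        "rate": int(counters[1]) / attempts if attempts else float("nan"),
    }
    final_state = replace(
        state, positions=pos, cached_energy=float(pref * u_final + const)
    )
    return Trajectory(
        cycles=cycles, energies=energies, snapshots=frames,
        acceptance=acceptance, params=params, final_state=final_state,
    )


def run_until_plateau(
    state: SystemState,
    params: MCParams,
    chunk_cycles: int = 5000,
    max_cycles: int = 200_000,
    tol_per_particle: float = 0.05,
) -> Trajectory:
    """Run in chunks until the chunk-mean energy per particle plateaus.

    Stops when consecutive chunk means differ by less than
    ``tol_per_particle`` (in kT per particle) or ``max_cycles`` is reached.
    The scaled-down stand-in for the full-length runs: aggregation energy
    decays to a plateau well before large-scale rearrangements stop.
    """
    current = state
    prev_mean = None
    total = 0
    chunk_idx = 0
    last_traj = None
    all_cycles, all_energies = [], []
    while total < max_cycles:
        p = replace(
            params,
            cycles=min(chunk_cycles, max_cycles - total),
            seed=(params.seed + 7919 * chunk_idx) % 2**31,
            snapshot_stride=max(chunk_cycles // 5, 1),
        )
        traj = run_mc(current, p)
        current = traj.final_state
        all_cycles.append(traj.cycles[1:] + total)
        all_energies.append(traj.energies[1:])
        total += p.cycles
        chunk_idx += 1
        mean = float(np.mean(traj.energies[1:])) / state.n
        if prev_mean is not None and abs(mean - prev_mean) < tol_per_particle:
            last_traj = traj
            break
        prev_mean = mean
        last_traj = traj
    cycles = np.concatenate([[0]] + all_cycles)
    energies = np.concatenate([[state.cached_energy or 0.0]] + all_energies)
    return Trajectory(
        cycles=cycles, energies=energies,
        snapshots=last_traj.snapshots[-1:][:],
        acceptance=last_traj.acceptance, params=params, final_state=current,
    )
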
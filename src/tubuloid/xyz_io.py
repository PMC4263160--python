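"""Extended-XYZ reading/writing for configurations and trajectories.

Plain-text format: a particle count line, a comment line carrying
``key=value`` metadata (box as a quoted ``Lattice`` matrix, shape, coupling,
charge offset, interaction mode, cycle index), then one ``ELL x y z`` record
per particle.  With ``sites=True`` the two charge sites are appended as
``QP``/``QM`` records for visualization; readers skip them.  Round-trips are
lossless at the printed precision (%.12g).
"""

from __future__ import annotations

import re
import shlex
from typing import IO, Iterator

import numpy as np

from .geometry import ChargePair, SpheroidShape, site_positions
from .system import SystemState

__all__ = ["write_xyz", "read_xyz", "read_frames"]

_FMT = "%.12g"


def _header(state: SystemState, cycle: int | None) -> str:
    lx, ly, lz = state.box
    lattice = f'"{_FMT % lx} 0 0 0 {_FMT % ly} 0 0 0 {_FMT % lz}"'
    fields = [
        f"Lattice={lattice}",
        "Properties=species:S:1:pos:R:3",
        f"rho={_FMT % state.shape.rho}",
        f"R={_FMT % state.shape.R}",
        f"gamma={_FMT % state.gamma}",
        f"d={_FMT % state.pair.d}",
        f"mode={state.mode}",
    ]
    if cycle is not None:
        fields.append(f"cycle={cycle}")
    if state.cached_energy is not None:
        fields.append(f"energy={_FMT % state.cached_energy}")
    return " ".join(fields)


def write_xyz(state: SystemState, fh: IO[str] | str, cycle: int | None = None,
              sites: bool = False) -> None:
    """Append one frame to an open text file or path."""
    if isinstance(fh, str):
        with open(fh, "a") as f:
            write_xyz(state, f, cycle=cycle, sites=sites)
        return
    n_records = state.n * (3 if sites else 1)
    fh.write(f"{n_records}\n")
    fh.write(_header(state, cycle) + "\n")
    for c in state.positions:
        fh.write(f"ELL {_FMT % c[0]} {_FMT % c[1]} {_FMT % c[2]}\n")
        if sites:
            sp = site_positions(c, state.pair)
            fh.write(f"QP {_FMT % sp[0, 0]} {_FMT % sp[0, 1]} {_FMT % sp[0, 2]}\n")
            fh.write(f"QM {_FMT % sp[1, 0]} {_FMT % sp[1, 1]} {_FMT % sp[1, 2]}\n")


def _parse_comment(line: str, lineno: int) -> dict:
    try:
        tokens = shlex.split(line)
    except ValueError as exc:
        raise ValueError(f"malformed header at line {lineno}: {exc}") from exc
    meta = {}
    for tok in tokens:
        if "=" not in tok:
            continue
        key, val = tok.split("=", 1)
        meta[key] = val
    return meta


def _frame(fh: IO[str], lineno: int):
    first = fh.readline()
    if not first:
        return None, lineno
    lineno += 1
    try:
        n = int(first.strip())
    except ValueError as exc:
        raise ValueError(f"line {lineno}: expected record count, got {first!r}") from exc
    comment = fh.readline()
    lineno += 1
    meta = _parse_comment(comment, lineno)
    centers = []
    for _ in range(n):
        rec = fh.readline()
        lineno += 1
        parts = rec.split()
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: malformed record {rec!r}")
        if parts[0] in ("QP", "QM"):
            continue
        centers.append([float(v) for v in parts[1:]])
    try:
        lat = [float(v) for v in meta["Lattice"].split()]
        box = np.array([lat[0], lat[4], lat[8]])
        shape = SpheroidShape(R=float(meta["R"]), rho=float(meta["rho"]))
        pair = ChargePair(d=float(meta["d"]))
        gamma = float(meta["gamma"])
    except KeyError as exc:
        raise ValueError(f"header near line {lineno} misses key {exc}") from exc
    state = SystemState(
        shape=shape, pair=pair, gamma=gamma, box=box,
        positions=np.array(centers), mode=meta.get("mode", "charge_pair"),
        cached_energy=float(meta["energy"]) if "energy" in meta else None,
    )
    return (state, meta), lineno


def read_frames(path: str) -> Iterator[tuple[SystemState, dict]]:
    """Yield (state, metadata) per frame of an extended-XYZ file."""
    with open(path) as fh:
        lineno = 0
        while True:
            out, lineno = _frame(fh, lineno)
            if out is None:
                return
            yield out


def read_xyz(path: str) -> SystemState:
    """First frame of the file as a :class:`SystemState`."""
    for state, _ in read_frames(path):
        return state
    raise ValueError(f"{path} contains no frames")
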
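"""Morphology classification: fluid / string / compact / sheet / tube.

Configurations are reduced to a contact graph (edges where the parallel-
spheroid contact function is within a tolerance ``delta`` of contact) and
analysed per cluster under the minimum-image convention.  A cluster spans an
axis when it connects to its own periodic image along that axis; a z-spanning
cluster whose z-slabs form closed, hollow rings is a tube, one of single- or
double-particle width is a string, and a cluster spanning two axes is a
sheet.  Everything else that holds most of the particles is a compact
aggregate; otherwise the configuration is a fluid.

The thresholds are artifact choices (the original morphologies were read off
visually); they are exposed as keyword arguments, and labels are required to
be robust over ``delta`` in [0.1, 0.3].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import SpheroidShape, charge_pair
from .lattice import LatticeSpec, _columns, build_sheet, build_tube
from .system import SystemState, minimum_image

__all__ = [
    "ContactGraph",
    "MorphologyLabel",
    "build_contact_graph",
    "spanning_dimensions",
    "classify",
    "build_fixture",
]

_AXES = ("x", "y", "z")


@dataclass
class ContactGraph:
    """Particle contact network under minimum image."""

    n: int
    edges: np.ndarray  # (E, 2) int
    labels: np.ndarray  # connected-component label per particle

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.n else 0

    def cluster_members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class MorphologyLabel:
    """Classification outcome of a configuration."""

    label: str  # fluid | string | compact | sheet | tube
    spanning: frozenset
    ring_counts: tuple | None
    cluster_sizes: tuple
    largest_fraction: float
    diagnostics: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def build_contact_graph(state: SystemState, delta: float = 0.2) -> ContactGraph:
    """Edges between pairs with contact function <= (1 + delta)^2."""
    if delta < 0:
        raise ValueError("neighbour tolerance delta must be >= 0")
    pos = state.wrapped()
    n = state.n
    rho = state.shape.rho
    lim = ((1.0 + delta) * 2.0 * state.shape.R) ** 2
    rows, cols = [], []
    for i in range(n - 1):
        d = pos[i + 1 :] - pos[i]
        d -= state.box * np.round(d / state.box)
        f = d[:, 0] ** 2 + d[:, 1] ** 2 + (d[:, 2] / rho) ** 2
        hits = np.flatnonzero(f <= lim)
        rows.extend([i] * len(hits))
        cols.extend((hits + i + 1).tolist())
    edges = np.array([rows, cols], dtype=int).T.reshape(-1, 2)
    data = np.ones(len(edges))
    adj = csr_matrix(
        (np.concatenate([data, data]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    return ContactGraph(n=n, edges=edges, labels=labels)


def _adjacency_lists(graph: ContactGraph):
    adj = [[] for _ in range(graph.n)]
    for a, b in graph.edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _unwrap_cluster(graph: ContactGraph, state: SystemState, members: np.ndarray):
    """BFS unwrap of one cluster; detects periodic winding per axis.

    Returns (unwrapped positions for members, spanning axis set).  A closing
    edge whose unwrapped positions disagree by ~a box length marks the
    cluster as connected to its own image along that axis.
    """
    pos = state.wrapped()
    box = state.box
    adj = _adjacency_lists(graph)
    upos = {}
    spans = set()
    start = int(members[0])
    upos[start] = pos[start].copy()
    queue = [start]
    while queue:
        u = queue.pop()
        for v in adj[u]:
            step = minimum_image(pos[v] - pos[u], box)
            cand = upos[u] + step
            if v not in upos:
                upos[v] = cand
                queue.append(v)
            else:
                diff = cand - upos[v]
                for k in range(3):
                    if abs(diff[k]) > 0.5 * box[k]:
                        spans.add(_AXES[k])
    arr = np.array([upos[int(m)] for m in members])
    return arr, frozenset(spans)


def spanning_dimensions(graph: ContactGraph, state: SystemState,
                        cluster: int | None = None) -> frozenset:
    """Axes along which a cluster connects to its own periodic image.

    With ``cluster=None`` the union over all clusters is returned.
    """
    spans = set()
    clusters = range(graph.n_clusters) if cluster is None else [cluster]
    for c in clusters:
        members = graph.cluster_members(c)
        if len(members) < 2:
            continue
        _, s = _unwrap_cluster(graph, state, members)
        spans |= s
    return frozenset(spans)


def _ring_analysis(state: SystemState, upos: np.ndarray, slab: float,
                   r_hollow_frac: float):
    """Per-slab ring statistics of a z-spanning cluster.

    Slabs of thickness ``slab`` tile one box period in z (wrapped z); the
    cluster axis is the lateral centroid of the unwrapped coordinates.
    """
    lz = state.box[2]
    nslab = max(int(round(lz / slab)), 1)
    edges = np.linspace(0.0, lz, nslab + 1)
    # anchor the slab grid off the lowest particle so lattice-perfect
    # configurations never sit exactly on a bin edge
    z0 = upos[:, 2].min()
    zw = np.mod(upos[:, 2] - z0 + 0.25 * lz / nslab, lz)
    # cluster axis: straight line x(z), y(z) fitted to the unwrapped
    # coordinates -- rigid like the field axis but tolerant of overall shear
    z = upos[:, 2]
    A = np.stack([np.ones_like(z), z], axis=1)
    (ax0, ax1), *_ = np.linalg.lstsq(A, upos[:, 0], rcond=None)
    (ay0, ay1), *_ = np.linalg.lstsq(A, upos[:, 1], rcond=None)
    dx = upos[:, 0] - (ax0 + ax1 * z)
    dy = upos[:, 1] - (ay0 + ay1 * z)
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    counts, hollow, closed = [], [], []
    for s in range(nslab):
        inside = (zw >= edges[s]) & (zw < edges[s + 1])
        c = int(inside.sum())
        counts.append(c)
        if c == 0:
            continue
        if c < 4:
            # too few members for a closed ring: a string segment or defect
            hollow.append(False)
            closed.append(False)
            continue
        rs = r[inside]
        mean_r = rs.mean()
        hollow.append(bool(mean_r > 0 and rs.min() > r_hollow_frac * mean_r))
        th = np.sort(theta[inside])
        gaps = np.diff(np.concatenate([th, [th[0] + 2 * np.pi]]))
        closed.append(bool(gaps.max() <= np.pi))
    occupied = [c for c in counts if c > 0]
    return {
        "counts": counts,
        "mean_occupancy": float(np.mean(occupied)) if occupied else 0.0,
        "hollow_fraction": float(np.mean(hollow)) if hollow else 0.0,
        "closed_fraction": float(np.mean(closed)) if closed else 0.0,
    }


def classify(
    state: SystemState,
    delta: float = 0.2,
    fluid_threshold: float = 0.5,
    r_hollow_frac: float = 0.5,
    string_width: float = 2.5,
    slab: float | None = None,
    ring_fraction: float = 0.7,
) -> MorphologyLabel:
    """Decision cascade over the contact-graph clusters.

    fluid: no spanning cluster and the largest cluster holds fewer than
    ``fluid_threshold`` of the particles.  string: spans z only, one to two
    particles per z-slab.  sheet: spans two or more axes.  tube: spans z
    only, slabs form closed rings with an empty interior.  compact:
    everything else (ambiguous cases land here, with diagnostics).
    """
    graph = build_contact_graph(state, delta=delta)
    sizes = graph.cluster_sizes()
    largest_fraction = float(sizes.max()) / state.n if state.n else 0.0
    if slab is None:
        slab = state.shape.length  # within-column period at closest stacking
    # prefer a spanning cluster, else the largest
    span_by_cluster = {}
    target, target_spans = None, frozenset()
    order = np.argsort(sizes)[::-1]
    for c in order:
        members = graph.cluster_members(int(c))
        if len(members) < 2:
            continue
        upos, spans = _unwrap_cluster(graph, state, members)
        span_by_cluster[int(c)] = spans
        if spans and target is None:
            target, target_spans, target_upos = int(c), spans, upos
    diagnostics = {"delta": delta, "cluster_spans": span_by_cluster}
    if target is None:
        target = int(order[0])
        members = graph.cluster_members(target)
        if len(members) >= 2:
            target_upos, target_spans = _unwrap_cluster(graph, state, members)
        else:
            target_upos = state.wrapped()[members]

    def result(label, ring_counts=None):
        return MorphologyLabel(
            label=label, spanning=target_spans, ring_counts=ring_counts,
            cluster_sizes=tuple(int(s) for s in np.sort(sizes)[::-1]),
            largest_fraction=largest_fraction, diagnostics=diagnostics,
        )

    if not target_spans:
        if largest_fraction < fluid_threshold:
            return result("fluid")
        return result("compact")
    if len(target_spans) >= 2:
        return result("sheet")
    if target_spans == frozenset({"z"}):
        rings = _ring_analysis(state, target_upos, slab, r_hollow_frac)
        diagnostics["rings"] = rings
        if rings["mean_occupancy"] <= string_width:
            return result("string")
        if (rings["hollow_fraction"] >= ring_fraction
                and rings["closed_fraction"] >= ring_fraction):
            counts = tuple(c for c in rings["counts"] if c > 0)
            return result("tube", ring_counts=counts)
        return result("compact")
    # spans a single lateral axis only: ambiguous
    return result("compact")


def build_fixture(
    kind: str,
    n_z: int,
    n_x: int = 1,
    shape: SpheroidShape | None = None,
    l_z: float | None = None,
    gamma: float = 1.0,
) -> SystemState:
    """Idealized tube / sheet / string configurations in a fitting periodic box.

    Built from the lattice module's geometry at head-to-tail stacking
    (``l_z = 2 rho R``) by default, so every designated neighbour pair is at
    exact contact.  Tubes and strings span z; sheets span x and z (``n_x``
    must be even so the alternating columns continue across the boundary).
    """
    if shape is None:
        shape = SpheroidShape()
    if l_z is None:
        l_z = shape.length
    pad = 8.0 * shape.R
    if kind == "string":
        centers = np.zeros((n_z, 3))
        centers[:, 2] = np.arange(n_z) * l_z
        box = np.array([pad, pad, n_z * l_z])
        centers[:, 0] = pad / 2.0
        centers[:, 1] = pad / 2.0
    elif kind == "tube":
        spec = LatticeSpec(kind="tube", n_z=n_z, n_x=n_x, l_z=l_z)
        centers = build_tube(spec, shape)
        xy, _ = _columns(spec, shape)
        r_c = float(np.hypot(xy[0, 0], xy[0, 1]))
        side = 2.0 * r_c + pad
        centers[:, 0] += side / 2.0
        centers[:, 1] += side / 2.0
        box = np.array([side, side, n_z * l_z])
    elif kind == "sheet":
        if n_x % 2:
            raise ValueError("sheet fixtures need even n_x to wrap periodically")
        spec = LatticeSpec(kind="sheet", n_z=n_z, n_x=n_x, l_z=l_z)
        centers = build_sheet(spec, shape)
        from .lattice import column_spacing

        l_x = column_spacing(l_z, shape)
        box = np.array([n_x * l_x, pad, n_z * l_z])
        centers[:, 1] = pad / 2.0
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return SystemState(
        shape=shape, pair=charge_pair(shape), gamma=gamma, box=box,
        positions=np.mod(centers, box),
    )
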
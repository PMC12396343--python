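"""Orientation-field-driven print lines and continuity optimization.

A layer to be printed is discretized into a rectangular grid of *units*,
each carrying the dominant local fiber orientation (in dermal tissue, the
Langer-line direction of collagen alignment).  Each unit is filled with
parallel print lines at its local angle; where a line ends on a border
shared with an already-generated neighbour, its endpoint is snapped to the
neighbour's nearest border endpoint and the two are joined, so extrusion can
continue across the border without a stop-start event.

The resulting waypoint graph is decomposed into continuous extrusion paths
by a randomized recursive depth-first search: pick a random untraversed
waypoint, extend forward to a branch point, explore each branch depth-first
keeping the longest, do the same in reverse, retire the traversed waypoints,
and repeat; the whole procedure is restarted many times and the decomposition
with the fewest distinct paths wins.  Fewer paths means fewer stop-start
extrusion events and better print quality in direct ink writing.

Units: millimetres and degrees.  Orientation angles are line directions,
reduced modulo 180.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from .voxel import ValidationError

__all__ = [
    "OrientationField",
    "WaypointGraph",
    "PathSet",
    "PathMetrics",
    "langer_field",
    "read_orientation_csv",
    "write_orientation_csv",
    "generate_unit_lines",
    "generate_grid_lines",
    "trim_to_contour",
    "naive_paths",
    "optimize_paths",
    "path_metrics",
    "write_paths_csv",
]

_EPS = 1e-6


# ---------------------------------------------------------------------------
# Orientation fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientationField:
    """Per-unit fiber orientation on an n-row by m-column grid.

    ``angles[iy, ix]`` is the line direction (degrees, reduced mod 180) of
    the unit whose lower-left corner is ``origin + unit_size * (ix, iy)``.
    """

    angles: np.ndarray
    unit_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float) % 180.0
        if a.ndim != 2 or min(a.shape) < 1:
            raise ValidationError("angles must be a 2-D grid with >= 1 unit")
        if self.unit_size <= 0:
            raise ValidationError("unit_size must be positive")
        object.__setattr__(self, "angles", a)

    @property
    def shape(self) -> tuple[int, int]:
        return self.angles.shape  # (n rows, m cols)

    def unit_rect(self, iy: int, ix: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the unit at row ``iy``, column ``ix``."""
        u = self.unit_size
        x0 = self.origin[0] + ix * u
        y0 = self.origin[1] + iy * u
        return (x0, y0, x0 + u, y0 + u)

    def unit_id(self, iy: int, ix: int) -> int:
        return iy * self.shape[1] + ix


def langer_field(
    n: int,
    m: int,
    mode: str = "random",
    seed: int | None = 0,
    *,
    unit_size: float = 5.0,
    origin: tuple[float, float] = (0.0, 0.0),
    angle: float = 0.0,
    amplitude: float = 20.0,
    period: float | None = None,
) -> OrientationField:
    """Synthetic orientation grids standing in for measured collagen maps.

    Modes
    -----
    ``constant``
        Every unit at ``angle`` degrees.
    ``random``
        Independent uniform angles in [0, 180); reproducible under ``seed``.
    ``langer_sine``
        A smooth, predominantly horizontal field reminiscent of dermal
        Langer lines: ``angle + amplitude * sin(2*pi*(ix + 0.5)/period)``
        sampled at unit centres (period defaults to the grid width ``m``).
    """
    if n < 1 or m < 1:
        raise ValidationError("grid dimensions must be >= 1")
    if mode == "constant":
        a = np.full((n, m), angle, dtype=float)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.0, 180.0, size=(n, m))
    elif mode == "langer_sine":
        p = float(period) if period is not None else float(m)
        ix = np.arange(m) + 0.5
        row = angle + amplitude * np.sin(2.0 * np.pi * ix / p)
        a = np.tile(row, (n, 1))
    else:
        raise ValidationError(f"unknown orientation mode {mode!r}")
    return OrientationField(angles=a, unit_size=unit_size, origin=origin)


def read_orientation_csv(
    path: str | Path, unit_size: float, origin: tuple[float, float] = (0.0, 0.0)
) -> OrientationField:
    """Read a headerless/headered CSV grid of angles in degrees."""
    df = pd.read_csv(path, header=None)
    arr = df.to_numpy()
    if isinstance(arr[0, 0], str):  # headered: skip first row
        arr = df.iloc[1:].to_numpy(dtype=float)
    return OrientationField(angles=arr.astype(float), unit_size=unit_size, origin=origin)


def write_orientation_csv(field_: OrientationField, path: str | Path) -> None:
    pd.DataFrame(field_.angles).to_csv(path, index=False, header=False)


# ---------------------------------------------------------------------------
# Waypoint graphs
# ---------------------------------------------------------------------------


@dataclass
class WaypointGraph:
    """Discretized print lines as an undirected traversal graph.

    Nodes are integers with attributes ``pos`` (x, y in mm) and ``unit``
    (grid-unit id).  Edges carry ``kind``: ``"line"`` for a printable
    segment inside one line, ``"junction"`` for a zero-length cross-border
    continuation created by endpoint snapping.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def pos(self, node: int) -> tuple[float, float]:
        return self.graph.nodes[node]["pos"]

    def positions(self) -> dict[int, tuple[float, float]]:
        return {n: d["pos"] for n, d in self.graph.nodes(data=True)}


@dataclass(frozen=True)
class PathSet:
    """A node-disjoint decomposition of a waypoint graph into paths."""

    paths: tuple[tuple[int, ...], ...]

    @classmethod
    def from_lists(cls, paths: Sequence[Sequence[int]]) -> "PathSet":
        return cls(paths=tuple(tuple(p) for p in paths))

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def n_waypoints(self) -> int:
        return sum(len(p) for p in self.paths)

    def validate(self, wg: WaypointGraph) -> None:
        """Check node-disjoint coverage and edge consistency; raise if violated."""
        seen: set[int] = set()
        for p in self.paths:
            for a, b in zip(p, p[1:]):
                if not wg.graph.has_edge(a, b):
                    raise ValidationError(f"path step {a}-{b} is not a graph edge")
            dup = seen.intersection(p)
            if dup or len(set(p)) != len(p):
                raise ValidationError("paths are not node-disjoint")
            seen.update(p)
        if seen != set(wg.graph.nodes):
            raise ValidationError("paths do not cover every waypoint exactly once")


@dataclass(frozen=True)
class PathMetrics:
    """Continuity metrics of a path decomposition."""

    n_paths: int
    waypoints_per_path: tuple[int, ...]
    naive_n_paths: int
    reduction_pct: float
    coverage_pct: float


# ---------------------------------------------------------------------------
# Line generation
# ---------------------------------------------------------------------------


def generate_unit_lines(
    rect: tuple[float, float, float, float],
    phi: float,
    spacing: float,
    shift: float = 0.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parallel segments at angle ``phi`` clipped to a rectangular unit.

    By default the family is anchored so one line passes through the unit
    centre and neighbouring lines sit at perpendicular distance ``spacing``;
    ``shift`` moves the whole family by that perpendicular offset (used to
    re-anchor a unit on a neighbour's border point).  Segments are returned
    in ascending offset order, each ``(p0, p1)`` ordered along the line
    direction ``(cos phi, sin phi)``.  A spacing larger than the unit
    diagonal yields a single line.
    """
    if spacing <= 0:
        raise ValidationError("line spacing must be positive")
    x0, y0, x1, y1 = rect
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    phi_r = np.deg2rad(phi % 180.0)
    u = np.array([np.cos(phi_r), np.sin(phi_r)])
    nrm = np.array([-u[1], u[0]])
    half_diag = 0.5 * np.hypot(x1 - x0, y1 - y0)
    kmax = int(np.floor((half_diag + abs(shift)) / spacing + 1e-9)) + 1
    unit_poly = box(x0, y0, x1, y1)
    L = 2.0 * half_diag + spacing  # long enough to cross the unit fully
    segments = []
    for k in range(-kmax, kmax + 1):
        c = np.array([cx, cy]) + (k * spacing + shift) * nrm
        line = LineString([c - L * u, c + L * u])
        clipped = line.intersection(unit_poly)
        if clipped.is_empty or clipped.length < _EPS:
            continue
        if clipped.geom_type == "MultiLineString":  # touching a corner
            clipped = max(clipped.geoms, key=lambda g: g.length)
        coords = np.asarray(clipped.coords)
        p0, p1 = coords[0], coords[-1]
        if np.dot(p1 - p0, u) < 0:
            p0, p1 = p1, p0
        segments.append((p0, p1))
    return segments


def _densify(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


@dataclass
class _Endpoint:
    node: int
    pos: np.ndarray
    matched: bool = False


def generate_grid_lines(
    field_: OrientationField,
    spacing: float,
    waypoint_spacing: float | None = None,
    *,
    waypoints_per_unit: int | None = None,
    snap_tol: float | None = None,
) -> WaypointGraph:
    """Generate per-unit print lines with cross-border continuity.

    Units are processed row-major from the lower-left, and endpoints that
    earlier units left on a shared border act as starting points for later
    ones: when such a point exists (and the unit's line direction is not
    parallel to that border) the new unit's line family is re-anchored — a
    perpendicular shift of at most half the line spacing — so one line
    passes through it exactly.  Each unit's family is clipped to the unit
    and densified into waypoints, either at ``waypoint_spacing`` along each
    line or distributing exactly ``waypoints_per_unit`` over the unit's
    lines (proportional to length, at least two per line).  Line endpoints
    on a shared border are then snapped to the neighbour's nearest
    unmatched endpoint (within ``snap_tol``, default half the line spacing)
    and joined to it by a zero-length junction edge; unequal line counts
    simply leave the surplus endpoints unmatched at degree 1.
    """
    if (waypoint_spacing is None) == (waypoints_per_unit is None):
        raise ValidationError("give exactly one of waypoint_spacing / waypoints_per_unit")
    if waypoint_spacing is not None and waypoint_spacing <= 0:
        raise ValidationError("waypoint_spacing must be positive")
    tol = 0.5 * spacing if snap_tol is None else float(snap_tol)

    wg = WaypointGraph()
    G = wg.graph
    ny, nx_ = field_.shape
    next_id = 0
    # endpoints[(iy, ix)] = {"L"/"R"/"B"/"T": [_Endpoint, ...]}
    endpoints: dict[tuple[int, int], dict[str, list[_Endpoint]]] = {}

    for iy in range(ny):
        for ix in range(nx_):
            rect = field_.unit_rect(iy, ix)
            x0, y0, x1, y1 = rect
            uid = field_.unit_id(iy, ix)
            phi = float(field_.angles[iy, ix])
            phi_r = np.deg2rad(phi)
            u = np.array([np.cos(phi_r), np.sin(phi_r)])
            nrm = np.array([-u[1], u[0]])
            centre = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
            # re-anchor on the first continuation point a processed
            # neighbour offers on a shared border the lines can cross
            shift = 0.0
            for (niy, nix), nb_side, border_normal in (
                ((iy, ix - 1), "R", np.array([1.0, 0.0])),
                ((iy - 1, ix), "T", np.array([0.0, 1.0])),
            ):
                if (niy, nix) not in endpoints:
                    continue
                # continue only across a border the family dominantly
                # crosses (within 45 degrees of its normal): a grazing
                # continuation would kink the filament instead of smoothly
                # extending the neighbour's line
                if abs(float(u @ border_normal)) < np.sqrt(0.5) - _EPS:
                    continue
                cands = [e for e in endpoints[(niy, nix)][nb_side] if not e.matched]
                if not cands:
                    continue
                anchor = min(cands, key=lambda e: e.node)
                t = float((anchor.pos - centre) @ nrm)
                shift = (t + spacing / 2.0) % spacing - spacing / 2.0
                break
            segs = generate_unit_lines(rect, phi, spacing, shift=shift)
            lengths = np.array([np.linalg.norm(p1 - p0) for p0, p1 in segs])
            if waypoints_per_unit is not None:
                if waypoints_per_unit < 2 * len(segs):
                    raise ValidationError(
                        f"waypoints_per_unit={waypoints_per_unit} cannot give every "
                        f"one of {len(segs)} lines its two endpoints"
                    )
                counts = _allocate(lengths, waypoints_per_unit)
            else:
                counts = [max(2, int(round(l / waypoint_spacing)) + 1) for l in lengths]

            unit_eps: dict[str, list[_Endpoint]] = {"L": [], "R": [], "B": [], "T": []}
            for (p0, p1), npts in zip(segs, counts):
                pts = _densify(p0, p1, npts)
                ids = list(range(next_id, next_id + npts))
                next_id += npts
                for nid, p in zip(ids, pts):
                    G.add_node(nid, pos=(float(p[0]), float(p[1])), unit=uid)
                for a, b in zip(ids, ids[1:]):
                    G.add_edge(a, b, kind="line")
                for nid, p in ((ids[0], pts[0]), (ids[-1], pts[-1])):
                    for side, onit in (
                        ("L", abs(p[0] - x0) < _EPS), ("R", abs(p[0] - x1) < _EPS),
                        ("B", abs(p[1] - y0) < _EPS), ("T", abs(p[1] - y1) < _EPS),
                    ):
                        if onit:
                            unit_eps[side].append(_Endpoint(node=nid, pos=np.asarray(p)))
            endpoints[(iy, ix)] = unit_eps

            # snap to already-generated neighbours: left and below
            for (niy, nix), my_side, nb_side in (
                ((iy, ix - 1), "L", "R"),
                ((iy - 1, ix), "B", "T"),
            ):
                if (niy, nix) not in endpoints:
                    continue
                mine = [e for e in unit_eps[my_side] if not e.matched]
                theirs = [e for e in endpoints[(niy, nix)][nb_side] if not e.matched]
                pairs = sorted(
                    ((float(np.linalg.norm(a.pos - b.pos)), a.node, b.node, a, b)
                     for a in mine for b in theirs),
                    key=lambda t: (t[0], t[1], t[2]),
                )
                for dist, _, _, a, b in pairs:
                    if dist > tol or a.matched or b.matched:
                        continue
                    a.matched = b.matched = True
                    G.nodes[a.node]["pos"] = G.nodes[b.node]["pos"]  # snap
                    a.pos = np.asarray(G.nodes[b.node]["pos"])
                    G.add_edge(a.node, b.node, kind="junction")
    return wg


def _allocate(lengths: np.ndarray, total: int) -> list[int]:
    """Distribute ``total`` waypoints over lines, proportional to length, >= 2 each."""
    n = len(lengths)
    if n == 0:
        return []
    base = np.full(n, 2, dtype=int)
    extra = total - 2 * n
    if extra > 0 and lengths.sum() > 0:
        quota = extra * lengths / lengths.sum()
        add = np.floor(quota).astype(int)
        rem = extra - add.sum()
        order = np.argsort(-(quota - add), kind="stable")
        add[order[:rem]] += 1
        base += add
    return base.tolist()


# ---------------------------------------------------------------------------
# Contour trimming
# ---------------------------------------------------------------------------


def trim_to_contour(wg: WaypointGraph, contour: Polygon) -> WaypointGraph:
    """Remove waypoints strictly outside a layer contour.

    Nodes on or inside the contour survive; an edge from a surviving node to
    a removed one is clipped at the boundary, inserting a new boundary node
    that inherits the surviving node's unit id.  Junction edges to removed
    nodes are simply dropped (nothing to extrude across the border there).
    """
    if not contour.is_valid or contour.is_empty:
        raise ValidationError("contour must be a non-empty simple polygon")
    G = wg.graph
    out = nx.Graph()
    inside = {n: contour.covers(Point(d["pos"])) for n, d in G.nodes(data=True)}
    for n, d in G.nodes(data=True):
        if inside[n]:
            out.add_node(n, **d)
    next_id = (max(G.nodes) + 1) if G.number_of_nodes() else 0
    for a, b, d in G.edges(data=True):
        if inside[a] and inside[b]:
            out.add_edge(a, b, **d)
        elif inside[a] != inside[b] and d.get("kind") == "line":
            keep, drop = (a, b) if inside[a] else (b, a)
            seg = LineString([G.nodes[keep]["pos"], G.nodes[drop]["pos"]])
            hit = seg.intersection(contour.exterior)
            if hit.is_empty:
                continue
            if hit.geom_type != "Point":
                hit = min(
                    (g for g in getattr(hit, "geoms", [hit])),
                    key=lambda g: Point(G.nodes[keep]["pos"]).distance(g),
                )
            if Point(G.nodes[keep]["pos"]).distance(hit) < _EPS:
                continue  # the kept node already sits on the boundary
            out.add_node(next_id, pos=(hit.x, hit.y), unit=G.nodes[keep]["unit"])
            out.add_edge(keep, next_id, **d)
            next_id += 1
    return WaypointGraph(graph=out)


# ---------------------------------------------------------------------------
# Path decomposition
# ---------------------------------------------------------------------------


def naive_paths(wg: WaypointGraph) -> PathSet:
    """Per-unit traversal baseline: every print line is its own path.

    Junction edges are ignored, so each connected run of line edges (one
    print line, or the surviving piece of one after trimming) becomes a
    separate path — the stop-start-heavy decomposition an unoptimized
    printer would execute.
    """
    G = wg.graph
    sub = nx.Graph()
    sub.add_nodes_from(G.nodes)
    sub.add_edges_from((a, b) for a, b, d in G.edges(data=True) if d.get("kind") == "line")
    paths = []
    for comp in sorted(nx.connected_components(sub), key=min):
        paths.append(_traverse_chain(sub, comp))
    return PathSet.from_lists(paths)


def _traverse_chain(G: nx.Graph, comp: set[int]) -> list[int]:
    """Deterministically linearize a component whose degrees are all <= 2."""
    ends = sorted(n for n in comp if G.degree(n) <= 1)
    start = ends[0] if ends else min(comp)  # cycle: break at smallest id
    path, visited, cur = [start], {start}, start
    while len(path) < len(comp):
        nxt = [n for n in G[cur] if n not in visited]
        if not nxt:
            break
        cur = min(nxt)
        path.append(cur)
        visited.add(cur)
    return path


def _longest_branch(G: nx.Graph, start: int, allowed: set[int]) -> list[int]:
    """Longest simple path from ``start`` through ``allowed`` nodes (DFS).

    Implemented with an explicit stack so arbitrarily long chains do not hit
    the interpreter recursion limit.  Ties resolve to the first branch found
    in sorted-neighbour order.
    """
    best: list[int] = [start]
    stack: list[tuple[list[int], set[int]]] = [([start], {start})]
    while stack:
        path, onpath = stack.pop()
        nbrs = [n for n in sorted(G[path[-1]], reverse=True) if n in allowed and n not in onpath]
        if not nbrs:
            if len(path) > len(best):
                best = path
            continue
        for n in nbrs:  # reversed sort + LIFO -> ascending exploration order
            stack.append((path + [n], onpath | {n}))
    return best


def _grow(G: nx.Graph, path: list[int], onpath: set[int], remaining: set[int]) -> None:
    """Extend ``path`` forward from its last node until it can grow no more."""
    while True:
        cur = path[-1]
        cands = [n for n in sorted(G[cur]) if n in remaining and n not in onpath]
        if not cands:
            return
        if len(cands) == 1:
            path.append(cands[0])
            onpath.add(cands[0])
            continue
        # branch point: explore each continuation depth-first, keep the longest
        allowed = remaining - onpath
        branches = [_longest_branch(G, c, allowed) for c in cands]
        best = max(branches, key=len)  # first-found on ties (stable max)
        path.extend(best)
        onpath.update(best)
        return


def _decompose_once(G: nx.Graph, rng: np.random.Generator) -> list[list[int]]:
    remaining = set(G.nodes)
    pool = sorted(remaining)
    paths: list[list[int]] = []
    while remaining:
        pool = [n for n in pool if n in remaining]
        seed_node = pool[int(rng.integers(len(pool)))]
        path = [seed_node]
        onpath = {seed_node}
        _grow(G, path, onpath, remaining)  # forward from the seed
        path.reverse()
        _grow(G, path, onpath, remaining)  # then in the reverse direction
        remaining.difference_update(onpath)
        paths.append(path)
    return paths


def _n_reversals(G: nx.Graph, paths: list[list[int]]) -> int:
    """Direction reversals: consecutive segment pairs turning by > 90 degrees."""
    total = 0
    for p in paths:
        if len(p) < 3:
            continue
        pts = np.array([G.nodes[n]["pos"] for n in p])
        v = np.diff(pts, axis=0)
        keep = np.linalg.norm(v, axis=1) > _EPS  # zero-length junction hops
        v = v[keep]
        if len(v) >= 2:
            total += int(np.sum(np.einsum("ij,ij->i", v[:-1], v[1:]) < 0))
    return total


def optimize_paths(wg: WaypointGraph, restarts: int = 100, seed: int = 0) -> PathSet:
    """Minimize the number of distinct extrusion paths by randomized DFS.

    Each restart draws random seed waypoints from the untraversed pool,
    grows the longest continuous path through each (forward, then reverse,
    choosing the longest branch at branch points by depth-first search),
    and retires traversed waypoints until the pool is empty.  Across
    restarts the decomposition with the fewest paths is kept; ties break by
    fewest direction reversals, then first found.  Fully deterministic for
    a given ``(graph, restarts, seed)``: restart ``r`` uses the child
    generator ``default_rng([seed, r])``, so the best-so-far result is a
    prefix-monotone function of ``restarts``.
    """
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    G = wg.graph
    if G.number_of_nodes() == 0:
        return PathSet.from_lists([])
    best: list[list[int]] | None = None
    best_key = (np.inf, np.inf)
    for r in range(restarts):
        rng = np.random.default_rng([int(seed), r])
        paths = _decompose_once(G, rng)
        key = (len(paths), _n_reversals(G, paths))
        if key < best_key:
            best, best_key = paths, key
    return PathSet.from_lists(best)


def path_metrics(
    paths: PathSet, wg: WaypointGraph, baseline_unit_waypoints: int = 10
) -> PathMetrics:
    """Continuity metrics of a decomposition against the per-line baseline.

    ``coverage_pct`` is the share of waypoints lying in paths strictly
    longer than ``baseline_unit_waypoints`` — an operational stand-in for
    "printing area traversed by merged, more continuous toolpaths".
    """
    paths.validate(wg)
    naive = naive_paths(wg)
    lens = tuple(len(p) for p in paths.paths)
    n_total = sum(lens)
    merged = sum(l for l in lens if l > baseline_unit_waypoints)
    reduction = 100.0 * (1.0 - paths.n_paths / naive.n_paths) if naive.n_paths else 0.0
    coverage = 100.0 * merged / n_total if n_total else 0.0
    return PathMetrics(
        n_paths=paths.n_paths,
        waypoints_per_path=lens,
        naive_n_paths=naive.n_paths,
        reduction_pct=reduction,
        coverage_pct=coverage,
    )


def write_paths_csv(paths: PathSet, wg: WaypointGraph, path: str | Path) -> None:
    """Export a decomposition as CSV rows (path_id, order, x, y)."""
    rows = []
    for pid, p in enumerate(paths.paths):
        for k, n in enumerate(p):
            x, y = wg.pos(n)
            rows.append((pid, k, x, y))
    pd.DataFrame(rows, columns=["path_id", "order", "x", "y"]).to_csv(path, index=False)
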
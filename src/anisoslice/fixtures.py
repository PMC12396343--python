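"""Synthetic inputs for every stage of the pipeline.

None of the physical inputs this package consumes — surface scans of a
printing substrate, collagen orientation maps, tensile test records,
spanning-width micrographs — ship with it, so each has a seeded generator
here producing data of the right shape and scale: a hyperbolic-paraboloid
shell like the cricothyrotomy training puck, inclined planes, orientation
grids, stress-strain curves and spanning-width tables, plus the toolpath
continuity benchmark harness.  All generators are deterministic under their
seed, and every output passes the validators of the module that consumes it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .toolpath import (
    OrientationField,
    generate_grid_lines,
    langer_field,
    naive_paths,
    optimize_paths,
    path_metrics,
)
from .voxel import StressStrainCurve, ValidationError

__all__ = [
    "make_paraboloid",
    "make_incline",
    "make_stress_strain",
    "make_spanning_table",
    "benchmark_graph",
    "make_benchmark_suite",
]

# Puck-like footprint: the training pucks this package models are ~40x40 mm.
DEFAULT_EXTENT = 40.0
DEFAULT_CURVATURE = 0.01  # 1/mm; gives ~4 mm of relief over a 40 mm footprint


def _grid_mesh(extent: float, resolution: int, zfun) -> trimesh.Trimesh:
    if resolution < 2:
        raise ValidationError("resolution must be >= 2")
    half = extent / 2.0
    g = np.linspace(-half, half, resolution)
    X, Y = np.meshgrid(g, g)
    Z = zfun(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    n = resolution
    for iy in range(n - 1):
        for ix in range(n - 1):
            a = iy * n + ix
            b, c, d = a + 1, a + n, a + n + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    # orient all faces with upward normals (outward for an open top shell)
    fn = mesh.face_normals
    flip = fn[:, 2] < 0
    f = mesh.faces.copy()
    f[flip] = f[flip][:, ::-1]
    mesh = trimesh.Trimesh(vertices=verts, faces=f, process=False)
    return mesh


def make_paraboloid(
    extent: float = DEFAULT_EXTENT,
    curvature: float = DEFAULT_CURVATURE,
    resolution: int = 41,
) -> trimesh.Trimesh:
    """Hyperbolic-paraboloid shell z = c (x^2 - y^2), triangulated on a grid.

    A ``resolution x resolution`` vertex grid gives ``resolution**2``
    vertices and ``2 (resolution-1)^2`` triangles; every vertex lies exactly
    on the analytic surface.  ``curvature=0`` degenerates to a flat plate.
    """
    return _grid_mesh(extent, resolution, lambda X, Y: curvature * (X**2 - Y**2))


def make_incline(
    alpha: float = 30.0, extent: float = DEFAULT_EXTENT, resolution: int = 21
) -> trimesh.Trimesh:
    """A plane tilted ``alpha`` degrees about Y: dz/dx = tan(alpha) exactly."""
    if not 0 <= alpha < 90:
        raise ValidationError("alpha must be in [0, 90)")
    slope = np.tan(np.deg2rad(alpha))
    return _grid_mesh(extent, resolution, lambda X, Y: slope * X)


def make_stress_strain(
    E: float = 100.0,
    model: str = "linear",
    noise_sd: float = 0.0,
    n: int = 100,
    seed: int = 0,
    max_strain: float = 0.4,
) -> StressStrainCurve:
    """Synthetic tensile record with tangent modulus ``E`` (kPa) at the origin.

    ``linear``: sigma = E*eps.  ``quadratic``: sigma = E*eps + 3*E*eps^2, a
    mildly stiffening response whose tangent at strain eps is E*(1 + 6*eps).
    Additive zero-mean Gaussian noise with SD ``noise_sd`` (kPa) when set.
    """
    eps = np.linspace(0.0, max_strain, n)
    if model == "linear":
        sigma = E * eps
    elif model == "quadratic":
        sigma = E * eps + 3.0 * E * eps**2
    else:
        raise ValidationError(f"unknown stress-strain model {model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_sd, size=sigma.shape)
        sigma[0] = 0.0  # record starts at rest
    return StressStrainCurve(strain=eps, stress=sigma)


def make_spanning_table(
    true_coeffs: tuple[float, ...] = (0.55, 0.55, -0.25, -0.15, 0.05, -0.10),
    noise_sd: float = 0.0,
    n: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic spanning-width measurements on a (h/d, s/d) design.

    Samples ``w_rel = quadratic(h/d, s/d) + noise`` over the practically
    relevant window h/d in [0.25, 1.0], s/d in [0.1, 0.8].  The default
    coefficients mimic the observed behaviour: narrowing that worsens as
    print height drops and spacing grows.
    """
    rng = np.random.default_rng(seed)
    if n < 6:
        raise ValidationError("need at least 6 samples")
    x = rng.uniform(0.25, 1.0, size=n)
    y = rng.uniform(0.1, 0.8, size=n)
    c = true_coeffs
    w = c[0] + c[1] * x + c[2] * y + c[3] * x * x + c[4] * x * y + c[5] * y * y
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"h_over_d": x, "s_over_d": y, "w_rel": np.clip(w, 0.0, 1.0)})


# ---------------------------------------------------------------------------
# Toolpath continuity benchmark
# ---------------------------------------------------------------------------

# Each grid unit hosts a single centre-anchored line at its local orientation,
# discretized to 10 waypoints — the per-unit resolution of the benchmark.
BENCHMARK_UNIT = 5.0  # mm
BENCHMARK_SPACING = 1.5 * BENCHMARK_UNIT  # > unit diagonal -> one line per unit
BENCHMARK_WAYPOINTS = 10


def benchmark_graph(size: int, seed: int, waypoints_per_unit: int = BENCHMARK_WAYPOINTS):
    """Random-orientation ``size x size`` benchmark graph (one line per unit)."""
    fld = langer_field(size, size, "random", seed=seed, unit_size=BENCHMARK_UNIT)
    return generate_grid_lines(
        fld, spacing=BENCHMARK_SPACING, waypoints_per_unit=waypoints_per_unit
    )


def make_benchmark_suite(
    grid_sizes: tuple[int, ...] = tuple(range(4, 13)),
    reps: int = 5,
    seed: int = 0,
    restarts: int = 100,
) -> pd.DataFrame:
    """Continuity-optimization benchmark over grid sizes and replicate seeds.

    For each size and replicate: draw a uniformly random orientation field,
    build the waypoint graph at 10 waypoints per unit, decompose it naively
    (one path per print line) and with the randomized DFS optimizer, and
    record the path counts and continuity metrics.  Fully seeded — the
    replicate ``r`` of size ``s`` derives its field and optimizer seeds from
    ``(seed, s, r)`` — so the same call reproduces the same table.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rows = []
    for size in grid_sizes:
        for r in range(reps):
            field_seed = [int(seed), int(size), r, 0]
            opt_seed = int(np.random.default_rng([int(seed), int(size), r, 1]).integers(2**31))
            fld = langer_field(size, size, "random", seed=field_seed, unit_size=BENCHMARK_UNIT)
            wg = generate_grid_lines(
                fld, spacing=BENCHMARK_SPACING, waypoints_per_unit=BENCHMARK_WAYPOINTS
            )
            ps = optimize_paths(wg, restarts=restarts, seed=opt_seed)
            m = path_metrics(ps, wg, BENCHMARK_WAYPOINTS)
            rows.append(
                {
                    "size": size,
                    "rep": r,
                    "n_units": size * size,
                    "n_waypoints": wg.n_nodes,
                    "naive_n_paths": m.naive_n_paths,
                    "optimized_n_paths": m.n_paths,
                    "reduction_pct": m.reduction_pct,
                    "coverage_pct": m.coverage_pct,
                }
            )
    return pd.DataFrame(rows)
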
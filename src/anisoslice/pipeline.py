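"""End-to-end planning: from mesh + orientation field to machine commands.

``plan_print`` composes the whole chain: reorient the model for minimal
build height, segment off the bottom surface, turn it into a height-field
template, stack conformal layers, fill each layer with orientation-aligned
print lines (successive infill layers rotated 90 degrees to build the
orthogonal voxel lattice), trim to the layer contour, minimize stop-start
events with the DFS optimizer, project onto the layer surface, and convert
the local gradient into nozzle-height and flow commands.

The output is a :class:`MachineProgram` — an ordered list of motion
commands with feed and volumetric flow — writable either as a generic
G-code dialect (E carries cumulative extruded volume in mm^3, F is mm/min)
or as a headered command CSV.  Both dialects round-trip through the
provided readers at six-decimal precision.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from . import geometry as geo
from . import toolpath as tp
from .voxel import ValidationError, VoxelSpec

__all__ = [
    "Command",
    "MachineProgram",
    "PlanOptions",
    "PlanError",
    "cric_layer_plan",
    "plan_print",
    "write_gcode",
    "read_gcode",
    "total_extruded_volume",
]

logger = logging.getLogger("anisoslice")

# Printing defaults: constant-speed direct ink writing with an 18-GA nozzle.
DEFAULT_SPEED = 16.667  # mm/s
DEFAULT_NOZZLE_D = 0.84  # mm (18 GA inner diameter)


@dataclass(frozen=True)
class Command:
    """One machine command: a move to (x, y, z) at ``feed``, extruding or not.

    ``flow`` is the volumetric extrusion rate in mm^3/s, positive only when
    ``extrude`` is on.  ``ink`` names the material section the move belongs
    to (e.g. structural vs sacrificial).
    """

    x: float
    y: float
    z: float
    feed: float  # mm/s
    flow: float  # mm^3/s
    extrude: bool
    ink: str = "structural"

    def __post_init__(self):
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValidationError("command position must be finite")
        if self.feed <= 0:
            raise ValidationError("feed must be positive")
        if self.flow < 0 or (self.flow > 0 and not self.extrude):
            raise ValidationError("flow must be >= 0 and only positive while extruding")


@dataclass(frozen=True)
class MachineProgram:
    """An ordered command list plus header metadata (units, nozzle, inks)."""

    commands: tuple[Command, ...]
    header: dict

    @property
    def n_commands(self) -> int:
        return len(self.commands)


class PlanError(RuntimeError):
    """A pipeline stage failed; carries the stage name and layer index."""

    def __init__(self, stage: str, layer: int | None, original: Exception):
        self.stage, self.layer, self.original = stage, layer, original
        where = f"stage {stage!r}" + ("" if layer is None else f", layer {layer}")
        super().__init__(f"{where}: {original}")


@dataclass(frozen=True)
class PlanOptions:
    """Tunable parameters of the planning pipeline (mm, mm/s, degrees)."""

    speed: float = DEFAULT_SPEED
    travel_speed: float = 50.0
    travel_clearance: float = 2.0  # nozzle lift between paths, mm
    grid_spacing: float = 0.5  # height-field resolution, mm
    waypoint_spacing: float = 1.0  # densification along print lines, mm
    restarts: int = 100
    seed: int = 0
    reorient: bool = True
    align_field: bool = True  # move the field origin to the footprint corner
    cover_angle: float = 0.0  # line direction of the first cover layer
    inks: tuple[tuple[str, str], ...] = (
        ("bottom_cover", "structural"),
        ("infill", "structural"),
        ("top_cover", "structural"),
        ("sacrificial", "sacrificial"),
    )


def cric_layer_plan(
    voxel: VoxelSpec, n_infill: int = 6, cover: float = 0.6
) -> list[tuple[str, float]]:
    """The standard skin-section stack: full-infill covers around an
    anisotropic lattice — ``cover`` mm top and bottom (600 um by default)
    with ``n_infill`` alternating infill layers at heights h1/h2 between.
    """
    plan = [("bottom_cover", cover)]
    for k in range(n_infill):
        plan.append(("infill", voxel.h1 if k % 2 == 0 else voxel.h2))
    plan.append(("top_cover", cover))
    return plan


def _stage(stage: str, layer: int | None = None):
    """Context that rewraps exceptions with pipeline stage/layer info."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s%s done in %.3f s", stage,
                            "" if layer is None else f"[layer {layer}]", dt)
                return False
            raise PlanError(stage, layer, exc) from exc
    return _Ctx()


def plan_print(
    mesh: trimesh.Trimesh,
    fld: tp.OrientationField,
    voxel: VoxelSpec,
    layer_plan: Sequence[tuple[str, float]] | None = None,
    options: PlanOptions = PlanOptions(),
) -> MachineProgram:
    """Plan a complete conformal anisotropic print of ``mesh``.

    Infill layers alternate between the two voxel line families: even
    infill layers run at the local field orientation with pitch ``L2``,
    odd ones rotated 90 degrees with pitch ``L1``, building the orthogonal
    lattice.  Cover and sacrificial layers are filled solid (pitch equal to
    the nozzle diameter) at alternating 0/90-degree directions.  Identical
    inputs and seed yield a byte-identical program.
    """
    if layer_plan is None:
        layer_plan = cric_layer_plan(voxel)
    inks = dict(options.inks)
    d = voxel.w1  # line width == nozzle inner diameter by flow control

    with _stage("reorient"):
        if options.reorient:
            mesh, _rot = geo.reorient_min_height(mesh)

    with _stage("split"):
        split = geo.split_top_bottom(mesh)
        idx = split.bottom_vertices
        if len(idx) < 3:  # open shells facing up have no downward normals
            idx = np.arange(len(mesh.vertices))
        pts = np.asarray(mesh.vertices)[idx]

    with _stage("heightfield"):
        base = geo.heightfield_from_points(pts, spacing=options.grid_spacing)

    with _stage("layers"):
        layers = geo.conformal_layers(base, list(layer_plan))

    if options.align_field:
        V = np.asarray(mesh.vertices)
        fld = replace(fld, origin=(float(V[:, 0].min()), float(V[:, 1].min())))
        ny, nx = fld.shape
        span = max(V[:, 0].max() - V[:, 0].min(), V[:, 1].max() - V[:, 1].min())
        if min(ny, nx) * fld.unit_size < span - 1e-9:
            raise PlanError("field", None, ValidationError(
                f"orientation grid ({ny}x{nx} units of {fld.unit_size} mm) "
                f"does not cover the {span:.1f} mm footprint"))

    commands: list[Command] = []
    n_infill_seen = 0
    for layer in layers:
        k = layer.index
        ink = inks.get(layer.role, "structural")
        with _stage("contour", k):
            # the plan defines the stack height; the mesh supplies template
            # and outline, so every planned layer shares the XY footprint
            polys = geo.mesh_footprint(mesh)
            if not polys:
                continue
            contour = max(polys, key=lambda p: p.area)

        with _stage("lines", k):
            if layer.role == "infill":
                rot = 90.0 * (n_infill_seen % 2)
                pitch = voxel.L2 if n_infill_seen % 2 == 0 else voxel.L1
                layer_field = replace(fld, angles=(fld.angles + rot) % 180.0)
                n_infill_seen += 1
            else:
                rot = options.cover_angle + 90.0 * (k % 2)
                pitch = d  # solid fill: adjacent lines touch
                layer_field = tp.OrientationField(
                    angles=np.full(fld.shape, rot % 180.0),
                    unit_size=fld.unit_size, origin=fld.origin,
                )
            wg = tp.generate_grid_lines(
                layer_field, spacing=pitch, waypoint_spacing=options.waypoint_spacing
            )

        with _stage("trim", k):
            wg = tp.trim_to_contour(wg, contour)
            if wg.n_nodes == 0:
                continue

        with _stage("optimize", k):
            paths = tp.optimize_paths(wg, restarts=options.restarts,
                                      seed=options.seed + k)

        with _stage("emit", k):
            substrate_offset = layer.offset - layer.thickness
            for p in paths.paths:
                xy = np.array([wg.pos(n) for n in p])
                # drop zero-length junction hops for motion purposes
                keep = np.ones(len(xy), dtype=bool)
                keep[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) > 1e-9
                xy = xy[keep]
                if len(xy) < 2:
                    continue
                p3 = geo.project_to_surface(xy, layer)
                alpha, sense = geo.path_gradient(p3)
                zs = []
                flows = []
                for a, sn in zip(alpha, sense):
                    h = geo.adjust_nozzle_height(geo.DepositionParams(
                        h0=layer.thickness, d=d, alpha=float(min(a, 89.9)),
                        travel_sense=str(sn), speed=options.speed))
                    zs.append(h)
                    flows.append(geo.flow_rate(options.speed, d, h))
                z_cmd = layer.base.sample(p3[:, 0], p3[:, 1]) + substrate_offset + np.array(zs)
                commands.append(Command(
                    x=float(p3[0, 0]), y=float(p3[0, 1]),
                    z=float(z_cmd[0] + options.travel_clearance),
                    feed=options.travel_speed, flow=0.0, extrude=False, ink=ink))
                commands.append(Command(
                    x=float(p3[0, 0]), y=float(p3[0, 1]), z=float(z_cmd[0]),
                    feed=options.travel_speed, flow=0.0, extrude=False, ink=ink))
                for i in range(1, len(p3)):
                    commands.append(Command(
                        x=float(p3[i, 0]), y=float(p3[i, 1]), z=float(z_cmd[i]),
                        feed=options.speed, flow=float(flows[i]),
                        extrude=True, ink=ink))

    header = {
        "units": "mm, mm/s, mm^3/s",
        "nozzle_d": d,
        "speed": options.speed,
        "n_layers": len(layers),
        "inks": sorted({c.ink for c in commands}) or ["structural"],
    }
    return MachineProgram(commands=tuple(commands), header=header)


# ---------------------------------------------------------------------------
# Program accounting and I/O
# ---------------------------------------------------------------------------


def total_extruded_volume(program: MachineProgram) -> float:
    """Replay the program kinematically: sum flow * segment_time, mm^3."""
    total = 0.0
    prev = None
    for c in program.commands:
        if prev is not None and c.extrude:
            dist = float(np.linalg.norm(
                [c.x - prev.x, c.y - prev.y, c.z - prev.z]))
            total += c.flow * dist / c.feed
        prev = c
    return total


def write_gcode(
    program: MachineProgram, path: str | Path, dialect: str = "generic_gcode"
) -> None:
    """Write a program as generic G-code or as a headered command CSV.

    G-code: ``G0`` travels, ``G1`` extruding moves with ``E`` the cumulative
    extruded volume (mm^3) and ``F`` in mm/min; each ``G1`` carries the
    volumetric rate as a ``;Q=`` comment so the reader recovers the flow
    without re-deriving it from rounded E deltas.  All numerics at six
    decimals.
    """
    path = Path(path)
    if dialect == "command_csv":
        rows = [
            {"x": round(c.x, 6), "y": round(c.y, 6), "z": round(c.z, 6),
             "feed": round(c.feed, 6), "flow": round(c.flow, 6),
             "extrude": int(c.extrude), "ink": c.ink}
            for c in program.commands
        ]
        df = pd.DataFrame(rows, columns=["x", "y", "z", "feed", "flow", "extrude", "ink"])
        with path.open("w") as fh:
            fh.write(f"# anisoslice command_csv; {program.header}\n")
            df.to_csv(fh, index=False, float_format="%.6f")
        return
    if dialect != "generic_gcode":
        raise ValidationError(f"unknown dialect {dialect!r}")
    lines = [
        "; anisoslice generic_gcode",
        f"; units: mm; F: mm/min; E: cumulative extruded volume, mm^3",
        f"; nozzle_d: {program.header.get('nozzle_d', '')}",
    ]
    e = 0.0
    prev = None
    current_ink = None
    for c in program.commands:
        if c.ink != current_ink:
            lines.append(f"; ink: {c.ink}")
            current_ink = c.ink
        if c.extrude and prev is not None:
            dist = float(np.linalg.norm([c.x - prev.x, c.y - prev.y, c.z - prev.z]))
            e += c.flow * dist / c.feed
            lines.append(
                f"G1 X{c.x:.6f} Y{c.y:.6f} Z{c.z:.6f} "
                f"E{e:.6f} F{c.feed * 60.0:.6f} ;Q={c.flow:.6f}"
            )
        else:
            lines.append(f"G0 X{c.x:.6f} Y{c.y:.6f} Z{c.z:.6f} F{c.feed * 60.0:.6f}")
        prev = c
    path.write_text("\n".join(lines) + "\n")


def read_gcode(path: str | Path, dialect: str = "generic_gcode") -> MachineProgram:
    """Read back a program written by :func:`write_gcode`."""
    path = Path(path)
    if dialect == "command_csv":
        df = pd.read_csv(path, comment="#")
        cmds = [
            Command(x=r.x, y=r.y, z=r.z, feed=r.feed, flow=r.flow,
                    extrude=bool(r.extrude), ink=str(r.ink))
            for r in df.itertuples()
        ]
        return MachineProgram(commands=tuple(cmds), header={"units": "mm, mm/s, mm^3/s"})
    if dialect != "generic_gcode":
        raise ValidationError(f"unknown dialect {dialect!r}")
    cmds = []
    ink = "structural"
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("; ink:"):
            ink = line.split(":", 1)[1].strip()
            continue
        if not line or line.startswith(";"):
            continue
        head, _, comment = line.partition(";")
        fields = dict(
            (tok[0], float(tok[1:])) for tok in head.split()[1:] if tok
        )
        extrude = head.startswith("G1")
        flow = 0.0
        if extrude and comment.startswith("Q="):
            flow = float(comment[2:])
        cmds.append(Command(
            x=fields["X"], y=fields["Y"], z=fields["Z"],
            feed=fields["F"] / 60.0, flow=flow, extrude=extrude, ink=ink))
    return MachineProgram(commands=tuple(cmds), header={"units": "mm, mm/s, mm^3/s"})
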
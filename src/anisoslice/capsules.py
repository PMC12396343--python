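"""Payload planning for embedded fluid-filled capsules.

Simulated body fluids (blood, pus, serous fluid) are stored inside printed
tissue simulants as water-oil-water double-emulsion capsules suspended in a
sacrificial carrier gel.  This module does the bookkeeping around that step:
spherical capsule volume from the mean radius, how many capsules realize a
target volumetric loading of the suspension, and capsule diameter extraction
from plate-compression traces.

Units: capsule radii in micrometres, volumes in microlitres, compression
gaps in millimetres, forces in newtons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .voxel import ValidationError

__all__ = [
    "CapsuleSpec",
    "capsule_volume",
    "loading_plan",
    "contact_diameter",
    "read_compression_csv",
    "plan_to_json",
]


@dataclass(frozen=True)
class CapsuleSpec:
    """A spherical capsule: radius in micrometres, volume in microlitres."""

    rc: float

    def __post_init__(self):
        if self.rc <= 0:
            raise ValidationError("capsule radius must be positive")

    @property
    def vc(self) -> float:
        return capsule_volume(self.rc)


def capsule_volume(rc: float) -> float:
    """Volume of a spherical capsule, vc = (4/3) pi rc^3, in microlitres.

    ``rc`` is in micrometres; 1 ul = 1e9 um^3.  The value is exact —
    rounding (e.g. to the 3 significant figures customarily reported) is
    left to display code.
    """
    if rc <= 0:
        raise ValidationError("capsule radius must be positive")
    return (4.0 / 3.0) * math.pi * rc**3 * 1e-9


def loading_plan(
    carrier_volume: float,
    fraction_vv: float,
    rc: float,
    *,
    convention: str = "gel",
) -> tuple[int, float]:
    """Capsule count and total capsule volume for a target v/v loading.

    With the default ``"gel"`` convention ``carrier_volume`` (ul) is the
    carrier-gel portion only — capsules are loaded on top of the solidified
    gel — so the capsule volume is ``carrier * f / (1 - f)`` and the implied
    suspension volume is ``carrier / (1 - f)``.  With ``"suspension"`` the
    given volume is the final suspension and the capsule volume is simply
    ``f * carrier_volume``.  Returns ``(n_capsules, capsule_total_volume)``
    with ``n_capsules = floor(capsule_volume / vc)``.
    """
    if not 0 <= fraction_vv < 1:
        raise ValidationError("fraction_vv must lie in [0, 1)")
    if carrier_volume <= 0:
        raise ValidationError("carrier_volume must be positive")
    vc = capsule_volume(rc)
    if convention == "gel":
        vol = carrier_volume * fraction_vv / (1.0 - fraction_vv)
    elif convention == "suspension":
        vol = carrier_volume * fraction_vv
    else:
        raise ValidationError(f"unknown volume convention {convention!r}")
    return int(math.floor(vol / vc)), vol


def contact_diameter(trace: np.ndarray, rise_threshold: float | None = None) -> float:
    """Capsule diameter from a plate-compression trace.

    ``trace`` is an (n, 2) array of (gap mm, force N) with strictly
    decreasing gap.  The diameter is the largest gap at which the force
    first exceeds the pre-contact baseline by ``rise_threshold``; when the
    threshold is omitted it defaults to 5x the standard deviation of the
    first quarter of the force record (the free-travel baseline), with a
    floor of 1e-12 N for noise-free traces.
    """
    T = np.asarray(trace, dtype=float)
    if T.ndim != 2 or T.shape[1] != 2 or T.shape[0] < 3:
        raise ValidationError("trace must be an (n>=3, 2) array of (gap, force)")
    gap, force = T[:, 0], T[:, 1]
    if not np.all(np.diff(gap) < 0):
        raise ValidationError("gap must be strictly decreasing")
    n_base = max(3, len(force) // 4)
    baseline = float(np.median(force[:n_base]))
    if rise_threshold is None:
        rise_threshold = max(5.0 * float(np.std(force[:n_base])), 1e-12)
    above = np.flatnonzero(force > baseline + rise_threshold)
    if above.size == 0:
        raise ValidationError("no contact detected: force never rises above baseline")
    return float(gap[above[0]])


def read_compression_csv(path: str | Path) -> np.ndarray:
    """Read a two-column compression trace CSV with columns ``gap``, ``force``."""
    df = pd.read_csv(path)
    return df[["gap", "force"]].to_numpy(float)


def plan_to_json(
    carrier_volume: float, fraction_vv: float, rc: float,
    path: str | Path | None = None, convention: str = "gel",
) -> str:
    """Serialize a loading plan (inputs and results) as JSON."""
    n, vol = loading_plan(carrier_volume, fraction_vv, rc, convention=convention)
    doc = {
        "carrier_volume_ul": carrier_volume,
        "fraction_vv": fraction_vv,
        "rc_um": rc,
        "convention": convention,
        "capsule_volume_ul": capsule_volume(rc),
        "n_capsules": n,
        "capsule_total_volume_ul": vol,
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
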
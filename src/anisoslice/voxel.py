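"""Closed-form mechanics of the orthogonal print-line voxel lattice.

Extrusion 3D printing with an orthogonal two-layer infill produces a periodic
lattice whose smallest repeating unit (a *voxel*) consists of one print-line
segment from each of two orthogonal layers plus the gaps between neighbouring
lines.  Homogenizing that unit cell under uniaxial tension gives closed-form
apparent moduli along the two print-line directions, and their ratio — the
anisotropic ratio ``gamma`` — is the design handle for printing structures
with tissue-like directional stiffness.

All lengths are carried in millimetres, moduli in kilopascals and angles in
degrees throughout the package.  Print-line cross sections are idealized as
rectangles; real filaments from a cylindrical nozzle are rounded, so the model
is an engineering approximation, not an exact elasticity solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ValidationError",
    "InfeasibleDesignError",
    "VoxelSpec",
    "VolumeFractions",
    "ElasticAnisotropy",
    "SpanningModel",
    "StressStrainCurve",
    "volume_fractions",
    "predict_anisotropy",
    "anisotropy_at_angle",
    "design_voxel",
    "modulus_from_curve",
    "fit_spanning_model",
    "read_stress_strain_csv",
    "read_spanning_csv",
    "voxel_spec_from_json",
    "voxel_spec_to_json",
]


class ValidationError(ValueError):
    """An input violates a documented invariant; the message names it."""


class InfeasibleDesignError(ValueError):
    """Requested anisotropy cannot be reached inside the printable region.

    Attributes
    ----------
    gamma_range : tuple of float
        The achievable ``(gamma_min, gamma_max)`` under the given bounds.
    """

    def __init__(self, message: str, gamma_range: tuple[float, float]):
        super().__init__(message)
        self.gamma_range = gamma_range


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelSpec:
    """Microdimensions and constituent moduli of one orthogonal voxel.

    Parameters
    ----------
    w1, w2 : float
        Print-line widths of the two orthogonal line families, mm.  In
        practice the flow rate is controlled so the width equals the nozzle
        inner diameter.
    h1, h2 : float
        Print-line heights (layer heights) of the two families, mm.
    L1, L2 : float
        Voxel pitches, mm.  The in-layer spacing between adjacent parallel
        lines of family 1 is ``s1 = L2 - w1`` and of family 2 ``s2 = L1 - w2``.
    E1, E2 : float
        Elastic moduli of the constituent inks, kPa.
    """

    w1: float
    w2: float
    h1: float
    h2: float
    L1: float
    L2: float
    E1: float
    E2: float

    def __post_init__(self):
        for name in ("w1", "w2", "h1", "h2", "L1", "L2", "E1", "E2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"VoxelSpec.{name} must be strictly positive, got {v!r}"
                )
        if self.w1 > self.L2 + 1e-12:
            raise ValidationError(
                f"line width w1={self.w1} exceeds pitch L2={self.L2} "
                "(spacing s1 = L2 - w1 must be >= 0)"
            )
        if self.w2 > self.L1 + 1e-12:
            raise ValidationError(
                f"line width w2={self.w2} exceeds pitch L1={self.L1} "
                "(spacing s2 = L1 - w2 must be >= 0)"
            )

    @property
    def s1(self) -> float:
        """In-layer spacing of line family 1, mm."""
        return self.L2 - self.w1

    @property
    def s2(self) -> float:
        """In-layer spacing of line family 2, mm."""
        return self.L1 - self.w2

    def swapped(self) -> "VoxelSpec":
        """The spec with all index-1 and index-2 parameters exchanged."""
        return VoxelSpec(
            w1=self.w2, w2=self.w1, h1=self.h2, h2=self.h1,
            L1=self.L2, L2=self.L1, E1=self.E2, E2=self.E1,
        )


@dataclass(frozen=True)
class VolumeFractions:
    """Constituent volumes of one voxel, mm^3.

    ``VL1``/``VL2`` are the solid line volumes of the two families,
    ``VS1``/``VS2`` the corresponding gap volumes, and ``VB`` the bounding
    voxel volume.  They satisfy ``VL1 + VS1 + VL2 + VS2 == VB`` exactly.
    """

    VL1: float
    VL2: float
    VS1: float
    VS2: float
    VB: float


@dataclass(frozen=True)
class ElasticAnisotropy:
    """Apparent moduli of the homogenized lattice and their ratio."""

    EL: float  # apparent longitudinal modulus, kPa
    ET: float  # apparent transverse modulus, kPa

    def __post_init__(self):
        if self.EL <= 0 or self.ET <= 0:
            raise ValidationError("apparent moduli must be positive")

    @property
    def gamma(self) -> float:
        """Anisotropic ratio EL/ET (dimensionless)."""
        return self.EL / self.ET


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def volume_fractions(spec: VoxelSpec) -> VolumeFractions:
    """Constituent volumes of the voxel from its microdimensions.

    ``VL1 = w1*h1*L1``, ``VL2 = w2*h2*L2``, ``VS1 = L1*h1*(L2-w1)``,
    ``VS2 = L2*h2*(L1-w2)`` and ``VB = L1*L2*(h1+h2)``; the definitions tile
    the voxel exactly, so line plus gap volumes sum to the bounding volume.
    """
    VL1 = spec.w1 * spec.h1 * spec.L1
    VL2 = spec.w2 * spec.h2 * spec.L2
    VS1 = spec.L1 * spec.h1 * (spec.L2 - spec.w1)
    VS2 = spec.L2 * spec.h2 * (spec.L1 - spec.w2)
    VB = spec.L1 * spec.L2 * (spec.h1 + spec.h2)
    return VolumeFractions(VL1=VL1, VL2=VL2, VS1=max(VS1, 0.0), VS2=max(VS2, 0.0), VB=VB)


def predict_anisotropy(spec: VoxelSpec) -> ElasticAnisotropy:
    """Apparent longitudinal/transverse moduli of the voxel lattice.

    The longitudinal modulus treats the family-1 lines as loaded along their
    axis: the line volume acts in parallel (iso-strain) with the serially
    coupled (iso-stress) combination of the orthogonal layer's line and gap
    volumes::

        EL = VL1*E1 * (VL1*E1 + (VS2+VL2)*E2) / (VB * (VL1*E1 + VS2*E2))

    ``ET`` is the same expression with all 1/2 indices exchanged, and
    ``gamma = EL/ET``.  With zero spacings both reduce to the Voigt rule of
    mixtures ``(VL1*E1 + VL2*E2)/VB``.
    """
    v = volume_fractions(spec)
    EL = (v.VL1 * spec.E1 * (v.VL1 * spec.E1 + (v.VS2 + v.VL2) * spec.E2)
          / (v.VB * (v.VL1 * spec.E1 + v.VS2 * spec.E2)))
    ET = (v.VL2 * spec.E2 * (v.VL2 * spec.E2 + (v.VS1 + v.VL1) * spec.E1)
          / (v.VB * (v.VL2 * spec.E2 + v.VS1 * spec.E1)))
    return ElasticAnisotropy(EL=EL, ET=ET)


def anisotropy_at_angle(
    aniso: ElasticAnisotropy, phi: float, form: str = "ellipse_sqrt"
) -> float:
    """Anisotropic ratio measured at angle ``phi`` to the print-line axes.

    When the spacings of alternate layers are equal, the measured ratio
    varies smoothly between ``gamma`` at 0 degrees and ``1/gamma`` at 90
    degrees.  Two interpolation forms are provided:

    ``ellipse_sqrt`` (default)
        ``sqrt((EL^2 cos^2 + ET^2 sin^2) / (EL^2 sin^2 + ET^2 cos^2))`` —
        the modulus-ellipse form; preserves ``gamma(0) = EL/ET``.
    ``linear_mix``
        ``(EL cos^2 + ET sin^2) / (EL sin^2 + ET cos^2)`` — first-power
        mixing of the moduli.

    Both forms coincide at 0, 45 and 90 degrees and satisfy the reciprocity
    ``gamma(phi) * gamma(phi + 90) == 1``.
    """
    phi_r = np.deg2rad(np.asarray(phi, dtype=float) % 180.0)
    c2, s2 = np.cos(phi_r) ** 2, np.sin(phi_r) ** 2
    if form == "ellipse_sqrt":
        num = aniso.EL ** 2 * c2 + aniso.ET ** 2 * s2
        den = aniso.EL ** 2 * s2 + aniso.ET ** 2 * c2
        out = np.sqrt(num / den)
    elif form == "linear_mix":
        out = (aniso.EL * c2 + aniso.ET * s2) / (aniso.EL * s2 + aniso.ET * c2)
    else:
        raise ValidationError(f"unknown angular form {form!r}")
    return float(out) if np.isscalar(phi) or np.ndim(phi) == 0 else out


# ---------------------------------------------------------------------------
# Printability (spanning) constraint surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpanningModel:
    """Quadratic surface describing cohesive narrowing of spanning lines.

    A line deposited across the gaps of the layer below narrows from its
    as-extruded width ``w0`` to ``w1`` by cohesive attraction.  The relative
    reduction ``w1/w0`` is modelled as a full bivariate quadratic in the
    normalized print height ``x = h/d`` and normalized spacing ``y = s/d``::

        w1/w0 = c0 + c1*x + c2*y + c3*x^2 + c4*x*y + c5*y^2

    with predictions clamped to [0, 1].  The printability cutoff is a plane
    at ``w1/d = threshold`` (default 0.5); since the flow rate is controlled
    so ``w0 == d``, the relative and absolute criteria coincide at the
    default, but both accessors are provided.
    """

    coeffs: tuple[float, float, float, float, float, float]
    d: float  # nozzle inner diameter, mm
    w0: float | None = None  # as-extruded width, mm; defaults to d
    threshold: float = 0.5

    def __post_init__(self):
        if self.d <= 0:
            raise ValidationError("nozzle diameter d must be positive")
        if not 0 < self.threshold <= 1:
            raise ValidationError("threshold must lie in (0, 1]")
        if self.w0 is None:
            object.__setattr__(self, "w0", self.d)

    def predict_w_rel(self, h_over_d, s_over_d):
        """Predicted relative width w1/w0, clamped to [0, 1]."""
        x = np.asarray(h_over_d, dtype=float)
        y = np.asarray(s_over_d, dtype=float)
        c = self.coeffs
        raw = c[0] + c[1] * x + c[2] * y + c[3] * x * x + c[4] * x * y + c[5] * y * y
        return np.clip(raw, 0.0, 1.0)

    def predict_w_over_d(self, h_over_d, s_over_d):
        """Predicted absolute relative width w1/d."""
        return self.predict_w_rel(h_over_d, s_over_d) * (self.w0 / self.d)

    def is_printable(self, h_over_d, s_over_d) -> bool | np.ndarray:
        """True where the predicted spanning width w1/d meets the threshold."""
        return self.predict_w_over_d(h_over_d, s_over_d) >= self.threshold

    def is_printable_relative(self, h_over_d, s_over_d) -> bool | np.ndarray:
        """True where the predicted relative reduction w1/w0 meets the threshold."""
        return self.predict_w_rel(h_over_d, s_over_d) >= self.threshold


def fit_spanning_model(
    measurements: pd.DataFrame | np.ndarray,
    d: float,
    threshold: float = 0.5,
    w0: float | None = None,
) -> SpanningModel:
    """Least-squares quadratic fit to spanning-width measurements.

    ``measurements`` holds columns ``h_over_d``, ``s_over_d``, ``w_rel``
    (a DataFrame, or an (n, 3) array in that column order).  At least six
    distinct (h/d, s/d) points in general position are required — the full
    bivariate quadratic has six coefficients; with exactly six such points
    the fit interpolates.
    """
    if isinstance(measurements, pd.DataFrame):
        arr = measurements[["h_over_d", "s_over_d", "w_rel"]].to_numpy(float)
    else:
        arr = np.asarray(measurements, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError("measurements must be (n, 3): h_over_d, s_over_d, w_rel")
    if arr.shape[0] < 6:
        raise ValidationError("need at least 6 measurements for a quadratic surface")
    x, y, z = arr[:, 0], arr[:, 1], arr[:, 2]
    A = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    if np.linalg.matrix_rank(A) < 6:
        raise ValidationError(
            "rank-deficient design matrix: (h/d, s/d) points are not in general position"
        )
    coeffs, *_ = np.linalg.lstsq(A, z, rcond=None)
    return SpanningModel(coeffs=tuple(coeffs), d=d, w0=w0, threshold=threshold)


# ---------------------------------------------------------------------------
# Tangent modulus from a stress-strain curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StressStrainCurve:
    """A uniaxial tension record: strain (dimensionless) vs stress (kPa)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.shape != stress.shape or strain.ndim != 1:
            raise ValidationError("strain and stress must be equal-length 1-D arrays")
        if strain.size < 5:
            raise ValidationError("need at least 5 points (degree-4 fit)")
        if strain[0] != 0:
            raise ValidationError("strain must start at 0")
        if not np.all(np.diff(strain) > 0):
            raise ValidationError("strain must be strictly increasing")


def modulus_from_curve(curve: StressStrainCurve, eval_strain: float = 0.05) -> float:
    """Tangent modulus (kPa) of a degree-4 polynomial fit at ``eval_strain``.

    A fourth-degree polynomial is least-squares fitted to the stress-strain
    record and its derivative evaluated at the requested strain (5% by
    default), the convention used for the soft silicone inks this package
    targets.
    """
    if not (curve.strain[0] <= eval_strain <= curve.strain[-1]):
        raise ValidationError(
            f"eval_strain {eval_strain} outside the recorded strain range "
            f"[{curve.strain[0]}, {curve.strain[-1]}]"
        )
    p = np.polynomial.Polynomial.fit(curve.strain, curve.stress, deg=4)
    return float(p.deriv()(eval_strain))


# ---------------------------------------------------------------------------
# Inverse design
# ---------------------------------------------------------------------------


def _gamma_for(h1, h2, s, d, E1, E2) -> float:
    spec = VoxelSpec(w1=d, w2=d, h1=h1, h2=h2, L1=d + s, L2=d + s, E1=E1, E2=E2)
    return predict_anisotropy(spec).gamma


def design_voxel(
    target_gamma: float,
    fixed: dict,
    constraints: SpanningModel | None = None,
    *,
    rel_tol: float = 1e-3,
) -> VoxelSpec:
    """Find voxel microdimensions realizing a requested anisotropic ratio.

    The design space follows printing practice: line widths equal the nozzle
    diameter ``d``, the in-layer spacing ``s`` is shared by both layers, and
    the print heights ``h1``/``h2`` are the free variables.  ``fixed`` must
    supply ``d``, ``E1`` and ``E2`` and may pin ``h2`` (mm, default ``d/2``),
    ``s`` (mm) and the height search bounds ``h_min``/``h_max`` (mm, default
    ``0.25*d`` and ``1.5*d``).

    The search scans candidate spacings from dense to sparse (fewest gaps
    first), keeps only (h, s) combinations inside the printable region of
    ``constraints`` when one is given, and bisects on ``h1`` — along which
    ``gamma`` is monotone — until the predicted ratio matches
    ``target_gamma`` to ``rel_tol`` (relative).  Deterministic throughout.

    Raises
    ------
    InfeasibleDesignError
        If no printable combination reaches the target; carries the
        achievable ``(gamma_min, gamma_max)``.
    """
    if target_gamma <= 0:
        raise ValidationError("target_gamma must be positive")
    try:
        d = fixed["d"]
        E1, E2 = fixed["E1"], fixed["E2"]
    except KeyError as exc:
        raise ValidationError(f"fixed must supply {exc.args[0]!r}") from None
    h2 = fixed.get("h2", 0.5 * d)
    h_min = fixed.get("h_min", 0.25 * d)
    h_max = fixed.get("h_max", 1.5 * d)
    if not (0 < h_min <= h2 <= h_max):
        raise ValidationError("need 0 < h_min <= h2 <= h_max")

    if "s" in fixed:
        s_candidates = [float(fixed["s"])]
    else:
        s_candidates = list(np.round(np.arange(0.0, 1.0 * d + 1e-9, 0.05 * d), 9))

    def h_bounds(s: float) -> tuple[float, float] | None:
        if constraints is None:
            return (h_min, h_max)
        hs = np.linspace(h_min, h_max, 201)
        ok = np.asarray(constraints.is_printable(hs / d, s / d))
        if not ok.any():
            return None
        return (float(hs[ok].min()), float(hs[ok].max()))

    achievable_lo, achievable_hi = np.inf, -np.inf
    for s in s_candidates:
        b = h_bounds(s)
        if b is None:
            continue
        lo, hi = b
        if constraints is not None and not bool(constraints.is_printable(h2 / d, s / d)):
            continue
        g_lo, g_hi = _gamma_for(lo, h2, s, d, E1, E2), _gamma_for(hi, h2, s, d, E1, E2)
        g_min, g_max = min(g_lo, g_hi), max(g_lo, g_hi)
        achievable_lo = min(achievable_lo, g_min)
        achievable_hi = max(achievable_hi, g_max)
        if g_min - 1e-12 <= target_gamma <= g_max + 1e-12:
            f = lambda h1: _gamma_for(h1, h2, s, d, E1, E2) - target_gamma
            # prefer the symmetric candidate when it already satisfies the target
            if lo <= h2 <= hi and abs(f(h2)) / target_gamma <= rel_tol:
                h1 = h2
            elif abs(f(lo)) / target_gamma <= rel_tol:
                h1 = lo
            elif abs(f(hi)) / target_gamma <= rel_tol:
                h1 = hi
            else:
                h1 = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
            return VoxelSpec(w1=d, w2=d, h1=h1, h2=h2, L1=d + s, L2=d + s, E1=E1, E2=E2)

    if not np.isfinite(achievable_lo):
        raise InfeasibleDesignError(
            "no printable (h, s) combination exists under the given constraints",
            (np.nan, np.nan),
        )
    raise InfeasibleDesignError(
        f"target gamma {target_gamma} outside achievable range "
        f"[{achievable_lo:.4g}, {achievable_hi:.4g}]",
        (achievable_lo, achievable_hi),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_stress_strain_csv(path: str | Path) -> StressStrainCurve:
    """Read a headered CSV with columns ``strain`` and ``stress`` (kPa)."""
    df = pd.read_csv(path)
    return StressStrainCurve(strain=df["strain"].to_numpy(), stress=df["stress"].to_numpy())


def read_spanning_csv(path: str | Path) -> pd.DataFrame:
    """Read spanning measurements: columns ``h_over_d``, ``s_over_d``, ``w_rel``."""
    df = pd.read_csv(path)
    missing = {"h_over_d", "s_over_d", "w_rel"} - set(df.columns)
    if missing:
        raise ValidationError(f"spanning CSV missing columns: {sorted(missing)}")
    return df


_VOXEL_FIELDS = ("w1", "w2", "h1", "h2", "L1", "L2", "E1", "E2")


def voxel_spec_from_json(source: str | Path | dict) -> VoxelSpec:
    """Build a VoxelSpec from a JSON file/string or an already-parsed dict."""
    if isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
    missing = set(_VOXEL_FIELDS) - set(data)
    if missing:
        raise ValidationError(f"voxel config missing fields: {sorted(missing)}")
    return VoxelSpec(**{k: float(data[k]) for k in _VOXEL_FIELDS})


def voxel_spec_to_json(spec: VoxelSpec, path: str | Path | None = None) -> str:
    """Serialize a VoxelSpec to JSON; write to ``path`` when given."""
    text = json.dumps({k: getattr(spec, k) for k in _VOXEL_FIELDS}, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
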
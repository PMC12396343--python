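# Methods

This note records the models implemented in `anisoslice`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generators do and do not emulate.  Units throughout: lengths mm
(capsule radii µm, volumes µl), moduli kPa, angles degrees, flow mm³/s.

## Voxel homogenization

The infill lattice is modelled by its repeating unit: one rectangular line
segment from each of two orthogonal layers plus their gaps.  Loading along
line family 1 treats that family's volume as iso-strain (parallel) with the
orthogonal layer, whose line and gap volumes combine iso-stress (serial);
exchanging indices gives the transverse modulus, and γ = E_L/E_T.  The
closed form assumes:

- **Rectangular cross-sections.**  Real filaments from a cylindrical nozzle
  are rounded; flow control makes width equal the nozzle inner diameter d.
- **Linear elasticity, small strain.**  No strain stiffening — the tangent
  modulus at 5% strain stands in for "the" modulus of each ink (see below).
- **Perfect bonding and periodicity.**  Edge effects and cover layers are
  outside the unit-cell picture; thick covers dilute the measured
  anisotropy of a finished part.

The volume definitions tile the voxel exactly, so
`VL1 + VS1 + VL2 + VS2 = VB` holds to machine precision — this identity is
the implementation's self-check (the bounding volume is `L1·L2·(h1+h2)`).
Useful limits: zero spacings recover the Voigt rule of mixtures for both
directions; full index symmetry gives γ = 1; exchanging all indices maps
γ → 1/γ.

**Angular variation.**  With equal spacings in alternate layers, the ratio
measured at angle φ to the line axes is interpolated by the modulus-ellipse
form γ(φ) = √[(E_L²c² + E_T²s²)/(E_L²s² + E_T²c²)] (c = cos φ, s = sin φ).
A first-power mixing form `(E_L c² + E_T s²)/(E_L s² + E_T c²)` is selectable
via `form="linear_mix"`.  The square-root form is the default because it
preserves γ(0) = E_L/E_T together with squared moduli inside the mix; both
forms coincide at 0°, 45° and 90° and satisfy γ(φ)·γ(φ+90°) = 1, so the
choice only matters at intermediate angles (the forms differ by < 3% for
γ ≤ 2).

**Inverse design.**  `design_voxel` fixes the practice-driven reductions
w₁ = w₂ = d and a shared spacing s, leaving (h₁, h₂, s) free.  γ is monotone
in h₁ (and in s) for fixed h₂, so the search scans spacings dense-to-sparse
(a denser lattice prints faster and spans less) and runs Brent's method on
h₁ inside the printable height window; the symmetric candidate h₁ = h₂ is
preferred when it already meets the target, making γ = 1 requests return the
symmetric voxel.  Height bounds default to h/d ∈ [0.25, 1.5] — below that
the filament smears, above it detaches and curls.  Infeasible targets raise
a structured error carrying the achievable γ range.  Deterministic; no
randomness.

**Printability.**  A line bridging the gaps of the layer below narrows by
cohesion.  The relative width w₁/w₀ is fit as a full bivariate quadratic in
(h/d, s/d) by ordinary least squares (≥ 6 points in general position; exact
interpolation at 6), predictions clamped to [0, 1].  The cutoff is
w₁/d ≥ 0.5 by default; because flow control sets w₀ = d the relative and
absolute criteria coincide, but both accessors exist (`is_printable`,
`is_printable_relative`) since either normalization is defensible.

**Tangent modulus.**  A degree-4 polynomial is least-squares fitted to the
stress–strain record and differentiated at 5% strain — low enough to sit in
the near-linear regime of soft silicones, high enough to escape seating
artefacts.  At least 5 points are required (the fit is otherwise
underdetermined).

## Conformal geometry

The bottom surface of the model is the *template*: vertices whose normal
Z-component is negative (faces by 2-of-3 vertex majority; near-vertical
normals, |n_z| < 1e-6, go to the top set and are counted in a warning).
Scattered template points become a regular-grid height field by barycentric
linear interpolation on their Delaunay triangulation — the standard
treatment of surface-scan data; cells outside the convex hull stay
undefined.  Layers are pure **vertical** offsets of the template, matching
3-axis gantry kinematics; offsetting along surface normals would require
tilting the nozzle.  The residual error of vertical offsetting on an incline
is compensated per waypoint:

    h = h0 / cos α ± (d/2)·tan α,    + descending, − ascending

The sign convention reflects the nozzle's leading edge sitting over the
higher substrate side when climbing, which shrinks the effective clearance;
it is exposed as `travel_sense` and can be swapped by callers with the
opposite geometry.  Accuracy degrades above ~45° of inclination — a known
limitation of 3-axis conformal deposition, not checked by the code.
Volumetric flow follows the rectangular-filament contract Q = v·d·h, which
makes total commanded volume per path equal d·h·length by construction.

Reorientation for minimal build height initializes from the least-variance
principal direction of the vertex cloud, then refines on an exhaustive 1°
grid of two tilt angles within ±45° (deterministic; ties to the smallest
tilt).  Mesh I/O goes through `trimesh` (ASCII and binary STL); vertices are
merged within 1e-6 mm.

## Orientation fields and toolpaths

A layer is discretized into square grid units, each carrying one line
direction (mod 180°) — in dermal tissue this is the local Langer-line
direction of collagen alignment.  Units are filled with parallel lines at
their angle (center-anchored, perpendicular pitch = the line spacing) and
processed row-major from the lower left so that endpoints earlier units
leave on a shared border act as starting points for later ones:

- **Re-anchoring.**  If a processed neighbour offers an unmatched endpoint
  on a shared border, and the new unit's line direction crosses that border
  within 45° of its normal, the whole family is shifted perpendicular by at
  most half the pitch so one line passes through that point exactly.  The
  45° alignment gate is the crossing-regime divider of a square: continuing
  a line across a border it only grazes would kink the filament instead of
  smoothly extending it.
- **Snapping.**  Remaining border endpoints are greedily matched to the
  neighbour's nearest unmatched endpoints within half the pitch, each
  endpoint at most once; matches become zero-length *junction* edges between
  the two endpoint nodes (both nodes are kept, so waypoint counts are
  preserved).  Unequal line counts simply leave surplus endpoints at
  degree 1.

Lines are densified into waypoints either at a fixed spacing or by
distributing an exact per-unit count proportional to line length (≥ 2 per
line).  Trimming against a layer contour removes nodes strictly outside and
clips boundary-crossing line edges with an inserted boundary node.

**Path optimization.**  The *naive* decomposition prints every line run as
its own path — the stop–start-heavy baseline.  The optimizer repeatedly:
draws a random untraversed waypoint; extends forward until a branch point;
explores each continuation by depth-first search (explicit stack, so long
chains cannot hit recursion limits) keeping the longest branch, first-found
on ties; repeats in reverse from the seed; retires the traversed waypoints.
The whole pass restarts `restarts` times (default 100) and the decomposition
with fewest paths wins, ties broken by fewest direction reversals
(consecutive segments turning > 90°), then first found.  Restart r uses the
child generator `default_rng([seed, r])`, so results are fully deterministic
and best-so-far is monotone in the restart count.  Minimum path cover is
NP-hard in general; on the near-linear graphs this generator produces, the
randomized DFS sits within one path of the exhaustive optimum on all small
instances tested.

**Benchmark conditions.**  The continuity benchmark draws uniformly random
per-unit orientations on n×n grids (n = 4…12, five replicate seeds per
size), 10 waypoints per unit, 100 restarts.  Units are 5 mm (an ~40 mm part
at 8×8) and the benchmark pitch exceeds the unit diagonal so each unit hosts
a single line discretized to 10 waypoints — the per-unit resolution that
makes the naive baseline exactly n² paths of 10.  Reported metrics: the
percentage reduction in distinct path count versus naive, and *coverage* —
the percentage of waypoints in paths strictly longer than the 10-waypoint
single-unit baseline, our operationalization of "area traversed by more
continuous toolpaths" (the phrase has no formal definition; the benchmark
report carries this note).  Under these conditions the reduction is ~43%
independent of grid size.  Coverage averages ~68–70%: with uniformly random
orientations, two neighbouring units merge only when both dominantly cross
their shared border, so the expected isolated-unit fraction (~30%)
structurally caps this metric — a smoother, correlated orientation field
(as real collagen maps are) merges more.

## Planning pipeline

`plan_print` composes the stages: reorient → split → template height field →
conformal layers → per-layer line generation (even infill layers at the
field orientation with pitch L₂, odd ones rotated 90° with pitch L₁; cover
and sacrificial layers solid-filled at alternating 0/90°) → trim to the mesh
footprint → optimize → project → gradient → nozzle-height compensation →
flow.  The layer plan, not the mesh thickness, defines the stack height:
the fixture meshes are open bottom-template shells, so every planned layer
shares the mesh's XY footprint.  Commanded nozzle z is the underlying
substrate surface plus the compensated clearance; travel moves between paths
lift by a 2 mm clearance.  Defaults: print speed 16.667 mm/s, 18-GA nozzle
(d = 0.84 mm), 600 µm covers, six infill layers.  Stage failures re-raise
with the stage name and layer index.  Identical inputs and seed produce
byte-identical programs.

The G-code dialect is self-defined (no common dialect carries volumetric
flow): G0 travels; G1 extruding moves with F in mm/min, E as cumulative
extruded volume in mm³, and the volumetric rate appended as a `;Q=` comment
so the reader recovers flow without re-deriving it from rounded E deltas.
All numerics print at six decimals and round-trip at that precision; the
command CSV dialect is a plain headered table.

## Capsule payloads

Fluid payloads (simulated blood) are stored as double-emulsion capsules in a
sacrificial carrier gel.  Capsule volume is the sphere formula on the mean
radius; counts are computed from the **exact** volume (the 3-significant-
figure display value 0.161 µl for r = 337.5 µm would give a count one higher
at the 800 µl/20% reference point — rounding is display-only).  The default
loading convention treats the given volume as the carrier-gel portion
(capsules are loaded on top of the solidified gel), so capsule volume is
`carrier·f/(1−f)`; a suspension-referenced convention is selectable.
Contact diameter from a compression trace is the largest plate gap at which
force first exceeds the pre-contact baseline (median of the first quarter of
the record) by a threshold, default 5× the baseline's standard deviation.

## Synthetic data

The generators produce every input the pipeline needs, deterministically
under a seed: hyperbolic-paraboloid shells z = c(x² − y²) (puck-like ~40 mm
footprint; vertices exactly on the analytic surface), inclined planes,
constant/random/sinusoidal ("Langer-like") orientation grids, linear and
mildly stiffening stress–strain curves with additive Gaussian noise, and
spanning-width tables from a known quadratic whose defaults narrow with
lower heights and wider spacings, staying within [0, 1] over the sampled
window.  They emulate shapes, scales and noise levels — not scanner
artefacts, ink rheology, or the spatial correlation of real collagen maps.
Consequently, passing tests demonstrate the correctness of the geometry,
the optimizer and the closed forms under controlled conditions; they do not
by themselves validate deposition physics on real hardware.

## Numerical choices

Vertex merge tolerance 1e-6 mm; border/endpoint tolerance 1e-6 mm; snapping
tolerance half the line pitch; degenerate (corner-touching) line clips
dropped below 1e-6 mm length; spanning predictions clamped to [0, 1]; Brent
root-finding at machine tolerance with a 1e-3 relative acceptance on
designed γ; near-vertical normals routed to the top set with a warning;
3-significant-figure rounding applied only at display time.
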
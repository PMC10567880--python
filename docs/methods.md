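# Methods

## Problem and approach

Rectal temperature is the standard input of temperature-based death-time
estimation, yet the exact probe position varies between examiners by
centimetres. `tdesens` quantifies the consequence of that variation: it
cools a synthetic body phantom numerically, reads the cooling curve at the
intended rectal locus C and at six displaced positions forming an
octahedron of radius R around C (± along each axis), and converts the
curve differences into *time* deviations of the inverted death-time
estimate. Everything is synthetic by design — no CT data, meshes or
subject measurements are used — so the package makes *qualitative*
claims about mechanisms and orderings, not subject-specific predictions.

## The phantom

A labelled voxel volume on a regular grid (X lateral, Y dorsal→ventral,
Z caudal→cranial). The default recipe is an adult male analog: tapering
leg cylinders, a full-section pelvic ring ending in a perineal face
between the thighs, an elliptic trunk with a subcutaneous fat shell, a
dorsal bone (spine) cylinder running into the pelvis, two lungs, a large
abdomino-pelvic viscera compartment, neck and head. The rectal locus C
sits on the mid-sagittal plane in the pelvic viscera with bone 2–3 cm
dorsal and roughly 15 cm of tissue caudally — deep-insertion rectal
measurement. After construction the phantom is scaled to exactly
1.74 m / 62 kg by a one-dimensional stretch k₁ = L′/L along Z and a
transverse dilation k₂ = √(M′L/(ML′)), which leaves densities unchanged
and lands the voxel-integrated mass exactly on target.

Anatomical choices that matter for the results:

- **Pelvic mass and the perineal face.** Early versions attached thin
  leg cylinders to an exposed flat trunk base; the resulting caudal cold
  front dominated every deviation measure. The shipped recipe closes the
  trunk base with a full-width pelvic ring (the body's most massive
  region) whose underside is the perineal surface, mostly covered by the
  attached thighs. This is both more anatomical and decisive for the
  direction results.
- **Mirror symmetry** is enforced exactly for the symmetric variant by
  mirroring one half of the label grid (floating-point ties on curved
  compartment boundaries would otherwise break it); SP_1/SP_2 curves then
  agree to ~1e-13 K.
- **Tissue table.** Literature-typical values shipped as CSV
  (`data/tissue_defaults.csv`): muscle κ=0.49 W/(m K), ρ=1090, c=3421;
  fat 0.21/911/2348; bone 0.75/1908/1313; viscera 0.52/1050/3600; inflated
  lung 0.39/394/3886; perfusion rates w of order 10⁻⁴–3·10⁻³ s⁻¹. All
  overridable per phantom.
- The **wet-soil slab** (κ=2 W/(m K), c=2200 J/(kg K), ρ=1900 kg/m³,
  ε=0.95) conforms to the dorsal body surface column by column — a soft
  bed in full contact with the back — and starts at ambient temperature.
- The **asymmetric variant** breaks the mirror symmetry with fixed organ
  offsets plus small seeded jitter; it stands in for an anatomically
  irregular, image-derived model but cannot reproduce real anatomy.

## Initial temperature fields

Two options, matching the two modelling traditions:

- `gradient_initial_field`: deep-body voxels at T_core = 37.2 °C with a
  linear ramp over depth through a shell of thickness `core_depth`
  (default 5 cm) down to T_skin = 28 °C at the surface. The shell
  default reflects the physiological situation of an isothermal warm
  core with only the outer centimetres graded; it also produces the
  characteristic postmortem temperature plateau at deep probes.
  `core_depth=None` normalises by the deepest point instead (a ramp
  everywhere).
- `solve_initial_field_bhte`: steady Pennes bioheat solve with the same
  Robin boundary as the transient problem (the boundary condition of the
  steady problem is a modelling choice; using the cooling boundary keeps
  the t=0 field consistent with the t→0⁺ dynamics). ρ_b c_b defaults to
  3.8·10⁶ J/(m³ K). For the asymmetric variant the solved field is
  additionally quantised to 10 discrete levels (bin-mean values),
  emulating an initial field carried over between solvers as discrete
  node sets.

T_core = 37.2 °C, T_skin = 28 °C and ρ_b c_b are documented literature
defaults, all configurable.

## Discretisation and solver

- 7-point finite volumes; interface conductivity is the harmonic mean of
  the two cell conductivities (exact flux continuity across tissue
  boundaries).
- Robin faces carry the half-cell conduction resistance in series:
  g = A_eff / (d/2κ + 1/γ). With γ ≈ 8 and d = 1 cm the series term is a
  ~15% effect and necessary for quantitative accuracy.
- **Staircase-area correction.** A voxelised smooth surface overestimates
  area by up to 3/2. Each exposed face is therefore weighted by the
  matching component of the outward normal of the smoothed signed
  distance field (Gaussian σ = 1 voxel); summed face areas then converge
  to the true surface area (sphere area error −0.8% at 20 voxels per
  radius). The correction is exact-neutral for axis-aligned geometry and
  can be disabled (`surface_correction=False`), which the box-based
  validation tests do since a cube's staircase area is already exact.
- Implicit Euler with adaptive steps: initial 0.1 s, per-step maximum
  temperature change 1 K (halve and redo on violation, double when the
  change stays under 0.45 K), capped at the probe output cadence
  (0.05 h default). The scheme is unconditionally stable and preserves
  the discrete maximum principle, which is asserted after every step.
- Each step solves the SPD system (C/Δt + L) T⁺ = C/Δt T + b by
  Jacobi-preconditioned conjugate gradients (rtol 1e-12) warm-started
  from the current state; the matrix is strongly diagonally dominant at
  these step sizes, so CG takes few iterations and scales to refined
  grids where a direct factorisation does not. Per-step energy balance
  (Σ cρΔT·V vs. boundary flux integral) holds to ~1e-11 relative.
- The steady bioheat system is solved directly (sparse LU); with no
  perfusion and no boundary exchange it is singular and rejected.
- Probes are read by trilinear interpolation of voxel-centre values.

Validation (in `tests/` and `scripts/acceptance.py`): Robin-sphere centre
history within 0.3% of the eigenfunction series (radius 10 cm, 30 voxels
per radius, 0.0125 h output steps); small-Biot cube within 0.25% of the
lumped exponential; pseudo-1-D bioheat slab equal to an independent dense
solve to 1e-13 K and to the continuous cosh profile to 5 mK at 1 mm
resolution.

## Deviation metrics

The calculus operates on monotone windows: each curve is clipped to
[a, b] = [1, 45] h (the first hour is excluded because of the plateau),
evaluation starts at the curve maximum inside the window, strict decrease
is required thereafter (tolerance 1e-6 K per sample) and flat ties
collapse to their earliest time, which fixes the inversion at plateaus.
T₀ := T_R(0) is taken from the *unclipped* curves at time zero. Clipping
happens before the range bounds T_MAX = min of first samples / T_MIN =
max of last samples are taken; [t_MIN, t_MAX] is the preimage of that
range under the piecewise-linear reference curve. K = 1000 grid points by
default (configurable); doubling K moves D_MAX by less than one grid
width. Q-intervals are half-open ]·,·] exactly; a grid point on a left
endpoint belongs to the previous interval. Boundary temperatures above
the reference range map to t_q = −∞, unreached ones to +∞, so interval
intersection with [t_MIN, t_MAX] handles partially covered cooling.
Because the global maximum runs over *all* K grid points while the
Q-intervals only cover Q ∈ (0.1, 1], the global value can exceed every
local one when cooling proceeds past Q = 0.1 inside the window; the code
guarantees global ≥ max(local) with equality when the intervals tile the
grid. Curves arriving on different time grids are linearly resampled onto
the union grid before the pointwise mean.

## Study design and problem sizes

The default study crosses three variants × T_A ∈ {5, 15, 25} °C ×
R ∈ {0.5, 1, 2} cm × six probes, on a 1 cm voxel grid (a 2 cm smoke grid
is one config key away). All radii share one simulation per
(variant, T_A): every probe point samples the same transient field, which
is also what makes SP_1 ≡ SP_2 exact for the symmetric variant. The full
default study runs in about three minutes on one CPU; the refined-sphere
validation about two. Coarse variants use the gradient initial field, the
asymmetric variant the quantised bioheat field. Identical configs and
seeds give bit-identical tables (the only randomness is the seeded organ
jitter of the asymmetric variant).

The grid-refinement check compares D_MAX between 1 cm and 0.5 cm voxels
on a compartment phantom whose boxes voxelise exactly at both spacings
(< 5% change per probe). On the curved default phantom the same halving
moves D_MAX by up to ~6%, but that difference conflates discretisation
with geometry re-realisation: each spacing produces a slightly different
voxel body.

## What passing tests show — and what they do not

The synthetic phantom reproduces, on a 1 cm grid, the qualitative
regularities expected of this measurement problem: D_MAX grows with
probe displacement R everywhere; with a conductive substrate the
dorso-ventral axis carries the largest deviation at every T_A and R, and
the deviation grows as the ambient temperature falls; the lateral probes
of the symmetric body coincide; and for the dorso-ventral probes the
first Q-interval holds the per-probe maximum — placement errors there act
like initial-temperature errors, large early and damped later. Deviation
magnitudes reach ~1.4 h at R = 2 cm, the low single-digit-hour scale
that makes probe placement a non-negligible error source.

Two patterns do **not** carry over from real-anatomy models, and the
package reports them honestly rather than forcing them. For
caudal-cranial probes, D_MAX,Qi *rises* with i: the legs act as a
persistent caudal heat sink, so the C–SP_6 time offset converges from
below to its single-mode asymptote ln(A₁/A₂)/λ, which exceeds the
near-zero early offset (physiologically, the deep abdomen is isothermal
along this axis at t = 0). For the lateral probes the deviations are
second-order by mirror symmetry and their Q-profile is effectively flat.
Both behaviours were stable across every phantom and initial-field
configuration explored (exposed vs. closed trunk base, pelvis width,
rectal locus depth, ramp vs. shell vs. bioheat initial fields, with and
without a sacral bone slab); reproducing a Q1-dominant caudal pattern
evidently requires anatomy- or mesh-specific initial heterogeneity that a
smooth synthetic phantom does not possess.

## Known limitations

- Voxel geometry, not anatomy: organ shapes are ellipsoids/cylinders;
  the asymmetric variant is an analog of an irregular body, not a replica.
- Radiation is linearised into γ throughout; no view factors, no
  clothing or covering layers, no convection modelling beyond h.
- The substrate conforms perfectly to the back; real contact is partial.
- Arms are not modelled separately (their mass is absorbed by the
  transverse scaling).
- Tissue properties are population-typical constants; no temperature
  dependence.
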
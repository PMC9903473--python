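# Methods

This note records the models behind `liftscan`, the parameters that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the problem was genuinely open.

## Stage motion model

Each stage axis is modelled as a constant-acceleration (bang-bang)
actuator with a velocity cap: accelerate at `a` until either `v_max` or
the half-way point, cruise if the cap is reached, decelerate
symmetrically. Move time over a line of length `L` is

    t(L) = 2 v_max / a + (L − 2 L_accel) / v_max      if L ≥ 2 L_accel
    t(L) = 2 √(L / a)                                 otherwise

with `L_accel = v_max² / (2a)`. The short-move (triangular) branch is our
extension chosen for physical consistency — the trapezoidal form is only
meaningful once the cap is reachable; the two branches agree at the
threshold, so `t(L)` is continuous and strictly increasing. Trigger
times along a line invert this profile piecewise (closed form per
segment); the test suite checks both against numerical quadrature of the
velocity profile to 1e−9 s.

Defaults are the demonstrator operating point: `v_max = 120 mm/s`,
`a = 100 mm/s²` (the hardware supports 500 mm/s² but is derated to limit
sloshing). On a 120 mm line this yields a reached peak of 109.5 mm/s and
`t_line = 2.191 s`.

**Line-time ambiguity.** A published line time of 2.26 s circulates for
this operating point, but the 120 mm inputs evaluate to 2.191 s under
the equation above; 2.26 s corresponds to a travel length of ≈127.76 mm
(the full plate footprint). The implementation follows the equation
literally over the configured travel length; setting
`plan.line_length_mm: 127.76` reproduces the 2.26 s reading. Both are
covered by tests.

**Two-axis moves.** The stop-and-go baseline needs a 2-D point-to-point
time the source material does not specify. Default is `max` of the
per-axis 1-D times (crossed stages move both axes simultaneously);
`euclidean` (one profile along the straight-line distance) and
`sequential` (axes one after another) are available as
`stopgo.move_model` so the sensitivity of the comparison can be probed.
`max` is the fastest of the three, i.e. the most conservative choice for
the continuous method's reported speed-up.

## Plate geometry and the cell-position generator

Well coordinates are not standardized in the source material, so the
layout uses common commercial six-well dimensions: 34.8 mm well
diameter, 39.12 mm center pitch, a 2×3 grid centered in the 120×80 mm
usable area of a 127.76×85.48 mm plate. Any layout can be supplied via
the config `plate` section.

Cells are sampled by choosing a well uniformly, then a position uniform
over the well disk (sqrt-radius transform); no margin keeps cells away
from well walls. This emulates the simulation harness the comparison
study was built on — *not* real cultures: actual colonies cluster, which
concentrates targets on fewer lines and would speed the continuous
method up further. Passing tests therefore validate the scheduling
arithmetic under the stated uniform conditions, not field performance.
Generation is deterministic given the seed, bit for bit.

## Continuous-scan planner

- Lines sit at `y0 + pitch/2 + k·pitch`, `k = 0..N−1`,
  `N = ⌊L_y/pitch⌋`: the half-pitch offset makes the 25 µm tolerance
  discs tile the band exactly at the default 50 µm pitch. Configurations
  with `tolerance > pitch/2` are rejected.
- Every target goes to its nearest line (tie exactly midway → lower
  index); the trigger fires at the target's exact x, so the tolerance is
  consumed only across-track. Along-track slack optimization is a
  non-goal.
- Lines with no target are skipped; visited lines are traversed
  serpentine (+x, −x, … over visited lines) at full travel length — no
  shortening to the first/last trigger, matching the fixed `t_line` in
  the total-time formula.
- Total time charges the settling pause once per visited line (a line
  end is a stop) and `t_switch = 0.04 s` per transition:
  `t = V(t_line + pause) + (V−1)·t_switch`. Switch time and pause are
  summed, not overlapped. Skipped-line gaps still cost one `t_switch`
  per transition (no 2-D shortcut moves).
- Targets at identical x on one line merge into a single trigger event
  carrying all their ids. Nearby LIFT events can interact physically; no
  firing rule is modelled, but `min_separation_violations` reports
  trigger pairs closer than a configurable along-track distance
  (`plan.min_trigger_separation_um`, default off).

## Stop-and-go baseline and the comparison

The baseline processes wells in ascending index, cells within a well by
ascending x (ties by y), with one pause per cell and no approach move to
the first target (negligible at the studied n). The comparison draws
`reps = 5` independent distributions per cell count
(seeds `base_seed .. base_seed+4`), schedules each with both methods at
the same pause, and reports mean times and the ratio of means. With the
defaults this reproduces the published comparison within a few percent
(ratios ≈ 2.1 / 3.5 / 20.8 against 2.04 / 3.46 / 20.05) — residual
differences trace to the unspecified 2-D move model and line length
discussed above.

## Colony morphometry

Colony-class components are 8-connected (background/hole logic
4-connected, the standard complementary pairing); records are numbered
in raster-scan order of first pixel. Centroids are pixel-center centers
of gravity (0-based, x = column, y = row). `size` is the pixel count.

`length` is the Crofton perimeter (4 directions) of the hole-filled
component: it converges to the geometric circumference, so a rasterized
disk scores roundness `4π·size/length² ≈ 1` and a one-pixel line ≈ 0.03,
and it counts both sides of thin structures, which an exposed-edge count
would also do but at the cost of overestimating smooth contours by a
factor approaching 8/(2π) (a disk would score ≈ 0.62, breaking the
circularity convention). Inner hole boundaries are excluded from
`length`; holes contribute to `childrenSize` instead, counting only
pixels of labelled classes other than background and the colony class
itself ("inclusions of a different class") — plain background holes
count nothing. `colonyPercent = 100·size/(size + childrenSize)`.

The caption-style formula `4π·size/length` (not dimensionless) is
available as `roundness_formula="literal"` for reproduction; the squared
form is the default and the documented intent.

Pixel → stage: `stage = well_origin + (section_offset + pixel)·pitch`
with the µm→mm conversion; the inverse is exact (round trip < 1e−9 mm).
Default pitch 1.3 µm/px. Stitching shifts of < 10 µm are checked against
the 50 µm transfer tolerance (boundary passes).

The upstream multi-class segmentation itself (PHANTAST/U-Net style) is
out of scope; `synth_label_image` rasterizes declared shapes (disks,
ellipses, lines) with ground-truth centroids and areas as its synthetic
stand-in, rejecting overlaps between different classes.

## Focal map

Sharpness is the variance of the finite-difference gradient magnitude:
zero for constant images, invariant to additive offsets, monotone under
defocus blur — the minimal properties peak search needs; no specific
metric is mandated by the application. Best focus is the score maximum,
refined by the vertex of a parabola through (z, log score) of the peak
and its neighbours (log because the score peak is much sharper than
quadratic), clamped to the neighbour interval; endpoint peaks are
returned unrefined. Identical scores raise an indeterminate-focus error.

The focal surface is a global least-squares polynomial per well — degree
2 with ≥ 6 control points, else a plane — rather than piecewise
interpolation, because z commands are needed beyond the sampled hull
(extrapolation). Sampling positions "equally spread over the well" are a
k×k grid spanning the well's inscribed square (default k = 3, so 9
points); the z range and slice count of the sweep are config parameters
(default ±8 µm, 9 slices → 2 µm steps).

The synthetic z-stack generator blurs a fixed random texture with a
Gaussian growing linearly in defocus (0.5 px at focus + 0.5 px/µm) plus
i.i.d. pixel noise (default σ = 0.2). It emulates monotone
blur-with-defocus only — no optical PSF physics, vignetting, or sample
motion — so recovery tests demonstrate the estimator pipeline, not
camera realism. End-to-end, a tilted-plane well bottom sampled at 2 µm
z-steps with that noise is recovered to < 1 µm maximum error.

## Problem sizes and numerics

The comparison study runs all four cell counts (10² … 10⁵) at five
replicates through vectorized schedulers in a few seconds. Quadrature
oracles in the tests use sqrt substitutions at the profile endpoints
where v → 0. Degenerate inputs fail loudly: non-positive kinematics,
negative distances, out-of-band targets (with ids), uncovered-band grid
configs, collinear surface control points, contradictory selection
bounds, malformed XML (naming the missing field).

## Known limitations

- Uniform, uncorrelated cell positions (see above); no clustered point
  processes.
- No globally optimal path finding; the serpentine full-length traversal
  is deliberately simple and matches the published total-time formula.
- No jerk-limited (S-curve) profiles, encoder/controller simulation, or
  slosh fluid dynamics — pauses are opaque inputs.
- In-flight firing produces oblique jets at speed (≈ 24 µm of sample
  travel per 200 µs event at 120 mm/s); the displacement is computed but
  its effect on transfer quality is not modelled.
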
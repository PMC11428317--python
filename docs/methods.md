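# Methods

`sprawlgait` is a kinematic — not dynamic — simulator: no forces, ground
reaction, buoyancy or drag are computed, and underwater walking is treated as
kinematically identical to walking on land.  Its purpose is to expose the
geometric consequences of gait parameters (stride timing, lateral bending,
limb proportions) on stride length, frequency and speed, exactly as one would
measure them from an animated armature with virtual trackers.

## Body model

The body is a stick armature in a fixed world frame: X forward (direction of
travel), Y left, Z up; ground plane Z = 0; lengths in meters, angles in
degrees.  Rotations compose intrinsically X-then-Y-then-Z, so a rotation
about the vertical is a pure `rz`; the BVH export uses the same convention,
which makes the two representations bit-consistent.

Only total length and SVL of the reference animals are published, so the
remaining proportions are package defaults (fractions of SVL): head 0.20,
pectoral girdle at 0.25, pelvic girdle at the vent, girdle half-width `w` =
0.10, forelimb segments 0.11 + 0.11, hindlimb segments 0.12 + 0.12 — a
deliberately short-limbed habitus; six trunk joints.  Every value can be
overridden in a body-plan file; the defaults are working fixtures, not
anatomical claims.  Two reference plans exist: the specimen-size plan
(0.64 m / 0.43 m) and the scaled plan (1.2 m / 0.8 m).  The published scaled
model is *not* a uniform scaling of the specimen (0.8/1.2 ≠ 0.43/0.64), so
`scale_plan` is strictly uniform and the two plans are constructed
independently rather than forced to agree.

## Axial standing wave

All trunk joints share one sinusoid: joint angle `(A/n)·sin(2π(t/T + φ))`
with amplitude `A` split over `n` joints, period `T` = one stride, phase
`φ`.  `A` is defined as the peak *total* deflection — the angle between the
pectoral and pelvic girdle axes — which is also what `trunk_angle_series`
measures back from the trackers.

Two modelling choices matter here:

* **Node placement.** The girdles are placed at the wave's nodes: both ride
  the midline, the pelvic girdle trailing the pectoral by the chord of the
  bent chain, and they yaw in antiphase by `∓A/2` (the serial chain makes the
  pelvic lateral offset cancel exactly for the symmetric standing wave).
  This matches trotting salamanders, in which planted diagonal limbs hold
  the girdles on track while the mid-trunk bows sideways.
* **Phase.** The default `φ` = 0.25 puts the peak bend at the LF/RH couplet
  touchdown, as in trotting salamanders (maximal flexion near diagonal-pair
  touchdown, curvature reversing each half-stride).  This phasing is what
  makes bending *useful*: at touchdown the girdle is rotated so the limb
  root (offset `w` from the midline) sits forward, and by liftoff it has
  rotated back — adding roughly `2w·sin(A/2)` of fore–aft root excursion per
  stance.  With the peak at mid-stance instead (φ = 0), the same excursion
  falls inside the stance where it cannot extend it, and bending only costs.

## Gait generation

Stride timing is quantized to whole frames at 30 frames/s: stance length is
`round(duty_factor × frames_per_stride)` frames (44 of 85 by default, i.e. a
measured duty factor of 51.8% ≈ 52%).  Touchdowns of the two couplets are
half a stride apart; with odd frame counts the crossing is rounded up.

Foot anchors are planned deterministically at touchdown: on the ground, at
`max_protraction` = 30° ahead of the limb root's transverse plane measured
in the girdle frame, at the lateral distance that puts the limb at 90% of
maximal reach — reachable at touchdown by construction.  During stance the
foot is held at the anchor by closed-form two-link inverse kinematics (law
of cosines); the elbow/knee branch is fixed (apex dorsal) so results are
bit-reproducible.  Swing feet interpolate root-relative from the liftoff
offset to the next anchor's offset with a half-sine vertical lift
(`swing_clearance`, default 0.02·SVL); because the interpolation is convex
in the root frame, swing never violates reach.  Limbs that are mid-cycle at
frame 0 are initialized from the analytically extrapolated previous stance,
so trajectories are periodic in the body frame from the first frame.

Stance height defaults to 0.45 × the shortest limb reach — a low, sprawling
carriage that leaves the limb enough horizontal reach for the 90% anchor
rule (the engine rejects configurations where it does not).

**Constraint flags.**  A stance frame is flagged when holding the anchor
would require the limb to stretch beyond `l1 + l2` or protract past
`max_protraction` in the girdle frame; the foot is released (clamped to the
nearest attainable point) and the violation recorded.  The same angle serves
as placement azimuth and joint limit: feet are planted *at* the protraction
limit, so any backward girdle rotation early in stance must be compensated
by forward travel.

## Feasible speed

`feasible_speed` returns the largest forward speed for which a three-stride
simulation raises no flags, to 1e-4 m/s.  Feasibility is **not monotone** in
speed: at low speed the girdle's early-stance back-rotation pushes the
planted foot past the protraction limit (forward travel is what absorbs it),
while at high speed reach fails at the end of stance.  The search therefore
scans a deterministic 101-point grid up to a reach-derived cap and bisects
the upper feasible edge; an empty feasible set returns 0 with a diagnostic.
The feasibility test uses the same closed-form body state and the same
constraint expressions as the simulator, so "no flags at the returned speed"
holds by construction (and is asserted in tests).

With the default plan this produces the characteristic rise-then-fall:
0.125 m/s with no bending, 0.167 m/s at 22.03°, rising further to ~0.22 m/s
near 50°, then collapsing to zero — above ≈52° the low-speed protraction
wall meets the high-speed reach wall and no flag-free speed exists.  The
extreme condition (59.97°) is past that point: in this model it cannot trot
at any speed.  Real animals escape by switching to undulatory locomotion;
gait switching is deliberately out of scope, so the experiment reports the
extreme row as stationary (stride and speed zero, frequency from its stride
period).  Qualitatively the orderings are the published ones — stride length
and speed: moderate > none > extreme; stride frequency highest at extreme —
but the absolute stride lengths of the original animated rig depend on its
unpublished geometry and are not reproduced.

## The three-condition experiment

Conditions none/moderate/extreme use amplitudes 0°, 22.03°, 59.97° and
stride periods of 80, 85 and 78 frames (the periods follow from the printed
stride frequencies 0.375, 0.353, 0.385 strides/s at 30 frames/s).  Every
condition shares the base gait and runs at `min(base speed, feasible
speed)`; with the default "auto" base speed each condition runs at its own
feasible maximum.  Percent changes are reported against the no-bending row.

`stride_length_decomposition` splits the measured stride kinematically, per
stance, in the frame advancing with the body tracker: the girdle
contribution is the fore–aft excursion of the limb root (touchdown minus
liftoff), the limb contribution is the fore–aft excursion of the foot
relative to the root, and the residual is the swing-phase advance; the three
parts sum to the measured stride exactly.  At zero amplitude the girdle
contribution is zero and the limb contribution equals stride × stance
fraction (the residual being the swing advance); at 22.03° the girdle
contributes ≈ `2w·sin(A/2)` ≈ 0.03 m, about 7% of the stride — within the
range reported for pelvic-rotation contributions in sprawling walkers.
These are excursion shares, not propulsive-force shares.

## Measurement layer

Ground contact = tracker height ≤ `height_tol` (1 mm) **and** per-frame
displacement ≤ `speed_tol` (0.1 mm/frame), where displacement is the smaller
of the backward and forward differences so both the touchdown and liftoff
frames classify as contact.  A touchdown event is the first frame of a
contact run preceded by at least 5 non-contact frames; the debounce absorbs
brief jitter dropouts (real swings last ~40 frames) without changing
noiseless results.  A contact run extending from frame 0 cannot be verified
as a true edge and is excluded from stride statistics when later events
exist.  Thresholds are explicit parameters: for noisy data they should be
set a few times above the noise scale (detection is exact for jitter up to
about a third of `speed_tol` at the defaults).

Reported values follow printed-table precision — lengths 3 decimals, %SVL
and percent changes 2, frequency 3 — with half-up decimal rounding
(binary-float `round` would turn 100×0.313/0.8 = 39.125 into 39.12).

## Synthetic fixtures

`generate_fixture_trace` emulates a tracker export with known ground truth:
a foot alternating programmed stance (stationary on the ground at anchors a
stride length apart) and swing (half-sine lift), plus a steadily advancing
body tracker, with optional seeded Gaussian jitter on every coordinate.  It
reproduces the schedule and noise character of tracker data, not its
artefacts: no marker occlusion, no drift, no correlated noise, no camera
distortion.  Tests passing on fixtures therefore validate the estimators'
logic and noise debouncing, not their behaviour on real capture data.

## Numerical choices and limitations

* Everything is double precision and deterministic; there is no randomness
  outside the fixture generator, which uses `numpy.random.default_rng(seed)`.
* IK tolerances: targets within 1e-9 m of the reach boundary are accepted
  (law-of-cosines arguments clipped to [-1, 1]); FK of an IK solution
  reproduces the target to < 1e-9 m.
* Constraint tolerances: reach 1e-9 m, protraction 1e-9 rad; the feasible
  speed is resolved to 1e-4 m/s.
* Problem sizes: the default experiment simulates 5 strides per condition
  and the acceptance computation 10 strides (851 frames); the engine's
  closed-form body state makes both sub-second operations.
* The tail is held straight behind the pelvis (its own wave is not
  modelled); no joint limits exist besides reach and protraction; there is
  no collision handling between limbs; the trunk wave is a pure standing
  wave (no travelling component), and gait switching (trot to undulation)
  is out of scope.
* Measured speed equals stride length × stride frequency identically in
  this engine (no-slip plus straight-line travel), so speed is not an
  independent observable as it can be for hand-animated rigs.
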
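# sprawlgait

Kinematic simulation and measurement of sprawling quadrupedal underwater
walking in a giant-salamander-like body — a stick-armature re-implementation
of an animated walking model, with no 3D-graphics dependency.

Extant giant salamanders are useful analogues for the first digit-bearing
tetrapods: large, aquatic, short-limbed, and walking with a trot-like
diagonal-couplet gait accompanied by lateral bending of the trunk.
`sprawlgait` models that gait as pure kinematics and asks a classic question
of sprawling locomotion: **how much does lateral trunk bending help?**
Moderate bending swings the girdles and lengthens the stride; excessive
bending outruns what the limbs can reach, so the gait must slow down.

## The model

* **Body** — an articulated chain in the world frame X forward / Y left / Z
  up (angles in degrees, XYZ Euler): head, a trunk of `n` lateral joints
  between the pectoral and pelvic girdles, straight tail, and four two-link
  limbs rooted `w` (one girdle half-width) lateral of each girdle.  The
  default plan is scaled to an early digit-bearing tetrapod: total length
  1.2 m, snout–vent length (SVL) 0.8 m.
* **Axial bending** — a standing wave: every trunk joint follows
  `(A/n)·sin(2π(t/T + φ))`, so the angle between the girdle axes peaks at the
  bending amplitude `A` once per stride period `T`.  The girdles sit at the
  wave's nodes: they stay on the line of travel and yaw in antiphase by
  `∓A/2`, the pelvis trailing the pectoral girdle by the bent chain's chord.
* **Gait** — a trot with duty factor 0.52 at 30 frames/s: the LF+RH couplet
  touches down together, RF+LH half a stride later.  Feet are planted at
  anchors placed `max_protraction` (30°) ahead of the limb root at 90% of
  maximal reach and held fixed by closed-form two-link inverse kinematics
  (law of cosines, dorsal elbow branch) — a strict no-slip contract.
* **Failure rule** — a stance frame is *flagged* when holding the foot would
  stretch the limb beyond its reach or protract it past `max_protraction`.
  `feasible_speed` finds the largest flag-free forward speed; the
  lateral-bending experiment caps each condition at that speed, reproducing
  deterministically the speed reduction an animator applies when the limbs
  can no longer keep up with the body.

Stride metrics are measured from virtual foot trackers exactly as in
motion-capture practice: touchdown = tracker on the ground and stationary,
stride length = XY distance between consecutive touchdowns of the same foot,
stride frequency = frame rate / frames per stride, relative stride length =
stride length / SVL.

## Worked example

```
$ sprawlgait --out out experiment
condition  bending_amplitude_deg  stride_length_m  stride_length_pct_svl  stride_frequency_hz  duty_factor  speed_m_s
     none                   0.00            0.334                   41.8                0.375        0.525      0.125
 moderate                  22.03            0.472                   59.0                0.353        0.518      0.167
  extreme                  59.97            0.000                    0.0                0.385          NaN      0.000
```

Each row runs the trot at its own largest feasible speed.  With no bending
the body plan manages 0.125 m/s.  Moderate bending (22.03° peak, the
amplitude inside the trunk-angle range of live trotting salamanders) swings
each girdle ±11°, moving the limb roots fore–aft and adding reach: the model
walks 33% faster with a 41% longer stride — stride length and speed rank
moderate > none > extreme, and only stride frequency is highest in the
extreme condition (its stride period is shortest).  At the extreme amplitude
(59.97°) no speed is flag-free: early in stance the girdle rotates back
faster than forward travel can compensate and the planted foot would exceed
the protraction limit, while faster travel breaks reach — the model cannot
trot at all and would have to switch to an undulatory gait, which this
simulator deliberately does not do.  Its row therefore reports zero stride
and speed.

The same measurements work on imported tracker data:

```
$ sprawlgait --seed 1 --out out fixtures --stride-length 0.316
$ sprawlgait measure out/fixture.csv --svl 0.8
stride_length_m,0.316
stride_length_pct_svl,39.50
stride_frequency_hz,0.353
duty_factor,0.518
speed_m_s,0.112
```

A stride of 0.316 m at SVL 0.8 m is 39.50 %SVL; 85 frames per stride at
30 frames/s is 0.353 strides/s; 44 of 85 stance frames give a duty factor of
0.518 ≈ 52%.

Trajectories export to long-format CSV and to BVH (root at the pelvic
girdle, meters, XYZ Euler channels) for use in animation tools.

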
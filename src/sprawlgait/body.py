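"""Articulated body plan and forward kinematics of the axial chain and limbs.

The body is a stick armature: a head segment, a trunk of ``n_trunk_joints``
lateral (yaw) joints spanning the pectoral-to-pelvic distance, a straight
tail, and four two-link sprawling limbs rooted at lateral offsets from the
girdles.  World frame: X forward (direction of travel), Y left, Z up, ground
plane at Z = 0.  All angles are degrees; rotations follow the intrinsic
X-then-Y-then-Z Euler convention (a rotation about the vertical is therefore
a pure ``rz``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "BodyPlan",
    "GirdleFrame",
    "FramePose",
    "AxialPose",
    "FORELIMBS",
    "HINDLIMBS",
    "LIMBS",
    "default_andrias_plan",
    "specimen_plan",
    "plan_from_dimensions",
    "scale_plan",
    "axial_forward_kinematics",
    "limb_forward_kinematics",
    "limb_root",
    "limb_segment_lengths",
    "load_body_plan",
    "save_body_plan",
]

FORELIMBS = ("LF", "RF")
HINDLIMBS = ("LH", "RH")
LIMBS = FORELIMBS + HINDLIMBS

_LENGTH_FIELDS = (
    "total_length",
    "svl",
    "head_length",
    "tail_length",
    "pectoral_position",
    "pelvic_position",
    "girdle_half_width",
    "humerus_length",
    "radius_length",
    "femur_length",
    "tibia_length",
)


def _wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    wrapped = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


@dataclass(frozen=True)
class BodyPlan:
    """Segment lengths and girdle geometry of the articulated body, meters.

    ``pectoral_position`` and ``pelvic_position`` are measured from the snout
    along the body axis; the pelvic girdle coincides with the vent, so
    ``pelvic_position`` equals the snout-vent length for a real animal.
    ``girdle_half_width`` is the lateral offset of each limb root from the
    midline.  Limb segments are stylopod and zeugopod+autopod lumped as two
    rigid links.
    """

    total_length: float
    svl: float
    head_length: float
    tail_length: float
    pectoral_position: float
    pelvic_position: float
    girdle_half_width: float
    humerus_length: float
    radius_length: float
    femur_length: float
    tibia_length: float
    n_trunk_joints: int = 6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        for name in _LENGTH_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_trunk_joints < 1:
            raise ValueError(f"n_trunk_joints must be >= 1, got {self.n_trunk_joints}")
        if not self.pectoral_position < self.pelvic_position:
            raise ValueError("pectoral_position must be < pelvic_position")
        if not self.pelvic_position <= self.svl:
            raise ValueError("pelvic_position must be <= svl")
        if not self.svl < self.total_length:
            raise ValueError("svl must be < total_length")
        span = self.pelvic_position - self.pectoral_position
        total = self.head_length + span + self.tail_length
        if abs(total - self.total_length) > 1e-9:
            raise ValueError(
                "head_length + trunk span + tail_length must equal total_length "
                f"(got {total} vs {self.total_length})"
            )
        if not self.humerus_length + self.radius_length > self.girdle_half_width:
            raise ValueError("forelimb reach must exceed girdle_half_width")
        if not self.femur_length + self.tibia_length > self.girdle_half_width:
            raise ValueError("hindlimb reach must exceed girdle_half_width")

    @property
    def trunk_span(self) -> float:
        return self.pelvic_position - self.pectoral_position

    @property
    def forelimb_reach(self) -> float:
        return self.humerus_length + self.radius_length

    @property
    def hindlimb_reach(self) -> float:
        return self.femur_length + self.tibia_length

    def limb_reach(self, limb: str) -> float:
        l1, l2 = limb_segment_lengths(self, limb)
        return l1 + l2


@dataclass(frozen=True)
class GirdleFrame:
    """World pose of a girdle: origin (x, y, z) in m and yaw about Z, degrees."""

    origin: tuple[float, float, float]
    yaw: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "yaw", _wrap_angle(self.yaw))

    @property
    def forward(self) -> np.ndarray:
        """Unit vector along the girdle's forward axis (horizontal)."""
        a = np.deg2rad(self.yaw)
        return np.array([np.cos(a), np.sin(a), 0.0])

    @property
    def left(self) -> np.ndarray:
        """Unit vector along the girdle axis toward the animal's left."""
        a = np.deg2rad(self.yaw)
        return np.array([-np.sin(a), np.cos(a), 0.0])


@dataclass
class FramePose:
    """Joint angles (XYZ Euler, degrees) and tracker world positions for one frame."""

    frame: int
    joint_angles: dict[str, tuple[float, float, float]]
    tracker_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")


@dataclass(frozen=True)
class AxialPose:
    """Result of axial forward kinematics."""

    snout: np.ndarray
    pectoral: GirdleFrame
    pelvic: GirdleFrame
    tail_tip: np.ndarray


def plan_from_dimensions(
    total_length: float, svl: float, n_trunk_joints: int = 6
) -> BodyPlan:
    """Build a body plan from total length and SVL using default proportions.

    Proportions (fractions of SVL): head 0.20, pectoral girdle at 0.25, pelvic
    girdle at the vent (1.0), girdle half-width 0.10, forelimb segments 0.11
    each, hindlimb segments 0.12 each — a short-limbed, long-tailed giant
    salamander habitus.  The tail takes up the remaining length.
    """
    head = 0.20 * svl
    pectoral = 0.25 * svl
    pelvic = svl
    tail = total_length - head - (pelvic - pectoral)
    return BodyPlan(
        total_length=total_length,
        svl=svl,
        head_length=head,
        tail_length=tail,
        pectoral_position=pectoral,
        pelvic_position=pelvic,
        girdle_half_width=0.10 * svl,
        humerus_length=0.11 * svl,
        radius_length=0.11 * svl,
        femur_length=0.12 * svl,
        tibia_length=0.12 * svl,
        n_trunk_joints=n_trunk_joints,
    )


def default_andrias_plan() -> BodyPlan:
    """Body plan scaled to an early digit-bearing tetrapod: 1.2 m total, 0.8 m SVL."""
    return plan_from_dimensions(1.2, 0.8)


def specimen_plan() -> BodyPlan:
    """Body plan at the museum specimen's size: 0.64 m total, 0.43 m SVL."""
    return plan_from_dimensions(0.64, 0.43)


def scale_plan(plan: BodyPlan, target_total_length: float) -> BodyPlan:
    """Uniformly scale every length so the total length matches the target."""
    if not target_total_length > 0:
        raise ValueError(f"target_total_length must be > 0, got {target_total_length}")
    factor = target_total_length / plan.total_length
    return replace(plan, **{f: getattr(plan, f) * factor for f in _LENGTH_FIELDS})


def limb_segment_lengths(plan: BodyPlan, limb: str) -> tuple[float, float]:
    """Proximal and distal segment lengths for a limb id (LF/RF/LH/RH)."""
    if limb in FORELIMBS:
        return plan.humerus_length, plan.radius_length
    if limb in HINDLIMBS:
        return plan.femur_length, plan.tibia_length
    raise ValueError(f"unknown limb id {limb!r}; expected one of {LIMBS}")


def limb_root(plan: BodyPlan, limb: str, girdle: GirdleFrame) -> np.ndarray:
    """World position of a limb's root: girdle origin offset half a girdle width
    along the girdle axis, to the limb's side."""
    side = 1.0 if limb[0] == "L" else -1.0
    if limb not in LIMBS:
        raise ValueError(f"unknown limb id {limb!r}; expected one of {LIMBS}")
    return np.asarray(girdle.origin) + side * plan.girdle_half_width * girdle.left


def axial_forward_kinematics(
    plan: BodyPlan,
    trunk_joint_angles: np.ndarray | list[float],
    base: GirdleFrame,
) -> AxialPose:
    """Chain the axial skeleton caudally from the pectoral girdle.

    ``base`` is the pectoral girdle pose.  The trunk span is divided into
    ``n_trunk_joints + 1`` equal segments with a yaw joint between successive
    segments; the end-tangent yaw at the pelvic girdle is the base yaw plus the
    sum of joint angles.  The snout lies ``pectoral_position`` ahead of the
    pectoral girdle along the base heading and the tail extends straight behind
    the pelvic girdle along the pelvic heading.
    """
    angles = np.asarray(trunk_joint_angles, dtype=float)
    if angles.shape != (plan.n_trunk_joints,):
        raise ValueError(
            f"expected {plan.n_trunk_joints} trunk joint angles, got {angles.shape}"
        )
    origin = np.asarray(base.origin, dtype=float)
    snout = origin + plan.pectoral_position * base.forward

    seg = plan.trunk_span / (plan.n_trunk_joints + 1)
    pos = origin.copy()
    yaw = base.yaw
    for i in range(plan.n_trunk_joints + 1):
        a = np.deg2rad(yaw)
        pos = pos - seg * np.array([np.cos(a), np.sin(a), 0.0])
        if i < plan.n_trunk_joints:
            yaw += angles[i]
    pelvic = GirdleFrame(origin=tuple(pos), yaw=yaw)
    tail_tip = pos - plan.tail_length * pelvic.forward
    return AxialPose(snout=snout, pectoral=base, pelvic=pelvic, tail_tip=tail_tip)


def limb_forward_kinematics(
    plan: BodyPlan,
    limb: str,
    girdle: GirdleFrame,
    joint_angles: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics of a two-link limb; returns (elbow/knee, foot).

    ``joint_angles`` are the limb's natural coordinates in degrees:

    * azimuth — horizontal swing of the proximal segment, measured from the
      girdle axis (pointing away from the body) toward the girdle's forward
      axis, so positive azimuth is protraction on either side;
    * elevation — angle of the proximal segment above the horizontal
      (negative when the limb reaches down to the ground);
    * flexion — elbow/knee angle between the two segments, 0 when straight,
      positive bending the distal segment ventrally (apex dorsal).

    At all-zero angles the limb sticks straight out laterally, so the foot sits
    ``girdle_half_width + l1 + l2`` from the midline.
    """
    l1, l2 = limb_segment_lengths(plan, limb)
    root = limb_root(plan, limb, girdle)
    side = 1.0 if limb[0] == "L" else -1.0
    az, el, flex = (np.deg2rad(float(a)) for a in joint_angles)

    e_away = side * girdle.left
    e_fwd = girdle.forward
    hdir = np.cos(az) * e_away + np.sin(az) * e_fwd
    zhat = np.array([0.0, 0.0, 1.0])

    d1 = np.cos(el) * hdir + np.sin(el) * zhat
    elbow = root + l1 * d1
    th2 = el - flex
    d2 = np.cos(th2) * hdir + np.sin(th2) * zhat
    foot = elbow + l2 * d2
    return elbow, foot


def _plan_to_dict(plan: BodyPlan) -> dict:
    return {f.name: getattr(plan, f.name) for f in fields(BodyPlan)}


def save_body_plan(plan: BodyPlan, path: str | Path) -> None:
    """Serialize a body plan as a flat JSON or YAML mapping (by extension)."""
    path = Path(path)
    data = _plan_to_dict(plan)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_body_plan(source: str | Path | Mapping) -> BodyPlan:
    """Read a body plan from a JSON/YAML file or a mapping; validates invariants."""
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        path = Path(source)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    known = {f.name for f in fields(BodyPlan)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown body plan field(s): {sorted(unknown)}")
    missing = known - set(data) - {"n_trunk_joints"}
    if missing:
        raise ValueError(f"missing body plan field(s): {sorted(missing)}")
    return BodyPlan(**data)
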
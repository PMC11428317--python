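"""Trot-like diagonal-couplet gait generator with sinusoidal lateral bending.

The engine produces a no-slip trajectory by closed-form body kinematics plus
per-frame two-link limb inverse kinematics:

* the trunk bends as a standing wave — all trunk joints share one sinusoid
  whose summed deflection (the angle between the pectoral and pelvic girdle
  axes) peaks at ``bending_amplitude`` once per stride, with the peak at the
  LF/RH couplet touchdown for the default ``bending_phase`` of 0.25;
* the pectoral girdle glides along the midline at the forward speed; the
  pelvic girdle trails it by the bent chain's chord.  Both girdles sit at the
  standing-wave nodes, so they yaw in antiphase (∓ half the total bend) while
  staying on the track — girdle yaw is what converts bending into stride;
* each foot is planted at a pre-planned anchor for ``round(duty_factor ×
  frames_per_stride)`` frames and held there by inverse kinematics (no slip);
  swing feet travel root-relative to the next anchor with a half-sine lift;
* a stance frame is *flagged* when the planted foot would require the limb to
  stretch beyond its reach or protract past ``max_protraction``; the foot is
  then released (clamped to the nearest attainable point) and the violation
  recorded — never silently absorbed.

Everything is deterministic: identical inputs give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .body import (
    BodyPlan,
    FramePose,
    GirdleFrame,
    LIMBS,
    limb_root,
    limb_segment_lengths,
)

__all__ = [
    "GaitParams",
    "Trajectory",
    "ReachViolation",
    "trunk_bend_angles",
    "limb_phase",
    "solve_limb_ik",
    "plan_footfall",
    "simulate",
    "max_flag_free_speed",
    "stance_height",
    "swing_clearance",
    "stance_frame_count",
    "FOOT_TRACKERS",
    "ROOT_TRACKERS",
]

_DEFAULT_OFFSETS = {"LF": 0.0, "RH": 0.0, "RF": 0.5, "LH": 0.5}

#: fraction of maximal limb reach at which feet are planted at touchdown
ANCHOR_REACH_FRACTION = 0.9
#: default girdle height above ground as a fraction of the shortest limb reach
STANCE_HEIGHT_FRACTION = 0.45

_REACH_TOL = 1e-9  # m
_AZ_TOL = 1e-9  # rad

FOOT_TRACKERS = {limb: f"foot_{limb.lower()}" for limb in LIMBS}


class ReachViolation(ValueError):
    """A limb target lies outside the reachable annulus of the two-link chain."""

    def __init__(self, message: str, shortfall: float):
        super().__init__(message)
        #: how far outside the reachable annulus the target lies, meters
        self.shortfall = shortfall


@dataclass(frozen=True)
class GaitParams:
    """Stride timing, phasing and bending parameters of the trot-like gait.

    Defaults describe the reference gait: 30 frames/s, 85 frames per stride
    (stride frequency 0.353 strides/s), duty factor 0.52, diagonal couplets
    LF+RH vs RF+LH in antiphase, and the biologically realistic moderate
    bending amplitude of 22.03 degrees peaking at couplet touchdown.
    ``forward_speed`` may be a number (m/s) or ``"auto"`` to use the largest
    flag-free speed.  ``swing_clearance`` and ``stance_height`` may be numbers
    (m) or ``"auto"`` for plan-proportional defaults.
    """

    frame_rate: float = 30.0
    frames_per_stride: int = 85
    duty_factor: float = 0.52
    phase_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSETS)
    )
    bending_amplitude: float = 22.03
    bending_phase: float = 0.25
    max_protraction: float = 30.0
    swing_clearance: float | str = "auto"
    stance_height: float | str = "auto"
    forward_speed: float | str = "auto"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if self.frames_per_stride < 4:
            raise ValueError("frames_per_stride must be >= 4")
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if set(self.phase_offsets) != set(LIMBS):
            raise ValueError(f"phase_offsets must cover exactly {LIMBS}")
        for limb, off in self.phase_offsets.items():
            if not 0.0 <= off < 1.0:
                raise ValueError(f"phase offset for {limb} must be in [0, 1)")
        if self.bending_amplitude < 0:
            raise ValueError("bending_amplitude must be >= 0")
        if not 0.0 < self.max_protraction < 90.0:
            raise ValueError("max_protraction must be in (0, 90) degrees")
        for name in ("swing_clearance", "stance_height", "forward_speed"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f'{name} must be a number or "auto"')
            elif not v >= 0:
                raise ValueError(f"{name} must be >= 0")


def stance_height(plan: BodyPlan, gait: GaitParams) -> float:
    """Girdle height above the ground during walking, meters."""
    if gait.stance_height != "auto":
        return float(gait.stance_height)
    return STANCE_HEIGHT_FRACTION * min(plan.forelimb_reach, plan.hindlimb_reach)


def swing_clearance(plan: BodyPlan, gait: GaitParams) -> float:
    """Peak vertical lift of the foot during swing, meters."""
    if gait.swing_clearance != "auto":
        return float(gait.swing_clearance)
    return 0.02 * plan.svl


def stance_frame_count(gait: GaitParams) -> int:
    """Stance duration quantized to whole frames."""
    return int(round(gait.duty_factor * gait.frames_per_stride))


def trunk_bend_angles(
    gait: GaitParams, plan: BodyPlan, frame: int | float
) -> np.ndarray:
    """Per-joint trunk yaw angles (degrees) at a frame.

    The amplitude is split equally across the trunk joints, so the summed
    deflection equals ``bending_amplitude × sin(2π(frame/frames_per_stride +
    bending_phase))`` and peaks at ``±bending_amplitude`` once per stride.
    """
    total = _total_bend(gait, np.asarray(float(frame)))
    return np.full(plan.n_trunk_joints, float(total) / plan.n_trunk_joints)


def _total_bend(gait: GaitParams, frames: np.ndarray) -> np.ndarray:
    """Summed trunk deflection (deg) = angle between the girdle axes."""
    return gait.bending_amplitude * np.sin(
        2.0 * np.pi * (frames / gait.frames_per_stride + gait.bending_phase)
    )


def limb_phase(gait: GaitParams, limb: str, frame: int | float) -> tuple[float, str]:
    """Phase fraction in [0, 1) of a limb's cycle and its stance/swing state."""
    if limb not in LIMBS:
        raise ValueError(f"unknown limb id {limb!r}; expected one of {LIMBS}")
    phase = float(
        (frame / gait.frames_per_stride + gait.phase_offsets[limb]) % 1.0
    )
    return phase, ("stance" if phase < gait.duty_factor else "swing")


def solve_limb_ik(
    plan: BodyPlan,
    limb: str,
    girdle: GirdleFrame,
    foot_target: np.ndarray | Iterable[float],
) -> tuple[float, float, float]:
    """Closed-form two-link inverse kinematics (law of cosines).

    Returns (azimuth, elevation, flexion) in degrees for
    :func:`~sprawlgait.body.limb_forward_kinematics`.  A single deterministic
    branch is used: the elbow/knee apex points dorsally (elevation takes the
    upper solution), which matches a sprawling posture and keeps results
    bit-reproducible.  Raises :class:`ReachViolation` carrying the shortfall
    when the target lies outside the reachable annulus.
    """
    l1, l2 = limb_segment_lengths(plan, limb)
    root = limb_root(plan, limb, girdle)
    side = 1.0 if limb[0] == "L" else -1.0
    w = np.asarray(foot_target, dtype=float) - root
    d = float(np.linalg.norm(w))

    if d > l1 + l2 + _REACH_TOL:
        raise ReachViolation(
            f"{limb} target {d:.6f} m from root exceeds reach {l1 + l2:.6f} m",
            shortfall=d - (l1 + l2),
        )
    min_reach = abs(l1 - l2)
    if d < min_reach - _REACH_TOL or d < 1e-12:
        raise ReachViolation(
            f"{limb} target {d:.6f} m from root is inside minimum reach "
            f"{min_reach:.6f} m",
            shortfall=min_reach - d,
        )

    e_away = side * girdle.left
    e_fwd = girdle.forward
    x_a = float(w @ e_away)
    x_f = float(w @ e_fwd)
    rho = math.hypot(x_a, x_f)
    wz = float(w[2])

    az = math.atan2(x_f, x_a)
    beta = math.atan2(wz, rho)
    cos_gamma = np.clip((l1 * l1 + d * d - l2 * l2) / (2.0 * l1 * d), -1.0, 1.0)
    gamma = math.acos(cos_gamma)
    cos_delta = np.clip((l1 * l1 + l2 * l2 - d * d) / (2.0 * l1 * l2), -1.0, 1.0)
    flexion = math.pi - math.acos(cos_delta)
    elevation = beta + gamma
    return math.degrees(az), math.degrees(elevation), math.degrees(flexion)


def plan_footfall(
    plan: BodyPlan, gait: GaitParams, girdle_at_touchdown: GirdleFrame, limb: str
) -> np.ndarray:
    """Ground anchor for a limb's next stance.

    The anchor sits on the ground plane at ``max_protraction`` degrees ahead of
    the limb root's transverse plane (measured in the girdle frame), at the
    horizontal distance that puts the limb at 90% of its maximal reach — so the
    anchor is reachable at touchdown by construction.
    """
    root = limb_root(plan, limb, girdle_at_touchdown)
    l1, l2 = limb_segment_lengths(plan, limb)
    reach = l1 + l2
    h = stance_height(plan, gait)
    radial = ANCHOR_REACH_FRACTION * reach
    if radial <= h:
        raise ValueError(
            f"stance height {h:.4f} m leaves no horizontal reach for limb {limb} "
            f"(90% reach = {radial:.4f} m)"
        )
    rho = math.sqrt(radial * radial - h * h)
    side = 1.0 if limb[0] == "L" else -1.0
    prot = math.radians(gait.max_protraction)
    direction = (
        math.cos(prot) * side * girdle_at_touchdown.left
        + math.sin(prot) * girdle_at_touchdown.forward
    )
    anchor = root + rho * direction
    anchor[2] = 0.0
    return anchor


# ---------------------------------------------------------------------------
# closed-form body state


def _axial_arrays(
    plan: BodyPlan, gait: GaitParams, speed: float, frames: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized girdle poses for arbitrary (possibly negative) frame numbers.

    The pectoral girdle advances along the midline at the forward speed; the
    pelvic girdle trails by the chord of the bent trunk chain.  For the
    symmetric standing wave the chain's lateral offsets cancel exactly, so the
    pelvic girdle also rides the midline — both girdles are wave nodes.
    """
    frames = np.asarray(frames, dtype=float)
    h = stance_height(plan, gait)
    bend = np.deg2rad(_total_bend(gait, frames))
    n = plan.n_trunk_joints
    seg = plan.trunk_span / (n + 1)
    # heading of trunk segment k (rostral to caudal): -B/2 + k*B/n
    fracs = -0.5 + np.arange(n + 1) / n
    headings = bend[..., None] * fracs  # (..., n+1)
    px = speed * frames / gait.frame_rate
    py = np.zeros_like(px)
    hx = px - seg * np.cos(headings).sum(axis=-1)
    hy = py - seg * np.sin(headings).sum(axis=-1)
    return {
        "pect_xy": np.stack([px, py], axis=-1),
        "pelv_xy": np.stack([hx, hy], axis=-1),
        "pect_yaw": -np.rad2deg(bend) / 2.0,
        "pelv_yaw": np.rad2deg(bend) / 2.0,
        "height": h,
    }


def _girdle_at(
    plan: BodyPlan, gait: GaitParams, speed: float, frame: float, girdle: str
) -> GirdleFrame:
    st = _axial_arrays(plan, gait, speed, np.asarray([float(frame)]))
    xy = st["pect_xy" if girdle == "pectoral" else "pelv_xy"][0]
    yaw = st["pect_yaw" if girdle == "pectoral" else "pelv_yaw"][0]
    return GirdleFrame(origin=(xy[0], xy[1], st["height"]), yaw=float(yaw))


def _limb_girdle_name(limb: str) -> str:
    return "pectoral" if limb[1] == "F" else "pelvic"


def _roots_and_axes(
    plan: BodyPlan, st: dict[str, np.ndarray], limb: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Limb root positions (N,3) and unit axes e_away/e_fwd (N,3) per frame."""
    side = 1.0 if limb[0] == "L" else -1.0
    fore = limb[1] == "F"
    xy = st["pect_xy"] if fore else st["pelv_xy"]
    yaw = np.deg2rad(st["pect_yaw"] if fore else st["pelv_yaw"])
    e_left = np.stack([-np.sin(yaw), np.cos(yaw), np.zeros_like(yaw)], axis=-1)
    e_fwd = np.stack([np.cos(yaw), np.sin(yaw), np.zeros_like(yaw)], axis=-1)
    e_away = side * e_left
    root = np.concatenate(
        [xy + side * plan.girdle_half_width * e_left[:, :2],
         np.full((len(yaw), 1), st["height"])],
        axis=-1,
    )
    return root, e_away, e_fwd, yaw


def _schedule_list(F: int, S: int, off: float, k_min: int, k_max: int):
    """(touchdown, liftoff) frame pairs for stride cycles k_min..k_max.

    Touchdowns occur where the limb's phase wraps through zero; with
    fractional offsets the touchdown frame is the ceiling of the crossing.
    """
    out = []
    for k in range(k_min, k_max + 1):
        t = int(math.ceil((k - off) * F))
        out.append((t, t + S))
    return out


@dataclass
class Trajectory:
    """Per-frame poses of the simulated (or imported) animation.

    ``frames`` is a contiguous sequence of :class:`FramePose` from index 0;
    ``flags`` lists (frame, limb) pairs where the stance constraint was
    violated and the foot released.  ``plan``/``gait`` are None for imported
    trajectories.
    """

    frames: list[FramePose]
    frame_rate: float
    plan: BodyPlan | None = None
    gait: GaitParams | None = None
    flags: list[tuple[int, str]] = field(default_factory=list)
    forward_speed: float | None = None

    def __post_init__(self) -> None:
        for i, fp in enumerate(self.frames):
            if fp.frame != i:
                raise ValueError("frame indices must be contiguous from 0")
        if self.frames:
            names = set(self.frames[0].tracker_positions)
            for fp in self.frames:
                if set(fp.tracker_positions) != names:
                    raise ValueError("tracker set must be constant across frames")
        self._tracker_cache: dict[str, np.ndarray] = {}

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def tracker_names(self) -> tuple[str, ...]:
        return tuple(self.frames[0].tracker_positions) if self.frames else ()

    def tracker(self, name: str) -> np.ndarray:
        """(n_frames, 3) world positions of a named tracker."""
        if name not in self._tracker_cache:
            if not self.frames or name not in self.frames[0].tracker_positions:
                raise KeyError(f"unknown tracker {name!r}")
            self._tracker_cache[name] = np.array(
                [fp.tracker_positions[name] for fp in self.frames]
            )
        return self._tracker_cache[name]

    def flagged_frames(self, limb: str | None = None) -> list[int]:
        return sorted({f for f, l in self.flags if limb is None or l == limb})


def _check_stance(
    anchor: np.ndarray,
    root: np.ndarray,
    e_away: np.ndarray,
    e_fwd: np.ndarray,
    reach: float,
    prot_rad: float,
) -> np.ndarray:
    """Boolean mask of violated stance frames (reach or protraction limit)."""
    w = anchor[None, :] - root
    d2 = np.einsum("ij,ij->i", w, w)
    over_reach = d2 > reach * reach + _REACH_TOL
    x_a = np.einsum("ij,ij->i", w, e_away)
    x_f = np.einsum("ij,ij->i", w, e_fwd)
    az = np.arctan2(x_f, x_a)
    over_prot = az > prot_rad + _AZ_TOL
    return over_reach | over_prot


def max_flag_free_speed(
    plan: BodyPlan,
    gait: GaitParams,
    n_strides: int = 3,
    speed_tol: float = 1e-4,
    grid_points: int = 100,
) -> float:
    """Largest forward speed at which the gait runs without reach/protraction
    violations, found deterministically.

    Feasibility is not monotone in speed — at low speeds the girdle's
    back-rotation early in stance can push the planted foot past the
    protraction limit, which faster forward travel absorbs — so a coarse
    grid locates the upper feasible edge and bisection refines it to
    ``speed_tol``.  Returns 0.0 when no speed is feasible (the gait cannot be
    executed flag-free at this amplitude).
    """
    reaches = {limb: plan.limb_reach(limb) for limb in LIMBS}
    S = stance_frame_count(gait)
    vcap = 2.0 * max(reaches.values()) * gait.frame_rate / max(S, 1)
    n_frames = n_strides * gait.frames_per_stride

    def feasible(v: float) -> bool:
        return not _any_violation(plan, gait, v, n_frames)

    grid = np.linspace(0.0, vcap, grid_points + 1)
    feas = [v for v in grid if feasible(float(v))]
    if not feas:
        return 0.0
    lo = float(max(feas))
    hi = min(lo + vcap / grid_points, vcap)
    if lo >= vcap:
        return vcap
    while hi - lo > speed_tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _any_violation(
    plan: BodyPlan, gait: GaitParams, speed: float, n_frames: int
) -> bool:
    prot = math.radians(gait.max_protraction)
    for limb in LIMBS:
        reach = plan.limb_reach(limb)
        for t0, t1 in _schedule_list(
            gait.frames_per_stride,
            stance_frame_count(gait),
            gait.phase_offsets[limb],
            math.floor(-gait.phase_offsets[limb]) - 1,
            math.ceil(n_frames / gait.frames_per_stride) + 1,
        ):
            fs = np.arange(max(t0, 0), min(t1, n_frames + 1))
            if len(fs) == 0:
                continue
            girdle = _girdle_at(plan, gait, speed, t0, _limb_girdle_name(limb))
            anchor = plan_footfall(plan, gait, girdle, limb)
            st = _axial_arrays(plan, gait, speed, fs)
            root, e_away, e_fwd, _ = _roots_and_axes(plan, st, limb)
            if _check_stance(anchor, root, e_away, e_fwd, reach, prot).any():
                return True
    return False


def simulate(plan: BodyPlan, gait: GaitParams, n_strides: int = 5) -> Trajectory:
    """Run the gait for ``n_strides`` strides and return the trajectory.

    Produces ``n_strides × frames_per_stride + 1`` frames so that limbs with a
    zero phase offset touch down on both the first and last frame, giving
    exactly ``n_strides`` measurable strides.  Limbs mid-cycle at frame 0 are
    initialized from the analytically extrapolated previous stance, so the
    trajectory is periodic in the body frame from the start.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    if gait.forward_speed == "auto":
        speed = max_flag_free_speed(plan, gait)
    else:
        speed = float(gait.forward_speed)

    F = gait.frames_per_stride
    n_frames = n_strides * F  # last frame index; total frames = n_frames + 1
    frames = np.arange(0, n_frames + 1)
    st = _axial_arrays(plan, gait, speed, frames.astype(float))
    h = st["height"]
    clearance = swing_clearance(plan, gait)
    prot = math.radians(gait.max_protraction)

    flags: list[tuple[int, str]] = []
    foot_pos: dict[str, np.ndarray] = {}
    limb_axes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}

    for limb in LIMBS:
        reach = plan.limb_reach(limb)
        root, e_away, e_fwd, yaw = _roots_and_axes(plan, st, limb)
        limb_axes[limb] = (root, e_away, e_fwd, yaw)
        foot = np.empty((n_frames + 1, 3))

        sched = _schedule_list(
            F,
            stance_frame_count(gait),
            gait.phase_offsets[limb],
            math.floor(-gait.phase_offsets[limb]) - 2,
            math.ceil(n_frames / F) + 1,
        )
        anchors = []
        for t0, _t1 in sched:
            girdle = _girdle_at(plan, gait, speed, t0, _limb_girdle_name(limb))
            anchors.append(plan_footfall(plan, gait, girdle, limb))

        def root_at(f: int) -> np.ndarray:
            if 0 <= f <= n_frames:
                return root[f]
            sub = _axial_arrays(plan, gait, speed, np.asarray([float(f)]))
            r, _, _, _ = _roots_and_axes(plan, sub, limb)
            return r[0]

        for idx in range(len(sched) - 1):
            t0, t_lift = sched[idx]
            t_next, _ = sched[idx + 1]
            anchor = anchors[idx]
            # stance: foot anchored unless the constraint is violated
            lift_foot = anchor
            for f in range(max(t0, 0), min(t_lift, n_frames + 1)):
                w = anchor - root[f]
                d = float(np.linalg.norm(w))
                x_a = float(w @ e_away[f])
                x_f = float(w @ e_fwd[f])
                az = math.atan2(x_f, x_a)
                if d > reach + _REACH_TOL or az > prot + _AZ_TOL:
                    flags.append((f, limb))
                    foot[f] = root[f] + min(d, reach) / d * w
                else:
                    foot[f] = anchor
                if f == t_lift - 1:
                    lift_foot = foot[f]
            # swing: root-relative interpolation to the next anchor
            lo = t_lift - 1
            rel_lo = lift_foot - root_at(lo)
            rel_td = anchors[idx + 1] - root_at(t_next)
            for f in range(max(t_lift, 0), min(t_next, n_frames + 1)):
                u = (f - lo) / (t_next - lo)
                foot[f] = (
                    root[f]
                    + (1.0 - u) * rel_lo
                    + u * rel_td
                    + np.array([0.0, 0.0, clearance * math.sin(math.pi * u)])
                )
        foot_pos[limb] = foot

    poses = _assemble_poses(plan, gait, st, foot_pos, limb_axes, n_frames)
    resolved = replace(gait, forward_speed=speed)
    return Trajectory(
        frames=poses,
        frame_rate=gait.frame_rate,
        plan=plan,
        gait=resolved,
        flags=sorted(flags),
        forward_speed=speed,
    )


def _batch_ik(
    l1: float, l2: float, w: np.ndarray, e_away: np.ndarray, e_fwd: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-link IK over frames; targets must be within reach."""
    d = np.linalg.norm(w, axis=1)
    x_a = np.einsum("ij,ij->i", w, e_away)
    x_f = np.einsum("ij,ij->i", w, e_fwd)
    rho = np.hypot(x_a, x_f)
    az = np.arctan2(x_f, x_a)
    beta = np.arctan2(w[:, 2], rho)
    cos_g = np.clip((l1 * l1 + d * d - l2 * l2) / (2.0 * l1 * d), -1.0, 1.0)
    gamma = np.arccos(cos_g)
    cos_d = np.clip((l1 * l1 + l2 * l2 - d * d) / (2.0 * l1 * l2), -1.0, 1.0)
    flex = np.pi - np.arccos(cos_d)
    return az, beta + gamma, flex


def _limb_frames(
    az: np.ndarray, el: np.ndarray, flex: np.ndarray,
    e_away: np.ndarray, e_fwd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """World rotation matrices of the proximal and distal limb segments.

    Each segment's frame has X along the segment and Z along the normal of the
    vertical plane that contains the limb, so the elbow/knee is a pure
    rotation about the shared Z.
    """
    zhat = np.array([0.0, 0.0, 1.0])
    hdir = np.cos(az)[:, None] * e_away + np.sin(az)[:, None] * e_fwd
    d1 = np.cos(el)[:, None] * hdir + np.sin(el)[:, None] * zhat
    th2 = el - flex
    d2 = np.cos(th2)[:, None] * hdir + np.sin(th2)[:, None] * zhat
    n = np.stack([hdir[:, 1], -hdir[:, 0], np.zeros(len(hdir))], axis=1)
    r1 = np.stack([d1, np.cross(n, d1), n], axis=2)
    r2 = np.stack([d2, np.cross(n, d2), n], axis=2)
    return r1, r2


def _rotz(yaw: np.ndarray) -> np.ndarray:
    c, s = np.cos(yaw), np.sin(yaw)
    zeros, ones = np.zeros_like(yaw), np.ones_like(yaw)
    return np.stack(
        [
            np.stack([c, -s, zeros], axis=1),
            np.stack([s, c, zeros], axis=1),
            np.stack([zeros, zeros, ones], axis=1),
        ],
        axis=1,
    )


def _euler_xyz(mats: np.ndarray) -> np.ndarray:
    """Batch conversion of rotation matrices to intrinsic XYZ Euler degrees."""
    return Rotation.from_matrix(mats).as_euler("XYZ", degrees=True)


_LIMB_JOINTS = {
    "LF": ("shoulder_lf", "elbow_lf"),
    "RF": ("shoulder_rf", "elbow_rf"),
    "LH": ("hip_lh", "knee_lh"),
    "RH": ("hip_rh", "knee_rh"),
}

ROOT_TRACKERS = {
    "LF": "shoulder_l",
    "RF": "shoulder_r",
    "LH": "hip_l",
    "RH": "hip_r",
}

_MID_TRACKERS = {
    "LF": "elbow_lf",
    "RF": "elbow_rf",
    "LH": "knee_lh",
    "RH": "knee_rh",
}


def _assemble_poses(
    plan: BodyPlan,
    gait: GaitParams,
    st: dict[str, np.ndarray],
    foot_pos: dict[str, np.ndarray],
    limb_axes: dict,
    n_frames: int,
) -> list[FramePose]:
    N = n_frames + 1
    h = st["height"]
    bend = _total_bend(gait, np.arange(N, dtype=float))
    per_joint = bend / plan.n_trunk_joints

    pect_yaw_rad = np.deg2rad(st["pect_yaw"])
    pelv_yaw_rad = np.deg2rad(st["pelv_yaw"])
    pect_fwd = np.stack(
        [np.cos(pect_yaw_rad), np.sin(pect_yaw_rad), np.zeros(N)], axis=1
    )
    pelv_fwd = np.stack(
        [np.cos(pelv_yaw_rad), np.sin(pelv_yaw_rad), np.zeros(N)], axis=1
    )
    pect = np.concatenate([st["pect_xy"], np.full((N, 1), h)], axis=1)
    pelv = np.concatenate([st["pelv_xy"], np.full((N, 1), h)], axis=1)
    snout = pect + plan.pectoral_position * pect_fwd
    tail_tip = pelv - plan.tail_length * pelv_fwd

    limb_data = {}
    for limb in LIMBS:
        l1, l2 = limb_segment_lengths(plan, limb)
        root, e_away, e_fwd, yaw = limb_axes[limb]
        w = foot_pos[limb] - root
        az, el, flex = _batch_ik(l1, l2, w, e_away, e_fwd)
        r1, r2 = _limb_frames(az, el, flex, e_away, e_fwd)
        rg = _rotz(yaw)
        loc1 = np.einsum("nji,njk->nik", rg, r1)  # girdle^T @ segment1
        loc2 = np.einsum("nji,njk->nik", r1, r2)  # segment1^T @ segment2
        zhat = np.array([0.0, 0.0, 1.0])
        hdir = np.cos(az)[:, None] * e_away + np.sin(az)[:, None] * e_fwd
        mid = root + l1 * (np.cos(el)[:, None] * hdir + np.sin(el)[:, None] * zhat)
        limb_data[limb] = {
            "root": root,
            "mid": mid,
            "euler1": _euler_xyz(loc1),
            "euler2": _euler_xyz(loc2),
        }

    poses = []
    for f in range(N):
        joints: dict[str, tuple[float, float, float]] = {
            "pectoral_girdle": (0.0, 0.0, float(st["pect_yaw"][f])),
            "pelvic_girdle": (0.0, 0.0, float(st["pelv_yaw"][f])),
        }
        for i in range(plan.n_trunk_joints):
            joints[f"trunk_{i + 1}"] = (0.0, 0.0, float(per_joint[f]))
        trackers: dict[str, np.ndarray] = {
            "body": pect[f].copy(),
            "pelvis": pelv[f].copy(),
            "snout": snout[f].copy(),
            "tail_tip": tail_tip[f].copy(),
        }
        for limb in LIMBS:
            data = limb_data[limb]
            jprox, jdist = _LIMB_JOINTS[limb]
            joints[jprox] = tuple(float(v) for v in data["euler1"][f])
            joints[jdist] = tuple(float(v) for v in data["euler2"][f])
            trackers[ROOT_TRACKERS[limb]] = data["root"][f].copy()
            trackers[_MID_TRACKERS[limb]] = data["mid"][f].copy()
            trackers[FOOT_TRACKERS[limb]] = foot_pos[limb][f].copy()
        poses.append(FramePose(frame=f, joint_angles=joints, tracker_positions=trackers))
    return poses
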
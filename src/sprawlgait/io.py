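"""File formats, configuration and synthetic tracker fixtures.

CSV is the canonical interchange format: long form, one row per (frame,
element), columns ``frame, time_s, element_type, name, rx, ry, rz, x, y, z``.
Joints carry XYZ Euler angles in degrees and leave the position columns empty;
trackers carry world positions in meters and leave the angle columns empty.
Values use '.' as decimal separator, 9 decimals, UTF-8.

BVH (Biovision Hierarchy) is a convenience export for animation tools: the
skeleton root sits at the pelvic girdle, offsets are in meters, and every
rotation channel triple is intrinsic X-then-Y-then-Z Euler in degrees
(channels listed ``Xrotation Yrotation Zrotation``), matching the package's
rotation convention bit for bit.  A minimal reader with forward-kinematic
replay is included for round-trip verification.

The fixture generator emulates motion-capture foot-tracker traces with known
stride parameters plus optional seeded Gaussian jitter; it stands in for
externally produced (e.g. Blender-exported) tracker data in tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .body import BodyPlan, FramePose, load_body_plan
from .experiment import Condition
from .gait import GaitParams, Trajectory

__all__ = [
    "CSV_COLUMNS",
    "FixtureSpec",
    "RunConfig",
    "export_trajectory_csv",
    "read_trajectory_csv",
    "export_bvh",
    "read_bvh",
    "generate_fixture_trace",
    "load_run_config",
]

log = logging.getLogger(__name__)

CSV_COLUMNS = ("frame", "time_s", "element_type", "name", "rx", "ry", "rz", "x", "y", "z")

_FMT = "%.9f"


def _fmt(value: float) -> str:
    return _FMT % value


def export_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the long-format CSV dialect described above."""
    path = Path(path)
    lines = [",".join(CSV_COLUMNS)]
    for fp in traj.frames:
        t = _fmt(fp.frame / traj.frame_rate)
        for name, (rx, ry, rz) in fp.joint_angles.items():
            lines.append(
                f"{fp.frame},{t},joint,{name},{_fmt(rx)},{_fmt(ry)},{_fmt(rz)},,,"
            )
        for name, pos in fp.tracker_positions.items():
            lines.append(
                f"{fp.frame},{t},tracker,{name},,,,"
                f"{_fmt(pos[0])},{_fmt(pos[1])},{_fmt(pos[2])}"
            )
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write trajectory CSV to {path}: {exc}") from exc


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Inverse of :func:`export_trajectory_csv`.

    Unknown columns are ignored with a logged warning; missing required
    columns raise a format error naming them.  The frame rate is recovered
    from the ``time_s`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"element_type": str, "name": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} is missing column(s): {missing}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        log.warning("ignoring unknown column(s) in %s: %s", path, extra)

    frames: list[FramePose] = []
    for frame_idx, group in df.groupby("frame", sort=True):
        joints = {}
        trackers = {}
        for row in group.itertuples(index=False):
            if row.element_type == "joint":
                joints[row.name] = (float(row.rx), float(row.ry), float(row.rz))
            elif row.element_type == "tracker":
                trackers[row.name] = np.array(
                    [float(row.x), float(row.y), float(row.z)]
                )
            else:
                raise ValueError(
                    f"unknown element_type {row.element_type!r} in {path}"
                )
        frames.append(
            FramePose(frame=int(frame_idx), joint_angles=joints, tracker_positions=trackers)
        )

    times = df.groupby("frame", sort=True)["time_s"].first().to_numpy()
    if len(times) >= 2:
        frame_rate = 1.0 / float(times[1] - times[0])
    else:
        frame_rate = 30.0
        log.warning("single-frame CSV %s: assuming 30 frames/s", path)
    return Trajectory(frames=frames, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# BVH


def _bvh_hierarchy(plan: BodyPlan) -> str:
    """HIERARCHY block with the root at the pelvic girdle, offsets in meters."""
    n = plan.n_trunk_joints
    seg = plan.trunk_span / (n + 1)
    hw = plan.girdle_half_width

    def off(x: float, y: float, z: float) -> str:
        return f"OFFSET {_fmt(x)} {_fmt(y)} {_fmt(z)}"

    def limb(indent: str, prox: str, dist: str, y: float, l1: float, l2: float) -> list[str]:
        i2, i3, i4 = indent + "  ", indent + "    ", indent + "      "
        return [
            f"{indent}JOINT {prox}",
            f"{indent}{{",
            f"{i2}{off(0.0, y, 0.0)}",
            f"{i2}CHANNELS 3 Xrotation Yrotation Zrotation",
            f"{i2}JOINT {dist}",
            f"{i2}{{",
            f"{i3}{off(l1, 0.0, 0.0)}",
            f"{i3}CHANNELS 3 Xrotation Yrotation Zrotation",
            f"{i3}End Site",
            f"{i3}{{",
            f"{i4}{off(l2, 0.0, 0.0)}",
            f"{i3}}}",
            f"{i2}}}",
            f"{indent}}}",
        ]

    lines = [
        "HIERARCHY",
        "ROOT pelvis",
        "{",
        f"  {off(0.0, 0.0, 0.0)}",
        "  CHANNELS 6 Xposition Yposition Zposition Xrotation Yrotation Zrotation",
        "  JOINT tail",
        "  {",
        f"    {off(0.0, 0.0, 0.0)}",
        "    CHANNELS 3 Xrotation Yrotation Zrotation",
        "    End Site",
        "    {",
        f"      {off(-plan.tail_length, 0.0, 0.0)}",
        "    }",
        "  }",
    ]
    lines += limb("  ", "hip_l", "knee_l", hw, plan.femur_length, plan.tibia_length)
    lines += limb("  ", "hip_r", "knee_r", -hw, plan.femur_length, plan.tibia_length)

    # spine chain rostral from the pelvis: one joint per trunk joint, then chest
    indent = "  "
    closers = []
    for i in range(n, 0, -1):
        lines += [
            f"{indent}JOINT spine_{i}",
            f"{indent}{{",
            f"{indent}  {off(seg, 0.0, 0.0)}",
            f"{indent}  CHANNELS 3 Xrotation Yrotation Zrotation",
        ]
        closers.append(indent)
        indent += "  "
    lines += [
        f"{indent}JOINT chest",
        f"{indent}{{",
        f"{indent}  {off(seg, 0.0, 0.0)}",
        f"{indent}  CHANNELS 3 Xrotation Yrotation Zrotation",
        f"{indent}  JOINT head",
        f"{indent}  {{",
        f"{indent}    {off(0.0, 0.0, 0.0)}",
        f"{indent}    CHANNELS 3 Xrotation Yrotation Zrotation",
        f"{indent}    End Site",
        f"{indent}    {{",
        f"{indent}      {off(plan.pectoral_position, 0.0, 0.0)}",
        f"{indent}    }}",
        f"{indent}  }}",
    ]
    lines += limb(
        indent + "  ", "shoulder_l", "elbow_l", hw, plan.humerus_length, plan.radius_length
    )
    lines += limb(
        indent + "  ", "shoulder_r", "elbow_r", -hw, plan.humerus_length, plan.radius_length
    )
    lines.append(f"{indent}}}")  # chest
    for closer in reversed(closers):
        lines.append(f"{closer}}}")  # spine joints
    lines.append("}")  # root
    return "\n".join(lines)


_BVH_LIMB_SOURCE = {
    "hip_l": "hip_lh",
    "knee_l": "knee_lh",
    "hip_r": "hip_rh",
    "knee_r": "knee_rh",
    "shoulder_l": "shoulder_lf",
    "elbow_l": "elbow_lf",
    "shoulder_r": "shoulder_rf",
    "elbow_r": "elbow_rf",
}

def export_bvh(traj: Trajectory, path: str | Path) -> None:
    """Write the trajectory as a standard BVH file.

    Requires a simulator trajectory (with an attached body plan and the
    girdle/limb joint angles the engine records).
    """
    if traj.plan is None:
        raise ValueError("BVH export requires a trajectory with an attached body plan")
    plan = traj.plan
    n = plan.n_trunk_joints
    header = _bvh_hierarchy(plan)

    lines = [header, "MOTION", f"Frames: {traj.n_frames}"]
    lines.append("Frame Time: %.6f" % (1.0 / traj.frame_rate))
    for fp in traj.frames:
        pelvis = fp.tracker_positions["pelvis"]
        pelv_yaw = fp.joint_angles["pelvic_girdle"][2]
        vals: list[float] = [pelvis[0], pelvis[1], pelvis[2], 0.0, 0.0, pelv_yaw]
        vals += [0.0, 0.0, 0.0]  # tail held straight
        for joint in ("hip_l", "knee_l", "hip_r", "knee_r"):
            vals += list(fp.joint_angles[_BVH_LIMB_SOURCE[joint]])
        # spine joints rostral: inverse of the caudally-chained trunk angles
        for i in range(n, 0, -1):
            vals += [0.0, 0.0, -fp.joint_angles[f"trunk_{i}"][2]]
        vals += [0.0, 0.0, 0.0]  # chest: heading already -B/2 after the spine
        vals += [0.0, 0.0, 0.0]  # head straight
        for joint in ("shoulder_l", "elbow_l", "shoulder_r", "elbow_r"):
            vals += list(fp.joint_angles[_BVH_LIMB_SOURCE[joint]])
        lines.append(" ".join(_fmt(v) for v in vals))
    try:
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write BVH to {path}: {exc}") from exc


@dataclass
class BvhJoint:
    """A node of a parsed BVH skeleton."""

    name: str
    offset: np.ndarray
    channels: list[str]
    children: list["BvhJoint"]
    end_site: np.ndarray | None = None


@dataclass
class BvhFile:
    """Parsed BVH: skeleton, per-frame channel values, frame time in seconds."""

    root: BvhJoint
    motion: np.ndarray  # (n_frames, n_channels)
    frame_time: float

    @property
    def n_frames(self) -> int:
        return len(self.motion)

    def joint_positions(self, frame: int) -> dict[str, np.ndarray]:
        """World positions of every joint and End Site by forward kinematics."""
        values = list(self.motion[frame])
        out: dict[str, np.ndarray] = {}

        def recurse(joint: BvhJoint, origin: np.ndarray, rot: Rotation) -> None:
            pos = origin + rot.apply(joint.offset)
            euler = [0.0, 0.0, 0.0]
            for ch in joint.channels:
                v = values.pop(0)
                if ch == "Xposition":
                    pos = pos + np.array([v, 0.0, 0.0])
                elif ch == "Yposition":
                    pos = pos + np.array([0.0, v, 0.0])
                elif ch == "Zposition":
                    pos = pos + np.array([0.0, 0.0, v])
                elif ch == "Xrotation":
                    euler[0] = v
                elif ch == "Yrotation":
                    euler[1] = v
                elif ch == "Zrotation":
                    euler[2] = v
            local = Rotation.from_euler("XYZ", euler, degrees=True)
            world = rot * local
            out[joint.name] = pos
            if joint.end_site is not None:
                out[f"{joint.name}/End"] = pos + world.apply(joint.end_site)
            for child in joint.children:
                recurse(child, pos, world)

        recurse(self.root, np.zeros(3), Rotation.identity())
        return out


def read_bvh(path: str | Path) -> BvhFile:
    """Parse a BVH file (hierarchy + motion); raises ValueError on malformed input."""
    tokens = Path(path).read_text(encoding="utf-8").split()
    it = iter(tokens)

    def expect(token: str) -> None:
        got = next(it)
        if got != token:
            raise ValueError(f"malformed BVH: expected {token!r}, got {got!r}")

    def parse_joint(name: str) -> BvhJoint:
        expect("{")
        expect("OFFSET")
        offset = np.array([float(next(it)) for _ in range(3)])
        tok = next(it)
        channels: list[str] = []
        if tok == "CHANNELS":
            count = int(next(it))
            channels = [next(it) for _ in range(count)]
            tok = next(it)
        joint = BvhJoint(name=name, offset=offset, channels=channels, children=[])
        while tok != "}":
            if tok == "JOINT":
                joint.children.append(parse_joint(next(it)))
            elif tok == "End":
                expect("Site")
                expect("{")
                expect("OFFSET")
                joint.end_site = np.array([float(next(it)) for _ in range(3)])
                expect("}")
            else:
                raise ValueError(f"malformed BVH: unexpected token {tok!r}")
            tok = next(it)
        return joint

    expect("HIERARCHY")
    expect("ROOT")
    root = parse_joint(next(it))
    expect("MOTION")
    expect("Frames:")
    n_frames = int(next(it))
    expect("Frame")
    expect("Time:")
    frame_time = float(next(it))
    rest = list(it)

    def count_channels(j: BvhJoint) -> int:
        return len(j.channels) + sum(count_channels(c) for c in j.children)

    n_ch = count_channels(root)
    if len(rest) != n_frames * n_ch:
        raise ValueError(
            f"malformed BVH: expected {n_frames * n_ch} motion values, got {len(rest)}"
        )
    motion = np.array([float(v) for v in rest]).reshape(n_frames, n_ch)
    return BvhFile(root=root, motion=motion, frame_time=frame_time)


# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic foot-tracker trace with known ground truth."""

    frames_per_stride: int = 85
    n_strides: int = 3
    stride_length: float = 0.316
    duty_factor: float = 0.52
    jitter_sd: float = 0.0
    seed: int = 0
    frame_rate: float = 30.0
    swing_lift: float = 0.03

    def __post_init__(self) -> None:
        for name in ("frames_per_stride", "n_strides", "stride_length", "duty_factor", "frame_rate", "swing_lift"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.duty_factor >= 1:
            raise ValueError("duty_factor must be < 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


def generate_fixture_trace(spec: FixtureSpec) -> Trajectory:
    """Synthetic left-hind foot + body tracker trace with programmed strides.

    The foot alternates programmed stance (on the ground, stationary at
    anchors ``stride_length`` apart) and swing (lifted on a half-sine, moving
    to the next anchor); the body tracker advances one stride length per
    stride.  Seeded Gaussian jitter of standard deviation ``jitter_sd`` is
    added to every coordinate; identical seeds give bit-identical traces.
    """
    F = spec.frames_per_stride
    S = int(round(spec.duty_factor * F))
    n_frames = spec.n_strides * F + 1
    rng = np.random.default_rng(spec.seed)

    foot = np.zeros((n_frames, 3))
    body = np.zeros((n_frames, 3))
    for f in range(n_frames):
        k, ph = divmod(f, F)
        if ph < S:
            foot[f] = (k * spec.stride_length, -0.1, 0.0)
        else:
            u = (ph - (S - 1)) / (F - (S - 1))
            foot[f] = (
                (k + u) * spec.stride_length,
                -0.1,
                spec.swing_lift * math.sin(math.pi * u),
            )
        body[f] = (spec.stride_length * f / F, 0.0, 0.05)
    if spec.jitter_sd > 0:
        foot = foot + rng.normal(0.0, spec.jitter_sd, foot.shape)
        body = body + rng.normal(0.0, spec.jitter_sd, body.shape)

    frames = [
        FramePose(
            frame=f,
            joint_angles={},
            tracker_positions={"foot_lh": foot[f], "body": body[f]},
        )
        for f in range(n_frames)
    ]
    return Trajectory(frames=frames, frame_rate=spec.frame_rate)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated inputs of a CLI run."""

    plan: BodyPlan
    gait: GaitParams
    conditions: list[Condition]
    n_strides: int = 5
    seed: int = 0
    export_csv: bool = True
    export_bvh: bool = False

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be an integer >= 0")


def _build_conditions(raw) -> list[Condition]:
    from .experiment import default_conditions

    if raw is None:
        return default_conditions()
    conditions = []
    for i, item in enumerate(raw):
        if not isinstance(item, Mapping) or "name" not in item:
            raise ValueError(f"conditions[{i}] must be a mapping with a 'name'")
        try:
            conditions.append(
                Condition(
                    name=str(item["name"]),
                    bending_amplitude=float(item.get("bending_amplitude", 0.0)),
                    frames_per_stride=item.get("frames_per_stride"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"conditions[{i}]: {exc}") from exc
    return conditions


def load_run_config(source: str | Path | Mapping | None = None) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON (or a mapping).

    Recognized keys: ``body`` (inline mapping or path to a body-plan file),
    ``gait`` (mapping of :class:`GaitParams` fields), ``conditions`` (list),
    ``n_strides``, ``seed``, ``export`` ({csv, bvh}).  Validation errors name
    the offending field.
    """
    from .body import default_andrias_plan

    if source is None:
        data: dict = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ValueError(f"config file does not exist: {path}")
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        ) or {}

    known = {"body", "gait", "conditions", "n_strides", "seed", "export"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")

    body_raw = data.get("body")
    if body_raw is None:
        plan = default_andrias_plan()
    elif isinstance(body_raw, str):
        if not Path(body_raw).exists():
            raise ValueError(f"body: referenced file does not exist: {body_raw}")
        plan = load_body_plan(body_raw)
    elif isinstance(body_raw, Mapping):
        try:
            plan = load_body_plan(body_raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"body: {exc}") from exc
    else:
        raise ValueError("body must be a mapping or a file path")

    gait_raw = data.get("gait") or {}
    if not isinstance(gait_raw, Mapping):
        raise ValueError("gait must be a mapping of gait parameters")
    try:
        gait = GaitParams(**gait_raw)
    except TypeError as exc:
        raise ValueError(f"gait: {exc}") from exc
    except ValueError as exc:
        raise ValueError(f"gait: {exc}") from exc

    export = data.get("export") or {}
    if not isinstance(export, Mapping):
        raise ValueError("export must be a mapping with boolean csv/bvh")

    try:
        return RunConfig(
            plan=plan,
            gait=gait,
            conditions=_build_conditions(data.get("conditions")),
            n_strides=int(data.get("n_strides", 5)),
            seed=int(data.get("seed", 0)),
            export_csv=bool(export.get("csv", True)),
            export_bvh=bool(export.get("bvh", False)),
        )
    except ValueError as exc:
        raise ValueError(str(exc)) from exc
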
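"""Tracker-based gait measurement: footfalls, stride length, frequency, duty
factor, speed, and trunk-bend amplitude.

All estimators work on a :class:`~sprawlgait.gait.Trajectory` regardless of
whether it came from the simulator or was imported from CSV/BVH, so externally
produced animations can be measured with the same code path.

Ground contact combines a height test with a near-zero tracker velocity test:
a foot is in contact when its tracker sits within ``height_tol`` of the ground
*and* moves less than ``speed_tol`` per frame.  The per-frame displacement is
the smaller of the backward and forward differences, so both the touchdown
frame (big step in, no step out) and the liftoff frame (no step in, big step
out) count as contact.  A pure height test would misclassify dragged feet.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .gait import FOOT_TRACKERS, Trajectory

__all__ = [
    "FootfallEvent",
    "StrideMetrics",
    "InsufficientDataError",
    "detect_footfalls",
    "contact_mask",
    "stride_lengths",
    "stride_length",
    "stride_frequency",
    "relative_stride_length",
    "duty_factor_measured",
    "mean_speed",
    "percent_change",
    "trunk_angle_series",
    "measure_stride_metrics",
]

DEFAULT_HEIGHT_TOL = 1e-3  # m
DEFAULT_SPEED_TOL = 1e-4  # m per frame


class InsufficientDataError(ValueError):
    """Raised when a trajectory holds too few events/strides for an estimator."""


def _report_round(
    numerator: float, denominator: float, decimals: int, scale: int = 1
) -> float:
    """Round ``scale * numerator / denominator`` to printed precision using
    decimal arithmetic with half-up ties.

    Binary floats turn exact decimal ratios like 100 x 0.313 / 0.8 into
    39.124999... and would round them down; printed tables round half up.
    """
    value = scale * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FootfallEvent:
    """A touchdown: the first frame of a ground-contact run of one foot."""

    limb: str
    frame: int
    position: tuple[float, float, float]


@dataclass(frozen=True)
class StrideMetrics:
    """Stride descriptors in the units of the comparison table.

    stride_length m, relative_stride_length %SVL, stride_frequency strides/s,
    duty_factor as a fraction, speed m/s.
    """

    stride_length: float
    relative_stride_length: float
    stride_frequency: float
    duty_factor: float
    speed: float

    def __post_init__(self) -> None:
        for name in ("stride_length", "stride_frequency", "speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _foot_tracker_name(traj: Trajectory, limb: str) -> str:
    name = FOOT_TRACKERS.get(limb.upper(), limb)
    if name in traj.tracker_names:
        return name
    if limb in traj.tracker_names:
        return limb
    raise ValueError(f"trajectory has no foot tracker for limb {limb!r}")


def contact_mask(
    traj: Trajectory,
    limb: str,
    height_tol: float = DEFAULT_HEIGHT_TOL,
    speed_tol: float = DEFAULT_SPEED_TOL,
) -> np.ndarray:
    """Boolean ground-contact mask per frame for one foot tracker."""
    pos = traj.tracker(_foot_tracker_name(traj, limb))
    if len(pos) == 0:
        return np.zeros(0, dtype=bool)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    big = np.inf
    back = np.concatenate([[big], step])
    fwd = np.concatenate([step, [big]])
    displacement = np.minimum(back, fwd)
    if len(pos) == 1:
        displacement = np.zeros(1)
    return (pos[:, 2] <= height_tol) & (displacement <= speed_tol)


def detect_footfalls(
    traj: Trajectory,
    limb: str,
    height_tol: float = DEFAULT_HEIGHT_TOL,
    speed_tol: float = DEFAULT_SPEED_TOL,
    min_gap: int = 5,
) -> list[FootfallEvent]:
    """Touchdown events: frames where contact begins after non-contact.

    A contact start only counts as a new touchdown when at least ``min_gap``
    non-contact frames precede it; shorter dropouts (brief noisy runs in a
    jittered trace, far shorter than any real swing) are treated as part of
    the ongoing stance.  Contact
    running from frame 0 yields a single event at frame 0.
    """
    mask = contact_mask(traj, limb, height_tol, speed_tol)
    pos = traj.tracker(_foot_tracker_name(traj, limb))
    events = []
    gap = min_gap  # frames before the trajectory count as non-contact
    for f, in_contact in enumerate(mask):
        if in_contact:
            if gap >= min_gap:
                events.append(
                    FootfallEvent(limb=limb.upper(), frame=f, position=tuple(pos[f]))
                )
            gap = 0
        else:
            gap += 1
    return events


def stride_lengths(events: list[FootfallEvent]) -> np.ndarray:
    """Horizontal (XY) distance between consecutive same-limb footfalls."""
    if len(events) < 2:
        raise InsufficientDataError(
            f"need >= 2 footfall events to measure stride length, got {len(events)}"
        )
    limbs = {e.limb for e in events}
    if len(limbs) > 1:
        raise ValueError(f"events mix limbs {sorted(limbs)}")
    pos = np.array([e.position for e in events])[:, :2]
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def stride_length(events: list[FootfallEvent]) -> float:
    """Mean stride length (m) over consecutive footfall pairs."""
    return float(stride_lengths(events).mean())


def stride_frequency(frames_per_stride: float, frame_rate: float) -> float:
    """Strides per second: frame rate over frames per stride, to 3 decimals."""
    if frames_per_stride <= 0 or frame_rate <= 0:
        raise ValueError("frames_per_stride and frame_rate must be > 0")
    return _report_round(frame_rate, frames_per_stride, 3)


def relative_stride_length(stride_length_m: float, svl: float) -> float:
    """Stride length as a percentage of snout-vent length, to 2 decimals."""
    if svl <= 0:
        raise ValueError(f"svl must be > 0, got {svl}")
    return _report_round(stride_length_m, svl, 2, scale=100)


def _complete_stride_windows(
    traj: Trajectory, limb: str, height_tol: float, speed_tol: float
) -> list[tuple[int, int]]:
    """(start, end) frame windows between verified consecutive touchdowns.

    A window starting at frame 0 is dropped when contact already runs from the
    first frame, because that touchdown cannot be verified as a true edge.
    """
    events = detect_footfalls(traj, limb, height_tol, speed_tol)
    windows = []
    for a, b in zip(events, events[1:]):
        if a.frame == 0:
            continue  # possibly a partial stance entering the trajectory
        windows.append((a.frame, b.frame))
    if not windows and len(events) >= 2:
        windows = [(events[0].frame, events[1].frame)]
    return windows


def duty_factor_measured(
    traj: Trajectory,
    limb: str,
    height_tol: float = DEFAULT_HEIGHT_TOL,
    speed_tol: float = DEFAULT_SPEED_TOL,
) -> float:
    """Stance frames over stride frames, averaged across complete strides."""
    windows = _complete_stride_windows(traj, limb, height_tol, speed_tol)
    if not windows:
        raise InsufficientDataError(
            f"no complete stride of limb {limb!r} in trajectory"
        )
    mask = contact_mask(traj, limb, height_tol, speed_tol)
    fractions = [mask[a:b].sum() / (b - a) for a, b in windows]
    return float(np.mean(fractions))


def mean_speed(
    traj: Trajectory, tracker: str = "body", frame_rate: float | None = None
) -> float:
    """Net XY displacement of a tracker divided by elapsed time, m/s."""
    if traj.n_frames < 2:
        raise InsufficientDataError("need >= 2 frames to measure speed")
    pos = traj.tracker(tracker)
    rate = traj.frame_rate if frame_rate is None else frame_rate
    dist = float(np.linalg.norm(pos[-1, :2] - pos[0, :2]))
    return dist / ((traj.n_frames - 1) / rate)


def percent_change(reference: float, new: float) -> float:
    """Relative change vs a reference, percent, to 2 decimals."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return float(
        (
            100
            * (Decimal(str(new)) - Decimal(str(reference)))
            / Decimal(str(reference))
        ).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def trunk_angle_series(traj: Trajectory) -> tuple[np.ndarray, float]:
    """Per-frame angle (deg) between the pectoral and pelvic girdle axes.

    The girdle axes are taken from the paired shoulder/hip root trackers; the
    returned peak absolute value is the measured bending amplitude.  The sign
    is positive when the pelvic axis is yawed left of the pectoral axis.
    """
    for name in ("shoulder_l", "shoulder_r", "hip_l", "hip_r"):
        if name not in traj.tracker_names:
            raise ValueError(f"trajectory lacks axial tracker {name!r}")
    ant = traj.tracker("shoulder_l") - traj.tracker("shoulder_r")
    post = traj.tracker("hip_l") - traj.tracker("hip_r")
    cross = ant[:, 0] * post[:, 1] - ant[:, 1] * post[:, 0]
    dot = ant[:, 0] * post[:, 0] + ant[:, 1] * post[:, 1]
    angles = np.degrees(np.arctan2(cross, dot))
    peak = float(np.max(np.abs(angles))) if len(angles) else 0.0
    return angles, peak


def measure_stride_metrics(
    traj: Trajectory,
    limb: str = "LH",
    svl: float | None = None,
    height_tol: float = DEFAULT_HEIGHT_TOL,
    speed_tol: float = DEFAULT_SPEED_TOL,
) -> StrideMetrics:
    """All stride metrics of one limb measured from a trajectory.

    Stride frequency is derived from the mean measured stride duration in
    frames.  ``svl`` defaults to the body plan attached to the trajectory.
    """
    if svl is None:
        if traj.plan is None:
            raise ValueError("svl must be given for trajectories without a body plan")
        svl = traj.plan.svl
    events = detect_footfalls(traj, limb, height_tol, speed_tol)
    # contact running from frame 0 is a stance already in progress, not a
    # verified touchdown edge; keep it only when nothing else is available
    if len(events) > 2 and events[0].frame == 0:
        events = events[1:]
    sl = stride_length(events)
    frames_per_stride = float(np.mean(np.diff([e.frame for e in events])))
    return StrideMetrics(
        stride_length=sl,
        relative_stride_length=relative_stride_length(sl, svl),
        stride_frequency=stride_frequency(frames_per_stride, traj.frame_rate),
        duty_factor=duty_factor_measured(traj, limb, height_tol, speed_tol),
        speed=mean_speed(traj),
    )
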
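"""The three-condition lateral-bending experiment and its analyses.

The experiment compares a trot with no (0°), moderate (22.03°) and extreme
(59.97°) peak trunk bending.  All conditions share the base gait; each runs at
the largest speed its geometry permits (``min(base speed, feasible speed)``),
which reproduces, as a deterministic rule, the manual speed reduction an
animator must apply when the limbs can no longer keep up with the body.  A
condition whose feasible speed is zero cannot trot at all in this kinematic
model (it would have to switch to an undulatory gait, which is out of scope);
its row reports zero stride length and speed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

import pandas as pd

from .body import BodyPlan
from .gait import (
    GaitParams,
    ROOT_TRACKERS,
    Trajectory,
    max_flag_free_speed,
    simulate,
)
from .metrics import (
    InsufficientDataError,
    StrideMetrics,
    _complete_stride_windows,
    contact_mask,
    measure_stride_metrics,
    percent_change,
    stride_frequency,
)

__all__ = [
    "Condition",
    "ComparisonTable",
    "default_conditions",
    "feasible_speed",
    "run_lateral_bending_experiment",
    "stride_length_decomposition",
]

log = logging.getLogger(__name__)

#: frames per stride of each published condition, from the printed stride
#: frequencies (frame rate 30 / frequency): none 0.375, moderate 0.353,
#: extreme 0.385 strides/s.
CONDITION_FRAMES = {"none": 80, "moderate": 85, "extreme": 78}


@dataclass(frozen=True)
class Condition:
    """One lateral-bending condition: a name and a peak bend amplitude."""

    name: str
    bending_amplitude: float
    frames_per_stride: int | None = None

    def __post_init__(self) -> None:
        if self.bending_amplitude < 0:
            raise ValueError("bending_amplitude must be >= 0")
        if self.frames_per_stride is not None and self.frames_per_stride < 4:
            raise ValueError("frames_per_stride must be >= 4")


def default_conditions() -> list[Condition]:
    """The three reference conditions, in order: none, moderate, extreme."""
    return [
        Condition("none", 0.0, CONDITION_FRAMES["none"]),
        Condition("moderate", 22.03, CONDITION_FRAMES["moderate"]),
        Condition("extreme", 59.97, CONDITION_FRAMES["extreme"]),
    ]


def feasible_speed(plan: BodyPlan, gait: GaitParams) -> float:
    """Largest flag-free forward speed (m/s) for a plan/gait, to 1e-4 m/s.

    Returns 0.0 with a logged diagnostic when no speed avoids reach or
    protraction violations.
    """
    v = max_flag_free_speed(plan, gait)
    if v == 0.0:
        log.warning(
            "no feasible flag-free speed at bending amplitude %.2f deg "
            "(frames_per_stride=%d); gait cannot be executed without "
            "constraint violations",
            gait.bending_amplitude,
            gait.frames_per_stride,
        )
    return v


_METRIC_FIELDS = (
    "stride_length",
    "relative_stride_length",
    "stride_frequency",
    "duty_factor",
    "speed",
)


@dataclass
class ComparisonTable:
    """Per-condition stride metrics plus percent changes vs the no-bending row."""

    conditions: list[Condition]
    rows: dict[str, StrideMetrics]
    changes: dict[str, dict[str, float]]
    speeds: dict[str, float] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "none" not in self.rows:
            raise ValueError("comparison table must contain the 'none' row")
        for metric, value in self.changes.get("none", {}).items():
            if value != 0.0:
                raise ValueError(f"changes['none'][{metric!r}] must be 0")

    def to_dataframe(self) -> pd.DataFrame:
        """Rows in the printed-table layout (lengths to 3 decimals, %SVL to 2,
        frequency to 3)."""
        records = []
        for cond in self.conditions:
            m = self.rows[cond.name]
            records.append(
                {
                    "condition": cond.name,
                    "bending_amplitude_deg": cond.bending_amplitude,
                    "stride_length_m": round(m.stride_length, 3),
                    "stride_length_pct_svl": round(m.relative_stride_length, 2),
                    "stride_frequency_hz": round(m.stride_frequency, 3),
                    "duty_factor": round(m.duty_factor, 3)
                    if not math.isnan(m.duty_factor)
                    else float("nan"),
                    "speed_m_s": round(m.speed, 3),
                    "note": self.notes.get(cond.name, ""),
                }
            )
        return pd.DataFrame.from_records(records)

    def changes_dataframe(self) -> pd.DataFrame:
        records = []
        for cond in self.conditions:
            rec = {"condition": cond.name}
            rec.update(
                {f"{k}_change_pct": v for k, v in self.changes[cond.name].items()}
            )
            records.append(rec)
        return pd.DataFrame.from_records(records)


def _condition_gait(base: GaitParams, cond: Condition) -> GaitParams:
    return replace(
        base,
        bending_amplitude=cond.bending_amplitude,
        frames_per_stride=cond.frames_per_stride or base.frames_per_stride,
    )


def run_lateral_bending_experiment(
    plan: BodyPlan,
    base_gait: GaitParams | None = None,
    conditions: list[Condition] | None = None,
    n_strides: int = 5,
    limb: str = "LH",
) -> ComparisonTable:
    """Simulate and measure every condition; assemble the comparison table.

    Each condition runs at ``min(base forward speed, feasible speed)``; a base
    speed of ``"auto"`` means every condition runs at its own feasible speed.
    Metric failures in one condition fail that row, not the table.
    """
    base_gait = base_gait or GaitParams()
    conditions = list(conditions) if conditions is not None else default_conditions()
    if not conditions:
        raise ValueError("conditions must be non-empty")
    if not any(c.bending_amplitude == 0 for c in conditions):
        raise ValueError("conditions must include a zero-amplitude (none) condition")
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")

    rows: dict[str, StrideMetrics] = {}
    speeds: dict[str, float] = {}
    notes: dict[str, str] = {}
    for cond in conditions:
        gait = _condition_gait(base_gait, cond)
        v_feasible = feasible_speed(plan, gait)
        if base_gait.forward_speed == "auto":
            v = v_feasible
        else:
            v = min(float(base_gait.forward_speed), v_feasible)
        speeds[cond.name] = v
        if v <= 0.0:
            # the condition cannot locomote flag-free at any speed: it walks
            # in place, so stride length and speed are zero by measurement
            rows[cond.name] = StrideMetrics(
                stride_length=0.0,
                relative_stride_length=0.0,
                stride_frequency=stride_frequency(
                    gait.frames_per_stride, gait.frame_rate
                ),
                duty_factor=float("nan"),
                speed=0.0,
            )
            notes[cond.name] = "no feasible flag-free speed; gait infeasible"
            continue
        try:
            traj = simulate(plan, replace(gait, forward_speed=v), n_strides=n_strides)
            rows[cond.name] = measure_stride_metrics(traj, limb=limb)
        except (InsufficientDataError, ValueError) as exc:  # fail the row only
            notes[cond.name] = f"measurement failed: {exc}"
            log.error("condition %s failed: %s", cond.name, exc)

    reference = rows.get("none")
    changes: dict[str, dict[str, float]] = {}
    for cond in conditions:
        if cond.name not in rows:
            continue
        row = rows[cond.name]
        changes[cond.name] = {}
        for metric in _METRIC_FIELDS:
            ref = getattr(reference, metric) if reference else float("nan")
            val = getattr(row, metric)
            if cond.name == "none":
                changes[cond.name][metric] = 0.0
            elif reference is None or ref == 0 or math.isnan(ref) or math.isnan(val):
                changes[cond.name][metric] = float("nan")
            else:
                changes[cond.name][metric] = percent_change(ref, val)
    return ComparisonTable(
        conditions=conditions, rows=rows, changes=changes, speeds=speeds, notes=notes
    )


def stride_length_decomposition(
    plan: BodyPlan,
    gait: GaitParams,
    traj: Trajectory,
    limb: str = "LH",
) -> tuple[float, float, float]:
    """Split stride length into girdle-rotation and limb-excursion parts.

    Purely kinematic accounting over each complete stance, in the frame moving
    with the body tracker:

    * girdle contribution — fore-aft excursion of the limb root (touchdown
      minus liftoff), i.e. how far girdle rotation retracts the hip/shoulder;
    * limb contribution — fore-aft excursion of the foot relative to the limb
      root, i.e. how far the limb itself retracts;
    * residual — the swing-phase advance, so that girdle + limb + residual
      equals the measured stride length exactly.

    Raises :class:`InsufficientDataError` for flagged trajectories or when no
    complete stride is present.
    """
    if traj.flags:
        raise InsufficientDataError(
            f"trajectory has {len(traj.flags)} flagged frames; decomposition "
            "requires a violation-free run"
        )
    windows = _complete_stride_windows(
        traj, limb, height_tol=1e-3, speed_tol=1e-4
    )
    if not windows:
        raise InsufficientDataError(f"no complete stride of limb {limb!r}")

    mask = contact_mask(traj, limb)
    root = traj.tracker(ROOT_TRACKERS[limb.upper()])
    foot = traj.tracker(f"foot_{limb.lower()}")
    body = traj.tracker("body")

    girdle_parts, limb_parts, strides = [], [], []
    for td, nxt in windows:
        lo = td
        while lo + 1 < nxt and mask[lo + 1]:
            lo += 1
        root_rel = root[:, 0] - body[:, 0]
        foot_rel = foot[:, 0] - root[:, 0]
        girdle_parts.append(root_rel[td] - root_rel[lo])
        limb_parts.append(foot_rel[td] - foot_rel[lo])
        strides.append(float(np.linalg.norm(foot[nxt, :2] - foot[td, :2])))

    girdle = float(np.mean(girdle_parts))
    limb_part = float(np.mean(limb_parts))
    residual = float(np.mean(strides)) - girdle - limb_part
    return girdle, limb_part, residual
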
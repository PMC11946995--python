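"""Tracking-based validation statistic for simulated screw loosening.

During cyclic flexion-extension loading, optical markers on the vertebra (L2)
and on each rod give 3-D reference-point trajectories.  Loosening shows up as
screw toggling: relative movement between implant and vertebra.  The
statistic is

* the per-sample relative movement ``dx_i = || x_L2 - x_rod ||`` (mm),
* its centered mean absolute value ``x_hat = mean(| dx - mean(dx) |)``
  (the mean absolute deviation of the series), and
* the loose/fixed ratio ``R_lf = x_hat_loose / x_hat_fixed``; a screw is
  declared loose when the ratio strictly exceeds the threshold (default 2,
  i.e. a doubling of relative movement).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrackedTrajectory",
    "RelativeMovementSeries",
    "LooseningAssessment",
    "synchronize",
    "relative_movement",
    "centered_mean_abs",
    "loosening_ratio",
    "assess_screws",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

BodyLabel = Literal["L2", "rod1", "rod2"]


@dataclass
class TrackedTrajectory:
    """3-D positions (mm) of one rigid body's reference point over time (s)."""

    timestamps: np.ndarray
    positions: np.ndarray
    body: str = "L2"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise ValueError("trajectory needs >= 2 timestamped samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.positions.shape != (self.timestamps.size, 3):
            raise ValueError(
                f"positions must be (n, 3), got {self.positions.shape} for "
                f"{self.timestamps.size} timestamps"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


@dataclass
class RelativeMovementSeries:
    """Euclidean implant-vertebra distances (mm) at synchronized times."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("relative movement must be non-negative")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class LooseningAssessment:
    """Per-screw loosening decision from the loose/fixed movement ratio."""

    screw_id: int
    x_hat_fixed: float
    x_hat_loose: float
    ratio: float
    threshold: float = 2.0

    @property
    def is_loose(self) -> bool:
        return self.ratio > self.threshold


def synchronize(
    traj_a: TrackedTrajectory, traj_b: TrackedTrajectory
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate two trajectories onto their common time grid.

    The grid spans the overlap of the two time ranges at the coarser of the
    two sampling rates.  Returns ``(t, pos_a, pos_b)``.
    """
    t0 = max(traj_a.timestamps[0], traj_b.timestamps[0])
    t1 = min(traj_a.timestamps[-1], traj_b.timestamps[-1])
    if t0 >= t1:
        raise ValueError(
            f"no temporal overlap between {traj_a.body} "
            f"[{traj_a.timestamps[0]:.3f}, {traj_a.timestamps[-1]:.3f}] and "
            f"{traj_b.body} [{traj_b.timestamps[0]:.3f}, {traj_b.timestamps[-1]:.3f}]"
        )
    if np.array_equal(traj_a.timestamps, traj_b.timestamps):
        return traj_a.timestamps.copy(), traj_a.positions.copy(), traj_b.positions.copy()
    dt = max(traj_a.median_dt, traj_b.median_dt)
    t = np.arange(t0, t1 + dt / 2, dt)
    t = t[t <= t1]
    pos_a = np.column_stack(
        [np.interp(t, traj_a.timestamps, traj_a.positions[:, k]) for k in range(3)]
    )
    pos_b = np.column_stack(
        [np.interp(t, traj_b.timestamps, traj_b.positions[:, k]) for k in range(3)]
    )
    return t, pos_a, pos_b


def relative_movement(
    traj_l2: TrackedTrajectory, traj_rod: TrackedTrajectory
) -> RelativeMovementSeries:
    """Per-sample Euclidean distance between vertebra and rod points (mm)."""
    _, pos_l2, pos_rod = synchronize(traj_l2, traj_rod)
    if pos_l2.shape != pos_rod.shape:
        raise ValueError("synchronized trajectories have mismatched lengths")
    return RelativeMovementSeries(np.linalg.norm(pos_l2 - pos_rod, axis=1))


def centered_mean_abs(series: RelativeMovementSeries | np.ndarray) -> float:
    """Centered mean absolute relative movement x_hat (mm).

    The mean absolute deviation of the distance series: invariant to constant
    offsets (marker standoff), linear in the toggling amplitude.
    """
    values = series.values if isinstance(series, RelativeMovementSeries) else np.asarray(series, dtype=np.float64)
    if values.size < 2:
        raise ValueError(f"need >= 2 synchronized measurements, got {values.size}")
    return float(np.mean(np.abs(values - values.mean())))


def loosening_ratio(
    x_hat_loose: float,
    x_hat_fixed: float,
    threshold: float = 2.0,
    screw_id: int = 1,
) -> LooseningAssessment:
    """Loose/fixed movement ratio with strict-threshold decision."""
    if x_hat_fixed <= 0:
        raise ValueError(
            f"x_hat_fixed must be positive to form a ratio, got {x_hat_fixed}"
        )
    if x_hat_loose < 0:
        raise ValueError(f"x_hat_loose must be non-negative, got {x_hat_loose}")
    return LooseningAssessment(
        screw_id=screw_id,
        x_hat_fixed=float(x_hat_fixed),
        x_hat_loose=float(x_hat_loose),
        ratio=float(x_hat_loose) / float(x_hat_fixed),
        threshold=threshold,
    )


TrajectoryPair = tuple[TrackedTrajectory, TrackedTrajectory]  # (L2, rod)


def assess_screws(
    screw_trajectories: Mapping[int, Mapping[str, TrajectoryPair]],
    threshold: float = 2.0,
) -> list[LooseningAssessment]:
    """Run the full statistic for each screw.

    ``screw_trajectories[screw_id][condition]`` is an (L2, rod) trajectory
    pair; both ``"fixed"`` and ``"loose"`` must be present for every screw.
    """
    out = []
    for screw_id in sorted(screw_trajectories):
        pairs = screw_trajectories[screw_id]
        for cond in ("fixed", "loose"):
            if cond not in pairs:
                raise ValueError(f"screw {screw_id}: missing {cond!r} trajectories")
        x_hat = {
            cond: centered_mean_abs(relative_movement(*pairs[cond]))
            for cond in ("fixed", "loose")
        }
        out.append(
            loosening_ratio(
                x_hat["loose"], x_hat["fixed"], threshold=threshold, screw_id=screw_id
            )
        )
    return out


def write_trajectory_csv(traj: TrackedTrajectory, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": traj.timestamps,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "z": traj.positions[:, 2],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_trajectory_csv(path: str | Path, body: str = "L2") -> TrackedTrajectory:
    """Read a ``t,x,y,z`` trajectory CSV (seconds, millimetres)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse trajectory CSV {path}: {exc}") from exc
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return TrackedTrajectory(
        timestamps=df["t"].to_numpy(),
        positions=df[["x", "y", "z"]].to_numpy(),
        body=body,
    )
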
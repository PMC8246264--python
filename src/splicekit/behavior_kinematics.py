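"""Swim-test kinematics from frame-level tracking of a 5-minute novel-tank assay.

Five summary statistics per fish: total swim distance; percent of time
actively swimming after removing pauses (a pause is at least 20 consecutive
frames — 2 s at 10 fps — with no between-frame speed greater than 1.5 cm/s,
both bounds taken literally: a 19-frame slow run is not a pause and a speed
of exactly 1.5 cm/s does not break one); mean speed during active swimming;
fastest speed, defined as the best mean over 100 consecutive frames (50- and
30-frame windows and a top-30 1-s-bin mode are available as robustness
variants); and a vertical position index where 0 is the tank bottom and 100
the surface.

Tracking gaps (dropped frames) make the spanning speed undefined: an
undefined speed terminates any pause run, is excluded from speed averages,
invalidates fastest-speed windows that contain it, and contributes no
distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import TankGeometry, TrajectoryFile

__all__ = [
    "PauseSegment",
    "KinematicsSummary",
    "frame_speeds",
    "detect_pauses",
    "percent_time_active",
    "active_speed",
    "fastest_window_speed",
    "vertical_position_index",
    "total_distance",
    "summarize",
]

PAUSE_MIN_FRAMES = 20
PAUSE_SPEED_THRESHOLD = 1.5  # cm/s
FASTEST_WINDOW_FRAMES = 100


@dataclass(frozen=True)
class PauseSegment:
    """Maximal run of sub-threshold between-frame speeds, half-open indices."""

    start_frame: int
    end_frame: int
    duration_s: float

    def __len__(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class KinematicsSummary:
    total_distance_cm: float
    percent_time_active: float
    active_speed_cm_s: float
    fastest_speed_cm_s: float
    vertical_position_index: float
    pause_min_frames: int = PAUSE_MIN_FRAMES
    pause_speed_threshold: float = PAUSE_SPEED_THRESHOLD
    fastest_window_frames: int = FASTEST_WINDOW_FRAMES


def frame_speeds(traj: TrajectoryFile) -> np.ndarray:
    """Between-frame speeds in cm/s; NaN where a tracking gap intervenes."""
    if len(traj) < 2:
        raise ValueError("need at least 2 frames to measure speed")
    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    speeds = np.hypot(dx, dy) * traj.fps
    speeds[traj.gap_after] = np.nan
    return speeds


def detect_pauses(
    speeds: np.ndarray,
    min_frames: int = PAUSE_MIN_FRAMES,
    threshold: float = PAUSE_SPEED_THRESHOLD,
    fps: float = 10.0,
) -> list[PauseSegment]:
    """Maximal runs of >= min_frames consecutive speeds not exceeding threshold.

    The bound is strict in the exceedance direction: a speed equal to the
    threshold stays inside a pause run. Undefined (NaN) speeds break runs.
    """
    slow = np.asarray(speeds) <= threshold  # NaN compares False
    out: list[PauseSegment] = []
    i = 0
    n = slow.size
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            if j - i >= min_frames:
                out.append(PauseSegment(i, j, (j - i) / fps))
            i = j
        else:
            i += 1
    return out


def _paused_mask(n: int, pauses: Sequence[PauseSegment]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for p in pauses:
        mask[p.start_frame : p.end_frame] = True
    return mask


def percent_time_active(
    traj: TrajectoryFile, pauses: Sequence[PauseSegment]
) -> float:
    """100 × fraction of the record outside detected pauses."""
    speeds_n = len(traj) - 1
    if speeds_n < 1:
        raise ValueError("need at least 2 frames")
    paused = _paused_mask(speeds_n, pauses).sum()
    return 100.0 * (speeds_n - paused) / speeds_n


def active_speed(traj: TrajectoryFile, pauses: Sequence[PauseSegment]) -> float:
    """Mean between-frame speed outside pauses (undefined speeds excluded)."""
    speeds = frame_speeds(traj)
    mask = ~_paused_mask(speeds.size, pauses) & ~np.isnan(speeds)
    if not mask.any():
        raise ValueError("no active frames in record")
    return float(speeds[mask].mean())


def fastest_window_speed(
    speeds: np.ndarray,
    window: int = FASTEST_WINDOW_FRAMES,
    mode: str = "window",
    fps: float = 10.0,
    top_n_seconds: int = 30,
) -> float:
    """Fastest sustained speed.

    ``mode="window"``: maximum over all length-``window`` contiguous runs of
    the mean speed (runs containing an undefined speed are skipped).
    ``mode="top-n-seconds"``: mean of the ``top_n_seconds`` highest
    non-overlapping 1-s-bin mean speeds.
    """
    speeds = np.asarray(speeds, dtype=float)
    if mode == "top-n-seconds":
        per_bin = int(round(fps))
        n_bins = speeds.size // per_bin
        if n_bins < 1:
            raise ValueError("record shorter than one 1-s bin")
        bins = speeds[: n_bins * per_bin].reshape(n_bins, per_bin)
        means = np.nanmean(bins, axis=1)
        means = means[~np.isnan(means)]
        top = np.sort(means)[::-1][: min(top_n_seconds, means.size)]
        return float(top.mean())
    if mode != "window":
        raise ValueError(f"unknown mode {mode!r}")
    if speeds.size < window:
        raise ValueError(
            f"record of {speeds.size} speeds shorter than window {window}"
        )
    csum = np.concatenate([[0.0], np.nancumsum(speeds)])
    bad = np.concatenate([[0], np.cumsum(np.isnan(speeds))])
    totals = csum[window:] - csum[:-window]
    has_gap = (bad[window:] - bad[:-window]) > 0
    valid = totals[~has_gap]
    if valid.size == 0:
        raise ValueError("every window contains an undefined speed")
    return float(valid.max() / window)


def vertical_position_index(
    traj: TrajectoryFile, tank: TankGeometry | None = None, tolerance: float = 0.05
) -> float:
    """Mean height above the tank bottom on a 0 (bottom) – 100 (top) scale."""
    tank = tank or traj.tank
    depth = tank.depth_cm
    slack = tolerance * depth
    if traj.y_cm.min() < -slack or traj.y_cm.max() > depth + slack:
        raise ValueError(
            "y positions fall outside the tank depth beyond tolerance; "
            "check px_per_cm calibration and flip_y"
        )
    y = np.clip(traj.y_cm, 0.0, depth)
    return float(100.0 * (y / depth).mean())


def total_distance(traj: TrajectoryFile) -> float:
    """Summed between-frame displacement in cm (pauses included, gaps excluded)."""
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    steps = np.hypot(dx, dy)
    steps[traj.gap_after] = 0.0
    return float(steps.sum())


def summarize(
    traj: TrajectoryFile,
    pause_min_frames: int = PAUSE_MIN_FRAMES,
    pause_speed_threshold: float = PAUSE_SPEED_THRESHOLD,
    fastest_window_frames: int = FASTEST_WINDOW_FRAMES,
) -> KinematicsSummary:
    """The five per-fish swim-test statistics in one pass."""
    speeds = frame_speeds(traj)
    pauses = detect_pauses(
        speeds, pause_min_frames, pause_speed_threshold, fps=traj.fps
    )
    return KinematicsSummary(
        total_distance_cm=total_distance(traj),
        percent_time_active=percent_time_active(traj, pauses),
        active_speed_cm_s=active_speed(traj, pauses),
        fastest_speed_cm_s=fastest_window_speed(
            speeds, fastest_window_frames, fps=traj.fps
        ),
        vertical_position_index=vertical_position_index(traj),
        pause_min_frames=pause_min_frames,
        pause_speed_threshold=pause_speed_threshold,
        fastest_window_frames=fastest_window_frames,
    )
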
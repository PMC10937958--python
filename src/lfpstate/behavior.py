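"""Open-field locomotion metrics from pose-tracking tables.

The animal's position is the per-frame average of all tracked body parts;
speed is the frame-to-frame centroid displacement times the frame rate.
Locomotion bouts are maximal runs with speed >= 2 cm/s lasting >= 0.5 s.
Turning bias is the signed sum of frame-to-frame heading changes of the
centroid displacement (positive = counterclockwise), with low-speed frames
excluded because displacement direction is undefined when the animal is
still.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter


@dataclass
class PoseTrack:
    """Pose-estimation export: per-frame x/y (cm) for each body part.

    ``data`` has MultiIndex columns (bodypart, coord) with coord in
    {x, y, likelihood?}; rows are contiguous frames.
    """

    data: pd.DataFrame
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("data columns must be (bodypart, coord) MultiIndex")

    @property
    def body_parts(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @classmethod
    def from_dlc_csv(cls, path: str | Path, fps: float = 25.0,
                     scale_cm_per_unit: float = 1.0) -> "PoseTrack":
        """Read the 3-row-header (scorer/bodyparts/coords) CSV dialect."""
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        df.columns = pd.MultiIndex.from_tuples(
            [(bp, coord) for _, bp, coord in df.columns],
            names=["bodypart", "coord"])
        xy = df.columns.get_level_values(1).isin(["x", "y"])
        df.loc[:, xy] = df.loc[:, xy] * scale_cm_per_unit
        return cls(data=df.reset_index(drop=True), fps=fps)

    @classmethod
    def from_long_csv(cls, path: str | Path, fps: float = 25.0) -> "PoseTrack":
        """Read long format (frame, bodypart, x, y[, likelihood])."""
        long = pd.read_csv(path)
        wide = long.pivot(index="frame", columns="bodypart",
                          values=[c for c in ("x", "y", "likelihood")
                                  if c in long.columns])
        wide.columns = pd.MultiIndex.from_tuples(
            [(bp, coord) for coord, bp in wide.columns],
            names=["bodypart", "coord"])
        return cls(data=wide.sort_index().reset_index(drop=True), fps=fps)

    def to_dlc_csv(self, path: str | Path, scorer: str = "synthetic") -> None:
        out = self.data.copy()
        out.columns = pd.MultiIndex.from_tuples(
            [(scorer, bp, coord) for bp, coord in out.columns],
            names=["scorer", "bodyparts", "coords"])
        out.to_csv(path)


@dataclass
class BoutConfig:
    min_speed: float = 2.0        # cm/s
    min_duration: float = 0.5     # s
    smoothing_frames: int = 5     # centered median filter; 1 = raw

    def __post_init__(self) -> None:
        if self.min_speed <= 0 or self.min_duration <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Bout:
    start_frame: int      # index into the speed series
    end_frame: int        # exclusive
    duration_s: float
    mean_speed: float     # cm/s
    distance_cm: float


def average_position(track: PoseTrack, max_gap_frames: int = 10) -> np.ndarray:
    """Per-frame centroid: mean of available body-part coordinates (cm).

    Frames where every part is missing are linearly interpolated (gaps up to
    ``max_gap_frames``; longer gaps stay NaN so bouts split there).
    """
    parts = track.body_parts
    xs = np.stack([track.data[(p, "x")].to_numpy(float) for p in parts])
    ys = np.stack([track.data[(p, "y")].to_numpy(float) for p in parts])
    with np.errstate(invalid="ignore"):
        cx = np.nanmean(xs, axis=0)
        cy = np.nanmean(ys, axis=0)
    out = np.column_stack([cx, cy])
    bad = ~np.isfinite(out).all(axis=1)
    if bad.any():
        idx = np.arange(len(out))
        runs = np.split(idx[bad], np.flatnonzero(np.diff(idx[bad]) > 1) + 1)
        for run in runs:
            if run.size == 0 or run.size > max_gap_frames:
                continue
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= len(out):
                continue
            w = (run - lo) / (hi - lo)
            out[run] = (1 - w)[:, None] * out[lo] + w[:, None] * out[hi]
    return out


def compute_speed(centroid: np.ndarray, fps: float,
                  smoothing_frames: int = 1) -> np.ndarray:
    """Centroid speed (cm/s): displacement between consecutive frames x fps.

    The series has length n_frames - 1; element i is the speed over the step
    from frame i to i+1.  An odd ``smoothing_frames`` > 1 applies a centered
    median filter (tracking-jitter suppression).
    """
    if len(centroid) < 2:
        raise ValueError("need at least two frames")
    disp = np.hypot(*np.diff(centroid, axis=0).T)
    speed = disp * fps
    if smoothing_frames > 1:
        speed = median_filter(speed, size=smoothing_frames, mode="nearest")
    return speed


def detect_bouts(speed: np.ndarray, fps: float,
                 config: BoutConfig | None = None) -> list[Bout]:
    """Maximal runs with speed >= min_speed lasting >= min_duration.

    The frame-count threshold is ceil(min_duration * fps) (13 frames at the
    default 0.5 s / 25 fps).  NaN speed frames terminate runs.
    """
    config = config or BoutConfig()
    if config.smoothing_frames > 1:
        speed = median_filter(np.asarray(speed, float),
                              size=config.smoothing_frames, mode="nearest")
    ok = np.nan_to_num(speed, nan=-1.0) >= config.min_speed
    min_frames = int(np.ceil(config.min_duration * fps))
    bouts: list[Bout] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        if i1 - i0 < min_frames:
            continue
        seg = speed[i0:i1]
        bouts.append(Bout(start_frame=int(i0), end_frame=int(i1),
                          duration_s=(i1 - i0) / fps,
                          mean_speed=float(np.mean(seg)),
                          distance_cm=float(np.sum(seg)) / fps))
    return bouts


def bout_statistics(bouts: list[Bout], window_s: float) -> dict:
    """Summary over an observation window: rate, mean speed/duration/distance.

    ``rate_per_min`` counts bout initiations per minute; with no bouts the
    means are reported as missing (NaN), not zero.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = len(bouts)
    out = {"n_bouts": n, "rate_per_min": n / (window_s / 60.0)}
    if n == 0:
        out.update(mean_speed=np.nan, mean_duration_s=np.nan,
                   mean_distance_cm=np.nan, locomotion_cm_per_s=0.0)
    else:
        out.update(
            mean_speed=float(np.mean([b.mean_speed for b in bouts])),
            mean_duration_s=float(np.mean([b.duration_s for b in bouts])),
            mean_distance_cm=float(np.mean([b.distance_cm for b in bouts])),
            locomotion_cm_per_s=float(sum(b.distance_cm for b in bouts)) / window_s,
        )
    return out


def cumulative_turning(centroid: np.ndarray, fps: float,
                       min_speed: float = 1.0) -> float:
    """Signed cumulative heading change (degrees; positive = counterclockwise).

    Heading is the direction of centroid displacement; frames moving slower
    than ``min_speed`` are excluded (direction is noise-dominated when
    still).  Raises if heading is undefined for more than half the frames.
    """
    steps = np.diff(centroid, axis=0)
    speed = np.hypot(*steps.T) * fps
    valid = speed > min_speed
    if valid.sum() < 2 or valid.sum() < 0.5 * len(valid):
        raise ValueError("heading undefined for more than half of the frames")
    heading = np.arctan2(steps[valid, 1], steps[valid, 0])
    dh = np.angle(np.exp(1j * np.diff(heading)))
    return float(np.degrees(np.sum(dh)))


def summarize_track(track: PoseTrack, config: BoutConfig | None = None) -> dict:
    """Convenience end-to-end summary for one session's track."""
    config = config or BoutConfig()
    centroid = average_position(track)
    speed = compute_speed(centroid, track.fps)
    bouts = detect_bouts(speed, track.fps, config)
    stats = bout_statistics(bouts, window_s=track.n_frames / track.fps)
    try:
        stats["cumulative_turning_deg"] = cumulative_turning(centroid, track.fps)
    except ValueError:
        stats["cumulative_turning_deg"] = np.nan
    return stats
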
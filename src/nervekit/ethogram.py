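"""Rule-based larval ethogram classification.

Implements the behavioral definitions used for FIM-tracked Drosophila larvae:

* stop       — no centroid movement for at least 5 frames
* head bend  — bending deviation |180° - γ| ≥ 20° for at least 5 frames
* turn       — a stop of ≥ 4 frames containing a ≥ 20° bend, followed by
               ≥ 20 frames of forward locomotion in a new direction (≥ 20°
               heading change)
* coil       — the head touches the tail tip (head–tail distance below a
               small fraction of the spine length)

γ is the bending angle at the spine midpoint: 180° means a straight larva.
"No movement" is operationalized as a per-frame centroid step below
``move_eps_mm`` (default 5% of the resting spine length) — scale-free and
robust to tracker pixel noise.  The coil criterion uses a head–tail distance
of at most 15% of the spine length, since a literal zero distance never
occurs in sampled data.  Both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .trackio import LarvaTrack

__all__ = [
    "BehaviorBout",
    "EthogramParams",
    "bending_angle",
    "bending_series",
    "detect_stops",
    "detect_head_bends",
    "detect_turns",
    "detect_coils",
    "detect_all",
]

BOUT_KINDS = ("stop", "head_bend", "turn", "coil")


@dataclass(frozen=True)
class BehaviorBout:
    """A typed behavioral interval, frame-inclusive on both ends."""

    kind: str
    start_frame: int
    end_frame: int
    peak_deviation_deg: float = float("nan")

    def __post_init__(self):
        if self.kind not in BOUT_KINDS:
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.start_frame > self.end_frame:
            raise ValueError("bout start after end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame + 1)


@dataclass(frozen=True)
class EthogramParams:
    """Thresholds of the rule-based classifiers (frame counts at 10 fps)."""

    move_eps_frac: float = 0.05  # fraction of resting spine length per frame
    move_eps_mm: float | None = None  # absolute override
    bend_thresh_deg: float = 20.0
    min_bend_frames: int = 5
    min_stop_frames: int = 5
    turn_stop_frames: int = 4
    turn_forward_frames: int = 20
    turn_heading_deg: float = 20.0
    coil_dist_frac: float = 0.15
    heading_smooth_frames: int = 3
    pre_stop_heading_frames: int = 10
    smooth_bend_frames: int = 0  # optional moving average before thresholding

    def __post_init__(self):
        for name in (
            "move_eps_frac", "bend_thresh_deg", "min_bend_frames", "min_stop_frames",
            "turn_stop_frames", "turn_forward_frames", "turn_heading_deg",
            "coil_dist_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def move_eps_for(self, track: LarvaTrack) -> float:
        if self.move_eps_mm is not None:
            return self.move_eps_mm
        ref_len = float(np.nanmedian(track.spine_len_mm))
        if not np.isfinite(ref_len) or ref_len <= 0:
            raise GeometryError("cannot derive move_eps: no valid spine length")
        return self.move_eps_frac * ref_len


def bending_angle(spine: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Interior angle γ (degrees, in [0, 180]) at the spine midpoint.

    Measured between the chords midpoint→head and midpoint→tail; a collinear
    spine gives 180°, a hairpin fold gives 0°.
    """
    pts = np.asarray(spine, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise GeometryError("spine must be an (K>=3, 2) point array")
    mid = pts[pts.shape[0] // 2]
    u = pts[0] - mid
    v = pts[-1] - mid
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("coincident spine points at midpoint/endpoint")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def bending_series(track: LarvaTrack, params: EthogramParams | None = None) -> np.ndarray:
    """Per-frame bending deviation |180° − γ|; NaN on invalid frames."""
    params = params or EthogramParams()
    dev = np.abs(180.0 - track.bending_deg)
    dev = np.where(track.valid, dev, np.nan)
    w = params.smooth_bend_frames
    if w and w > 1:
        kernel = np.ones(w) / w
        dev = np.convolve(np.nan_to_num(dev, nan=0.0), kernel, mode="same")
    return dev


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs in a boolean array as inclusive (start, end) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def motionless_runs(track: LarvaTrack, eps: float) -> list[tuple[int, int]]:
    """Maximal frame intervals during which the centroid does not move.

    A run of m consecutive centroid steps smaller than ``eps`` means the larva
    held (essentially) one position over m+1 frames; the returned inclusive
    interval covers those m+1 frames.  NaN steps (invalid frames) break runs.
    """
    d = track.displacements_mm()  # step i joins frames i and i+1
    small = np.nan_to_num(d, nan=np.inf) < eps
    return [(s, e + 1) for s, e in _runs(small)]


def detect_stops(track: LarvaTrack, params: EthogramParams | None = None) -> list[BehaviorBout]:
    """Maximal motionless runs lasting at least ``min_stop_frames``."""
    params = params or EthogramParams()
    eps = params.move_eps_for(track)
    dev = bending_series(track, params)
    bouts = []
    for s, e in motionless_runs(track, eps):
        if e - s + 1 >= params.min_stop_frames:
            peak = float(np.nanmax(dev[s : e + 1])) if np.any(np.isfinite(dev[s : e + 1])) else float("nan")
            bouts.append(BehaviorBout("stop", s, e, peak))
    return bouts


def detect_head_bends(track: LarvaTrack, params: EthogramParams | None = None) -> list[BehaviorBout]:
    """Maximal runs with bending deviation ≥ 20° lasting at least 5 frames."""
    params = params or EthogramParams()
    dev = bending_series(track, params)
    mask = np.nan_to_num(dev, nan=0.0) >= params.bend_thresh_deg
    bouts = []
    for s, e in _runs(mask):
        if e - s + 1 >= params.min_bend_frames:
            bouts.append(BehaviorBout("head_bend", s, e, float(np.nanmax(dev[s : e + 1]))))
    return bouts


def heading_series(track: LarvaTrack, params: EthogramParams | None = None) -> np.ndarray:
    """Per-step heading (degrees) of the centroid path, length n-1.

    Displacement vectors are box-smoothed over ``heading_smooth_frames``
    steps before taking the angle; steps with no net movement give NaN.
    """
    params = params or EthogramParams()
    vec = np.diff(track.centroid_mm, axis=0)
    w = max(1, params.heading_smooth_frames)
    if w > 1:
        kernel = np.ones(w)
        sx = np.convolve(vec[:, 0], kernel, mode="same")
        sy = np.convolve(vec[:, 1], kernel, mode="same")
        vec = np.column_stack([sx, sy])
    ang = np.degrees(np.arctan2(vec[:, 1], vec[:, 0]))
    ang[np.linalg.norm(vec, axis=1) == 0] = np.nan
    return ang


def _circ_mean_deg(angles: np.ndarray) -> float:
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        return float("nan")
    rad = np.radians(angles)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def _ang_diff_deg(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def detect_turns(track: LarvaTrack, params: EthogramParams | None = None) -> list[BehaviorBout]:
    """Stop-and-redirect events.

    A turn is a motionless run of at least ``turn_stop_frames`` whose bending
    deviation reaches ≥ ``bend_thresh_deg`` within the run, followed by at
    least ``turn_forward_frames`` moving frames whose mean heading differs
    from the pre-stop heading by ≥ ``turn_heading_deg``.  The reported
    interval is the motionless run.
    """
    params = params or EthogramParams()
    n = track.n_frames
    eps = params.move_eps_for(track)
    dev = bending_series(track, params)
    head = heading_series(track, params)
    d = track.displacements_mm()
    moving = np.nan_to_num(d, nan=0.0) >= eps

    bouts = []
    for s, e in motionless_runs(track, eps):
        if e - s + 1 < params.turn_stop_frames:
            continue
        seg_dev = dev[s : e + 1]
        if not np.any(np.nan_to_num(seg_dev, nan=0.0) >= params.bend_thresh_deg):
            continue
        # pre-stop heading: up to `pre_stop_heading_frames` moving steps before the run
        pre_steps = np.arange(max(0, s - params.pre_stop_heading_frames), s)
        pre_steps = pre_steps[moving[pre_steps]]
        if pre_steps.size < 3:
            continue
        pre_heading = _circ_mean_deg(head[pre_steps])
        # post-stop locomotion: the first `turn_forward_frames` steps after frame e
        post_steps = np.arange(e, min(n - 1, e + params.turn_forward_frames))
        if post_steps.size < params.turn_forward_frames:
            continue
        if not np.all(moving[post_steps]):
            continue
        post_heading = _circ_mean_deg(head[post_steps])
        if not (np.isfinite(pre_heading) and np.isfinite(post_heading)):
            continue
        if _ang_diff_deg(post_heading, pre_heading) >= params.turn_heading_deg:
            peak = float(np.nanmax(seg_dev))
            bouts.append(BehaviorBout("turn", s, e, peak))
    return bouts


def coil_mask(track: LarvaTrack, params: EthogramParams | None = None) -> np.ndarray:
    """Boolean per-frame coil flag: head–tail distance ≤ coil_dist_frac × spine length."""
    params = params or EthogramParams()
    head = track.spine_mm[:, 0]
    tail = track.spine_mm[:, -1]
    dist = np.linalg.norm(head - tail, axis=1)
    thresh = params.coil_dist_frac * track.spine_len_mm
    mask = dist <= thresh
    mask &= track.valid
    mask &= np.isfinite(dist)
    return mask


def detect_coils(track: LarvaTrack, params: EthogramParams | None = None) -> list[BehaviorBout]:
    """Maximal runs of coiled frames (any length ≥ 1)."""
    params = params or EthogramParams()
    dev = bending_series(track, params)
    bouts = []
    for s, e in _runs(coil_mask(track, params)):
        peak = float(np.nanmax(dev[s : e + 1])) if np.any(np.isfinite(dev[s : e + 1])) else float("nan")
        bouts.append(BehaviorBout("coil", s, e, peak))
    return bouts


def detect_all(track: LarvaTrack, params: EthogramParams | None = None) -> dict[str, list[BehaviorBout]]:
    """All four detectors on one track, keyed by bout kind."""
    params = params or EthogramParams()
    return {
        "stop": detect_stops(track, params),
        "head_bend": detect_head_bends(track, params),
        "turn": detect_turns(track, params),
        "coil": detect_coils(track, params),
    }
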
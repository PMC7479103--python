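"""Read/write tracker-style posture tables and extract posture features from silhouettes.

The on-disk dialect is a long-format CSV, one row per (larva_id, frame):

    larva_id, frame, x_mm, y_mm,
    spine0_x_mm, spine0_y_mm, ..., spine{K-1}_x_mm, spine{K-1}_y_mm,
    bending_deg, area_mm2, spine_len_mm

Coordinates are in millimetres with the origin at the arena's lower-left
corner and y pointing up; frame indices are 0-based and spine points are
ordered head -> tail.  Frame-rate and pixel-size metadata travel in a JSON
sidecar next to the CSV (``<name>.json``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DialectError, TrackFormatError

__all__ = [
    "PostureFrame",
    "LarvaTrack",
    "read_tracks",
    "write_tracks",
    "extract_features",
]

DEFAULT_SPINE_POINTS = 5


@dataclass(frozen=True)
class PostureFrame:
    """Single-frame posture of one larva (a read-only view into a track)."""

    frame_index: int
    centroid_xy_mm: np.ndarray
    spine_xy_mm: np.ndarray  # (K, 2), head -> tail
    bending_angle_deg: float
    body_area_mm2: float
    spine_length_mm: float
    valid: bool = True


@dataclass
class LarvaTrack:
    """Per-frame posture features for one larva.

    Arrays are frame-aligned; ``valid`` marks frames where the posture could
    not be measured (missing rows on read, failed segmentation on feature
    extraction).  Invalid frames carry NaN geometry and are never silently
    interpolated.
    """

    larva_id: str
    fps: float
    centroid_mm: np.ndarray  # (n, 2)
    spine_mm: np.ndarray  # (n, K, 2) head -> tail
    bending_deg: np.ndarray  # (n,)
    area_mm2: np.ndarray  # (n,)
    spine_len_mm: np.ndarray  # (n,)
    valid: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=float)
        self.spine_mm = np.asarray(self.spine_mm, dtype=float)
        self.bending_deg = np.asarray(self.bending_deg, dtype=float)
        self.area_mm2 = np.asarray(self.area_mm2, dtype=float)
        self.spine_len_mm = np.asarray(self.spine_len_mm, dtype=float)
        n = self.centroid_mm.shape[0]
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if n < 1:
            raise TrackFormatError(f"track {self.larva_id!r} has no frames")
        if self.fps <= 0:
            raise TrackFormatError("fps must be positive")
        for name, arr, shape in (
            ("spine_mm", self.spine_mm, (n,)),
            ("bending_deg", self.bending_deg, (n,)),
            ("area_mm2", self.area_mm2, (n,)),
            ("spine_len_mm", self.spine_len_mm, (n,)),
            ("valid", self.valid, (n,)),
        ):
            if arr.shape[0] != n:
                raise TrackFormatError(f"{name} length does not match centroid length")

    @property
    def n_frames(self) -> int:
        return self.centroid_mm.shape[0]

    @property
    def n_spine_points(self) -> int:
        return self.spine_mm.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def frame(self, i: int) -> PostureFrame:
        return PostureFrame(
            frame_index=i,
            centroid_xy_mm=self.centroid_mm[i].copy(),
            spine_xy_mm=self.spine_mm[i].copy(),
            bending_angle_deg=float(self.bending_deg[i]),
            body_area_mm2=float(self.area_mm2[i]),
            spine_length_mm=float(self.spine_len_mm[i]),
            valid=bool(self.valid[i]),
        )

    def displacements_mm(self) -> np.ndarray:
        """Per-frame centroid step lengths; element i is the step into frame i+1.

        Length n-1.  Steps touching invalid frames are NaN.
        """
        d = np.linalg.norm(np.diff(self.centroid_mm, axis=0), axis=1)
        bad = ~(self.valid[:-1] & self.valid[1:])
        d = d.astype(float)
        d[bad] = np.nan
        return d


def _dialect_columns(n_spine: int) -> list[str]:
    cols = ["larva_id", "frame", "x_mm", "y_mm"]
    for i in range(n_spine):
        cols += [f"spine{i}_x_mm", f"spine{i}_y_mm"]
    cols += ["bending_deg", "area_mm2", "spine_len_mm"]
    return cols


def _infer_n_spine(columns: Sequence[str]) -> int:
    k = 0
    while f"spine{k}_x_mm" in columns:
        k += 1
    return k


def write_tracks(tracks: Iterable[LarvaTrack], path, sidecar: dict | None = None) -> None:
    """Serialize tracks to the long CSV dialect with 6-significant-digit floats.

    A JSON sidecar (fps plus any caller-supplied metadata) is written next to
    the CSV.  An empty collection yields a header-only file.
    """
    tracks = list(tracks)
    path = Path(path)
    n_spine = tracks[0].n_spine_points if tracks else DEFAULT_SPINE_POINTS
    cols = _dialect_columns(n_spine)
    rows = []
    for tr in tracks:
        if tr.n_spine_points != n_spine:
            raise TrackFormatError("all tracks must share the same spine point count")
        for i in range(tr.n_frames):
            if not tr.valid[i]:
                continue
            row = [tr.larva_id, i, tr.centroid_mm[i, 0], tr.centroid_mm[i, 1]]
            row += list(tr.spine_mm[i].reshape(-1))
            row += [tr.bending_deg[i], tr.area_mm2[i], tr.spine_len_mm[i]]
            rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.6g")
    meta = {"fps": tracks[0].fps if tracks else None, "n_spine_points": n_spine}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_tracks(path, fps: float | None = None) -> list[LarvaTrack]:
    """Parse a long-dialect CSV into one :class:`LarvaTrack` per larva id.

    ``fps`` is taken from the JSON sidecar when not given.  Gaps in the frame
    index are kept as invalid (NaN) frames, never interpolated.  Unknown
    columns and duplicated (larva, frame) pairs raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    n_spine = _infer_n_spine(df.columns)
    expected = set(_dialect_columns(n_spine))
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise DialectError(f"unknown column(s) in track table: {', '.join(unknown)}")
    missing = [c for c in _dialect_columns(n_spine) if c not in df.columns]
    if missing:
        raise DialectError(f"missing column(s) in track table: {', '.join(missing)}")

    if fps is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise DialectError("fps not given and no JSON sidecar found")
        fps = json.loads(sidecar.read_text())["fps"]

    tracks: list[LarvaTrack] = []
    for larva_id, sub in df.groupby("larva_id", sort=True):
        if sub.duplicated("frame").any():
            raise TrackFormatError(f"duplicated (larva, frame) rows for larva {larva_id!r}")
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy(dtype=int)
        if frames.min() < 0:
            raise TrackFormatError("negative frame index")
        n = int(frames.max()) + 1
        centroid = np.full((n, 2), np.nan)
        spine = np.full((n, n_spine, 2), np.nan)
        bend = np.full(n, np.nan)
        area = np.full(n, np.nan)
        slen = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        centroid[frames, 0] = sub["x_mm"].to_numpy()
        centroid[frames, 1] = sub["y_mm"].to_numpy()
        for k in range(n_spine):
            spine[frames, k, 0] = sub[f"spine{k}_x_mm"].to_numpy()
            spine[frames, k, 1] = sub[f"spine{k}_y_mm"].to_numpy()
        bend[frames] = sub["bending_deg"].to_numpy()
        area[frames] = sub["area_mm2"].to_numpy()
        slen[frames] = sub["spine_len_mm"].to_numpy()
        valid[frames] = True
        tracks.append(
            LarvaTrack(
                larva_id=str(larva_id),
                fps=float(fps),
                centroid_mm=centroid,
                spine_mm=spine,
                bending_deg=bend,
                area_mm2=area,
                spine_len_mm=slen,
                valid=valid,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Feature extraction from binary silhouette stacks
# ---------------------------------------------------------------------------


def _skeleton_path(mask: np.ndarray) -> np.ndarray | None:
    """Longest geodesic path through the skeleton of ``mask``, as (m, 2) pixel
    coordinates (row, col).  Returns None when the mask yields no usable path."""
    import networkx as nx
    from skimage.morphology import skeletonize

    skel = skeletonize(mask)
    pts = np.argwhere(skel)
    if len(pts) < 2:
        return None
    index = {tuple(p): i for i, p in enumerate(pts)}
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=math.hypot(dr, dc))
    if g.number_of_edges() == 0:
        return None
    # double-sweep: farthest node from an arbitrary node, then farthest from it
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    src = next(iter(comp))
    d1 = nx.single_source_dijkstra_path_length(sub, src)
    a = max(d1, key=d1.get)
    d2, paths = nx.single_source_dijkstra(sub, a)
    b = max(d2, key=d2.get)
    return pts[paths[b]]


def _resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample an (m, 2) polyline to k points at equal arc-length spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(points[:1], k, axis=0)
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 2))
    out[:, 0] = np.interp(targets, s, points[:, 0])
    out[:, 1] = np.interp(targets, s, points[:, 1])
    return out


def extract_features(
    stack: np.ndarray,
    pixel_size_mm: float,
    fps: float,
    *,
    n_spine_points: int = DEFAULT_SPINE_POINTS,
    larva_id: str = "larva0",
    min_area_px: int = 10,
    head_window_frames: int = 10,
) -> LarvaTrack:
    """Replay tracker-style feature extraction on a binary silhouette stack.

    Per frame: the centroid and area of the single foreground component, a
    midline ("spine") as ``n_spine_points`` equally spaced points along the
    longest geodesic path of the skeleton, and the bending angle at the spine
    midpoint.  The spine is oriented by motion continuity: the endpoint that
    leads the net centroid displacement over a ``head_window_frames`` window
    is called the head; ties keep the previous orientation.

    Frames with zero or more than one large component are marked invalid.
    Image rows map to decreasing y (origin lower-left, y up).
    """
    from skimage.measure import label, regionprops
    from .ethogram import bending_angle

    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, rows, cols) stack")
    n, n_rows, _ = stack.shape
    px = float(pixel_size_mm)

    def to_mm(rc: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(rc)
        out = np.empty_like(rc, dtype=float)
        out[:, 0] = (rc[:, 1] + 0.5) * px  # x from col
        out[:, 1] = (n_rows - rc[:, 0] - 0.5) * px  # y from row, flipped
        return out

    centroid = np.full((n, 2), np.nan)
    spine = np.full((n, n_spine_points, 2), np.nan)
    bend = np.full(n, np.nan)
    area = np.full(n, np.nan)
    slen = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    paths_mm: list[np.ndarray | None] = []

    for i in range(n):
        mask = stack[i] > 0
        lab = label(mask)
        regions = [r for r in regionprops(lab) if r.area >= min_area_px]
        if len(regions) != 1:
            paths_mm.append(None)
            continue
        region = regions[0]
        mask = lab == region.label
        path_px = _skeleton_path(mask)
        if path_px is None:
            paths_mm.append(None)
            continue
        path = to_mm(path_px)
        pts = _resample_polyline(path, n_spine_points)
        centroid[i] = to_mm(np.array(region.centroid))[0]
        spine[i] = pts
        area[i] = region.area * px * px
        slen[i] = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        try:
            bend[i] = bending_angle(pts)
        except Exception:
            bend[i] = np.nan
        valid[i] = True
        paths_mm.append(pts)

    # orient head by motion continuity
    flipped_prev = False
    for i in range(n):
        if not valid[i]:
            continue
        j0 = max(0, i - head_window_frames)
        j1 = min(n - 1, i + head_window_frames)
        disp = np.zeros(2)
        if valid[j1] and valid[j0]:
            disp = centroid[j1] - centroid[j0]
        head_vec = spine[i, 0] - centroid[i]
        tail_vec = spine[i, -1] - centroid[i]
        score = float(head_vec @ disp - tail_vec @ disp)
        if score < 0:
            flip = True
        elif score > 0:
            flip = False
        else:
            flip = flipped_prev  # tie: keep previous assignment
        if flip:
            spine[i] = spine[i, ::-1]
        flipped_prev = flip

    return LarvaTrack(
        larva_id=larva_id,
        fps=fps,
        centroid_mm=centroid,
        spine_mm=spine,
        bending_deg=bend,
        area_mm2=area,
        spine_len_mm=slen,
        valid=valid,
    )
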
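"""Per-larva and per-group locomotion statistics.

Distances are reported in cm/min, event counts on the time bases used in the
field (stops and turns per minute, head bends per 10 s), coiling as the
percentage of frames pooled across tracks, and peristalsis as contraction
cycles per second (from rhythmic body-size changes) with an efficacy in cm
crawled per wave.  Group comparisons are Shapiro–Wilk-gated: two-sample t
test when both groups look normal, Wilcoxon rank-sum otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .errors import DegenerateInputError
from .ethogram import BehaviorBout, EthogramParams, bending_series, coil_mask, detect_all
from .trackio import LarvaTrack

__all__ = [
    "BehaviorSummary",
    "CoilClipHistogram",
    "GroupComparison",
    "accumulated_distance",
    "distance_to_origin",
    "event_rates",
    "coil_fraction",
    "coil_clip_histogram",
    "peristalsis_stats",
    "group_compare",
    "summarize_track",
]

MM_PER_CM = 10.0
CLIP_CLASS_EDGES = ((0, 0), (1, 30), (31, 60), (61, None))  # coiled frames per clip
CLIP_CLASS_LABELS = ("0", "1-30", "31-60", ">60")


@dataclass(frozen=True)
class BehaviorSummary:
    """The per-larva locomotion statistics panel."""

    larva_id: str
    accumulated_distance_cm_min: float
    distance_to_origin_cm_min: float
    stops_per_min: float
    head_bends_per_10s: float
    turns_per_min: float
    coil_frame_fraction_pct: float
    median_stop_bend_deg: float
    peristalsis_cycles_per_s: float
    peristalsis_efficacy_cm_per_wave: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CoilClipHistogram:
    """Distribution of coiled-frame counts over consecutive fixed-length clips."""

    clip_frames: int
    counts: np.ndarray  # per class, classes = CLIP_CLASS_LABELS
    n_clips: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != self.n_clips:
            raise ValueError("class counts must sum to the clip count")

    @property
    def proportions(self) -> np.ndarray:
        if self.n_clips == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_clips

    def to_dict(self) -> dict:
        return {
            "clip_frames": self.clip_frames,
            "classes": list(CLIP_CLASS_LABELS),
            "counts": self.counts.tolist(),
            "proportions": self.proportions.round(6).tolist(),
            "n_clips": self.n_clips,
        }


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t" or "ranksum"
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float

    def to_dict(self) -> dict:
        return asdict(self)


def _duration_min(track: LarvaTrack) -> float:
    if track.n_frames < 2:
        raise DegenerateInputError("distances undefined for a single-frame track")
    return track.duration_s / 60.0


def accumulated_distance(track: LarvaTrack) -> float:
    """Total centroid path length per minute (cm/min)."""
    d = track.displacements_mm()
    return float(np.nansum(d) / MM_PER_CM / _duration_min(track))


def distance_to_origin(track: LarvaTrack) -> float:
    """Net displacement from the first to the last valid centroid, per minute
    (cm/min)."""
    dur = _duration_min(track)
    ok = np.flatnonzero(track.valid)
    if ok.size < 2:
        raise DegenerateInputError("need two valid frames")
    net = np.linalg.norm(track.centroid_mm[ok[-1]] - track.centroid_mm[ok[0]])
    return float(net / MM_PER_CM / dur)


def event_rates(bouts: dict[str, list[BehaviorBout]], track: LarvaTrack) -> dict:
    """Bout counts normalized to the field's time bases."""
    minutes = _duration_min(track)
    ten_s = track.duration_s / 10.0
    return {
        "stops_per_min": len(bouts.get("stop", [])) / minutes,
        "head_bends_per_10s": len(bouts.get("head_bend", [])) / ten_s,
        "turns_per_min": len(bouts.get("turn", [])) / minutes,
    }


def coil_fraction(tracks: Sequence[LarvaTrack], params: EthogramParams | None = None) -> float:
    """Percent of frames showing a coil, pooled over all tracks."""
    params = params or EthogramParams()
    coiled = 0
    total = 0
    for tr in tracks:
        coiled += int(coil_mask(tr, params).sum())
        total += tr.n_frames
    if total == 0:
        raise DegenerateInputError("no frames")
    return 100.0 * coiled / total


def coil_clip_histogram(
    tracks: Sequence[LarvaTrack],
    clip_frames: int = 300,
    params: EthogramParams | None = None,
) -> CoilClipHistogram:
    """Coiled-frame counts per non-overlapping clip, classified into
    {0, 1–30, 31–60, >60} coiled frames.

    Clips are anchored at frame 0 of each track; trailing partial clips are
    dropped.
    """
    params = params or EthogramParams()
    per_clip: list[int] = []
    for tr in tracks:
        mask = coil_mask(tr, params)
        n_clips = tr.n_frames // clip_frames
        for c in range(n_clips):
            per_clip.append(int(mask[c * clip_frames : (c + 1) * clip_frames].sum()))
    if not per_clip:
        raise DegenerateInputError("no track is long enough for one clip")
    counts = np.zeros(len(CLIP_CLASS_EDGES), dtype=int)
    for v in per_clip:
        for k, (lo, hi) in enumerate(CLIP_CLASS_EDGES):
            if v >= lo and (hi is None or v <= hi):
                counts[k] += 1
                break
    return CoilClipHistogram(clip_frames=clip_frames, counts=counts, n_clips=len(per_clip))


def peristalsis_stats(
    track: LarvaTrack,
    prominence_iqr_frac: float = 0.25,
    min_separation_s: float = 0.3,
) -> dict:
    """Peristaltic contraction frequency and efficacy from the body-size series.

    The area series is linearly detrended; peaks with prominence of at least
    ``prominence_iqr_frac`` of the series IQR and separation of at least
    ``min_separation_s`` are counted as contraction waves.  Frequency is
    peaks per second; efficacy is accumulated distance (cm) per wave.  A flat
    signal yields 0 cycles/s and a flagged, undefined efficacy.
    """
    if track.duration_s < 10.0:
        raise DegenerateInputError("need at least 10 s of body-size signal")
    area = track.area_mm2[track.valid]
    if area.size < 3:
        raise DegenerateInputError("not enough valid frames")
    x = signal.detrend(area, type="linear")
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr == 0.0 or np.allclose(x, 0.0):
        return {"cycles_per_s": 0.0, "efficacy_cm_per_wave": float("nan"), "n_peaks": 0, "flat": True}
    distance = max(1, int(round(min_separation_s * track.fps)))
    peaks, _ = signal.find_peaks(x, prominence=prominence_iqr_frac * iqr, distance=distance)
    cycles = peaks.size / track.duration_s
    total_cm = float(np.nansum(track.displacements_mm())) / MM_PER_CM
    efficacy = total_cm / peaks.size if peaks.size else float("nan")
    return {"cycles_per_s": cycles, "efficacy_cm_per_wave": efficacy, "n_peaks": int(peaks.size), "flat": False}


def group_compare(samples_a: Sequence[float], samples_b: Sequence[float], alpha: float = 0.05) -> GroupComparison:
    """Shapiro–Wilk-gated two-sample comparison.

    Both groups normal at ``alpha`` → Student's t test; otherwise Wilcoxon
    rank-sum.  Two-tailed p values.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DegenerateInputError("each group needs at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant group: comparison degenerate")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    if sw_a > alpha and sw_b > alpha:
        res = stats.ttest_ind(a, b)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), float(sw_a), float(sw_b))
    res = stats.ranksums(a, b)
    return GroupComparison("ranksum", float(res.statistic), float(res.pvalue), float(sw_a), float(sw_b))


def summarize_track(
    track: LarvaTrack,
    bouts: dict[str, list[BehaviorBout]] | None = None,
    params: EthogramParams | None = None,
) -> BehaviorSummary:
    """Full per-larva statistics panel; classifies bouts when not given."""
    params = params or EthogramParams()
    if bouts is None:
        bouts = detect_all(track, params)
    rates = event_rates(bouts, track)
    dev = bending_series(track, params)
    stop_frames = np.zeros(track.n_frames, dtype=bool)
    for b in bouts.get("stop", []):
        stop_frames[b.start_frame : b.end_frame + 1] = True
    stop_dev = dev[stop_frames & np.isfinite(dev)]
    median_stop_bend = float(np.median(stop_dev)) if stop_dev.size else float("nan")
    try:
        peri = peristalsis_stats(track)
    except DegenerateInputError:
        peri = {"cycles_per_s": float("nan"), "efficacy_cm_per_wave": float("nan")}
    return BehaviorSummary(
        larva_id=track.larva_id,
        accumulated_distance_cm_min=accumulated_distance(track),
        distance_to_origin_cm_min=distance_to_origin(track),
        stops_per_min=rates["stops_per_min"],
        head_bends_per_10s=rates["head_bends_per_10s"],
        turns_per_min=rates["turns_per_min"],
        coil_frame_fraction_pct=coil_fraction([track], params),
        median_stop_bend_deg=median_stop_bend,
        peristalsis_cycles_per_s=peri["cycles_per_s"],
        peristalsis_efficacy_cm_per_wave=peri["efficacy_cm_per_wave"],
    )
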
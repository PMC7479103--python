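"""Nerve conduction-velocity estimation from dual extracellular recordings.

The estimator follows the distance/delay-quotient procedure: spikes are
detected on both traces, assigned to units by amplitude, matched across
electrodes, and each matched pair yields v = Δd / Δt.  Per-recording means
are taken after iterative Grubbs outlier removal; group statistics then run
on recording means.

Spike times follow the positive-peak convention (the waveform feature that
anchors Δt is configurable only in the sense that callers may pass their own
spike times to the matching stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal, stats

from .errors import ConfigError, DegenerateInputError

__all__ = [
    "DualRecording",
    "MatchedSpikePair",
    "VelocityEstimate",
    "detect_spikes",
    "sort_units",
    "match_spikes",
    "conduction_velocity",
    "recording_velocity",
    "percent_reduction",
    "grubbs_prune",
    "estimate_recording",
]

V_MIN_M_S = 0.05  # slowest plausible propagation; bounds the matching search


@dataclass
class DualRecording:
    """Two simultaneously sampled voltage traces and the electrode separation."""

    sampling_hz: float
    trace1_volts: np.ndarray
    trace2_volts: np.ndarray
    electrode_distance_mm: float

    def __post_init__(self):
        self.trace1_volts = np.asarray(self.trace1_volts, dtype=float)
        self.trace2_volts = np.asarray(self.trace2_volts, dtype=float)
        if self.trace1_volts.shape != self.trace2_volts.shape:
            raise ConfigError("traces must have equal length")
        if self.electrode_distance_mm <= 0 or self.sampling_hz <= 0:
            raise ConfigError("electrode distance and sampling rate must be positive")

    @classmethod
    def from_csv(cls, path1, path2, sidecar) -> "DualRecording":
        """Load two (time_s, volts) CSVs plus a JSON sidecar with
        ``sampling_hz`` and ``electrode_distance_mm``."""
        import pandas as pd

        meta = json.loads(Path(sidecar).read_text())
        t1 = pd.read_csv(path1)
        t2 = pd.read_csv(path2)
        return cls(
            sampling_hz=float(meta["sampling_hz"]),
            trace1_volts=t1["volts"].to_numpy(),
            trace2_volts=t2["volts"].to_numpy(),
            electrode_distance_mm=float(meta["electrode_distance_mm"]),
        )


@dataclass(frozen=True)
class MatchedSpikePair:
    """One spike observed at both electrodes; Δt = t2 − t1 > 0 for
    orthodromic propagation (electrode 1 upstream)."""

    t1_s: float
    t2_s: float
    unit_id: int

    @property
    def delay_s(self) -> float:
        return self.t2_s - self.t1_s


@dataclass
class VelocityEstimate:
    """Per-spike velocities and the recording mean after outlier removal."""

    per_spike_velocities_m_s: np.ndarray
    recording_mean_m_s: float
    n_spikes: int
    outliers_removed: int
    n_unmatched: int = 0

    def to_dict(self) -> dict:
        return {
            "per_spike_velocities_m_s": [round(float(v), 6) for v in self.per_spike_velocities_m_s],
            "recording_mean_m_s": round(float(self.recording_mean_m_s), 3),
            "n_spikes": int(self.n_spikes),
            "outliers_removed": int(self.outliers_removed),
            "n_unmatched": int(self.n_unmatched),
        }


def detect_spikes(
    trace: np.ndarray,
    sampling_hz: float,
    threshold_sd: float = 5.0,
    refractory_ms: float = 2.0,
    smooth_ms: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-crossing spike detection with robust-SD scaling.

    The trace is boxcar-smoothed over ``smooth_ms`` (a crude matched filter
    that suppresses sample-to-sample noise without blurring a 2-ms spike);
    the threshold is ``threshold_sd`` times the MAD-based robust standard
    deviation of the smoothed trace.  Detections are realigned to the local
    absolute extremum of the raw trace and separated by at least the
    refractory period.  Returns (times_s, peak_amplitudes); amplitudes are
    raw-trace values and keep their sign.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    k = max(1, int(round(smooth_ms / 1000.0 * sampling_hz)))
    smoothed = np.convolve(trace, np.ones(k) / k, mode="same") if k > 1 else trace
    robust_sd = stats.median_abs_deviation(smoothed, scale="normal")
    if robust_sd == 0:
        robust_sd = np.std(smoothed) or 1e-12
    thresh = threshold_sd * robust_sd
    distance = max(1, int(round(refractory_ms / 1000.0 * sampling_hz)))
    peaks, _ = signal.find_peaks(np.abs(smoothed), height=thresh, distance=distance)
    # realign each detection to the raw-trace extremum nearby
    w = max(1, int(round(0.3e-3 * sampling_hz)))
    aligned = []
    for p in peaks:
        lo, hi = max(0, p - w), min(trace.size, p + w + 1)
        aligned.append(lo + int(np.argmax(np.abs(trace[lo:hi]))))
    if not aligned:
        return np.array([]), np.array([])
    aligned = np.array(sorted(set(aligned)))
    keep = [0]
    for i in range(1, aligned.size):
        if aligned[i] - aligned[keep[-1]] >= distance:
            keep.append(i)
        elif np.abs(trace[aligned[i]]) > np.abs(trace[aligned[keep[-1]]]):
            keep[-1] = i
    aligned = aligned[keep]
    return aligned / sampling_hz, trace[aligned]


def sort_units(amplitudes: np.ndarray, n_units: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means on spike peak amplitudes.

    Centers are initialized at the (j+0.5)/k quantiles of |amplitude|, then
    refined by Lloyd iterations; labels are sorted so unit 0 has the smallest
    mean amplitude.  Depends only on the multiset of values, so labels are
    stable under permutation of the input order.
    """
    amps = np.abs(np.asarray(amplitudes, dtype=float))
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if amps.size < n_units:
        raise DegenerateInputError("fewer spikes than units")
    if n_units == 1:
        return np.zeros(amps.size, dtype=int)
    centers = np.quantile(amps, (np.arange(n_units) + 0.5) / n_units)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(amps[:, None] - centers[None, :]), axis=1)
        new = np.array([amps[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(n_units)])
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    remap = np.empty(n_units, dtype=int)
    remap[order] = np.arange(n_units)
    return remap[labels]


def match_spikes(
    times1_s: np.ndarray,
    times2_s: np.ndarray,
    max_delay_ms: float,
    unit_id: int = 0,
    anchor_delay_ms: float | None = None,
) -> tuple[list[MatchedSpikePair], int]:
    """Greedy nearest-neighbour matching of one unit's spikes across electrodes.

    Candidate pairs with 0 < Δt ≤ max_delay are collected; the modal delay of
    the candidate set (cross-correlogram peak, 0.5-ms bins) serves as the
    anchor unless ``anchor_delay_ms`` is given, and pairs are then accepted
    greedily in order of |Δt − anchor|, each spike used at most once.
    Anchoring keeps the pairing correct even when the propagation delay
    exceeds the unit's minimum inter-spike interval, where raw
    smallest-delay matching would systematically cross-pair.  Returns the
    matched pairs (sorted by t1) and the number of unmatched spikes.
    """
    t1 = np.sort(np.asarray(times1_s, dtype=float))
    t2 = np.sort(np.asarray(times2_s, dtype=float))
    max_delay = max_delay_ms / 1000.0
    candidates = []
    for i, a in enumerate(t1):
        for j in range(np.searchsorted(t2, a, side="right"), t2.size):
            dt = t2[j] - a
            if dt > max_delay:
                break
            if dt > 0:
                candidates.append((dt, i, j))
    if candidates:
        if anchor_delay_ms is None:
            dts = np.array([c[0] for c in candidates])
            bins = np.arange(0.0, max_delay + 0.5e-3, 0.5e-3)
            hist, edges = np.histogram(dts, bins=bins)
            mode = edges[int(np.argmax(hist))] + 0.25e-3
        else:
            mode = anchor_delay_ms / 1000.0
        candidates = [(abs(dt - mode), dt, i, j) for dt, i, j in candidates]
        candidates.sort()
        candidates = [(dt, i, j) for _, dt, i, j in candidates]
    used1 = np.zeros(t1.size, dtype=bool)
    used2 = np.zeros(t2.size, dtype=bool)
    pairs = []
    for dt, i, j in candidates:
        if used1[i] or used2[j]:
            continue
        used1[i] = used2[j] = True
        pairs.append(MatchedSpikePair(t1_s=float(t1[i]), t2_s=float(t2[j]), unit_id=unit_id))
    pairs.sort(key=lambda p: p.t1_s)
    unmatched = int((~used1).sum() + (~used2).sum())
    return pairs, unmatched


def conduction_velocity(delta_d_mm: float, delta_t_ms: float) -> float:
    """Distance/delay quotient in m/s: (Δd mm) / (Δt ms) = Δd/Δt m/s."""
    if delta_d_mm <= 0:
        raise ValueError("electrode distance must be positive")
    if delta_t_ms <= 0:
        raise ValueError("delay must be positive")
    return delta_d_mm / delta_t_ms


def grubbs_prune(values: np.ndarray, alpha: float = 0.05, max_frac: float = 0.2) -> tuple[np.ndarray, int]:
    """Iterated two-sided Grubbs outlier removal.

    Removes at most one point per iteration (the most extreme deviation from
    the mean) while the Grubbs statistic exceeds its critical value at
    ``alpha``; stops after removing ``max_frac`` of the points.  Returns
    (retained values, number removed).
    """
    x = np.asarray(values, dtype=float).copy()
    if x.size < 3:
        raise DegenerateInputError("Grubbs test needs at least 3 values")
    limit = max(1, int(np.floor(max_frac * x.size)))
    removed = 0
    while x.size >= 3 and removed < limit:
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - x.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / s
        n = x.size
        t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        g_crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        if g > g_crit:
            x = np.delete(x, idx)
            removed += 1
        else:
            break
    return x, removed


def recording_velocity(
    pairs: list[MatchedSpikePair],
    delta_d_mm: float,
    grubbs_alpha: float = 0.05,
    n_unmatched: int = 0,
) -> VelocityEstimate:
    """Per-pair velocities and the Grubbs-pruned recording mean."""
    if len(pairs) < 3:
        raise DegenerateInputError("need at least 3 matched spike pairs")
    v = np.array([conduction_velocity(delta_d_mm, p.delay_s * 1000.0) for p in pairs])
    kept, removed = grubbs_prune(v, alpha=grubbs_alpha)
    return VelocityEstimate(
        per_spike_velocities_m_s=v,
        recording_mean_m_s=float(kept.mean()),
        n_spikes=len(pairs),
        outliers_removed=removed,
        n_unmatched=n_unmatched,
    )


def percent_reduction(reference: float, value: float) -> tuple[int, float]:
    """Percent decrease of ``value`` relative to ``reference``.

    Returns (rounded to nearest integer, unrounded).
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    pct = 100.0 * (reference - value) / reference
    return int(round(pct)), pct


def estimate_recording(
    rec: DualRecording,
    n_units: int = 1,
    threshold_sd: float = 5.0,
    refractory_ms: float = 2.0,
    max_delay_ms: float | None = None,
    grubbs_alpha: float = 0.05,
) -> VelocityEstimate:
    """End-to-end velocity estimation from a raw dual recording.

    Detect spikes on both traces, sort them into units by amplitude, match
    each unit's spikes across electrodes, and pool the matched pairs into a
    Grubbs-pruned recording mean.
    """
    if max_delay_ms is None:
        # bounds the search without excluding slow ablated nerves
        max_delay_ms = 2.0 * rec.electrode_distance_mm / V_MIN_M_S
    t1, a1 = detect_spikes(rec.trace1_volts, rec.sampling_hz, threshold_sd, refractory_ms)
    t2, a2 = detect_spikes(rec.trace2_volts, rec.sampling_hz, threshold_sd, refractory_ms)
    if t1.size < n_units or t2.size < n_units:
        raise DegenerateInputError("not enough detected spikes to sort")
    lab1 = sort_units(a1, n_units)
    lab2 = sort_units(a2, n_units)
    pairs: list[MatchedSpikePair] = []
    unmatched = 0
    for u in range(n_units):
        p, um = match_spikes(t1[lab1 == u], t2[lab2 == u], max_delay_ms, unit_id=u)
        pairs.extend(p)
        unmatched += um
    return recording_velocity(pairs, rec.electrode_distance_mm, grubbs_alpha, n_unmatched=unmatched)
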
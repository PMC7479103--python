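"""Seeded synthetic-data generators with known ground truth.

Three generators emulate the three input kinds of the pipeline:

* :func:`simulate_tracks` — larval crawling tracks with a Markov-style bout
  scheduler (stop / head-bend / turn / coil) and a peristaltic body-size
  oscillation, returning the ground-truth bout log next to the posture data;
* :func:`simulate_recording` — dual-electrode extracellular traces in which
  every spike on electrode 1 reappears on electrode 2 after a known
  propagation delay (plus optional jitter);
* :func:`simulate_nerve` — nerve cross-section annotations with lognormal
  axon radii and configurable wrapping-unit layout.

All randomness flows from a single integer seed per call; with the seed fixed
every generator is bit-reproducible.  The bout scheduler is constructed so
that the rule-based classifiers in :mod:`nervekit.ethogram` recover the bout
log exactly: bouts respect the classifiers' minimum durations, crawl segments
never cross the movement threshold, and each bout is followed by a forced
crawl refractory so maximal runs map one-to-one onto logged bouts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .ethogram import BehaviorBout, EthogramParams, bending_series
from .trackio import LarvaTrack

__all__ = [
    "LocomotionConfig",
    "EphysConfig",
    "NerveConfig",
    "TrackSimulation",
    "RecordingSimulation",
    "simulate_tracks",
    "simulate_recording",
    "simulate_nerve",
    "rasterize_track",
    "expected_bout_statistics",
]

# forced crawl frames after each bout kind; keeps logged bouts separated so
# that maximal detector runs coincide with the log, and provides the moving
# pre-window the turn classifier needs
REFRACTORY_FRAMES = {"stop": 12, "head_bend": 12, "turn": 24, "coil": 5}
WARMUP_FRAMES = 12
MIN_DWELL = {"stop": 5, "head_bend": 5, "turn": 4, "coil": 1}


@dataclass(frozen=True)
class LocomotionConfig:
    """Study conditions for the track generator (3-min recordings at 10 fps)."""

    fps: float = 10.0
    duration_s: float = 180.0
    n_larvae: int = 15
    arena_size_mm: float = 200.0
    spine_length_mm: float = 4.0
    peristalsis_hz: float = 1.2
    crawl_speed_mm_s: float = 3.0
    bout_rates: dict = field(
        default_factory=lambda: {"stop": 0.004, "head_bend": 0.010, "turn": 0.003, "coil": 0.00134}
    )
    bout_duration_frames: dict = field(
        default_factory=lambda: {"stop": 10.0, "head_bend": 8.0, "turn": 4.0, "coil": 1.0}
    )
    coil_frame_fraction_target: float | None = None
    n_spine_points: int = 5
    heading_noise_deg: float = 1.5
    bend_noise_deg: float = 4.0
    area_osc_frac: float = 0.08
    speed_osc_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigError("fps and duration_s must be positive")
        if self.arena_size_mm <= 0 or self.spine_length_mm <= 0:
            raise ConfigError("arena and spine length must be positive")
        if self.n_larvae < 1:
            raise ConfigError("need at least one larva")
        for k, r in self.bout_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"bout rate for {k!r} outside [0, 1]")
        for k, d in self.bout_duration_frames.items():
            if d < 1:
                raise ConfigError(f"mean dwell for {k!r} below 1 frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class EphysConfig:
    """Study conditions for the dual-electrode recording generator (20 kHz)."""

    sampling_hz: float = 20000.0
    electrode_distance_mm: float = 2.0
    true_velocity_m_s: float = 0.196
    firing_rate_hz: float = 5.0  # per unit
    jitter_ms: float = 0.3
    noise_sd: float = 0.1  # relative to the smallest unit's peak amplitude
    n_units: int = 2
    duration_s: float = 60.0
    min_isi_ms: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_hz <= 0:
            raise ConfigError("sampling_hz must be positive")
        if self.electrode_distance_mm <= 0 or self.true_velocity_m_s <= 0:
            raise ConfigError("electrode distance and velocity must be positive")
        if self.duration_s <= 0 or self.n_units < 1:
            raise ConfigError("duration must be positive, n_units >= 1")
        if self.true_delay_s >= self.duration_s:
            raise ConfigError("propagation delay exceeds trace duration")

    @property
    def true_delay_s(self) -> float:
        # mm / (m/s) = ms; convert to s
        return (self.electrode_distance_mm / self.true_velocity_m_s) / 1000.0


@dataclass(frozen=True)
class NerveConfig:
    """Study conditions for the nerve cross-section generator.

    Default layout approximates a control abdominal nerve: ~79 axons, a
    median axon radius of 0.194 µm, and enough individually wrapped axons
    plus wrapped fascicles to give a wrapping index near 19.
    """

    n_axons: int = 79
    radius_log_mean_um: float = math.log(0.194)
    radius_log_sd_um: float = 0.55
    n_fascicles: int = 8
    frac_individually_wrapped: float = 0.09
    seed: int = 0

    def __post_init__(self):
        if self.n_axons < 1:
            raise ConfigError("need at least one axon")
        if not 0.0 <= self.frac_individually_wrapped <= 1.0:
            raise ConfigError("frac_individually_wrapped outside [0, 1]")
        if self.n_fascicles < 0 or self.n_fascicles > self.n_axons:
            raise ConfigError("n_fascicles must be between 0 and n_axons")


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------


@dataclass
class TrackSimulation:
    """Tracks plus the generator's ground-truth bout log, keyed by larva id."""

    tracks: list[LarvaTrack]
    bouts: dict[str, list[BehaviorBout]]
    config: LocomotionConfig

    def pooled_coil_frames(self) -> int:
        return sum(b.n_frames for log in self.bouts.values() for b in log if b.kind == "coil")

    def total_frames(self) -> int:
        return sum(t.n_frames for t in self.tracks)


def expected_bout_statistics(config: LocomotionConfig) -> dict:
    """Closed-form renewal expectations of the bout scheduler.

    With per-eligible-frame entry rates r_k, mean dwells d_k and refractory
    R_k, the fraction of eligible (crawl) frames is
    ``phi = 1 / (1 + sum_k r_k (d_k + R_k))``; bout-k initiations occur at
    ``r_k * phi`` per frame and frames in state k at ``r_k * phi * d_k``.
    The scheduler's warm-up shortens the effective track.
    """
    rates = config.bout_rates
    dwell = {k: max(MIN_DWELL[k], config.bout_duration_frames.get(k, MIN_DWELL[k])) for k in rates}
    s = sum(rates[k] * (dwell[k] + REFRACTORY_FRAMES[k]) for k in rates)
    phi = 1.0 / (1.0 + s)
    n_eff = max(0, config.n_frames - WARMUP_FRAMES)
    out = {"phi": phi, "effective_frames": n_eff}
    for k in rates:
        init_per_frame = rates[k] * phi
        out[k] = {
            "expected_bouts_per_larva": init_per_frame * n_eff,
            "expected_frame_fraction": init_per_frame * dwell[k] * (n_eff / config.n_frames),
        }
    return out


def coil_rate_for_fraction(config: LocomotionConfig, target_fraction: float) -> float:
    """Invert the renewal expectation to get the coil entry rate that yields
    ``target_fraction`` coiled frames (fraction of all frames)."""
    d_c = max(MIN_DWELL["coil"], config.bout_duration_frames.get("coil", 1.0))
    r_c = REFRACTORY_FRAMES["coil"]
    n = config.n_frames
    f = target_fraction * n / max(1, n - WARMUP_FRAMES)
    s_other = sum(
        config.bout_rates[k]
        * (max(MIN_DWELL[k], config.bout_duration_frames.get(k, MIN_DWELL[k])) + REFRACTORY_FRAMES[k])
        for k in config.bout_rates
        if k != "coil"
    )
    denom = d_c - f * (d_c + r_c)
    if denom <= 0:
        raise ConfigError("coil fraction target unreachable with this dwell/refractory")
    return f * (1.0 + s_other) / denom


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


def _unit(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([math.cos(r), math.sin(r)])


def _draw_dwell(rng: np.random.Generator, kind: str, mean: float) -> int:
    lo = MIN_DWELL[kind]
    if kind == "turn":
        return int(mean) if mean >= lo else lo
    if mean <= lo:
        return lo
    return lo + int(rng.poisson(mean - lo))


def _spine_for(
    centroid: np.ndarray, heading_deg: float, dev_deg: float, length: float, k: int, coil: bool
) -> np.ndarray:
    """Construct a K-point head→tail spine at the given posture.

    Normal posture: two straight chords meeting at the centroid with an
    interior angle of 180° − dev.  Coil: spine laid on a closed circle so the
    head point coincides with the tail tip.
    """
    if coil:
        rho = length / (2.0 * math.pi)
        theta = np.linspace(0.0, 2.0 * math.pi, k) + math.radians(heading_deg)
        pts = centroid[None, :] + rho * np.column_stack([np.cos(theta), np.sin(theta)])
        return pts
    u_tail = -_unit(heading_deg)
    u_head = _rot(dev_deg) @ _unit(heading_deg)
    half = length / 2.0
    n_half = k // 2
    pts = np.empty((k, 2))
    pts[n_half] = centroid
    for j in range(1, n_half + 1):
        frac = j / n_half
        pts[n_half - j] = centroid + frac * half * u_head
        pts[n_half + j] = centroid + frac * half * u_tail
    return pts


def simulate_tracks(config: LocomotionConfig) -> TrackSimulation:
    """Generate seeded larval tracks together with the ground-truth bout log.

    Frame-resolution renewal scheduler: from crawl, each eligible frame enters
    a bout kind with its configured probability; dwells respect the
    classifiers' minimum durations; every bout is followed by a forced crawl
    refractory.  Stops and the stop phase of turns hold the centroid exactly
    (zero displacement); head bends move while bent ≥ 20°; coils fold the
    head onto the tail tip while gliding.  Turns are only started when the
    arena leaves room for the post-turn straight run, so every logged turn is
    geometrically detectable.
    """
    rates = dict(config.bout_rates)
    if config.coil_frame_fraction_target is not None:
        rates["coil"] = coil_rate_for_fraction(config, config.coil_frame_fraction_target)
    order = ["stop", "head_bend", "turn", "coil"]
    cum = np.cumsum([rates.get(k, 0.0) for k in order])
    if cum[-1] > 1.0:
        raise ConfigError("summed bout entry rates exceed 1")

    n = config.n_frames
    fps = config.fps
    L = config.spine_length_mm
    k_spine = config.n_spine_points
    margin = 2.0 * L
    lo, hi = margin, config.arena_size_mm - margin
    if hi <= lo:
        raise ConfigError("arena too small for the spine length")
    base_step = config.crawl_speed_mm_s / fps
    width = 0.12 * L
    area0 = L * width
    eps_guard = EthogramParams().move_eps_frac * L  # crawl steps must stay above this
    if base_step * (1.0 - config.speed_osc_frac) <= eps_guard:
        warnings.warn(
            "crawl speed is so low that crawling frames may fall below the "
            "default movement threshold; stop detection will not match the log",
            stacklevel=2,
        )

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_larvae)
    tracks: list[LarvaTrack] = []
    logs: dict[str, list[BehaviorBout]] = {}

    for idx in range(config.n_larvae):
        rng = np.random.default_rng(seeds[idx])
        larva_id = f"larva{idx:03d}"
        pos = np.empty((n, 2))
        heading = np.empty(n)
        dev = np.empty(n)
        coil_flag = np.zeros(n, dtype=bool)
        osc_on = np.ones(n, dtype=bool)
        state = np.array(["crawl"] * n, dtype=object)
        log: list[BehaviorBout] = []

        center = config.arena_size_mm / 2.0
        span = (hi - lo) * 0.3
        pos[0] = center + rng.uniform(-span, span, size=2)
        heading[0] = rng.uniform(0.0, 360.0)
        phase = rng.uniform(0.0, 2.0 * math.pi)

        # schedule pass is interleaved with kinematics so turns can respect walls
        bout_until = -1  # last frame of the active bout
        refractory_until = WARMUP_FRAMES - 1
        hold_step = False  # True while the active bout freezes the centroid
        last_bounce = -10_000

        t = 0
        while t < n - 1:
            i = t + 1  # frame being generated by this step
            # possibly start a new bout at frame i
            if i > bout_until and i > refractory_until:
                u = rng.random()
                kind = None
                for k_, c_ in zip(order, cum):
                    if u < c_:
                        kind = k_
                        break
                if kind is not None:
                    dwell = _draw_dwell(rng, kind, config.bout_duration_frames.get(kind, MIN_DWELL[kind]))
                    fits = i + dwell <= n
                    if kind == "turn":
                        fits = fits and (i + dwell + EthogramParams().turn_forward_frames + 2 <= n)
                        fits = fits and (i - 1 - last_bounce) > WARMUP_FRAMES
                    if kind == "turn" and fits:
                        # steer so the post-turn straight run stays inside the arena
                        turn_delta = None
                        for _ in range(8):
                            delta = rng.uniform(45.0, 120.0) * rng.choice([-1.0, 1.0])
                            probe = pos[t] + 40.0 * base_step * _unit((heading[t] + delta) % 360.0)
                            if np.all((probe > lo) & (probe < hi)):
                                turn_delta = delta
                                break
                        if turn_delta is None:
                            fits = False
                    if fits:
                        bout_until = i + dwell - 1
                        state[i : i + dwell] = kind
                        refractory_until = bout_until + REFRACTORY_FRAMES[kind]
                        if kind == "turn":
                            bend_peak = rng.uniform(25.0, 45.0)
                        elif kind == "head_bend":
                            bend_peak = min(70.0, 22.0 + rng.exponential(8.0))
                        else:
                            bend_peak = float("nan")

            st = state[i]
            in_bout = i <= bout_until
            # centroid step into frame i: the first frame of a stationary bout
            # still carries the approach step; later frames hold position
            osc_step = base_step * (
                1.0 + config.speed_osc_frac * math.sin(2 * math.pi * config.peristalsis_hz * (i / fps) + phase)
            )
            if st in ("stop", "turn") and state[i - 1] == st:
                step_len = 0.0
            else:
                step_len = osc_step

            if st == "crawl":
                heading[i] = heading[t] + rng.normal(0.0, config.heading_noise_deg)
            else:
                heading[i] = heading[t]

            nxt = pos[t] + step_len * _unit(heading[i])
            if step_len > 0 and not np.all((nxt > lo) & (nxt < hi)):
                # reflect at the wall
                h = heading[i] % 360.0
                if nxt[0] <= lo or nxt[0] >= hi:
                    h = (180.0 - h) % 360.0
                if nxt[1] <= lo or nxt[1] >= hi:
                    h = (-h) % 360.0
                heading[i] = h
                nxt = pos[t] + step_len * _unit(heading[i])
                nxt = np.clip(nxt, lo, hi)
                last_bounce = i
            pos[i] = nxt

            # posture
            if st == "coil":
                coil_flag[i] = True
                dev[i] = float("nan")  # computed from spine geometry later
                osc_on[i] = False
            elif st in ("head_bend", "turn"):
                # stays strictly above the 20 deg classifier threshold
                dev[i] = 21.0 + (bend_peak - 21.0) * rng.uniform(0.0, 1.0)
                osc_on[i] = st == "head_bend"
            elif st == "stop":
                dev[i] = min(15.0, abs(rng.normal(0.0, config.bend_noise_deg)))
                osc_on[i] = False
            else:
                dev[i] = min(15.0, abs(rng.normal(0.0, config.bend_noise_deg)))

            # bout bookkeeping: log on the bout's last frame; apply turn heading
            if in_bout and i == bout_until:
                s_frame = bout_until
                while s_frame > 0 and state[s_frame - 1] == st:
                    s_frame -= 1
                log.append(BehaviorBout(st, s_frame, bout_until))
                if st == "turn":
                    heading[i] = (heading[i] + turn_delta) % 360.0
            t += 1

        dev[0] = min(15.0, abs(rng.normal(0.0, config.bend_noise_deg)))

        # body area: peristaltic oscillation while locomoting, held during
        # stationary/coiled frames
        area = np.empty(n)
        times = np.arange(n) / fps
        osc = area0 * (1.0 + config.area_osc_frac * np.sin(2 * math.pi * config.peristalsis_hz * times + phase))
        area[0] = osc[0]
        for i in range(1, n):
            area[i] = osc[i] if osc_on[i] else area[i - 1]

        # assemble spines and derived per-frame features
        spine = np.empty((n, k_spine, 2))
        bend_deg = np.empty(n)
        slen = np.empty(n)
        for i in range(n):
            pts = _spine_for(pos[i], heading[i], dev[i] if np.isfinite(dev[i]) else 0.0, L, k_spine, coil_flag[i])
            spine[i] = pts
            slen[i] = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            mid = pts[k_spine // 2]
            u = pts[0] - mid
            v = pts[-1] - mid
            c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
            bend_deg[i] = math.degrees(math.acos(c))

        track = LarvaTrack(
            larva_id=larva_id,
            fps=fps,
            centroid_mm=pos,
            spine_mm=spine,
            bending_deg=bend_deg,
            area_mm2=area,
            spine_len_mm=slen,
        )
        # fill logged peak deviations from the emitted series so the log and
        # the classifiers agree to the bit
        series = bending_series(track)
        log = [
            replace(b, peak_deviation_deg=float(np.nanmax(series[b.start_frame : b.end_frame + 1])))
            for b in log
        ]
        tracks.append(track)
        logs[larva_id] = sorted(log, key=lambda b: b.start_frame)

    return TrackSimulation(tracks=tracks, bouts=logs, config=config)


# ---------------------------------------------------------------------------
# Silhouette rasterization
# ---------------------------------------------------------------------------


def rasterize_track(
    track: LarvaTrack,
    pixel_size_mm: float,
    arena_size_mm: float | None = None,
) -> np.ndarray:
    """Render a track as a stack of binary silhouettes (one page per frame).

    The larva is drawn as a thick polyline along the spine; the body width is
    derived from the stored area (width = area / spine length).  Frames whose
    spine leaves the canvas are clipped with a warning.  The stack round-trips
    through multi-page TIFF via :mod:`tifffile`.
    """
    from skimage.draw import disk

    px = float(pixel_size_mm)
    valid_idx = np.flatnonzero(track.valid)
    if valid_idx.size == 0:
        return np.zeros((0, 1, 1), dtype=np.uint8)
    if arena_size_mm is None:
        pts = track.spine_mm[valid_idx].reshape(-1, 2)
        pad = 2.0 * float(np.nanmax(track.spine_len_mm))
        x0, y0 = np.nanmin(pts, axis=0) - pad
        x1, y1 = np.nanmax(pts, axis=0) + pad
        x0 = min(x0, 0.0)
        y0 = min(y0, 0.0)
    else:
        x0 = y0 = 0.0
        x1 = y1 = arena_size_mm
    n_cols = int(math.ceil((x1 - x0) / px))
    n_rows = int(math.ceil((y1 - y0) / px))
    stack = np.zeros((valid_idx.size, n_rows, n_cols), dtype=np.uint8)

    clipped = False
    for page, i in enumerate(valid_idx):
        pts = track.spine_mm[i]
        width = max(track.area_mm2[i] / max(track.spine_len_mm[i], 1e-9), 2.5 * px)
        radius_px = max(1.5, (width / 2.0) / px)
        # dense resample of the polyline
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n_samp = max(2, int(s[-1] / (px * 0.5)))
        targets = np.linspace(0.0, s[-1], n_samp)
        xs = np.interp(targets, s, pts[:, 0])
        ys = np.interp(targets, s, pts[:, 1])
        for x, y in zip(xs, ys):
            r = n_rows - (y - y0) / px - 0.5
            c = (x - x0) / px - 0.5
            if r < 0 or r >= n_rows or c < 0 or c >= n_cols:
                clipped = True
            rr, cc = disk((r, c), radius_px, shape=(n_rows, n_cols))
            stack[page, rr, cc] = 1
    if clipped:
        warnings.warn("spine outside canvas: silhouette clipped", stacklevel=2)
    return stack


# ---------------------------------------------------------------------------
# Dual-electrode recording simulation
# ---------------------------------------------------------------------------


def _spike_template(sampling_hz: float) -> tuple[np.ndarray, int]:
    """Fixed 2-ms biphasic spike template; returns (waveform, index of the
    positive peak sample)."""
    t = np.arange(-0.6e-3, 1.4e-3, 1.0 / sampling_hz)
    w = np.exp(-(t**2) / (2 * (0.15e-3) ** 2)) - 0.55 * np.exp(-((t - 0.55e-3) ** 2) / (2 * (0.25e-3) ** 2))
    peak = int(np.argmax(w))
    return w / w[peak], peak


@dataclass
class RecordingSimulation:
    """A simulated dual recording plus its ground truth."""

    recording: "DualRecording"
    spike_times1_s: np.ndarray
    spike_times2_s: np.ndarray
    unit_ids: np.ndarray
    unit_amplitudes: np.ndarray
    config: EphysConfig

    @property
    def true_delay_s(self) -> float:
        return self.config.true_delay_s


def simulate_recording(config: EphysConfig) -> RecordingSimulation:
    """Simulate a dual extracellular recording with known conduction delay.

    Each unit fires as a Poisson process (thinned to a minimum ISI); its
    biphasic spikes appear on electrode 1 and again on electrode 2 after
    Δd / v plus Gaussian jitter.  Units are separated by amplitude.  Spike
    times are quantized to the sample grid (positive-peak convention), so at
    zero jitter and a delay that is an integer number of samples the
    downstream velocity estimate is exact.
    """
    from .ephys import DualRecording

    rng = np.random.default_rng(config.seed)
    fs = config.sampling_hz
    n = int(round(config.duration_s * fs))
    delay_samples = int(round(config.true_delay_s * fs))
    template, peak_idx = _spike_template(fs)
    guard = len(template) / fs

    t1_all, t2_all, units = [], [], []
    amplitudes = 1.0 + np.arange(config.n_units)
    for u in range(config.n_units):
        n_expect = config.firing_rate_hz * config.duration_s
        raw = np.sort(rng.uniform(0.0, config.duration_s, size=rng.poisson(n_expect)))
        keep = []
        last = -np.inf
        for t in raw:
            if (t - last) * 1000.0 >= config.min_isi_ms:
                keep.append(t)
                last = t
        for t in keep:
            s1 = int(round(t * fs))
            jitter = rng.normal(0.0, config.jitter_ms / 1000.0) if config.jitter_ms > 0 else 0.0
            s2 = s1 + delay_samples + int(round(jitter * fs))
            if s1 - peak_idx < 0 or s2 + len(template) - peak_idx >= n:
                continue
            if s2 <= s1:
                continue
            t1_all.append(s1 / fs)
            t2_all.append(s2 / fs)
            units.append(u)

    t1 = np.asarray(t1_all)
    t2 = np.asarray(t2_all)
    unit_ids = np.asarray(units, dtype=int)
    order = np.argsort(t1)
    t1, t2, unit_ids = t1[order], t2[order], unit_ids[order]

    trace1 = np.zeros(n)
    trace2 = np.zeros(n)
    for tt1, tt2, u in zip(t1, t2, unit_ids):
        a = amplitudes[u]
        s1 = int(round(tt1 * fs)) - peak_idx
        s2 = int(round(tt2 * fs)) - peak_idx
        trace1[s1 : s1 + len(template)] += a * template
        trace2[s2 : s2 + len(template)] += a * template
    if config.noise_sd > 0:
        trace1 += rng.normal(0.0, config.noise_sd, size=n)
        trace2 += rng.normal(0.0, config.noise_sd, size=n)

    rec = DualRecording(
        sampling_hz=fs,
        trace1_volts=trace1,
        trace2_volts=trace2,
        electrode_distance_mm=config.electrode_distance_mm,
    )
    return RecordingSimulation(
        recording=rec,
        spike_times1_s=t1,
        spike_times2_s=t2,
        unit_ids=unit_ids,
        unit_amplitudes=amplitudes,
        config=config,
    )


# ---------------------------------------------------------------------------
# Nerve cross-section simulation
# ---------------------------------------------------------------------------


def simulate_nerve(config: NerveConfig):
    """Simulate a nerve cross-section annotation with known wrapping layout.

    Axon areas follow the lognormal radius model (area = π r²).  A configured
    fraction of axons is individually wrapped; the rest are pooled into
    wrapped fascicles, or into a single naked (unwrapped) unit when no
    fascicles are requested.  Returns ``(section, ground_truth_index)``.
    """
    from .morpho import NerveSection

    rng = np.random.default_rng(config.seed)
    n = config.n_axons
    radii = np.exp(rng.normal(config.radius_log_mean_um, config.radius_log_sd_um, size=n))
    areas = math.pi * radii**2

    n_ind = int(round(config.frac_individually_wrapped * n))
    n_rest = n - n_ind
    if config.n_fascicles > n_rest:
        raise ConfigError("more fascicles than axons left after individual wrapping")

    axon_ids = [f"ax{i:04d}" for i in range(n)]
    perm = rng.permutation(n)
    unit_of = {}
    units: dict[str, bool] = {}
    for j in range(n_ind):
        uid = f"ind{j:04d}"
        unit_of[axon_ids[perm[j]]] = uid
        units[uid] = True
    rest = perm[n_ind:]
    if config.n_fascicles > 0 and n_rest > 0:
        # each fascicle gets at least one axon, remainder assigned uniformly
        assign = np.concatenate(
            [np.arange(config.n_fascicles), rng.integers(0, config.n_fascicles, size=n_rest - config.n_fascicles)]
        )
        rng.shuffle(assign)
        for ax_i, f_i in zip(rest, assign):
            uid = f"fas{f_i:03d}"
            unit_of[axon_ids[ax_i]] = uid
            units[uid] = True
    elif n_rest > 0:
        for ax_i in rest:
            unit_of[axon_ids[ax_i]] = "naked"
        units["naked"] = False

    section = NerveSection(
        nerve_id=f"sim{config.seed:08d}",
        axon_ids=axon_ids,
        areas_um2=areas,
        unit_of_axon=[unit_of[a] for a in axon_ids],
        wrapped_units={u for u, w in units.items() if w},
        all_units=set(units),
    )
    n_wrapped_units = sum(1 for w in units.values() if w)
    truth = 100.0 * n_wrapped_units / n
    return section, truth
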
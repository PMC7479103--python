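import math

import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from nervekit.trackio import LarvaTrack


def _unit(deg):
    r = math.radians(deg)
    return np.array([math.cos(r), math.sin(r)])


def build_track(
    positions,
    fps: float = 10.0,
    dev_deg=None,
    spine_length_mm: float = 4.0,
    coil=None,
    larva_id: str = "t0",
    area=None,
) -> LarvaTrack:
    """Construct a track with explicit centroid path and bending deviations.

    Spines are two straight chords meeting at the centroid with interior
    angle 180 - dev; coil frames place the spine on a closed circle so the
    head coincides with the tail.  Heading follows the centroid displacement
    (held through stationary frames).
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    dev = np.zeros(n) if dev_deg is None else np.asarray(dev_deg, dtype=float)
    coil = np.zeros(n, dtype=bool) if coil is None else np.asarray(coil, dtype=bool)
    L = spine_length_mm
    k = 5
    heading = np.zeros(n)
    for i in range(1, n):
        step = pos[i] - pos[i - 1]
        heading[i] = math.degrees(math.atan2(step[1], step[0])) if np.linalg.norm(step) > 0 else heading[i - 1]
    heading[0] = heading[1] if n > 1 else 0.0

    spine = np.empty((n, k, 2))
    for i in range(n):
        if coil[i]:
            rho = L / (2 * math.pi)
            th = np.linspace(0, 2 * math.pi, k)
            spine[i] = pos[i] + rho * np.column_stack([np.cos(th), np.sin(th)])
        else:
            u_tail = -_unit(heading[i])
            r = math.radians(dev[i])
            rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
            u_head = rot @ _unit(heading[i])
            half = L / 2
            spine[i, 2] = pos[i]
            spine[i, 1] = pos[i] + 0.5 * half * u_head
            spine[i, 0] = pos[i] + half * u_head
            spine[i, 3] = pos[i] + 0.5 * half * u_tail
            spine[i, 4] = pos[i] + half * u_tail
    slen = np.array([np.linalg.norm(np.diff(spine[i], axis=0), axis=1).sum() for i in range(n)])
    bend = np.empty(n)
    for i in range(n):
        u = spine[i, 0] - spine[i, 2]
        v = spine[i, 4] - spine[i, 2]
        c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        bend[i] = math.degrees(math.acos(c))
    if area is None:
        area = np.full(n, 0.48 * L)
    return LarvaTrack(
        larva_id=larva_id,
        fps=fps,
        centroid_mm=pos,
        spine_mm=spine,
        bending_deg=bend,
        area_mm2=np.asarray(area, dtype=float),
        spine_len_mm=slen,
    )


def straight_path(n, step=0.3, heading_deg=0.0, start=(50.0, 50.0)):
    u = _unit(heading_deg)
    return np.asarray(start) + step * np.outer(np.arange(n), u)


@pytest.fixture
def moving_track():
    return build_track(straight_path(60))
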
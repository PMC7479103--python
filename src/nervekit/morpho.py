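"""Axon morphometry from EM cross-section annotations.

Inputs are per-axon area tables with wrapping-unit membership (the tracing
itself is manual and out of scope).  Provides the circular-equivalent radius,
axon-size histograms with per-bin relative changes between conditions, the
76–82-axon nerve filter, and the wrapping index

    w_i = 100 × (# wrapped units) / (# axons),

where a wrapped unit is a single individually wrapped axon or a wrapped
fascicle; w_i = 100 means every axon is wrapped on its own.  Axons not
enclosed by any glial unit sit in a single "naked" unit with wrapped=False
and contribute nothing to the numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "NerveSection",
    "SizeHistogram",
    "radius_from_area",
    "wrapping_index",
    "filter_nerves",
    "size_histogram",
    "relative_change",
    "summarize_radii",
    "read_sections",
    "write_sections",
    "AXON_COUNT_RANGE",
]

AXON_COUNT_RANGE = (76, 82)  # inclusive bounds of the nerve-quality filter
DEFAULT_BIN_WIDTH_UM2 = 0.04


@dataclass
class NerveSection:
    """Annotation of one nerve cross-section."""

    nerve_id: str
    axon_ids: list[str]
    areas_um2: np.ndarray
    unit_of_axon: list[str]
    wrapped_units: set[str]
    all_units: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if len(self.axon_ids) != len(self.areas_um2) or len(self.axon_ids) != len(self.unit_of_axon):
            raise ValueError("axon ids, areas and unit membership must align")
        if np.any(self.areas_um2 <= 0):
            raise ValueError("axon areas must be positive")
        if not self.all_units:
            self.all_units = set(self.unit_of_axon) | set(self.wrapped_units)
        missing = set(self.unit_of_axon) - self.all_units
        if missing:
            raise ValueError(f"axons reference unknown unit(s): {sorted(missing)}")

    @property
    def n_axons(self) -> int:
        return len(self.axon_ids)

    def radii_um(self) -> np.ndarray:
        return radius_from_area(self.areas_um2)


@dataclass
class SizeHistogram:
    """Axon-area histogram with fixed half-open bins [k·w, (k+1)·w)."""

    bin_width: float
    counts: np.ndarray
    n_axons: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != self.n_axons:
            raise ValueError("bin counts must sum to the number of axons")

    @property
    def edges(self) -> np.ndarray:
        return self.bin_width * np.arange(len(self.counts) + 1)


def radius_from_area(area_um2):
    """Circular-equivalent radius r = sqrt(area / π).

    Areas are measured instead of diameters to minimize the effect of
    fixation artifacts on shape.
    """
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    r = np.sqrt(area / math.pi)
    return float(r) if np.isscalar(area_um2) or area.ndim == 0 else r


def wrapping_index(section: NerveSection) -> float:
    """100 × (individually wrapped axons + wrapped fascicles) / total axons."""
    if section.n_axons == 0:
        raise DegenerateInputError("wrapping index undefined for an empty nerve")
    occupied = set(section.unit_of_axon)
    n_wrapped_units = len(occupied & section.wrapped_units)
    return 100.0 * n_wrapped_units / section.n_axons


def filter_nerves(
    sections: Iterable[NerveSection],
    axon_range: tuple[int, int] = AXON_COUNT_RANGE,
) -> tuple[list[NerveSection], list[dict]]:
    """Keep nerves whose axon count lies within the inclusive range.

    Returns (retained sections, exclusion log with ids and reasons).
    """
    lo, hi = axon_range
    kept, log = [], []
    for sec in sections:
        if lo <= sec.n_axons <= hi:
            kept.append(sec)
        else:
            side = "below" if sec.n_axons < lo else "above"
            log.append(
                {"nerve_id": sec.nerve_id, "n_axons": sec.n_axons,
                 "reason": f"axon count {side} the {lo}-{hi} range"}
            )
    return kept, log


def size_histogram(areas_um2: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH_UM2) -> SizeHistogram:
    """Histogram of axon areas in fixed-width half-open bins starting at 0."""
    areas = np.asarray(areas_um2, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if areas.size == 0:
        return SizeHistogram(bin_width=bin_width, counts=np.zeros(0, dtype=int), n_axons=0)
    n_bins = int(np.floor(areas.max() / bin_width)) + 1
    idx = np.floor(areas / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return SizeHistogram(bin_width=bin_width, counts=counts, n_axons=areas.size)


def relative_change(hist_control: SizeHistogram, hist_treat: SizeHistogram) -> np.ndarray:
    """Per-bin relative change (n_treat − n_control) / n_control.

    Bins empty in the control are undefined and returned as NaN.  Both
    histograms must use the same bin width; the shorter one is zero-padded.
    """
    if not math.isclose(hist_control.bin_width, hist_treat.bin_width):
        raise ValueError("histograms use different bin widths")
    n = max(len(hist_control.counts), len(hist_treat.counts))
    c = np.zeros(n)
    t = np.zeros(n)
    c[: len(hist_control.counts)] = hist_control.counts
    t[: len(hist_treat.counts)] = hist_treat.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (t - c) / c
    out[c == 0] = np.nan
    return out


def summarize_radii(sections: Sequence[NerveSection]) -> dict:
    """Pooled mean radius over all axons of the given (already filtered) nerves."""
    sections = list(sections)
    if not sections:
        raise DegenerateInputError("no nerves to summarize")
    radii = np.concatenate([s.radii_um() for s in sections])
    return {
        "mean_radius_um": float(radii.mean()),
        "median_radius_um": float(np.median(radii)),
        "n_axons": int(radii.size),
        "n_nerves": len(sections),
    }


# ---------------------------------------------------------------------------
# CSV dialect: axons.csv (nerve_id, axon_id, area_um2, unit_id)
#              units.csv (nerve_id, unit_id, wrapped)
# ---------------------------------------------------------------------------


def write_sections(sections: Iterable[NerveSection], axons_path, units_path) -> None:
    ax_rows, un_rows = [], []
    for sec in sections:
        for aid, area, uid in zip(sec.axon_ids, sec.areas_um2, sec.unit_of_axon):
            ax_rows.append({"nerve_id": sec.nerve_id, "axon_id": aid, "area_um2": area, "unit_id": uid})
        for uid in sorted(sec.all_units):
            un_rows.append({"nerve_id": sec.nerve_id, "unit_id": uid, "wrapped": uid in sec.wrapped_units})
    pd.DataFrame(ax_rows, columns=["nerve_id", "axon_id", "area_um2", "unit_id"]).to_csv(
        axons_path, index=False, float_format="%.6g"
    )
    pd.DataFrame(un_rows, columns=["nerve_id", "unit_id", "wrapped"]).to_csv(units_path, index=False)


def read_sections(axons_path, units_path) -> list[NerveSection]:
    ax = pd.read_csv(axons_path)
    un = pd.read_csv(units_path)
    out = []
    for nerve_id, sub in ax.groupby("nerve_id", sort=True):
        usub = un[un["nerve_id"] == nerve_id]
        wrapped = set(usub.loc[usub["wrapped"].astype(bool), "unit_id"].astype(str))
        out.append(
            NerveSection(
                nerve_id=str(nerve_id),
                axon_ids=[str(a) for a in sub["axon_id"]],
                areas_um2=sub["area_um2"].to_numpy(),
                unit_of_axon=[str(u) for u in sub["unit_id"]],
                wrapped_units=wrapped,
                all_units=set(usub["unit_id"].astype(str)),
            )
        )
    return out
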
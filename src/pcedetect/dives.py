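"""Dive detection, surface-dive classification and phase splitting.

A dive is any maximal run of samples deeper than 0.4 m.  Dives with maximum
depth <= 2 m or duration <= 10 s are "surface dives" and are not split into
phases.  Deeper/longer ("regular") dives are partitioned into descent,
bottom and ascent using the normalized depth rate of change: the descent
ends at the first point where the normalized rate drops below 0.5 while the
depth exceeds 50% of the dive's maximum; the ascent start is found by the
mirror-image criterion scanning the time-reversed dive.

The depth rate is evaluated on the 1 Hz grid anchored at the dive start
(matching the native TDR resolution), smoothed with a 3-point moving
average, and normalized by the dive's maximum absolute smoothed 1 s
difference, which makes the 0.5 threshold scale-free.  Boundary equality
(rate exactly 0.5, depth exactly 50%) does not satisfy the strict
inequalities.

Indices are 0-based sample indices into the 25 Hz merged series and all
intervals are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SyncedSeries

logger = logging.getLogger(__name__)

SURFACE = "surface"
DESCENT = "descent"
BOTTOM = "bottom"
ASCENT = "ascent"


@dataclass
class DiveConfig:
    """Thresholds for dive detection and phase splitting (metres, seconds)."""

    dive_threshold_m: float = 0.4
    surface_dive_max_depth_m: float = 2.0
    surface_dive_max_duration_s: float = 10.0
    rate_norm_threshold: float = 0.5
    depth_frac_threshold: float = 0.5
    rate_smooth_points: int = 3

    def __post_init__(self) -> None:
        for name in ("dive_threshold_m", "surface_dive_max_depth_m",
                     "surface_dive_max_duration_s", "rate_norm_threshold",
                     "depth_frac_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DiveConfig.{name} must be positive")


@dataclass
class Dive:
    """One detected dive: [start_idx, end_idx) on the 25 Hz series."""

    dive_id: int
    start_idx: int
    end_idx: int
    max_depth_m: float
    duration_s: float
    kind: str = "regular"
    descent_end_idx: int | None = None
    ascent_start_idx: int | None = None
    degenerate_bottom: bool = False
    foraging: bool = False
    pitch_sd_deg: float | None = None
    individual_id: str = field(default="", repr=False)

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    def phase_of(self, idx: int) -> str:
        """Phase of a 25 Hz sample index (``surface`` if outside the dive
        or if the dive is a surface dive, which is not phase-split)."""
        if idx < self.start_idx or idx >= self.end_idx:
            return SURFACE
        if self.kind == SURFACE:
            return SURFACE
        if idx < self.descent_end_idx:
            return DESCENT
        if idx >= self.ascent_start_idx:
            return ASCENT
        return BOTTOM


def detect_dives(series: SyncedSeries, cfg: DiveConfig | None = None) -> list[Dive]:
    """Find maximal runs of depth > threshold, classify and phase-split them.

    Returns dives ordered by start index; an empty list when the depth never
    exceeds the threshold.
    """
    cfg = cfg or DiveConfig()
    under = series.depth > cfg.dive_threshold_m
    if not under.any():
        return []
    edges = np.diff(under.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if under[0]:
        starts = np.r_[0, starts]
    if under[-1]:
        ends = np.r_[ends, len(under)]
    dives = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        d = Dive(
            dive_id=i,
            start_idx=int(s),
            end_idx=int(e),
            max_depth_m=float(series.depth[s:e].max()),
            duration_s=(e - s) / series.rate_hz,
            individual_id=series.individual_id,
        )
        d.kind = classify_dive(d, cfg)
        if d.kind == "regular":
            d.descent_end_idx, d.ascent_start_idx = split_phases(d, series, cfg)
        dives.append(d)
    return dives


def classify_dive(dive: Dive, cfg: DiveConfig | None = None) -> str:
    """``surface`` iff max depth <= 2 m OR duration <= 10 s, else ``regular``."""
    cfg = cfg or DiveConfig()
    if (dive.max_depth_m <= cfg.surface_dive_max_depth_m
            or dive.duration_s <= cfg.surface_dive_max_duration_s):
        return SURFACE
    return "regular"


def _smooth3(x: np.ndarray, k: int) -> np.ndarray:
    """Centered k-point moving average with shrinking edge windows."""
    if len(x) == 0 or k <= 1:
        return x.astype(np.float64)
    half = k // 2
    c = np.cumsum(np.r_[0.0, x])
    out = np.empty(len(x))
    for i in range(len(x)):
        a, b = max(0, i - half), min(len(x), i + half + 1)
        out[i] = (c[b] - c[a]) / (b - a)
    return out


def _descent_end_grid(depth_1hz: np.ndarray, max_depth: float,
                      cfg: DiveConfig) -> int | None:
    """First 1 Hz grid point at which descent has ended, or None.

    The rate at grid step k is depth[k+1]-depth[k]; descent ends at point
    k+1 when the smoothed normalized rate at step k is < threshold and the
    depth at point k+1 is > depth_frac_threshold * max depth (strict).
    """
    d = np.diff(depth_1hz)
    if len(d) == 0:
        return None
    sm = _smooth3(d, cfg.rate_smooth_points)
    denom = np.abs(sm).max()
    if denom == 0:
        return None
    norm = sm / denom
    ok = (norm < cfg.rate_norm_threshold) & \
         (depth_1hz[1:] > cfg.depth_frac_threshold * max_depth)
    hits = np.flatnonzero(ok)
    return int(hits[0]) + 1 if hits.size else None


def split_phases(dive: Dive, series: SyncedSeries,
                 cfg: DiveConfig | None = None) -> tuple[int, int]:
    """Return (descent_end_idx, ascent_start_idx) for a regular dive.

    The ascent start is located by applying the descent criterion to the
    time-reversed dive.  If either criterion is never met, or the two
    boundaries cross, the split falls back to the deepest sample and the
    dive is flagged ``degenerate_bottom``.
    """
    cfg = cfg or DiveConfig()
    step = int(round(series.rate_hz))  # 1 Hz grid on the 25 Hz series
    depth = series.depth[dive.start_idx:dive.end_idx]
    grid = np.arange(0, len(depth), step)
    d1 = depth[grid]

    k_desc = _descent_end_grid(d1, dive.max_depth_m, cfg)
    k_asc_rev = _descent_end_grid(d1[::-1], dive.max_depth_m, cfg)

    if k_desc is None or k_asc_rev is None:
        deepest = dive.start_idx + int(np.argmax(depth))
        dive.degenerate_bottom = True
        logger.info("dive %d: phase criteria never met, deepest-point split",
                    dive.dive_id)
        return deepest, deepest

    # forward: descent = grid points [0, k_desc); mirrored: ascent =
    # the last k_asc_rev grid points, so it starts at len(grid) - k_asc_rev
    descent_end = dive.start_idx + int(grid[k_desc])
    ascent_start = dive.start_idx + int(grid[len(grid) - k_asc_rev])
    if descent_end >= ascent_start:
        deepest = dive.start_idx + int(np.argmax(depth))
        dive.degenerate_bottom = True
        return deepest, deepest
    return descent_end, ascent_start


def flag_foraging(dive: Dive, labels: np.ndarray) -> bool:
    """True iff at least one labelled prey-capture sample overlaps the dive."""
    return bool(np.any(labels[dive.start_idx:dive.end_idx]))


def phase_of_sample(idx: int, dives: list[Dive]) -> str:
    """Phase of a sample index given a sorted dive list (surface if in none)."""
    for d in dives:
        if d.start_idx <= idx < d.end_idx:
            return d.phase_of(idx)
    return SURFACE


def dive_table(dives: list[Dive], rate_hz: float = 25.0):
    """Dive list as a pandas DataFrame (one row per dive)."""
    import pandas as pd

    return pd.DataFrame([{
        "dive_id": d.dive_id,
        "individual_id": d.individual_id,
        "start_s": d.start_idx / rate_hz,
        "end_s": d.end_idx / rate_hz,
        "max_depth_m": d.max_depth_m,
        "duration_s": d.duration_s,
        "kind": d.kind,
        "descent_end_s": None if d.descent_end_idx is None else d.descent_end_idx / rate_hz,
        "ascent_start_s": None if d.ascent_start_idx is None else d.ascent_start_idx / rate_hz,
        "degenerate_bottom": d.degenerate_bottom,
        "foraging": d.foraging,
        "pitch_sd_deg": d.pitch_sd_deg,
    } for d in dives])
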
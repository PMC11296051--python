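"""Static/dynamic acceleration, pitch, and the dive-threshold balancing filter.

The gravity (static) component of each accelerometer axis is estimated with
a centered 2 s running mean; the residual is the dynamic component.  Pitch
(body rotation about the sway axis, positive head-up) follows

    pitch = atan2(Xs, sqrt(Ys^2 + Zs^2))      [degrees]

Krill-eating penguins forage mostly in deeper dives and show large pitch
variability while feeding, so the training set for the windowed CNN is
balanced by keeping only samples inside dives that pass all of:
max depth > 2 m, duration > 10 s, pitch s.d. > 15 deg — and by dropping each
passing dive's descent phase, where captures are rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dives import Dive
from .io import SyncedSeries

logger = logging.getLogger(__name__)


@dataclass
class BalanceConfig:
    """Dive-level thresholds of the CNN training-data balancing filter."""

    min_max_depth_m: float = 2.0
    min_duration_s: float = 10.0
    min_pitch_sd_deg: float = 15.0
    exclude_descent: bool = True
    smoothing_window_s: float = 2.0

    def __post_init__(self) -> None:
        if min(self.min_max_depth_m, self.min_duration_s,
               self.min_pitch_sd_deg, self.smoothing_window_s) <= 0:
            raise ValueError("BalanceConfig thresholds must be positive")


def _odd_window(window_s: float, rate_hz: float) -> int:
    n = int(round(window_s * rate_hz))
    return max(1, n + 1 if n % 2 == 0 else n)


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available data."""
    return (pd.Series(x)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy())


def static_acceleration(series: SyncedSeries,
                        window_s: float = 2.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis gravity estimate: centered running mean (2 s -> 51 samples).

    Series shorter than the window are smoothed with shrunk windows and a
    warning is logged.
    """
    w = _odd_window(window_s, series.rate_hz)
    if len(series) < w:
        logger.warning("series shorter than the %0.1f s smoothing window; "
                       "edge-shrunk windows used throughout", window_s)
    return (running_mean(series.x, w),
            running_mean(series.y, w),
            running_mean(series.z, w))


def pitch_deg(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Pitch angle in degrees in [-90, 90] from static acceleration.

    atan2(0, 0) = 0 by convention; all-zero static vectors are counted in
    the log since their pitch is undefined physically.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    zs = np.asarray(zs, dtype=np.float64)
    zero = (xs == 0) & (ys == 0) & (zs == 0)
    nzero = int(np.count_nonzero(zero))
    if nzero:
        logger.warning("%d all-zero static-acceleration samples; pitch set to 0",
                       nzero)
    return np.degrees(np.arctan2(xs, np.hypot(ys, zs)))


def dive_pitch_sd(dive: Dive, pitch: np.ndarray) -> float:
    """Sample standard deviation of pitch over the dive interval (degrees)."""
    seg = pitch[dive.start_idx:dive.end_idx]
    if len(seg) < 2:
        return 0.0
    return float(np.std(seg, ddof=1))


def balancing_mask(series: SyncedSeries, dives: list[Dive],
                   cfg: BalanceConfig | None = None,
                   pitch: np.ndarray | None = None) -> np.ndarray:
    """Boolean per-sample mask of "most likely foraging" periods.

    True only inside dives with max depth > ``min_max_depth_m`` (strict),
    duration > ``min_duration_s`` (strict) and pitch s.d. >
    ``min_pitch_sd_deg`` (strict); descent-phase samples of passing dives
    are excluded when ``exclude_descent``.  Surface dives fail the depth or
    duration thresholds by definition.  Also records ``pitch_sd_deg`` on
    each dive.
    """
    cfg = cfg or BalanceConfig()
    if pitch is None:
        xs, ys, zs = static_acceleration(series, cfg.smoothing_window_s)
        pitch = pitch_deg(xs, ys, zs)
    mask = np.zeros(len(series), dtype=bool)
    for d in dives:
        d.pitch_sd_deg = dive_pitch_sd(d, pitch)
        if (d.max_depth_m > cfg.min_max_depth_m
                and d.duration_s > cfg.min_duration_s
                and d.pitch_sd_deg > cfg.min_pitch_sd_deg):
            lo = d.start_idx
            if cfg.exclude_descent and d.descent_end_idx is not None:
                lo = d.descent_end_idx
            mask[lo:d.end_idx] = True
    return mask


def balance_summary(mask: np.ndarray, labels: np.ndarray) -> dict:
    """Retention/reduction bookkeeping of the balancing filter.

    retention: fraction of labelled prey-capture samples kept by the mask;
    reduction: fraction of all samples removed; masked_prevalence: label
    prevalence within the kept region.
    """
    labels = np.asarray(labels, dtype=bool)
    total_pos = int(labels.sum())
    kept_pos = int((labels & mask).sum())
    kept = int(mask.sum())
    return {
        "retention": kept_pos / total_pos if total_pos else float("nan"),
        "reduction": 1.0 - kept / len(mask),
        "masked_in_fraction": kept / len(mask),
        "masked_prevalence": kept_pos / kept if kept else float("nan"),
    }


def normalize_axes(series: SyncedSeries) -> np.ndarray:
    """Per-individual, per-axis z-score of the (n, 3) accelerometer matrix.

    Computed over the individual's full series: removes logger mounting
    offsets and gain differences without leaking statistics across
    individuals.  Constant axes map to zero.
    """
    a = series.accel_matrix
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    sd[sd == 0] = 1.0
    return (a - mu) / sd


def feature_table(dives: list[Dive], cfg: BalanceConfig | None = None):
    """Per-dive feature CSV contents: thresholds inputs + filter outcome."""
    cfg = cfg or BalanceConfig()
    return pd.DataFrame([{
        "dive_id": d.dive_id,
        "individual_id": d.individual_id,
        "max_depth_m": d.max_depth_m,
        "duration_s": d.duration_s,
        "pitch_sd_deg": d.pitch_sd_deg,
        "passes_filter": (
            d.max_depth_m > cfg.min_max_depth_m
            and d.duration_s > cfg.min_duration_s
            and (d.pitch_sd_deg or 0.0) > cfg.min_pitch_sd_deg),
    } for d in dives])
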
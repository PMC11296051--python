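"""Reading, writing and merging of bio-logger exports.

Loggers deployed on diving seabirds typically produce two delimited text
streams per individual: a tri-axial accelerometer stream at 25 Hz (surge X,
sway Y, heave Z, in units of g) and a time-depth-recorder (TDR) stream at
1 Hz (depth in metres, positive down, plus optional temperature).  Analysis
happens on a single merged 25 Hz series in which the 1 Hz depth has been
linearly interpolated onto the accelerometer time base; the accelerometer
clock is taken as authoritative.

All timestamps are seconds since the first accelerometer sample of the trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column-name dialects for the supported logger exports.  Values are the
#: column names for (time, X, Y, Z) in accelerometer files and
#: (time, depth, temperature) in TDR files.
DIALECTS = {
    "default": {
        "accel": ("time_s", "ax_g", "ay_g", "az_g"),
        "tdr": ("time_s", "depth_m", "temp_c"),
    },
    "axytrek": {
        "accel": ("Timestamp", "X", "Y", "Z"),
        "tdr": ("Timestamp", "Depth", "Temp"),
    },
    "agm": {
        "accel": ("time", "accX", "accY", "accZ"),
        "tdr": ("time", "depth", "temperature"),
    },
}


class LoggerFileError(ValueError):
    """Raised when a logger export fails validation."""


@dataclass
class AccelSeries:
    """Tri-axial accelerometer stream at a nominal 25 Hz.

    Axes follow the body frame convention: X surge (forward), Y sway
    (lateral), Z heave (dorso-ventral).  Units are g.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    individual_id: str = ""
    rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise LoggerFileError("accelerometer columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class DepthSeries:
    """TDR stream at 1 Hz: depth in metres (positive down), optional °C."""

    t: np.ndarray
    depth: np.ndarray
    temperature: np.ndarray | None = None
    individual_id: str = ""
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=np.float64)
        if len(self.depth) != len(self.t):
            raise LoggerFileError("depth column length differs from timestamps")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SyncedSeries:
    """Merged 25 Hz analysis series: acceleration + interpolated depth.

    ``label`` is the optional per-sample binary prey-capture annotation
    (1 inside the 8-sample window around each capture, 0 elsewhere).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    depth: np.ndarray
    label: np.ndarray | None = None
    individual_id: str = ""
    rate_hz: float = 25.0
    clamped_samples: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if len(self.depth) != len(self.t):
            raise LoggerFileError("one depth value per accelerometer sample required")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=np.uint8)
            if len(self.label) != len(self.t):
                raise LoggerFileError("label length differs from series length")
            bad = np.setdiff1d(np.unique(self.label), [0, 1])
            if bad.size:
                raise LoggerFileError(f"labels must be binary, found {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def accel_matrix(self) -> np.ndarray:
        """(n, 3) array with columns X, Y, Z."""
        return np.column_stack([self.x, self.y, self.z])


def _validate_timestamps(t: np.ndarray, what: str) -> None:
    if len(t) == 0:
        raise LoggerFileError(f"{what}: file contains no data rows")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        # +2: 1-based line numbering plus the header row
        raise LoggerFileError(
            f"{what}: non-monotone timestamp at data line {int(bad[0]) + 2} "
            f"(t={t[bad[0] + 1]!r} follows t={t[bad[0]]!r})"
        )


def _read_table(path: str | Path, columns: tuple[str, ...], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise LoggerFileError(f"{what}: {path} is empty") from None
    for col in columns:
        if col not in df.columns:
            raise LoggerFileError(f"{what}: missing column {col!r} in {path}")
    if len(df) == 0:
        raise LoggerFileError(f"{what}: {path} contains no data rows")
    return df


def read_accel(path: str | Path, dialect: str = "default",
               individual_id: str = "") -> AccelSeries:
    """Read a 25 Hz tri-axial accelerometer CSV export.

    Raises :class:`LoggerFileError` on missing columns, empty files or
    non-monotone timestamps (reported with their data line number).
    """
    cols = DIALECTS[dialect]["accel"]
    df = _read_table(path, cols, "accelerometer file")
    t = df[cols[0]].to_numpy(dtype=np.float64)
    _validate_timestamps(t, "accelerometer file")
    return AccelSeries(
        t=t,
        x=df[cols[1]].to_numpy(dtype=np.float64),
        y=df[cols[2]].to_numpy(dtype=np.float64),
        z=df[cols[3]].to_numpy(dtype=np.float64),
        individual_id=individual_id or _id_from_path(path),
    )


def read_tdr(path: str | Path, dialect: str = "default",
             individual_id: str = "") -> DepthSeries:
    """Read a 1 Hz TDR (depth + optional temperature) CSV export."""
    cols = DIALECTS[dialect]["tdr"]
    df = _read_table(path, cols[:2], "TDR file")
    t = df[cols[0]].to_numpy(dtype=np.float64)
    _validate_timestamps(t, "TDR file")
    temp = None
    if cols[2] in df.columns:
        temp = df[cols[2]].to_numpy(dtype=np.float64)
    return DepthSeries(
        t=t,
        depth=df[cols[1]].to_numpy(dtype=np.float64),
        temperature=temp,
        individual_id=individual_id or _id_from_path(path),
    )


def read_labels(path: str | Path) -> np.ndarray:
    """Read a per-sample binary label CSV (column ``label``)."""
    df = _read_table(path, ("label",), "label file")
    lab = df["label"].to_numpy()
    bad = np.setdiff1d(np.unique(lab), [0, 1])
    if bad.size:
        raise LoggerFileError(f"label file: non-binary values {bad.tolist()}")
    return lab.astype(np.uint8)


def _id_from_path(path: str | Path) -> str:
    return Path(path).stem.split("_")[0]


def write_accel(series: AccelSeries, path: str | Path,
                dialect: str = "default") -> None:
    cols = DIALECTS[dialect]["accel"]
    pd.DataFrame({
        cols[0]: series.t, cols[1]: series.x,
        cols[2]: series.y, cols[3]: series.z,
    }).to_csv(path, index=False, float_format="%.17g")


def write_tdr(series: DepthSeries, path: str | Path,
              dialect: str = "default") -> None:
    cols = DIALECTS[dialect]["tdr"]
    data = {cols[0]: series.t, cols[1]: series.depth}
    if series.temperature is not None:
        data[cols[2]] = series.temperature
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"label": np.asarray(labels, dtype=np.uint8)}).to_csv(
        path, index=False)


def merge_streams(accel: AccelSeries, depth: DepthSeries,
                  label: np.ndarray | None = None) -> SyncedSeries:
    """Interpolate 1 Hz depth onto the 25 Hz accelerometer time base.

    Depth is linearly interpolated; accelerometer samples outside the TDR
    record's time span are clamped to the nearest depth value and their
    count is logged.  Zero temporal overlap is an error.
    """
    if accel.t[-1] < depth.t[0] or depth.t[-1] < accel.t[0]:
        raise LoggerFileError(
            "accelerometer and TDR records have no temporal overlap "
            f"(accel [{accel.t[0]}, {accel.t[-1]}] s, "
            f"TDR [{depth.t[0]}, {depth.t[-1]}] s)"
        )
    depth_interp = np.interp(accel.t, depth.t, depth.depth)
    clamped = int(np.sum((accel.t < depth.t[0]) | (accel.t > depth.t[-1])))
    if clamped:
        logger.warning(
            "%d accelerometer samples outside the TDR span; depth clamped "
            "to the nearest record", clamped)
    return SyncedSeries(
        t=accel.t, x=accel.x, y=accel.y, z=accel.z,
        depth=depth_interp, label=label,
        individual_id=accel.individual_id or depth.individual_id,
        clamped_samples=clamped,
    )


def split_on_gaps(accel: AccelSeries, max_gap_intervals: float = 2.0) -> list[AccelSeries]:
    """Split an accelerometer series at recording gaps.

    A gap longer than ``max_gap_intervals`` nominal sampling intervals
    splits the record into segments that are processed independently
    (mirrors the removal of unusable spans from field recordings).
    """
    nominal = 1.0 / accel.rate_hz
    dt = np.diff(accel.t)
    cuts = np.flatnonzero(dt > max_gap_intervals * nominal) + 1
    if cuts.size == 0:
        return [accel]
    segments = []
    for i, (s, e) in enumerate(zip(np.r_[0, cuts], np.r_[cuts, len(accel)])):
        segments.append(AccelSeries(
            t=accel.t[s:e], x=accel.x[s:e], y=accel.y[s:e], z=accel.z[s:e],
            individual_id=f"{accel.individual_id}_seg{i}" if accel.individual_id else "",
            rate_hz=accel.rate_hz,
        ))
    logger.info("split accelerometer record into %d segments at %d gaps",
                len(segments), cuts.size)
    return segments
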
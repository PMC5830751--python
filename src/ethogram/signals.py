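"""Sensor streams, annotations and the four derived analysis signals.

The classification pipeline never looks at individual axes: each window
is described through the Euclidean magnitude of the accelerometer
(``accel_mag``), the magnitude of the gyroscope (``gyro_mag``) and the
per-sample rate of change of each magnitude (``d_accel_mag``,
``d_gyro_mag``).  This module reads the CSV dialects, validates them,
computes those four streams and aligns the behaviour annotation to the
sample grid.

CSV dialects
------------
Recording
    header ``t,ax,ay,az,gx,gy,gz``; ``t`` in seconds on a uniform grid,
    acceleration in g, angular rate in deg/s.
Annotation
    header ``start_s,end_s,behaviour``; half-open intervals
    ``[start_s, end_s)``; behaviours lower-case, from the three-class
    ethogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

#: The behaviour classes, in the fixed order used everywhere downstream
#: (confusion matrices, κ weights, tie-breaks).
CLASSES: tuple[str, ...] = ("lying", "standing", "walking")

#: Sample label code meaning "outside every annotated interval".
UNLABELLED: int = -1

_CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}

_RECORDING_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_ANNOTATION_COLUMNS = ["start_s", "end_s", "behaviour"]

_T_TOL = 1e-9  # tolerated jitter on the uniform time grid, seconds


@dataclass
class SensorRecording:
    """Uniformly sampled tri-axial accelerometer + gyroscope series.

    Acceleration axes are in g, gyroscope axes in deg/s; ``t`` is the
    shared timestamp grid in seconds with spacing ``1/fs``.
    """

    fs: float
    position: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray

    def __post_init__(self) -> None:
        series = [self.t, self.ax, self.ay, self.az, self.gx, self.gy, self.gz]
        n = len(self.t)
        if any(len(s) != n for s in series):
            raise DataError("all seven series must have equal length")
        if self.fs <= 0:
            raise DataError(f"sampling frequency must be positive, got {self.fs}")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise DataError(f"timestamps not strictly increasing at sample {i + 1}")
            if np.any(np.abs(dt - 1.0 / self.fs) > _T_TOL):
                i = int(np.argmax(np.abs(dt - 1.0 / self.fs) > _T_TOL))
                raise DataError(
                    f"timestamp spacing at sample {i + 1} deviates from 1/fs"
                )

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping behaviour intervals.

    Each interval is ``(start_s, end_s, behaviour)`` with the half-open
    convention ``[start_s, end_s)``.  Gaps between intervals are legal;
    samples falling in a gap stay unlabelled.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for i, (start, end, behaviour) in enumerate(self.intervals):
            if behaviour not in _CLASS_CODE:
                raise DataError(
                    f"interval {i}: behaviour {behaviour!r} not in ethogram {CLASSES}"
                )
            if not start < end:
                raise DataError(f"interval {i}: start {start} must be < end {end}")
            if start < prev_end:
                raise DataError(f"interval {i}: overlaps previous interval")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def total_duration(self) -> float:
        return float(sum(end - start for start, end, _ in self.intervals))

    def behaviour_durations(self) -> dict[str, float]:
        """Total annotated seconds per behaviour class."""
        out = {c: 0.0 for c in CLASSES}
        for start, end, behaviour in self.intervals:
            out[behaviour] += end - start
        return out


@dataclass
class LabelledSamples:
    """The four analysis streams plus a per-sample behaviour code.

    ``accel_mag``/``gyro_mag`` and ``labels`` have length N; the
    difference streams have length N−1 (no padding is invented).
    ``labels`` holds indices into :data:`CLASSES`, or :data:`UNLABELLED`.
    """

    fs: float
    accel_mag: np.ndarray
    gyro_mag: np.ndarray
    d_accel_mag: np.ndarray
    d_gyro_mag: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.accel_mag)
        if len(self.gyro_mag) != n or len(self.labels) != n:
            raise DataError("accel_mag, gyro_mag and labels must share length")
        if len(self.d_accel_mag) != max(n - 1, 0) or len(self.d_gyro_mag) != max(n - 1, 0):
            raise DataError("difference streams must have length N-1")

    def __len__(self) -> int:
        return len(self.accel_mag)


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm √(x²+y²+z²) of three axis series."""
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    if not (len(x) == len(y) == len(z)):
        raise DataError("axis series must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def rate_of_change(m: np.ndarray) -> np.ndarray:
    """First differences m[i+1] − m[i]; length N−1.

    Kept on the per-sample scale (not multiplied by fs): features are
    computed per window and a constant rescale of a stream leaves the
    classifier's split structure unchanged.
    """
    m = np.asarray(m, float)
    if len(m) < 2:
        raise DataError("rate_of_change needs at least 2 samples")
    return np.diff(m)


def align(recording: SensorRecording, annotation: AnnotationTrack) -> LabelledSamples:
    """Label every sample by the interval containing its timestamp.

    A sample at exactly an interval start belongs to that interval
    (half-open convention).  Samples outside every interval get
    :data:`UNLABELLED` and are later excluded from windowing.
    """
    accel_mag = magnitude(recording.ax, recording.ay, recording.az)
    gyro_mag = magnitude(recording.gx, recording.gy, recording.gz)
    labels = np.full(len(recording), UNLABELLED, dtype=np.int64)
    t = recording.t
    for start, end, behaviour in annotation.intervals:
        lo = int(np.searchsorted(t, start - _T_TOL, side="left"))
        hi = int(np.searchsorted(t, end - _T_TOL, side="left"))
        labels[lo:hi] = _CLASS_CODE[behaviour]
    n = len(recording)
    empty = np.empty(0)
    return LabelledSamples(
        fs=recording.fs,
        accel_mag=accel_mag,
        gyro_mag=gyro_mag,
        d_accel_mag=rate_of_change(accel_mag) if n >= 2 else empty,
        d_gyro_mag=rate_of_change(gyro_mag) if n >= 2 else empty,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_recording(path: str | Path, position: str = "collar") -> SensorRecording:
    """Read a recording CSV; the sampling frequency is inferred from ``t``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in _RECORDING_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & ~df[col].isna()
        if bad.any() or df[col].isna().any():
            row = int((values.isna()).idxmax())
            raise ParseError(f"{path}: non-numeric or missing {col!r} at data row {row}")
        df[col] = values
    t = df["t"].to_numpy(float)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ParseError(f"{path}: timestamps not strictly increasing at data row {row}")
    fs = 1.0 / float(np.median(dt))
    # snap to an integer rate when the grid is within tolerance of one
    if abs(fs - round(fs)) < 1e-6:
        fs = float(round(fs))
    return SensorRecording(
        fs=fs,
        position=position,
        t=t,
        ax=df["ax"].to_numpy(float),
        ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float),
        gx=df["gx"].to_numpy(float),
        gy=df["gy"].to_numpy(float),
        gz=df["gz"].to_numpy(float),
    )


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation CSV; rows with unknown behaviours are errors."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    intervals: list[tuple[float, float, str]] = []
    for row, rec in enumerate(df.itertuples(index=False)):
        behaviour = str(rec.behaviour)
        if behaviour not in _CLASS_CODE:
            raise ParseError(
                f"{path}: unknown behaviour {behaviour!r} at data row {row} "
                f"(ethogram: {', '.join(CLASSES)})"
            )
        try:
            start, end = float(rec.start_s), float(rec.end_s)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric interval at data row {row}") from exc
        intervals.append((start, end, behaviour))
    try:
        return AnnotationTrack(intervals)
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_recording(recording: SensorRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {c: getattr(recording, c) for c in _RECORDING_COLUMNS}
    )
    # 17 significant digits round-trip float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_annotations(annotation: AnnotationTrack, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(annotation.intervals, columns=_ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)
    return path
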
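"""Sliding-window discretization with 50 % overlap.

Labelled streams are cut into fixed-length windows of ``window_seconds``
(3, 5 and 7 s in the study grid) whose starts advance by half a window,
so consecutive windows share exactly half their samples.  A window whose
samples all carry one behaviour label is *non-mixed*; a window spanning
a bout boundary is *mixed* and receives its predominant label, which is
how annotated field data are windowed before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .signals import CLASSES, UNLABELLED, LabelledSamples

__all__ = [
    "LabelledWindow",
    "MixedSummary",
    "segment",
    "label_window",
    "mixed_summary",
    "mixed_summary_table",
]


@dataclass
class LabelledWindow:
    """One fixed-length sample block with its collective label."""

    index: int
    start_sample: int
    n: int
    label: str
    mixed: bool
    streams: dict[str, np.ndarray]
    fs: float
    window_seconds: float


@dataclass
class MixedSummary:
    """Mixed / non-mixed window percentages for one (fs, window) cell."""

    fs: float
    window_seconds: float
    n_windows: int
    pct_non_mixed: float
    pct_mixed: float


def label_window(sample_labels: np.ndarray) -> tuple[str, bool]:
    """Collective label of a window: the predominant sample label.

    ``mixed`` is True iff more than one distinct label occurs.  A tie
    between modal labels is broken in favour of the one occurring
    earliest in the window (deterministic and order-respecting).
    """
    codes = np.asarray(sample_labels)
    if codes.size == 0:
        raise DataError("label_window needs a non-empty window")
    if np.any(codes == UNLABELLED):
        raise DataError("window contains unlabelled samples")
    values, first_pos, counts = np.unique(
        codes, return_index=True, return_counts=True
    )
    mixed = len(values) > 1
    top = counts == counts.max()
    winner = values[top][np.argmin(first_pos[top])]
    return CLASSES[int(winner)], mixed


def segment(samples: LabelledSamples, window_seconds: float) -> list[LabelledWindow]:
    """Cut labelled streams into half-overlapping windows.

    Windows start at 0, n/2, n, ... where ``n = window_seconds × fs``
    (which must be a whole number of samples; a non-integer count is a
    configuration error rather than a silent truncation).  A trailing
    partial window is discarded, as is any window touching an
    unlabelled sample — a gap is an annotation boundary of unknown
    behaviour, so no window may span it.
    """
    n_float = window_seconds * samples.fs
    if abs(n_float - round(n_float)) > 1e-9:
        raise ConfigError(
            f"window of {window_seconds} s at fs={samples.fs} Hz is "
            f"{n_float} samples, not an integer"
        )
    n = int(round(n_float))
    if n < 2:
        raise ConfigError(f"window must span >= 2 samples, got {n}")
    step = n // 2
    windows: list[LabelledWindow] = []
    N = len(samples)
    for start in range(0, N - n + 1, step):
        codes = samples.labels[start : start + n]
        if np.any(codes == UNLABELLED):
            continue
        label, mixed = label_window(codes)
        streams = {
            "accel_mag": samples.accel_mag[start : start + n],
            "gyro_mag": samples.gyro_mag[start : start + n],
            # derivative streams are one sample shorter by construction
            "d_accel_mag": samples.d_accel_mag[start : start + n - 1],
            "d_gyro_mag": samples.d_gyro_mag[start : start + n - 1],
        }
        windows.append(
            LabelledWindow(
                index=len(windows),
                start_sample=start,
                n=n,
                label=label,
                mixed=mixed,
                streams=streams,
                fs=samples.fs,
                window_seconds=window_seconds,
            )
        )
    return windows


def mixed_summary(windows: list[LabelledWindow]) -> MixedSummary:
    """Percentage of mixed vs non-mixed windows in one configuration."""
    if not windows:
        raise DataError("mixed_summary of zero windows is undefined")
    n = len(windows)
    n_mixed = sum(w.mixed for w in windows)
    return MixedSummary(
        fs=windows[0].fs,
        window_seconds=windows[0].window_seconds,
        n_windows=n,
        pct_non_mixed=100.0 * (n - n_mixed) / n,
        pct_mixed=100.0 * n_mixed / n,
    )


def mixed_summary_table(summaries: list[MixedSummary]) -> pd.DataFrame:
    """Arrange summaries as a table: rows fs × {non-mixed, mixed},
    columns window sizes."""
    rows = {}
    for s in summaries:
        rows.setdefault((s.fs, "non-mixed"), {})[s.window_seconds] = s.pct_non_mixed
        rows.setdefault((s.fs, "mixed"), {})[s.window_seconds] = s.pct_mixed
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["fs_hz", "type"])
    df.columns = [f"{w:g} s" for w in df.columns]
    return df.sort_index(level=0, sort_remaining=False)
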
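"""Per-window feature characteristics.

Eleven characteristics — interquartile range, kurtosis, mean, standard
deviation, minimum, maximum, zero crossings, spectral entropy, dominant
frequency, signal area and absolute signal area — are computed on each
of the four analysis streams (accelerometer magnitude, gyroscope
magnitude and their rates of change), giving a 44-dimensional feature
vector per window.

Conventions (recorded here because the formulas alone do not fix them):

* moments are population moments (ddof = 0); kurtosis is the biased
  Fisher *excess* kurtosis m4/m2² − 3, defined as 0 for a constant
  window;
* the interquartile range uses linear interpolation between order
  statistics (the "type 7" percentile rule);
* spectral quantities come from the raw one-sided periodogram
  PSD(f) = |X(f)|² of the un-tapered, un-detrended window; spectral
  entropy is the natural-log Shannon entropy of the normalized PSD
  over *all* bins (DC included), an identically-zero spectrum having
  entropy 0 by convention;
* the dominant frequency excludes the DC bin by default — magnitude
  streams carry a ~1 g offset that would otherwise always win — with
  ties resolved to the lowest frequency;
* zero-crossing counting is strict: after mean-centering, exact zeros
  inherit the previous non-zero sign (leading zeros take the first
  non-zero sign) and only sign changes between consecutive samples
  count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .windowing import LabelledWindow

__all__ = [
    "STREAMS",
    "BASE_FEATURES",
    "FEATURE_NAMES",
    "FeatureVector",
    "basic_stats",
    "zero_crossings",
    "spectral_entropy",
    "dominant_frequency",
    "signal_areas",
    "extract_features",
    "features_table",
]

STREAMS: tuple[str, ...] = ("accel_mag", "gyro_mag", "d_accel_mag", "d_gyro_mag")

BASE_FEATURES: tuple[str, ...] = (
    "iqr",
    "kurtosis",
    "mean",
    "std",
    "min",
    "max",
    "zero_crossings",
    "spectral_entropy",
    "dominant_frequency_hz",
    "signal_area",
    "abs_signal_area",
)

#: The fixed, alphabetical feature ordering — 44 names — used for every
#: feature table and trained model, so model files stay portable.
FEATURE_NAMES: tuple[str, ...] = tuple(
    sorted(f"{feat}__{stream}" for feat in BASE_FEATURES for stream in STREAMS)
)


@dataclass
class FeatureVector:
    """The 44 named feature values of one window, plus provenance."""

    values: dict[str, float]
    label: str
    mixed: bool
    fs: float
    window_seconds: float
    position: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES])


def basic_stats(w: np.ndarray) -> dict[str, float]:
    """Mean, population std, min, max, type-7 IQR and excess kurtosis."""
    w = np.asarray(w, float)
    if len(w) < 2:
        raise DataError("basic_stats needs at least 2 samples")
    centred = w - w.mean()
    m2 = float(np.mean(centred**2))
    if m2 == 0.0:
        kurt = 0.0  # constant window: excess kurtosis by convention
    else:
        kurt = float(np.mean(centred**4) / m2**2 - 3.0)
    q75, q25 = np.percentile(w, [75, 25])
    return {
        "mean": float(w.mean()),
        "std": float(w.std()),
        "min": float(w.min()),
        "max": float(w.max()),
        "iqr": float(q75 - q25),
        "kurtosis": kurt,
    }


def zero_crossings(w: np.ndarray) -> int:
    """Strict sign changes of the mean-centred window."""
    w = np.asarray(w, float)
    if len(w) < 2:
        raise DataError("zero_crossings needs at least 2 samples")
    c = w - w.mean()
    s = np.sign(c)
    nonzero = np.flatnonzero(s)
    if nonzero.size == 0:
        return 0
    # exact zeros inherit the previous non-zero sign; leading zeros the first
    filled = s.copy()
    filled[: nonzero[0]] = s[nonzero[0]]
    for i in range(nonzero[0] + 1, len(filled)):
        if filled[i] == 0:
            filled[i] = filled[i - 1]
    return int(np.count_nonzero(filled[1:] != filled[:-1]))


def _periodogram(w: np.ndarray) -> np.ndarray:
    """One-sided PSD |X(f)|² of the raw window (no taper, no detrend)."""
    X = np.fft.rfft(np.asarray(w, float))
    return np.abs(X) ** 2


def spectral_entropy(w: np.ndarray) -> float:
    """Shannon entropy (natural log) of the normalized one-sided PSD."""
    if len(w) < 2:
        raise DataError("spectral_entropy needs at least 2 samples")
    psd = _periodogram(w)
    total = psd.sum()
    if total == 0.0:
        return 0.0  # identically zero window
    p = psd / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def dominant_frequency(w: np.ndarray, fs: float, exclude_dc: bool = True) -> float:
    """Bin-centre frequency of the maximal PSD bin; ties → lowest.

    With ``exclude_dc`` (the default) the 0 Hz bin is ignored; a window
    whose spectrum is zero everywhere else reports 0 Hz.
    """
    if len(w) < 2:
        raise DataError("dominant_frequency needs at least 2 samples")
    psd = _periodogram(w)
    freqs = np.fft.rfftfreq(len(w), d=1.0 / fs)
    # bins below the spectrum's floating-point noise floor count as zero,
    # so a constant window reports 0 Hz at any length
    floor = psd.max() * 1e-12
    if exclude_dc:
        psd, freqs = psd[1:], freqs[1:]
    if psd.size == 0 or psd.max() <= floor:
        return 0.0
    return float(freqs[int(np.argmax(psd))])


def signal_areas(w: np.ndarray, fs: float) -> dict[str, float]:
    """Signal area Σw/fs and absolute signal area Σ|w|/fs."""
    w = np.asarray(w, float)
    return {
        "signal_area": float(w.sum() / fs),
        "abs_signal_area": float(np.abs(w).sum() / fs),
    }


def _stream_features(w: np.ndarray, fs: float, exclude_dc: bool) -> dict[str, float]:
    out = basic_stats(w)
    out["zero_crossings"] = float(zero_crossings(w))
    out["spectral_entropy"] = spectral_entropy(w)
    out["dominant_frequency_hz"] = dominant_frequency(w, fs, exclude_dc=exclude_dc)
    out.update(signal_areas(w, fs))
    return out


def extract_features(
    window: LabelledWindow,
    position: str = "",
    domfreq_exclude_dc: bool = True,
) -> FeatureVector:
    """The full 44-value feature vector of one labelled window."""
    values: dict[str, float] = {}
    for stream in STREAMS:
        w = window.streams[stream]
        if len(w) < 2:
            raise DataError(
                f"stream {stream!r} has {len(w)} samples; windows must be "
                "long enough that the difference streams keep >= 2"
            )
        per = _stream_features(w, window.fs, domfreq_exclude_dc)
        for feat, value in per.items():
            values[f"{feat}__{stream}"] = value
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(
        values=ordered,
        label=window.label,
        mixed=window.mixed,
        fs=window.fs,
        window_seconds=window.window_seconds,
        position=position,
    )


def features_table(
    windows: list[LabelledWindow],
    position: str = "",
    domfreq_exclude_dc: bool = True,
):
    """Feature matrix for many windows as a pandas DataFrame.

    Columns are the 44 feature names (fixed order) followed by
    ``label, fs, window_s, position, mixed``.
    """
    import pandas as pd

    rows = []
    for w in windows:
        fv = extract_features(w, position=position, domfreq_exclude_dc=domfreq_exclude_dc)
        row = dict(fv.values)
        row.update(
            label=fv.label,
            fs=fv.fs,
            window_s=fv.window_seconds,
            position=fv.position,
            mixed=fv.mixed,
        )
        rows.append(row)
    columns = list(FEATURE_NAMES) + ["label", "fs", "window_s", "position", "mixed"]
    return pd.DataFrame(rows, columns=columns)
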
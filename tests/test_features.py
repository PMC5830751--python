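"""Feature characteristics vs independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ethogram as e
from ethogram.errors import DataError
from ethogram.features import FEATURE_NAMES, STREAMS
from ethogram.windowing import LabelledWindow


# ---------------------------------------------------------------------------
# oracles: explicit O(n^2) DFT and naive loops, independent of numpy.fft


def dft_psd_oracle(w):
    n = len(w)
    psd = []
    for k in range(n // 2 + 1):
        re = sum(w[j] * math.cos(-2 * math.pi * j * k / n) for j in range(n))
        im = sum(w[j] * math.sin(-2 * math.pi * j * k / n) for j in range(n))
        psd.append(re * re + im * im)
    return psd


def spectral_entropy_oracle(w):
    psd = dft_psd_oracle(w)
    total = sum(psd)
    if total == 0:
        return 0.0
    return -sum(p / total * math.log(p / total) for p in psd if p > 0)


def dominant_frequency_oracle(w, fs):
    psd = dft_psd_oracle(w)[1:]  # DC excluded
    if not psd or max(psd) == 0:
        return 0.0
    k = psd.index(max(psd)) + 1
    return k * fs / len(w)


def zero_crossings_oracle(w):
    c = [v - sum(w) / len(w) for v in w]
    signs = []
    for v in c:
        s = int(v > 0) - int(v < 0)
        signs.append(s)
    # zeros inherit previous non-zero sign; leading zeros the first one
    first = next((s for s in signs if s != 0), 0)
    filled, prev = [], first
    for s in signs:
        prev = s if s != 0 else prev
        filled.append(prev)
    return sum(1 for a, b in zip(filled, filled[1:]) if a != b)


def _window(values, fs=16.0, label="lying"):
    values = np.asarray(values, float)
    return LabelledWindow(
        index=0,
        start_sample=0,
        n=len(values),
        label=label,
        mixed=False,
        streams={
            "accel_mag": values,
            "gyro_mag": values * 2.0,
            "d_accel_mag": np.diff(values),
            "d_gyro_mag": np.diff(values * 2.0),
        },
        fs=fs,
        window_seconds=len(values) / fs,
    )


class TestBasicStats:
    def test_simple_window(self):
        s = e.basic_stats([1, 2, 3, 4])
        assert s["mean"] == 2.5 and s["min"] == 1 and s["max"] == 4

    def test_population_excess_kurtosis(self):
        # m2 = 1, m4 = 1 -> kurtosis = 1/1 - 3 = -2
        assert e.basic_stats([1, 1, -1, -1])["kurtosis"] == pytest.approx(-2.0)

    def test_constant_window_conventions(self):
        s = e.basic_stats(np.full(16, 3.0))
        assert s["std"] == 0 and s["iqr"] == 0 and s["kurtosis"] == 0

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            e.basic_stats([1.0])


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "w,expected",
        [
            ([1, -1, 1, -1], 3),
            (np.ones(8), 0),
            # one full sine cycle crossing strictly down then up
            (np.sin(2 * np.pi * (np.arange(16) + 2) / 16), 2),
        ],
    )
    def test_known_counts(self, w, expected):
        assert e.zero_crossings(w) == expected
        assert zero_crossings_oracle(list(np.asarray(w, float))) == expected

    def test_matches_naive_loop_on_random_windows(self, rng):
        for _ in range(50):
            w = rng.normal(size=rng.integers(2, 64))
            w[rng.random(len(w)) < 0.2] = w.mean()  # plant exact zeros
            assert e.zero_crossings(w) == zero_crossings_oracle(list(w))


class TestSpectral:
    def test_pure_tone_on_bin_has_zero_entropy(self):
        t = np.arange(112) / 16.0
        w = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz on an exact bin of n=112
        assert e.spectral_entropy(w) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_spectrum_reaches_log_k(self):
        # a unit impulse has a flat spectrum over all n//2+1 bins
        w = np.zeros(64)
        w[0] = 1.0
        assert e.spectral_entropy(w) == pytest.approx(math.log(33), rel=1e-12)

    def test_identically_zero_window_has_zero_entropy(self):
        assert e.spectral_entropy(np.zeros(32)) == 0.0

    def test_entropy_matches_dft_oracle(self, rng):
        w = rng.normal(size=112)
        se = e.spectral_entropy(w)
        assert abs(se - spectral_entropy_oracle(list(w))) <= 1e-10 * max(se, 1.0)

    @pytest.mark.parametrize(
        "freqs_amps,fs,n,expected",
        [
            ([(2.0, 1.0)], 16.0, 112, 2.0),
            ([(1.0, 1.0), (3.0, 2.0)], 32.0, 160, 3.0),
        ],
    )
    def test_dominant_frequency_known_tones(self, freqs_amps, fs, n, expected):
        t = np.arange(n) / fs
        w = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        assert e.dominant_frequency(w, fs) == pytest.approx(expected)
        assert dominant_frequency_oracle(list(w), fs) == pytest.approx(expected)

    def test_constant_window_reports_zero_hz(self):
        assert e.dominant_frequency(np.full(48, 5.0), 16.0) == 0.0

    def test_dominant_frequency_matches_oracle_on_noise(self, rng):
        for _ in range(10):
            w = rng.normal(size=64)
            assert e.dominant_frequency(w, 32.0) == pytest.approx(
                dominant_frequency_oracle(list(w), 32.0)
            )


class TestSignalAreas:
    def test_unit_window(self):
        areas = e.signal_areas(np.ones(24), fs=8.0)
        assert areas["signal_area"] == pytest.approx(3.0)
        assert areas["abs_signal_area"] == pytest.approx(3.0)

    def test_sign_cancellation(self):
        areas = e.signal_areas([-1.0, 1.0], fs=1.0)
        assert areas["signal_area"] == 0.0 and areas["abs_signal_area"] == 2.0

    def test_non_negative_stream_sa_equals_asa(self, rng):
        w = np.abs(rng.normal(size=50))
        areas = e.signal_areas(w, fs=16.0)
        assert areas["signal_area"] == areas["abs_signal_area"]


class TestExtractFeatures:
    def test_vector_has_exactly_44_named_values(self, rng):
        fv = e.extract_features(_window(rng.normal(size=112) + 1.0))
        assert len(fv.values) == 44
        assert list(fv.values) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_pure_function(self, rng):
        w = _window(rng.normal(size=80))
        assert e.extract_features(w).values == e.extract_features(w).values

    def test_invariant_ranges(self, rng):
        fv = e.extract_features(_window(np.abs(rng.normal(size=112)) + 0.5))
        for stream in STREAMS:
            v = fv.values
            assert v[f"min__{stream}"] <= v[f"mean__{stream}"] <= v[f"max__{stream}"]
            assert v[f"iqr__{stream}"] >= 0 and v[f"std__{stream}"] >= 0
            assert 0 <= v[f"dominant_frequency_hz__{stream}"] <= 8.0
            assert v[f"spectral_entropy__{stream}"] >= 0
            assert v[f"abs_signal_area__{stream}"] >= abs(v[f"signal_area__{stream}"])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(min_value=0.1, max_value=50.0),
    )
    def test_scale_equivariance_pattern(self, seed, c):
        """Scaling a window by c > 0 scales the linear features by c and
        leaves counts, frequencies, entropy and kurtosis unchanged."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=48)
        f1 = e.extract_features(_window(base)).values
        f2 = e.extract_features(_window(c * base)).values
        for stream in STREAMS:
            for feat in ("mean", "std", "min", "max", "iqr",
                         "signal_area", "abs_signal_area"):
                assert f2[f"{feat}__{stream}"] == pytest.approx(
                    c * f1[f"{feat}__{stream}"], rel=1e-9, abs=1e-12
                )
            for feat in ("zero_crossings", "dominant_frequency_hz",
                         "kurtosis", "spectral_entropy"):
                assert f2[f"{feat}__{stream}"] == pytest.approx(
                    f1[f"{feat}__{stream}"], rel=1e-7, abs=1e-9
                )

    def test_feature_table_layout(self, small_feature_table):
        cols = list(small_feature_table.columns)
        assert cols[:44] == list(FEATURE_NAMES)
        assert cols[44:] == ["label", "fs", "window_s", "position", "mixed"]

    def test_lying_vs_walking_effect_size(self, small_feature_table):
        """mean accel magnitude separates lying from walking strongly."""
        t = small_feature_table[~small_feature_table["mixed"]]
        for col in ("mean__accel_mag", "signal_area__accel_mag"):
            ly = t.loc[t["label"] == "lying", col]
            wa = t.loc[t["label"] == "walking", col]
            pooled = math.sqrt((ly.var(ddof=1) + wa.var(ddof=1)) / 2)
            assert abs(wa.mean() - ly.mean()) / pooled > 2
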
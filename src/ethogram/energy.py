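"""Embedded energy budget of on-device classification.

When a collar/ear device classifies on board, the IMU still samples at
a constant rate, so acquisition *volume* per hour is fixed; what the
window size changes is the number of times the processor wakes to read
a batch of samples (once per window) and the cadence at which the
SRAM buffer of classification records fills and is flushed to flash.
This module reproduces that arithmetic and projects battery life.

Counts are exact integer arithmetic:

* acquisitions/h = floor(3600 / window_seconds)
* seconds to flush = floor(buffer_bytes / record_bytes) × window_seconds
* writes/h = 3600 / seconds_to_flush, rounded half-up

The per-event energy constants are calibration values (fitted once to
bench measurements of the reference device) rather than physical
specifications, and are configurable on :class:`DeviceProfile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError

__all__ = [
    "DeviceProfile",
    "EnergyReport",
    "window_energy_profile",
    "battery_life_years",
    "energy_table",
]


@dataclass
class DeviceProfile:
    """Hardware constants of the embedded logger.

    ``energy_per_acquisition`` and ``energy_per_flash_write`` (µA h per
    event) are least-squares calibrations against bench measurements;
    ``processing_energy_per_hour`` is constant because the bytes
    processed per hour do not depend on the window size.
    """

    sram_buffer_bytes: int = 256
    classification_record_bytes: int = 8
    bytes_per_sample: int = 14
    energy_per_acquisition_uah: float = 0.277651
    energy_per_flash_write_uah: float = 0.261103
    processing_energy_per_hour_uah: float = 1000.0
    battery_capacity_mah: float = 270.0
    hours_per_year: float = 8766.0  # 365.25 days

    def __post_init__(self) -> None:
        for name in (
            "sram_buffer_bytes",
            "classification_record_bytes",
            "bytes_per_sample",
            "energy_per_acquisition_uah",
            "energy_per_flash_write_uah",
            "processing_energy_per_hour_uah",
            "battery_capacity_mah",
            "hours_per_year",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.classification_record_bytes > self.sram_buffer_bytes:
            raise ConfigError("classification record does not fit in the SRAM buffer")


@dataclass
class EnergyReport:
    """Duty-cycle counts and energy components for one (fs, window)."""

    fs: float
    window_seconds: float
    samples_per_window: int
    bytes_per_window: int
    acquisitions_per_hour: int
    bytes_per_hour: int
    seconds_per_flush: float
    writes_per_hour: int
    acquisition_energy_uah: float
    processing_energy_uah: float
    flash_energy_uah: float

    @property
    def total_energy_uah(self) -> float:
        return (
            self.acquisition_energy_uah
            + self.processing_energy_uah
            + self.flash_energy_uah
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def window_energy_profile(
    fs: float, window_seconds: float, device: DeviceProfile | None = None
) -> EnergyReport:
    """Per-hour duty-cycle counts and energy for one configuration."""
    device = device or DeviceProfile()
    if fs <= 0 or window_seconds <= 0:
        raise ConfigError("fs and window_seconds must be positive")
    samples_per_window = int(round(fs * window_seconds))
    records_per_flush = device.sram_buffer_bytes // device.classification_record_bytes
    seconds_per_flush = records_per_flush * window_seconds
    acquisitions_per_hour = int(3600 // window_seconds)
    writes_per_hour = _round_half_up(3600.0 / seconds_per_flush)
    return EnergyReport(
        fs=fs,
        window_seconds=window_seconds,
        samples_per_window=samples_per_window,
        bytes_per_window=samples_per_window * device.bytes_per_sample,
        acquisitions_per_hour=acquisitions_per_hour,
        bytes_per_hour=int(round(fs * 3600)) * device.bytes_per_sample,
        seconds_per_flush=seconds_per_flush,
        writes_per_hour=writes_per_hour,
        acquisition_energy_uah=acquisitions_per_hour
        * device.energy_per_acquisition_uah,
        processing_energy_uah=device.processing_energy_per_hour_uah,
        flash_energy_uah=writes_per_hour * device.energy_per_flash_write_uah,
    )


def battery_life_years(
    hourly_drain_uah: float, device: DeviceProfile | None = None
) -> float:
    """Years of battery life at a constant hourly drain (µA h per hour)."""
    device = device or DeviceProfile()
    if hourly_drain_uah <= 0:
        raise ConfigError("hourly drain must be positive")
    hours = device.battery_capacity_mah * 1000.0 / hourly_drain_uah
    return hours / device.hours_per_year


def energy_table(
    fs: float,
    window_sizes: tuple[float, ...] = (3.0, 5.0, 7.0),
    device: DeviceProfile | None = None,
) -> pd.DataFrame:
    """Duty-cycle/energy table: one row per measure, one column per
    window size (energy rows rounded to whole µA h for display)."""
    device = device or DeviceProfile()
    reports = [window_energy_profile(fs, w, device) for w in window_sizes]
    rows = {
        "no. samples/window": [r.samples_per_window for r in reports],
        "no. bytes/window": [r.bytes_per_window for r in reports],
        "no. sample acquisition/h": [r.acquisitions_per_hour for r in reports],
        "uAh energy (sample acquisitions/h)": [
            round(r.acquisition_energy_uah) for r in reports
        ],
        "no. bytes/h sampled": [r.bytes_per_hour for r in reports],
        "uAh energy (data processing/h)": [
            round(r.processing_energy_uah) for r in reports
        ],
        "SRAM buffer size in bytes": [device.sram_buffer_bytes] * len(reports),
        "classification record size in bytes": [
            device.classification_record_bytes
        ] * len(reports),
        "no. seconds before buffer is full and write to flash is executed": [
            round(r.seconds_per_flush) for r in reports
        ],
        "no. writes per hour": [r.writes_per_hour for r in reports],
        "uAh energy (writes to flash)": [round(r.flash_energy_uah) for r in reports],
    }
    return pd.DataFrame(
        rows, index=[f"{w:g} s" for w in window_sizes]
    ).T.rename_axis("measure")
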
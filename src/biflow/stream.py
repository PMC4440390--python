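"""Photon-stream containers for TCSPC FIFO data.

A time-correlated single photon counting (TCSPC) card operated in
first-in first-out mode emits one record per detected photon:

* ``macro_time`` — arrival time in the lab frame, spanning the whole
  acquisition.  Stored in **seconds** as float64 (sub-ns resolution over
  minutes of acquisition).
* ``micro_time`` — delay after the laser synchronisation pulse, stored in
  **nanoseconds**; its histogram is the fluorescence decay.
* ``channel`` — integer detector id (a router allows several detectors on
  one card).

:class:`PhotonStream` bundles the per-photon arrays with an
:class:`AcquisitionConfig` and, for simulated data, a list of
:class:`ParticleTruth` ground-truth records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "ParticleTruth",
    "PhotonStream",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Static acquisition parameters of a TCSPC FIFO measurement.

    Parameters
    ----------
    sync_period : float
        Laser synchronisation period in ns.  Default 12.5 ns (80 MHz).
    micro_window : float
        Width of the recorded micro-time window in ns; must not exceed
        ``sync_period``.  Some ADC configurations record a 10 ns window
        within the 12.5 ns period.
    adc_bins : int
        Number of micro-time histogram channels used when building decay
        histograms.
    bin_width : float
        Macro-time binning width in µs used for burst extraction
        (default 20 µs).
    channels : tuple of int
        Detector channel ids present in the stream.
    """

    sync_period: float = 12.5
    micro_window: float = 12.5
    adc_bins: int = 256
    bin_width: float = 20.0
    channels: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.micro_window <= 0:
            raise ValueError("micro_window must be positive")
        if self.micro_window > self.sync_period + 1e-12:
            raise ValueError("micro_window must not exceed sync_period")
        if self.adc_bins < 2:
            raise ValueError("adc_bins must be >= 2")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.channels) == 0:
            raise ValueError("at least one detector channel required")


@dataclass(frozen=True)
class ParticleTruth:
    """Ground truth for one simulated particle transit.

    ``arrival_time`` is the transit centre (s); ``transit_fwhm`` the full
    width at half maximum of the Gaussian photon-rate envelope (s).
    ``true_lifetimes`` holds one or two decay times (ns) and
    ``true_amplitude_fractions`` the matching photon (intensity)
    fractions, which sum to 1.  ``channel_split`` gives the per-channel
    emission probabilities in the order of ``config.channels``.
    """

    arrival_time: float
    transit_fwhm: float
    expected_photons: float
    true_lifetimes: tuple[float, ...]
    true_amplitude_fractions: tuple[float, ...]
    channel_split: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.expected_photons <= 0:
            raise ValueError("expected_photons must be positive")
        if self.transit_fwhm <= 0:
            raise ValueError("transit duration must be positive")
        if any(t <= 0 for t in self.true_lifetimes):
            raise ValueError("lifetimes must be positive")
        if abs(sum(self.true_amplitude_fractions) - 1.0) > 1e-9:
            raise ValueError("amplitude fractions must sum to 1")


@dataclass
class PhotonStream:
    """Ordered per-photon records plus acquisition metadata."""

    macro_times: np.ndarray  # seconds, non-decreasing
    micro_times: np.ndarray  # ns, in [0, micro_window)
    channels: np.ndarray  # int detector ids
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    truth: list[ParticleTruth] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.macro_times = np.asarray(self.macro_times, dtype=np.float64)
        self.micro_times = np.asarray(self.micro_times, dtype=np.float64)
        self.channels = np.asarray(self.channels, dtype=np.int64)
        n = self.macro_times.size
        if self.micro_times.size != n or self.channels.size != n:
            raise ValueError("record arrays must have equal length")
        if n and np.any(np.diff(self.macro_times) < 0):
            raise ValueError("macro times must be non-decreasing")
        if n and (
            self.micro_times.min() < 0
            or self.micro_times.max() >= self.config.micro_window
        ):
            raise ValueError("micro times must lie in [0, micro_window)")
        if n and not np.isin(self.channels, self.config.channels).all():
            raise ValueError("stream contains channels not in config.channels")

    def __len__(self) -> int:
        return int(self.macro_times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhotonStream):
            return NotImplemented
        return (
            self.config == other.config
            and self.seed == other.seed
            and self.truth == other.truth
            and np.array_equal(self.macro_times, other.macro_times)
            and np.array_equal(self.micro_times, other.micro_times)
            and np.array_equal(self.channels, other.channels)
        )

    @property
    def duration(self) -> float:
        """Span of the acquisition in seconds (0 for an empty stream)."""
        if len(self) == 0:
            return 0.0
        return float(self.macro_times[-1] - self.macro_times[0])

    def select(self, start: int, stop: int) -> "PhotonStream":
        """Record-index slice as a new stream (truth not propagated)."""
        return replace(
            self,
            macro_times=self.macro_times[start:stop].copy(),
            micro_times=self.micro_times[start:stop].copy(),
            channels=self.channels[start:stop].copy(),
            truth=None,
        )
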
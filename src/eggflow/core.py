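"""Core domain types and spectral operations for cutaneous EGG processing.

The electrogastrogram (EGG) records gastric myoelectrical activity from
abdominal surface electrodes.  The quantities of interest live in a narrow
frequency range conventionally expressed in cycles per minute (cpm):
bradygastria 1-2 cpm, normogastria 2-4 cpm (the healthy ~3 cpm pacesetter
rhythm) and tachygastria 4-10 cpm.  This module provides the shared
building blocks used by both the offline analysis pipeline and the
real-time feedback engine:

* uniformly sampled single-channel recordings (:class:`RawRecording`),
* the canonical gastric frequency-band taxonomy (:class:`BandDefinition`),
* decimation with anti-aliasing, linear detrending and Butterworth
  bandpass filtering,
* a Hann-windowed, zero-padded FFT power spectral density
  (:class:`SpectralEstimate`) and percent-of-total band powers
  (:class:`BandPowerSummary`).

All operations are pure functions of their inputs; nothing here touches
files or global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EggError",
    "ConfigurationError",
    "UndefinedResultError",
    "ParseError",
    "RawRecording",
    "BandDefinition",
    "CANONICAL_BANDS",
    "FilterSpec",
    "SpectralEstimate",
    "BandPowerSummary",
    "cpm_to_hz",
    "hz_to_cpm",
    "downsample",
    "detrend",
    "bandpass",
    "bandpass_sos",
    "spectrum",
    "band_powers",
    "dominant_frequency",
]

#: Upper/lower edge of the gastric range analysed throughout, in cpm.
GASTRIC_LO_CPM = 1.0
GASTRIC_HI_CPM = 10.0


class EggError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(EggError, ValueError):
    """A parameter combination is invalid (bad cutoffs, rates, targets...)."""


class UndefinedResultError(EggError, ArithmeticError):
    """The requested quantity is undefined for this input (e.g. zero power)."""


class ParseError(EggError, ValueError):
    """A file could not be parsed; carries the offending location."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawRecording:
    """A uniformly sampled single-channel EGG trace.

    Parameters
    ----------
    samples
        Sample values in arbitrary acquisition units.  The physical scale
        (e.g. mV per unit) is metadata only and never enters the band-power
        percentages, which are scale invariant.
    fs
        Sampling rate in Hz.  Acquisition hardware typically records at
        1000 Hz; the analysis pipeline decimates to 10 Hz.
    start_time
        Offset of the first sample, in seconds.
    markers
        Session events as ``(time_s, label)`` pairs, sorted by time, with
        times relative to the start of the recording (e.g. water intake).
    channel_label
        Free-text channel name.
    unit_scale
        Multiplicative factor converting raw units to mV (metadata only).
    """

    samples: np.ndarray
    fs: float = 1000.0
    start_time: float = 0.0
    markers: tuple[tuple[float, str], ...] = ()
    channel_label: str = "EGG"
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        markers = tuple((float(t), str(lab)) for t, lab in self.markers)
        times = [t for t, _ in markers]
        if times != sorted(times):
            raise ValueError("markers must be sorted by time")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("marker times must lie within [0, duration]")
        object.__setattr__(self, "markers", markers)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the recording."""
        return np.arange(self.samples.size) / self.fs

    def replace(self, **changes) -> "RawRecording":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class BandDefinition:
    """A gastric frequency band ``[lo_cpm, hi_cpm)`` in cycles per minute.

    Bands are half-open at the top so that the canonical taxonomy tiles
    1-10 cpm without double counting; the highest band is treated as
    closed at its upper edge by :func:`band_powers`.
    """

    name: str
    lo_cpm: float
    hi_cpm: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_cpm < self.hi_cpm:
            raise ValueError(
                f"band {self.name!r} requires 0 < lo < hi, got "
                f"[{self.lo_cpm}, {self.hi_cpm})"
            )


#: Bradygastria / normogastria / tachygastria, tiling 1-10 cpm.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("bradygastria", 1.0, 2.0),
    BandDefinition("normogastria", 2.0, 4.0),
    BandDefinition("tachygastria", 4.0, 10.0),
)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification for the gastric range.

    The defaults, 0.016-0.16 Hz, bracket 1-10 cpm.  ``zero_phase`` selects
    forward-backward filtering (no phase distortion, acausal) as used
    offline; the streaming path uses the causal single-pass variant.
    """

    lo_hz: float = 0.016
    hi_hz: float = 0.16
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ConfigurationError(
                f"need 0 < lo_hz < hi_hz, got {self.lo_hz}, {self.hi_hz}"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    n_fft: int
    window: str = "hann"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_hz, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape:
            raise ValueError("freqs_hz and power must have the same shape")
        if freqs[0] != 0 or np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs_hz must start at 0 and increase strictly")
        if np.any(power < 0):
            raise ValueError("power must be nonnegative")
        if self.n_fft < 1 or (self.n_fft & (self.n_fft - 1)) != 0:
            raise ValueError(f"n_fft must be a power of 2, got {self.n_fft}")
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "power", power)

    @property
    def freqs_cpm(self) -> np.ndarray:
        """Frequency axis in cycles per minute (Hz x 60)."""
        return self.freqs_hz * 60.0

    @property
    def bin_width_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass(frozen=True)
class BandPowerSummary:
    """Percent power per gastric band plus the absolute in-range total.

    Percentages are relative to the total power in 1-10 cpm only, so the
    three always sum to 100 (within float round-off) when any in-range
    power is present.
    """

    pct_brady: float
    pct_normo: float
    pct_tachy: float
    total_power: float

    def __post_init__(self) -> None:
        for name in ("pct_brady", "pct_normo", "pct_tachy"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 100 + 1e-9:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.total_power < 0:
            raise ValueError("total_power must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_brady": self.pct_brady,
            "pct_normo": self.pct_normo,
            "pct_tachy": self.pct_tachy,
            "total_power": self.total_power,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def cpm_to_hz(f_cpm: float) -> float:
    """Convert cycles per minute to Hz (3 cpm -> 0.05 Hz)."""
    if f_cpm < 0:
        raise ValueError(f"frequency must be nonnegative, got {f_cpm} cpm")
    return f_cpm / 60.0


def hz_to_cpm(f_hz: float) -> float:
    """Convert Hz to cycles per minute."""
    if f_hz < 0:
        raise ValueError(f"frequency must be nonnegative, got {f_hz} Hz")
    return f_hz * 60.0


def _antialias_sos(fs: float, target_fs: float, order: int = 8) -> np.ndarray:
    # Low-pass at 0.8 x target Nyquist keeps mains/motion energy from
    # folding into the gastric band.
    return sps.butter(order, 0.8 * target_fs / 2.0, btype="low", fs=fs, output="sos")


def downsample(rec: RawRecording, target_fs: float = 10.0, *, causal: bool = False) -> RawRecording:
    """Decimate a recording to ``target_fs`` with anti-alias low-pass.

    An 8th-order Butterworth low-pass at 0.8 x the target Nyquist is
    applied before taking every ``fs/target_fs``-th sample.  The default
    zero-phase filtering is appropriate offline; ``causal=True`` uses a
    single forward pass so the output at time t depends only on input up
    to t (streaming use).

    Raises
    ------
    ConfigurationError
        If the decimation ratio is not a positive integer.
    """
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if q < 2 or abs(ratio - q) > 1e-9:
        raise ConfigurationError(
            f"target_fs={target_fs} must divide fs={rec.fs} with integer ratio >= 2"
        )
    sos = _antialias_sos(rec.fs, target_fs)
    if causal:
        low = sps.sosfilt(sos, rec.samples)
    else:
        low = sps.sosfiltfilt(sos, rec.samples)
    return rec.replace(samples=np.asarray(low)[::q], fs=target_fs)


def detrend(samples: Sequence[float]) -> np.ndarray:
    """Remove the least-squares straight line from a signal.

    Linear detrending removes slow electrode drift without attacking
    oscillatory content at 1 cpm and above.  A constant input maps to all
    zeros.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("detrend requires at least 2 samples")
    return sps.detrend(x, type="linear")


def bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order-section coefficients for the gastric bandpass at ``fs``."""
    if spec.hi_hz >= fs / 2.0:
        raise ConfigurationError(
            f"upper cutoff {spec.hi_hz} Hz must be below Nyquist {fs / 2.0} Hz"
        )
    return sps.butter(
        spec.order, [spec.lo_hz, spec.hi_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(samples: Sequence[float], fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth bandpass a signal to the gastric range.

    With ``spec.zero_phase`` (the offline default) the filter runs forward
    then backward, doubling the effective attenuation and cancelling phase
    delay; otherwise a causal single pass is used.

    Raises
    ------
    ConfigurationError
        If a cutoff is at or above Nyquist.
    ValueError
        If the signal is too short for the filter order.
    """
    spec = spec or FilterSpec()
    x = np.asarray(samples, dtype=float)
    if x.size <= 3 * (2 * spec.order + 1):
        raise ValueError(
            f"signal of {x.size} samples too short for order-{spec.order} bandpass"
        )
    sos = bandpass_sos(spec, fs)
    if spec.zero_phase:
        return np.asarray(sps.sosfiltfilt(sos, x))
    return np.asarray(sps.sosfilt(sos, x))


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1).bit_length())


def spectrum(samples: Sequence[float], fs: float, *, window: str = "hann") -> SpectralEstimate:
    """Hann-windowed, zero-padded one-sided power spectral density.

    The signal is multiplied by the window, zero-padded to the next power
    of 2 and Fourier transformed.  Density scaling divides by
    ``fs * sum(w**2)`` and doubles all bins except DC and Nyquist, so that
    the integral of the PSD approximates the windowed signal's mean power.
    Only power ratios enter the band percentages, so the scaling
    convention cannot change a :class:`BandPowerSummary`.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("spectrum requires at least 2 samples")
    if not fs > 0:
        raise ValueError("fs must be positive")
    w = sps.get_window(window, x.size, fftbins=True)
    n_fft = _next_pow2(x.size)
    spec = np.fft.rfft(x * w, n=n_fft)
    psd = (np.abs(spec) ** 2) / (fs * np.sum(w**2))
    psd[1:] *= 2.0
    if n_fft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    return SpectralEstimate(freqs_hz=freqs, power=psd, n_fft=n_fft, window=window)


def _band_mask(freqs_cpm: np.ndarray, band: BandDefinition, *, closed_top: bool) -> np.ndarray:
    lo, hi = band.lo_cpm, band.hi_cpm
    if closed_top:
        return (freqs_cpm >= lo) & (freqs_cpm <= hi * (1 + 1e-12))
    return (freqs_cpm >= lo) & (freqs_cpm < hi)


def band_powers(
    spec: SpectralEstimate, bands: Sequence[BandDefinition] = CANONICAL_BANDS
) -> BandPowerSummary:
    """Integrate the PSD per gastric band and express it as percent of total.

    Each band integrates (trapezoid rule) over the bins whose centre
    frequency falls in ``[lo, hi)`` cpm, the highest band closed at its
    upper edge.  The total is the sum over the three bands, i.e. over
    1-10 cpm only, so the percentages sum to 100 by construction.

    Raises
    ------
    UndefinedResultError
        If the total in-range power is zero (e.g. an all-zero signal).
    """
    bands = sorted(bands, key=lambda b: b.lo_cpm)
    if len(bands) != 3 or {b.name for b in bands} != {b.name for b in CANONICAL_BANDS}:
        raise ConfigurationError("bands must be the three canonical gastric bands")
    freqs_cpm = spec.freqs_cpm
    if freqs_cpm[-1] < bands[-1].hi_cpm:
        raise ConfigurationError("spectrum does not cover the full gastric range")
    powers: dict[str, float] = {}
    for i, band in enumerate(bands):
        mask = _band_mask(freqs_cpm, band, closed_top=(i == len(bands) - 1))
        p, f = spec.power[mask], spec.freqs_hz[mask]
        if p.size >= 2:
            powers[band.name] = float(np.trapezoid(p, f))
        elif p.size == 1:
            powers[band.name] = float(p[0] * spec.bin_width_hz)
        else:
            powers[band.name] = 0.0
    total = sum(powers.values())
    if total <= 0.0:
        raise UndefinedResultError("no power in the 1-10 cpm gastric range")
    return BandPowerSummary(
        pct_brady=100.0 * powers["bradygastria"] / total,
        pct_normo=100.0 * powers["normogastria"] / total,
        pct_tachy=100.0 * powers["tachygastria"] / total,
        total_power=total,
    )


def dominant_frequency(
    spec: SpectralEstimate,
    lo_cpm: float = GASTRIC_LO_CPM,
    hi_cpm: float = GASTRIC_HI_CPM,
) -> float:
    """Frequency (cpm) of the maximal PSD bin within the gastric range.

    Ties break toward the lower frequency.  Raises
    :class:`UndefinedResultError` if the in-range spectrum is all zero.
    """
    freqs_cpm = spec.freqs_cpm
    mask = (freqs_cpm >= lo_cpm) & (freqs_cpm <= hi_cpm * (1 + 1e-12))
    if not np.any(mask):
        raise UndefinedResultError("spectrum has no bins in the gastric range")
    p = spec.power[mask]
    if not np.any(p > 0):
        raise UndefinedResultError("spectrum is zero across the gastric range")
    return float(freqs_cpm[mask][int(np.argmax(p))])
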
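"""Synthetic electrogastrogram generation.

Real abdominal-surface EGG is dominated by a narrow-band gastric slow
wave (normally ~3 cpm) riding on electrode drift and broadband noise.
The generator models exactly that: a mixture of sinusoids at configurable
cpm frequencies, a linear drift term, white Gaussian noise, and optional
ADC-style quantization (acquisition hardware records 16-bit samples at
1000 Hz).  The model is deliberately simple — every component has a
closed-form band-power contribution, so analysis results can be checked
against analytically known targets.

Scenario presets map the within-session physiology onto band-power
targets: normogastria is lowest in the fasted state, rises after water
intake/training and falls back somewhat after drinking to fullness
(which can induce mild nausea and dysrhythmia).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    ConfigurationError,
    FilterSpec,
    RawRecording,
    bandpass_sos,
    cpm_to_hz,
)

__all__ = [
    "SimulationConfig",
    "ScenarioLabel",
    "SCENARIOS",
    "simulate_egg",
    "simulate_scenario",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the sinusoid-mixture EGG model.

    Parameters
    ----------
    duration_s
        Recording length in seconds.
    fs
        Sampling rate in Hz (acquisition default 1000).
    components
        Sinusoids as ``(freq_cpm, amplitude, phase_rad)`` triples; each
        contributes ``amplitude * sin(2*pi*f*t + phase)``.
    drift_slope
        Linear drift in units per second, emulating slow electrode drift.
    noise_sd
        Standard deviation of additive white Gaussian noise, in raw units.
    quantize_bits
        If set, samples are quantized to this many bits over the signal
        range and returned as integer ADC counts.
    seed
        Seed for the noise generator; a fixed seed gives bit-identical
        output.
    """

    duration_s: float
    fs: float = 1000.0
    components: tuple[tuple[float, float, float], ...] = ()
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    quantize_bits: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigurationError("duration_s must be positive")
        if not self.fs > 0:
            raise ConfigurationError("fs must be positive")
        comps = tuple((float(f), float(a), float(p)) for f, a, p in self.components)
        for f, _, _ in comps:
            if not 0 < f < 30:
                raise ConfigurationError(
                    f"component frequency must lie in (0, 30) cpm, got {f}"
                )
        object.__setattr__(self, "components", comps)
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.quantize_bits is not None and self.quantize_bits < 2:
            raise ConfigurationError("quantize_bits must be >= 2")


@dataclass(frozen=True)
class ScenarioLabel:
    """A named physiological state with target band-power percentages."""

    name: str
    target_normo_pct: float
    target_brady_pct: float
    target_tachy_pct: float

    def __post_init__(self) -> None:
        targets = (self.target_normo_pct, self.target_brady_pct, self.target_tachy_pct)
        if any(t < 0 for t in targets):
            raise ConfigurationError("scenario targets must be nonnegative")
        if abs(sum(targets) - 100.0) > 1e-6:
            raise ConfigurationError(
                f"scenario targets must sum to 100, got {sum(targets)}"
            )


#: Illustrative per-timepoint presets: normogastria lowest when fasted,
#: highest after water intake during training, partially reduced at
#: fullness after the water-load test.
SCENARIOS: dict[str, ScenarioLabel] = {
    "fasted": ScenarioLabel("fasted", 40.0, 35.0, 25.0),
    "post_water": ScenarioLabel("post_water", 70.0, 20.0, 10.0),
    "fullness": ScenarioLabel("fullness", 50.0, 30.0, 20.0),
}


def simulate_egg(config: SimulationConfig) -> RawRecording:
    """Generate a synthetic EGG recording from a :class:`SimulationConfig`.

    The output is the sum of the configured sinusoids, linear drift and
    Gaussian noise; with ``quantize_bits`` set, samples are mapped to
    integer levels spanning the signal range (a constant signal is left
    untouched, as there is no range to span).
    """
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    x = np.zeros(n)
    for f_cpm, amp, phase in config.components:
        x += amp * np.sin(2 * np.pi * cpm_to_hz(f_cpm) * t + phase)
    x += config.drift_slope * t
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        x += rng.normal(0.0, config.noise_sd, size=n)
    if config.quantize_bits is not None:
        lo, hi = float(x.min()), float(x.max())
        if hi > lo:
            levels = 2**config.quantize_bits - 1
            x = np.round((x - lo) / (hi - lo) * levels)
    return RawRecording(samples=x, fs=config.fs)


# Tone placement for the three bands: band-centre frequencies (geometric
# centre for the wide tachygastric band) keep Hann leakage inside the band.
_BAND_TONES_CPM = {"bradygastria": 1.5, "normogastria": 3.0, "tachygastria": 6.0}


def _pipeline_gain(f_cpm: float, fs_out: float = 10.0) -> float:
    """Amplitude gain of the offline zero-phase bandpass at ``f_cpm``.

    Used to pre-compensate tone amplitudes so that analysed band
    percentages land on the scenario targets despite the filter's
    band-edge roll-off.  Zero-phase filtering applies the transfer
    function twice, hence the squared magnitude.
    """
    sos = bandpass_sos(FilterSpec(), fs_out)
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * cpm_to_hz(f_cpm) / fs_out])
    return float(np.abs(h[0]) ** 2)


def simulate_scenario(
    label: ScenarioLabel | str,
    duration_s: float = 900.0,
    seed: int = 0,
    *,
    fs: float = 1000.0,
    noise_sd: float = 0.1,
    drift_slope: float = 1e-4,
) -> RawRecording:
    """Generate a recording whose analysed band powers match a scenario.

    One tone is placed in each gastric band (1.5, 3 and 6 cpm).  Band
    power scales with amplitude squared, so amplitudes are set to
    ``sqrt(target_pct)`` and divided by the offline filter's gain at the
    tone frequency; the analysed percentages then recover the targets to
    within a few points (Hann leakage and noise account for the rest).
    """
    if isinstance(label, str):
        try:
            label = SCENARIOS[label]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario {label!r}; choose from {sorted(SCENARIOS)}"
            ) from None
    targets = {
        "bradygastria": label.target_brady_pct,
        "normogastria": label.target_normo_pct,
        "tachygastria": label.target_tachy_pct,
    }
    rng = np.random.default_rng(seed)
    components = []
    for band, pct in targets.items():
        if pct <= 0:
            continue
        f_cpm = _BAND_TONES_CPM[band]
        amp = np.sqrt(pct / 100.0) / _pipeline_gain(f_cpm)
        components.append((f_cpm, amp, float(rng.uniform(0, 2 * np.pi))))
    config = SimulationConfig(
        duration_s=duration_s,
        fs=fs,
        components=tuple(components),
        drift_slope=drift_slope,
        noise_sd=noise_sd,
        seed=seed,
    )
    return simulate_egg(config)
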
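"""Streaming gastric biofeedback engine.

Translates a live EGG sample stream into per-frame feedback states, the
way a rendering front end (VR headset or flat screen) would consume
them.  Three feedback elements are produced:

* **Pacemaker**: a reference sphere filling and draining at a steady
  3 cpm, the healthy gastric rhythm participants try to match.
* **Direct feedback**: a sphere whose fill tracks the participant's own
  bandpass-filtered EGG in real time, normalized by its trailing
  min/max so it self-calibrates across electrode gains.
* **Dimensional FFT feedback**: the fraction of normogastric (2-4 cpm)
  power in a sliding window, mapped onto environment parameters —
  higher normogastria means fewer clouds, clearer water, less wind.

The whole chain is causal: the state emitted at time ``t`` depends only
on samples up to ``t``.  Filtering therefore uses the single-pass
(phase-delaying) Butterworth variant rather than the offline zero-phase
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import (
    CANONICAL_BANDS,
    ConfigurationError,
    FilterSpec,
    RawRecording,
    UndefinedResultError,
    band_powers,
    bandpass_sos,
    detrend,
    downsample,
    spectrum,
)

__all__ = [
    "StreamConfig",
    "EnvironmentParams",
    "FeedbackState",
    "pacemaker_fill",
    "direct_feedback",
    "fft_feedback",
    "stream_process",
]

#: Internal processing rate of the feedback chain, in Hz.
STREAM_FS = 10.0

#: Neutral environment shown before the first full spectral window.
NEUTRAL_ENV_LEVEL = 0.5


@dataclass(frozen=True)
class StreamConfig:
    """Streaming parameters.

    ``window_s`` is the sliding-window length for the spectral branch: at
    least 60 s is needed to resolve 1 cpm at all, but a Hann window only
    confines a tone's main lobe to within +/-0.5 cpm (half the width of
    the narrowest gastric band) once T >= 240 s, so 240 s is the default;
    shorter windows smear bradygastric power into the neighbouring band.
    ``hop_s`` sets the update cadence (1 s keeps visuals smooth).
    ``direct_norm_s`` is the trailing history used to normalize the
    direct-feedback sphere.
    """

    window_s: float = 240.0
    hop_s: float = 1.0
    direct_norm_s: float = 60.0
    pacemaker_cpm: float = 3.0
    filter_spec: FilterSpec = FilterSpec(zero_phase=False)

    def __post_init__(self) -> None:
        if self.window_s < 60:
            raise ConfigurationError("window_s must be >= 60 s to resolve 1 cpm")
        if not self.hop_s > 0:
            raise ConfigurationError("hop_s must be positive")
        if not self.direct_norm_s > 0:
            raise ConfigurationError("direct_norm_s must be positive")
        if not self.pacemaker_cpm > 0:
            raise ConfigurationError("pacemaker_cpm must be positive")
        if self.filter_spec.zero_phase:
            raise ConfigurationError(
                "streaming requires a causal filter (zero_phase=False)"
            )


@dataclass(frozen=True)
class EnvironmentParams:
    """Weather/sound parameters of the feedback scene, each in [0, 1]."""

    cloud_density: float
    water_clarity: float
    wind_gain: float
    water_sound_gain: float

    def __post_init__(self) -> None:
        for name in ("cloud_density", "water_clarity", "wind_gain", "water_sound_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "cloud_density": self.cloud_density,
            "water_clarity": self.water_clarity,
            "wind_gain": self.wind_gain,
            "water_sound_gain": self.water_sound_gain,
        }


NEUTRAL_ENV = EnvironmentParams(
    NEUTRAL_ENV_LEVEL, NEUTRAL_ENV_LEVEL, NEUTRAL_ENV_LEVEL, NEUTRAL_ENV_LEVEL
)


@dataclass(frozen=True)
class FeedbackState:
    """One time-stamped frame of biofeedback output."""

    t: float
    pacemaker_fill: float
    user_fill: float
    normo_fraction: float | None
    env: EnvironmentParams
    warmed_up: bool

    def __post_init__(self) -> None:
        for name in ("pacemaker_fill", "user_fill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        if self.normo_fraction is not None and not 0.0 <= self.normo_fraction <= 1.0:
            raise ValueError(f"normo_fraction out of [0, 1]: {self.normo_fraction}")

    def as_dict(self, *, include_env: bool = True) -> dict:
        d = {
            "t": self.t,
            "pacemaker_fill": self.pacemaker_fill,
            "user_fill": self.user_fill,
            "normo_fraction": self.normo_fraction,
            "warmed_up": self.warmed_up,
        }
        if include_env:
            d["env"] = self.env.as_dict()
        return d


def pacemaker_fill(t: float | np.ndarray, cpm: float = 3.0) -> float | np.ndarray:
    """Raised-cosine fill of the pacemaker sphere at time ``t`` seconds.

    ``(1 - cos(2*pi*cpm*t/60)) / 2``: zero (empty) at t=0, full at half
    the 60/cpm-second period, back to empty each cycle.
    """
    if not cpm > 0:
        raise ValueError("cpm must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    fill = (1.0 - np.cos(2.0 * np.pi * cpm * t / 60.0)) / 2.0
    out = np.clip(fill, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def direct_feedback(filtered_window: Sequence[float]) -> float:
    """Map the latest filtered sample to [0, 1] by trailing min-max.

    The affine map uses the min and max over the supplied trailing
    window; a (near-)constant window maps to 0.5 so a flat signal parks
    the sphere at half fill rather than jittering.
    """
    w = np.asarray(filtered_window, dtype=float)
    if w.size < 2:
        raise ValueError("direct feedback needs at least 2 samples of history")
    lo, hi = float(w.min()), float(w.max())
    span = hi - lo
    if span <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return 0.5
    return float((w[-1] - lo) / span)


def fft_feedback(normo_fraction: float) -> EnvironmentParams:
    """Map the normogastric power fraction onto environment parameters.

    Linear mappings, chosen so that higher normogastria gives sunnier
    weather: clouds and wind fade out, water clears, and the water sound
    swells from a 0.25 floor (the lake never falls fully silent).
    """
    if not 0.0 <= normo_fraction <= 1.0:
        raise ValueError(f"normo_fraction out of [0, 1]: {normo_fraction}")
    return EnvironmentParams(
        cloud_density=1.0 - normo_fraction,
        water_clarity=normo_fraction,
        wind_gain=1.0 - normo_fraction,
        water_sound_gain=0.25 + 0.75 * normo_fraction,
    )


def _causal_streams(rec: RawRecording, spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Causally decimate to 10 Hz and bandpass.

    Returns ``(direct, spectral)`` streams.  The direct-feedback stream is
    a single causal pass (lowest latency).  The spectral stream runs the
    same filter twice: its magnitude response then equals the offline
    zero-phase filter's squared magnitude, so windowed band percentages
    agree with the offline pipeline (the extra phase delay is irrelevant
    to a power spectrum) while remaining causal.
    """
    if abs(rec.fs - STREAM_FS) < 1e-9:
        low = rec
    else:
        ratio = rec.fs / STREAM_FS
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 2:
            raise ConfigurationError(
                f"stream input must be at {STREAM_FS:g} Hz or an integer "
                f"multiple of it, got fs={rec.fs}"
            )
        low = downsample(rec, STREAM_FS, causal=True)
    sos = bandpass_sos(spec, STREAM_FS)
    direct = np.asarray(sps.sosfilt(sos, low.samples))
    spectral = np.asarray(sps.sosfilt(sos, direct))
    return direct, spectral


def stream_process(
    rec: RawRecording, cfg: StreamConfig | None = None
) -> list[FeedbackState]:
    """Run the full causal feedback chain over a recording.

    Emits one :class:`FeedbackState` per hop, at t = hop, 2*hop, ...
    Frames before a full spectral window has accumulated carry
    ``warmed_up=False``, an undefined ``normo_fraction`` and a neutral
    environment.  The chain is deterministic and causal: each frame uses
    only samples at or before its timestamp, so truncating the input
    never changes earlier frames.
    """
    cfg = cfg or StreamConfig()
    direct, spectral = _causal_streams(rec, cfg.filter_spec)
    n_win = int(round(cfg.window_s * STREAM_FS))
    n_norm = int(round(cfg.direct_norm_s * STREAM_FS))
    states: list[FeedbackState] = []
    n_frames = int(math.floor(rec.duration / cfg.hop_s + 1e-9))
    for k in range(1, n_frames + 1):
        t = k * cfg.hop_s
        i = min(int(math.floor(t * STREAM_FS + 1e-9)), direct.size)
        norm_win = direct[max(0, i - n_norm) : i]
        user = direct_feedback(norm_win) if norm_win.size >= 2 else 0.5
        warmed = i >= n_win
        normo: float | None = None
        env = NEUTRAL_ENV
        if warmed:
            seg = detrend(spectral[i - n_win : i])
            try:
                summary = band_powers(spectrum(seg, STREAM_FS), CANONICAL_BANDS)
            except UndefinedResultError:
                pass
            else:
                normo = summary.pct_normo / 100.0
                env = fft_feedback(normo)
        states.append(
            FeedbackState(
                t=t,
                pacemaker_fill=float(pacemaker_fill(t, cfg.pacemaker_cpm)),
                user_fill=user,
                normo_fraction=normo,
                env=env,
                warmed_up=warmed,
            )
        )
    return states
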
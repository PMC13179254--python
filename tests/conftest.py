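"""Shared fixtures and the brute-force spectral oracle.

The oracle recomputes the Hann-windowed, zero-padded, one-sided PSD by a
direct O(n^2) matrix DFT, independently of the FFT implementation, so it
can vouch for the windowing/padding/scaling logic of the package's
spectrum estimator.
"""

from __future__ import annotations

import numpy as np
import pytest

from eggflow.core import RawRecording
from eggflow.simulate import SimulationConfig, simulate_egg


def dft_psd_oracle(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann PSD via a direct DFT matrix; returns (freqs_hz, psd)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))  # periodic Hann
    n_fft = 1
    while n_fft < n:
        n_fft *= 2
    xp = np.zeros(n_fft)
    xp[:n] = x * w
    k = np.arange(n_fft // 2 + 1)
    # (n_fft/2+1, n_fft) DFT matrix; fine for n_fft <= 4096
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n_fft)) / n_fft)
    spec = dft @ xp
    psd = np.abs(spec) ** 2 / (fs * np.sum(w**2))
    psd[1:] *= 2.0
    if n_fft % 2 == 0:
        psd[-1] /= 2.0
    freqs = k * fs / n_fft
    return freqs, psd


def tone_recording(
    f_cpm: float,
    duration_s: float = 900.0,
    fs: float = 1000.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawRecording:
    """A single-tone synthetic EGG recording."""
    return simulate_egg(
        SimulationConfig(
            duration_s=duration_s,
            fs=fs,
            components=((f_cpm, amplitude, 0.0),),
            noise_sd=noise_sd,
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def normo_recording() -> RawRecording:
    """900 s of a pure 3 cpm tone at 1000 Hz."""
    return tone_recording(3.0)
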
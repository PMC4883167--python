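"""Two-class synthetic EEG generator.

Emulates the statistical contrast the texture pipeline relies on: healthy
surface EEG is modelled as low-amplitude 1/f-shaped broadband noise with an
alpha rhythm riding on top, while ictal EEG is a high-amplitude rhythmic
spike-wave discharge in the delta/low-theta range (fundamental plus 2nd/3rd
harmonics, sharpened to produce spike-like peaks). Amplitudes differ by a
configurable ratio, mirroring the visibly larger amplitude of seizure EEG.

The generator makes no claim of physiological fidelity; it exists so that the
full spectrogram -> texture -> classifier pipeline is exercisable end to end
with a known two-class structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import DEFAULT_FS, Signal


@dataclass
class SynthConfig:
    """Parameters of the two-class generator.

    Attributes
    ----------
    n_per_class : int
        Number of signals generated per class.
    n_samples : int
        Samples per signal (default 4097, a 23.6 s segment at ``fs``).
    fs : float
        Sampling rate in Hz (default ~173.61).
    seed : int
        Seed for the random generator; same seed gives bit-identical output.
    normal_alpha_freq : float
        Alpha-rhythm frequency of the healthy class, Hz.
    seizure_spike_freq : float
        Spike-wave fundamental of the ictal class, Hz.
    amplitude_ratio : float
        Target ratio of seizure RMS to mean normal RMS (must be > 1).
    """

    n_per_class: int
    n_samples: int = 4097
    fs: float = DEFAULT_FS
    seed: int = 0
    normal_alpha_freq: float = 10.0
    seizure_spike_freq: float = 3.5
    amplitude_ratio: float = 5.0

    def __post_init__(self):
        if self.n_per_class < 0:
            raise ParameterError("n_per_class must be >= 0")
        if self.n_samples < 256:
            raise ParameterError("n_samples must be >= 256")
        max_f = max(self.normal_alpha_freq, 3 * self.seizure_spike_freq)
        if self.fs <= 2 * max_f:
            raise ParameterError(
                f"fs={self.fs} too low: need fs > 2 x max generated frequency ({max_f} Hz)"
            )
        if self.amplitude_ratio <= 1:
            raise ParameterError("amplitude_ratio must be > 1")


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # flat below 1 Hz to keep variance finite, 1/sqrt(f) rolloff above
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x**2))


def _normal_signal(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    t = np.arange(cfg.n_samples) / cfg.fs
    noise = _pink_noise(rng, cfg.n_samples, cfg.fs)
    phase = rng.uniform(0, 2 * np.pi)
    alpha_amp = 1.4 * (1 + 0.15 * rng.standard_normal())
    return noise + alpha_amp * np.sin(2 * np.pi * cfg.normal_alpha_freq * t + phase)


def _seizure_signal(rng: np.random.Generator, cfg: SynthConfig, target_rms: float) -> np.ndarray:
    t = np.arange(cfg.n_samples) / cfg.fs
    f0 = cfg.seizure_spike_freq * (1 + 0.05 * rng.standard_normal())
    phase = rng.uniform(0, 2 * np.pi)
    wave = (
        np.sin(2 * np.pi * f0 * t + phase)
        + 0.5 * np.sin(2 * np.pi * 2 * f0 * t + 2 * phase)
        + 0.25 * np.sin(2 * np.pi * 3 * f0 * t + 3 * phase)
    )
    # sharpening nonlinearity: compresses magnitude, makes peaks spike-like
    wave = np.sign(wave) * np.abs(wave) ** 0.7
    wave = wave + 0.1 * _pink_noise(rng, cfg.n_samples, cfg.fs)
    rms = np.sqrt(np.mean(wave**2))
    jitter = 1 + 0.1 * rng.standard_normal()
    return wave * (target_rms * jitter / rms)


def generate_dataset(config: SynthConfig) -> list[Signal]:
    """Generate ``2 * n_per_class`` labelled signals (normals first).

    Deterministic for a fixed ``config.seed``. Seizure signals are scaled so
    their RMS is ``amplitude_ratio`` times the expected normal-class RMS
    (with ~10% per-signal jitter).
    """
    rng = np.random.default_rng(config.seed)
    signals: list[Signal] = []
    normal_rms = []
    for i in range(config.n_per_class):
        x = _normal_signal(rng, config)
        normal_rms.append(np.sqrt(np.mean(x**2)))
        signals.append(
            Signal(x, fs=config.fs, label="normal", source_id=f"synthetic/normal/{i:03d}")
        )
    # expected normal RMS: unit-RMS noise plus alpha sinusoid of amplitude ~1.4
    expected_rms = float(np.mean(normal_rms)) if normal_rms else np.sqrt(1 + 1.4**2 / 2)
    target = config.amplitude_ratio * expected_rms
    for i in range(config.n_per_class):
        x = _seizure_signal(rng, config, target)
        signals.append(
            Signal(x, fs=config.fs, label="seizure", source_id=f"synthetic/seizure/{i:03d}")
        )
    return signals
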
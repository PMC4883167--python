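"""Time-frequency representation: log-power STFT spectrogram, 8-bit
gray-scale quantization, and rhythm-band segmentation.

The spectrogram of a windowed short-time Fourier transform is

    S(n, k) = log |X(n, k)|^2,    X(n, k) = sum_m x[m] w[n - m] e^{-j 2pi k m / N},

evaluated on the one-sided frequency grid f_k = k * fs / N, k = 0..N/2. A
floor of ``eps * max |X|^2`` replaces zero power before the log so the image
stays finite. Each spectrogram is min-max mapped onto {0, ..., 255}
independently (per-image normalization), then cut into the five conventional
EEG rhythm bands:

    delta 0-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz, gamma 30-50 Hz

with half-open intervals [low, high); rows at or above 50 Hz are discarded.

Image orientation: row index increases with frequency (row 0 is DC); this is
internal only — all consumers address bands through :class:`BandSubimages`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .errors import ConfigurationError, ParameterError
from .io import Signal

#: (name, low_hz, high_hz) in fixed concatenation order, low to high.
RHYTHM_BANDS = (
    ("delta", 0.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, 50.0),
)

#: Relative floor applied to power before taking the log.
LOG_FLOOR_REL = 1e-12


@dataclass
class Spectrogram:
    """Log-power STFT values, time frames x frequency bins."""

    values: np.ndarray  # (n_frames, n_bins), natural-log power
    freqs: np.ndarray  # (n_bins,) Hz
    times: np.ndarray  # (n_frames,) seconds, frame centres
    n_fft: int


@dataclass
class TFImage:
    """8-bit gray-scale time-frequency image (frequency rows x time columns)."""

    pixels: np.ndarray  # uint8, (n_bins, n_frames)
    freqs: np.ndarray  # (n_bins,) Hz, ascending with row index


@dataclass
class BandSubimages:
    """The five rhythm-band slices of a :class:`TFImage`."""

    delta: TFImage
    theta: TFImage
    alpha: TFImage
    beta: TFImage
    gamma: TFImage
    band_edges: dict

    def __iter__(self):
        for name, _, _ in RHYTHM_BANDS:
            yield name, getattr(self, name)


def stft_spectrogram(
    signal: Signal,
    window_len: int = 128,
    overlap: int = 64,
    n_fft: int = 256,
) -> Spectrogram:
    """Compute the log-power spectrogram of a signal.

    Hann-windowed frames of ``window_len`` samples advance by
    ``window_len - overlap``; each frame is zero-padded to ``n_fft`` before
    the DFT. Defaults (128/64/256) give ~63 frames on a 4097-sample segment
    and ~0.68 Hz bins, so every rhythm band spans at least 5 frequency rows.
    """
    x = signal.samples
    if window_len > x.size:
        raise ParameterError(
            f"window_len={window_len} exceeds signal length {x.size}"
        )
    if not 0 <= overlap < window_len:
        raise ParameterError("require 0 <= overlap < window_len")
    if n_fft < window_len:
        raise ParameterError("n_fft must be >= window_len")

    hop = window_len - overlap
    n_frames = (x.size - window_len) // hop + 1
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    window = hann(window_len, sym=False)
    frames = x[idx] * window
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2

    floor = LOG_FLOOR_REL * power.max()
    if floor == 0.0:  # all-zero signal: keep a finite, constant image
        floor = LOG_FLOOR_REL
    values = np.log(np.maximum(power, floor))

    freqs = np.arange(n_fft // 2 + 1) * signal.fs / n_fft
    times = (hop * np.arange(n_frames) + window_len / 2) / signal.fs
    return Spectrogram(values=values, freqs=freqs, times=times, n_fft=n_fft)


def to_gray8(spec: Spectrogram) -> TFImage:
    """Min-max quantize a spectrogram onto {0, ..., 255}.

    Rounding is half-away-from-zero. A constant spectrogram maps to all
    zeros by convention. Output rows are frequency (ascending), columns time.
    """
    values = spec.values
    if not np.all(np.isfinite(values)):
        raise ParameterError("spectrogram contains non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        pixels = np.zeros_like(values, dtype=np.uint8)
    else:
        scaled = (values - lo) * (255.0 / (hi - lo))
        pixels = np.floor(scaled + 0.5).astype(np.uint8)  # scaled >= 0
    return TFImage(pixels=pixels.T.copy(), freqs=spec.freqs.copy())


def band_split(img: TFImage) -> BandSubimages:
    """Cut a t-f image into the five rhythm-band sub-images.

    Each band keeps rows with ``low <= f < high``; rows at or above the gamma
    upper edge (50 Hz) are discarded.
    """
    if img.freqs.max() < RHYTHM_BANDS[-1][2]:
        raise ConfigurationError(
            f"frequency axis reaches only {img.freqs.max():.1f} Hz; "
            "the gamma band needs >= 50 Hz (sampling rate too low)"
        )
    parts = {}
    edges = {}
    for name, lo, hi in RHYTHM_BANDS:
        rows = (img.freqs >= lo) & (img.freqs < hi)
        if not rows.any():
            raise ConfigurationError(
                f"band {name} [{lo}, {hi}) Hz contains no frequency rows; "
                "increase n_fft or the sampling rate"
            )
        parts[name] = TFImage(pixels=img.pixels[rows], freqs=img.freqs[rows])
        edges[name] = (lo, hi)
    return BandSubimages(band_edges=edges, **parts)


def save_png(img: TFImage, path) -> None:
    """Export a t-f image (or band sub-image) as an 8-bit gray PNG.

    Rendered with low frequencies at the bottom, as spectrograms are usually
    displayed.
    """
    from PIL import Image

    Image.fromarray(img.pixels[::-1], mode="L").save(path)
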
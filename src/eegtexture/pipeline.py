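"""Per-signal feature extraction: spectrogram -> 8-bit t-f image -> five
rhythm-band sub-images -> one texture descriptor per band -> concatenation.

Band order in the concatenated vector is fixed low-to-high (delta, theta,
alpha, beta, gamma). Per band the descriptors contribute:

* GLCM  — 4 angles (0, 45, 90, 135 deg at distance ``glcm_delta``) x 4
  statistics (contrast, correlation, energy, homogeneity) = 16 values,
  hence an 80-dimensional signal descriptor;
* TFCM  — the 12 TFN statistics, hence 60 dimensions;
* LBP   — the 256-bin code histogram, hence 1280 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glcm as _glcm
from . import lbp as _lbp
from . import tfcm as _tfcm
from . import tfr as _tfr
from .errors import ConfigurationError, ParameterError
from .io import Signal

DESCRIPTORS = ("glcm", "tfcm", "lbp")

#: Expected per-band and total dimensions per descriptor.
FEATURES_PER_BAND = {"glcm": 16, "tfcm": 12, "lbp": 256}

GLCM_ANGLES = (0, 45, 90, 135)


@dataclass
class TFRParams:
    """STFT parameters handed to :func:`eegtexture.tfr.stft_spectrogram`."""

    window_len: int = 128
    overlap: int = 64
    n_fft: int = 256


@dataclass
class FeatureVector:
    """Concatenated per-band descriptor of one signal."""

    values: np.ndarray
    descriptor: str
    names: list[str]
    band_spans: dict  # band -> (start, stop) slice into values


def _band_features(band: str, pixels: np.ndarray, descriptor: str,
                   glcm_delta: int, tfcm_tolerance: float):
    if descriptor == "glcm":
        values, names = [], []
        for theta in GLCM_ANGLES:
            m = _glcm.compute_glcm(pixels, delta=glcm_delta, theta=theta)
            values.append(_glcm.glcm_features(m))
            names.extend(f"{band}_glcm_{theta}_{f}" for f in _glcm.GLCM_FEATURE_NAMES)
        return np.concatenate(values), names
    if descriptor == "tfcm":
        tfn = _tfcm.encode_tfn(pixels, _tfcm.TFCMConfig(tolerance=tfcm_tolerance))
        names = [f"{band}_tfcm_{f}" for f in _tfcm.TFCM_FEATURE_NAMES]
        return _tfcm.tfcm_features(tfn), names
    if descriptor == "lbp":
        hist = _lbp.lbp_histogram(_lbp.lbp_image(pixels))
        names = [f"{band}_lbp_{code}" for code in range(256)]
        return hist, names
    raise ParameterError(f"unknown descriptor {descriptor!r}; choose from {DESCRIPTORS}")


def extract_features(
    signal: Signal,
    descriptor: str,
    tfr_params: TFRParams | None = None,
    glcm_delta: int = 1,
    tfcm_tolerance: float = 80.0,
) -> FeatureVector:
    """Run the full per-signal pipeline for one descriptor family."""
    if descriptor not in DESCRIPTORS:
        raise ParameterError(f"unknown descriptor {descriptor!r}; choose from {DESCRIPTORS}")
    tfr_params = tfr_params or TFRParams()
    spec = _tfr.stft_spectrogram(
        signal, tfr_params.window_len, tfr_params.overlap, tfr_params.n_fft
    )
    bands = _tfr.band_split(_tfr.to_gray8(spec))
    chunks, names, spans = [], [], {}
    start = 0
    for band, sub in bands:
        if min(sub.pixels.shape) < 3 and descriptor in ("tfcm", "lbp"):
            raise ParameterError(
                f"band {band!r} sub-image {sub.pixels.shape} is below the 3x3 "
                f"support of the {descriptor.upper()} operator; increase n_fft"
            )
        vals, nms = _band_features(band, sub.pixels, descriptor, glcm_delta, tfcm_tolerance)
        chunks.append(vals)
        names.extend(nms)
        spans[band] = (start, start + vals.size)
        start += vals.size
    values = np.concatenate(chunks)
    if not np.all(np.isfinite(values)):
        raise ParameterError("non-finite feature values produced")
    return FeatureVector(values=values, descriptor=descriptor, names=names, band_spans=spans)


def build_matrix(
    signals: list[Signal],
    descriptor: str,
    tfr_params: TFRParams | None = None,
    glcm_delta: int = 1,
    tfcm_tolerance: float = 80.0,
) -> pd.DataFrame:
    """Feature matrix for a list of signals.

    Returns a DataFrame with one row per signal, named feature columns and a
    final ``label`` column; all signals must share one sampling rate.
    """
    if not signals:
        raise ConfigurationError("empty signal list")
    fs = {s.fs for s in signals}
    if len(fs) > 1:
        raise ConfigurationError(f"mixed sampling rates in dataset: {sorted(fs)}")
    rows, labels, names = [], [], None
    for s in signals:
        fv = extract_features(s, descriptor, tfr_params, glcm_delta, tfcm_tolerance)
        rows.append(fv.values)
        labels.append(s.label)
        names = fv.names
    df = pd.DataFrame(np.vstack(rows), columns=names)
    df["label"] = labels
    return df
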
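"""Read and write single-channel EEG segments stored as one-sample-per-line
ASCII files, and load labelled dataset directories.

A dataset root contains one subdirectory per class; the directory name maps
to a label through :data:`DEFAULT_LABEL_MAP` (``A``/``Z``/``normal`` are
healthy surface EEG, ``E``/``S``/``seizure`` are ictal recordings, following
the common public-dataset conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParameterError, ParseError

#: Sampling rate implied by 4097 samples over a 23.6 s segment.
DEFAULT_FS = 4097 / 23.6  # ~173.61 Hz

#: Directory-name (case-insensitive) to class-label mapping.
DEFAULT_LABEL_MAP = {
    "normal": "normal",
    "a": "normal",
    "z": "normal",
    "seizure": "seizure",
    "e": "seizure",
    "s": "seizure",
}


@dataclass
class Signal:
    """A single-channel EEG segment.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence, one value per sample.
    fs : float
        Sampling rate in Hz.
    label : str
        ``"normal"``, ``"seizure"`` or ``"unknown"``.
    source_id : str
        Provenance tag (file path or generator id).
    """

    samples: np.ndarray
    fs: float
    label: str = "unknown"
    source_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("a Signal needs a 1-D sample sequence of length >= 2")
        if not math.isfinite(self.fs) or self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("signal samples must all be finite")

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


def read_signal(path, fs: float = DEFAULT_FS, label_map=None) -> Signal:
    """Read a one-sample-per-line ASCII signal file.

    The class label is inferred from the parent directory name when it is
    recognised by *label_map* (default :data:`DEFAULT_LABEL_MAP`), otherwise
    ``"unknown"``.
    """
    path = Path(path)
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    values = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ParseError(path, line_no, text) from None
    if len(values) < 2:
        raise FormatError(f"{path}: expected at least 2 samples, found {len(values)}")
    label = label_map.get(path.parent.name.lower(), "unknown")
    return Signal(np.asarray(values), fs=fs, label=label, source_id=str(path))


def write_signal(signal: Signal, path) -> None:
    """Write a signal as one ASCII sample per line (used by the simulator)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, signal.samples, fmt="%.6f")


def load_dataset(root, fs: float = DEFAULT_FS, label_map=None) -> list[Signal]:
    """Load every signal under class subdirectories of *root*.

    Ordering is deterministic: class directories and files are visited in
    sorted path order. Raises :class:`ConfigurationError` when no recognised
    class subdirectory exists.
    """
    root = Path(root)
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    if not root.is_dir():
        raise ConfigurationError(f"dataset root {root} is not a directory")
    class_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and d.name.lower() in label_map
    )
    if not class_dirs:
        raise ConfigurationError(
            f"{root} contains no recognised class subdirectory "
            f"(expected one of {sorted(set(label_map))})"
        )
    signals = []
    for d in class_dirs:
        for f in sorted(d.iterdir()):
            if f.is_file():
                signals.append(read_signal(f, fs=fs, label_map=label_map))
    return signals


def export_features_csv(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix (one row per signal, final column = label)."""
    if "label" not in matrix.columns:
        raise ConfigurationError("feature matrix must carry a 'label' column")
    cols = [c for c in matrix.columns if c != "label"] + ["label"]
    matrix[cols].to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`export_features_csv`."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ConfigurationError(f"{path}: missing 'label' column")
    return df
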
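"""Texture Feature Coding Method (TFCM).

TFCM encodes each interior pixel's local gray-level variation into a texture
feature number (TFN) and then summarizes the TFN image with 12 statistics.

Encoding, per interior pixel with center value c and tolerance Delta:

1. Four connectivity sets from the 3x3 neighbourhood — horizontal
   (left, right), vertical (up, down), and the two diagonals (up-left,
   down-right) and (up-right, down-left) — each give a 2-element difference
   vector ``(neighbour - c, neighbour' - c)``.
2. Each difference d is quantized to -1 (d < -Delta), 0 (|d| <= Delta) or
   +1 (d > Delta): negative, no change, positive.
3. Each quantized 2-vector maps to a variation class in {1, 2, 3, 4} by
   degree of variation: 1 = (0, 0) flat; 2 = exactly one nonzero;
   3 = both nonzero with opposite signs (monotone slope through the pixel);
   4 = both nonzero with equal signs (ridge or valley).
4. The two first-order classes (horizontal, vertical) combine into an index
   a1 and the two diagonal classes into a2 via the unordered pair
   ``idx = min * 10 + max`` ranked into 1..10 (pairs sorted ascending:
   11, 12, 13, 14, 22, 23, 24, 33, 34, 44). The final code is
   ``TFN = (a1 - 1) * 10 + (a2 - 1)``, so the alphabet is {0, ..., 99}.

This concrete class/pair-composition table is a fixed, documented variant:
it preserves the "degree of variation" ordering and the two-level
(first-order / diagonal) composition that define the method, and fixing it
makes results reproducible. Border pixels are excluded (all four
connectivity sets must exist), so the TFN image is the input interior.

The 12 features, with H the normalized TFN histogram (mean mu) and P_theta
the normalized TFN co-occurrence matrices at distance 1 for the four angles
(P-bar their average):

    1  mean convergence          sum_t H(t) |t - mu|
    2  code variance             sum_t H(t) (t - mu)^2
    3  code entropy              -sum_{H>0} H log2 H
    4  uniformity                sum_t H(t)^2
    5  first-order difference moment           sum |t1 - t2| Pbar
    6  first-order inverse difference moment   sum Pbar / (1 + |t1 - t2|)
    7  second-order difference moment          sum (t1 - t2)^2 Pbar
    8  second-order inverse difference moment  sum Pbar / (1 + (t1 - t2)^2)
    9-12  energy sum P_theta^2 for theta = 0, 45, 90, 135 deg
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .glcm import ANGLE_OFFSETS, compute_glcm

#: Rank of each unordered class pair (min*10+max) among the 10 possibilities.
_PAIR_RANK = {
    pair: rank + 1
    for rank, pair in enumerate((11, 12, 13, 14, 22, 23, 24, 33, 34, 44))
}

TFN_ALPHABET = 100

TFCM_FEATURE_NAMES = (
    "mean_convergence",
    "code_variance",
    "code_entropy",
    "uniformity",
    "diff_moment_1",
    "inv_diff_moment_1",
    "diff_moment_2",
    "inv_diff_moment_2",
    "energy_0",
    "energy_45",
    "energy_90",
    "energy_135",
)


@dataclass
class TFCMConfig:
    """Tolerance Delta, in gray-level units, for difference quantization."""

    tolerance: float = 80.0

    def __post_init__(self):
        if self.tolerance < 0:
            raise ParameterError("tolerance must be >= 0")


@dataclass
class TFNImage:
    """Texture-feature-number image (input interior)."""

    codes: np.ndarray  # integer matrix, values in [0, code_alphabet_size)
    code_alphabet_size: int = TFN_ALPHABET


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ParameterError(f"TFCM needs an image of at least 3x3, got {img.shape}")
    return img


def quantize_differences(img: np.ndarray, config: TFCMConfig = TFCMConfig()) -> np.ndarray:
    """Quantized difference vectors for every interior pixel.

    Returns an array of shape ``(rows-2, cols-2, 4, 2)`` with values in
    {-1, 0, +1}; axis 2 indexes the connectivity sets (horizontal, vertical,
    main diagonal, anti-diagonal), axis 3 the two neighbours of each set.
    """
    img = _check_image(img)
    c = img[1:-1, 1:-1]
    # neighbour pairs per connectivity set: (left,right), (up,down),
    # (up-left,down-right), (up-right,down-left)
    pairs = np.stack(
        [
            np.stack([img[1:-1, :-2], img[1:-1, 2:]], axis=-1),
            np.stack([img[:-2, 1:-1], img[2:, 1:-1]], axis=-1),
            np.stack([img[:-2, :-2], img[2:, 2:]], axis=-1),
            np.stack([img[:-2, 2:], img[2:, :-2]], axis=-1),
        ],
        axis=2,
    )
    d = pairs - c[..., None, None]
    tol = config.tolerance
    return (d > tol).astype(np.int8) - (d < -tol).astype(np.int8)


def _variation_class(q: np.ndarray) -> np.ndarray:
    """Map quantized 2-vectors (..., 2) to variation classes {1, 2, 3, 4}."""
    a, b = q[..., 0].astype(int), q[..., 1].astype(int)
    nz = (a != 0).astype(int) + (b != 0).astype(int)
    cls = np.ones_like(a)
    cls[nz == 1] = 2
    both = nz == 2
    cls[both & (a * b < 0)] = 3
    cls[both & (a * b > 0)] = 4
    return cls


def _pair_index(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Rank (1..10) of the unordered class pair."""
    lo = np.minimum(c1, c2)
    hi = np.maximum(c1, c2)
    lut = np.zeros(45, dtype=int)
    for pair, rank in _PAIR_RANK.items():
        lut[pair] = rank
    return lut[lo * 10 + hi]


def encode_tfn(img: np.ndarray, config: TFCMConfig = TFCMConfig()) -> TFNImage:
    """Encode a gray image into its texture-feature-number image."""
    q = quantize_differences(img, config)
    cls = _variation_class(q)  # (rows-2, cols-2, 4)
    a1 = _pair_index(cls[..., 0], cls[..., 1])  # horizontal + vertical
    a2 = _pair_index(cls[..., 2], cls[..., 3])  # the two diagonals
    codes = (a1 - 1) * 10 + (a2 - 1)
    return TFNImage(codes=codes)


def tfcm_features(tfn: TFNImage) -> np.ndarray:
    """The 12 TFCM statistics of a TFN image.

    Requires a TFN image of at least 2x2 so that every co-occurrence
    direction has at least one pixel pair. A constant image is fine and
    yields the degenerate vector (0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 1, 1).
    """
    codes = np.asarray(tfn.codes)
    if codes.ndim != 2 or codes.shape[0] < 2 or codes.shape[1] < 2:
        raise ParameterError(
            f"TFN image must be at least 2x2 for co-occurrence statistics, got {codes.shape}"
        )
    L = tfn.code_alphabet_size
    hist = np.bincount(codes.ravel(), minlength=L).astype(float)
    H = hist / hist.sum()
    t = np.arange(L, dtype=float)
    mu = t @ H
    nz = H > 0
    mean_convergence = float(np.abs(t - mu) @ H)
    code_variance = float(((t - mu) ** 2) @ H)
    code_entropy = float(-(H[nz] @ np.log2(H[nz])))
    uniformity = float(H @ H)

    P_dirs = [
        compute_glcm(codes, delta=1, theta=theta, levels=L).normalized()
        for theta in sorted(ANGLE_OFFSETS)
    ]
    P_bar = np.mean(P_dirs, axis=0)
    diff = t[:, None] - t[None, :]
    dm1 = float((np.abs(diff) * P_bar).sum())
    idm1 = float((P_bar / (1.0 + np.abs(diff))).sum())
    dm2 = float((diff**2 * P_bar).sum())
    idm2 = float((P_bar / (1.0 + diff**2)).sum())
    energies = [float((P**2).sum()) for P in P_dirs]

    return np.array(
        [
            mean_convergence,
            code_variance,
            code_entropy,
            uniformity,
            dm1,
            idm1,
            dm2,
            idm2,
            *energies,
        ]
    )
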
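"""Local binary patterns on a 3x3 block, and the 256-bin code histogram.

Each interior pixel gets the code

    LBP(x) = sum_{i=1..8} f(G(x_i) - G(x)) 2^{i-1},   f(t) = 1 if t >= 0 else 0,

where the eight neighbours x_1..x_8 are taken clockwise starting at the
top-left corner. Note f(0) = 1, so a constant block codes to 255. Border
pixels are excluded (no padding); the LBP image is the input interior.

Any fixed neighbour ordering yields the same histogram up to a permutation
of code labels, so the clockwise-from-top-left convention is simply fixed
and documented. Raw counts (not frequencies) are the feature; scaling is
left to the classification stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: Neighbour (row, col) offsets, clockwise from the top-left corner.
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


@dataclass
class LBPImage:
    """Integer code matrix, values 0-255, shaped like the input interior."""

    codes: np.ndarray


def lbp_code(block: np.ndarray) -> int:
    """LBP code of a single 3x3 block."""
    block = np.asarray(block, dtype=float)
    if block.shape != (3, 3):
        raise ParameterError(f"expected a 3x3 block, got {block.shape}")
    center = block[1, 1]
    code = 0
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if block[1 + dr, 1 + dc] - center >= 0:
            code |= 1 << i
    return code


def lbp_image(img: np.ndarray) -> LBPImage:
    """Per-pixel LBP codes of the image interior."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ParameterError(f"LBP needs an image of at least 3x3, got {img.shape}")
    center = img[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    r, c = img.shape
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neigh = img[1 + dr : r - 1 + dr, 1 + dc : c - 1 + dc]
        codes |= (neigh - center >= 0).astype(np.int64) << i
    return LBPImage(codes=codes)


def lbp_histogram(lbp: LBPImage) -> np.ndarray:
    """Counts of each code 0-255, in code order (length exactly 256)."""
    codes = np.asarray(lbp.codes)
    if codes.size == 0:
        raise ParameterError("empty LBP image")
    return np.bincount(codes.ravel(), minlength=256).astype(float)
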
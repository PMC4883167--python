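"""Gray-level co-occurrence matrices and Haralick-style statistics.

The GLCM ``M[p, q]`` counts pixel pairs ``(I[n, m], I[n', m']) = (p, q)``
whose positions differ by a fixed displacement (distance ``delta``, angle
``theta``). Counting is asymmetric (the pair and its reverse are distinct)
and pairs whose second pixel falls outside the image are skipped. With row
index increasing downward, the displacement vectors are

    0 deg -> ( 0, +d)     45 deg -> (-d, +d)
    90 deg -> (-d,  0)    135 deg -> (-d, -d)

After normalizing to a joint distribution P, four statistics summarize it:
contrast, correlation, energy (angular second moment) and homogeneity
(inverse difference moment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FeatureUndefinedError, ParameterError

#: Angle (degrees) -> (row, col) displacement per unit distance.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: Feature names in output order.
GLCM_FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass
class GLCMatrix:
    """Raw co-occurrence counts with their displacement parameters."""

    counts: np.ndarray  # (levels, levels) integer counts
    delta: int
    theta: int
    levels: int

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise FeatureUndefinedError(
                f"GLCM (delta={self.delta}, theta={self.theta}) has no pixel pairs"
            )
        return self.counts / total


def compute_glcm(img: np.ndarray, delta: int = 1, theta: int = 0, levels: int = 256) -> GLCMatrix:
    """Count gray-level co-occurrences at displacement (*delta*, *theta*).

    *img* is any integer gray image with values in ``[0, levels)``. If the
    offset does not fit anywhere in the image the result is an all-zero
    matrix and a warning is emitted (no crash).
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ParameterError("image must be a non-empty 2-D array")
    if delta < 1:
        raise ParameterError("delta must be >= 1")
    if theta not in ANGLE_OFFSETS:
        raise ParameterError(f"theta must be one of {sorted(ANGLE_OFFSETS)} degrees")
    if img.min() < 0 or img.max() >= levels:
        raise ParameterError(f"pixel values must lie in [0, {levels})")

    dr, dc = (delta * o for o in ANGLE_OFFSETS[theta])
    n, k = img.shape
    counts = np.zeros((levels, levels), dtype=np.int64)

    r0 = slice(max(0, -dr), min(n, n - dr))
    c0 = slice(max(0, -dc), min(k, k - dc))
    first = img[r0, c0]
    if first.size == 0:
        warnings.warn(
            f"offset (delta={delta}, theta={theta}) does not fit in a "
            f"{n}x{k} image; returning all-zero GLCM",
            RuntimeWarning,
            stacklevel=2,
        )
        return GLCMatrix(counts=counts, delta=delta, theta=theta, levels=levels)
    r1 = slice(r0.start + dr, r0.stop + dr)
    c1 = slice(c0.start + dc, c0.stop + dc)
    second = img[r1, c1]
    flat = first.astype(np.int64) * levels + second.astype(np.int64)
    counts = np.bincount(flat.ravel(), minlength=levels * levels).reshape(levels, levels)
    return GLCMatrix(counts=counts, delta=delta, theta=theta, levels=levels)


def glcm_features(glcm: GLCMatrix) -> np.ndarray:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM.

    Correlation is defined as 0 when either marginal standard deviation
    vanishes (e.g. a constant image). Raises
    :class:`FeatureUndefinedError` for an all-zero matrix.
    """
    P = glcm.normalized()
    levels = np.arange(glcm.levels, dtype=float)
    p_mar = P.sum(axis=1)
    q_mar = P.sum(axis=0)
    mu_p = levels @ p_mar
    mu_q = levels @ q_mar
    var_p = ((levels - mu_p) ** 2) @ p_mar
    var_q = ((levels - mu_q) ** 2) @ q_mar

    diff = levels[:, None] - levels[None, :]
    contrast = float((diff**2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(diff))).sum())
    if var_p <= 0 or var_q <= 0:
        correlation = 0.0
    else:
        cov = float(((levels[:, None] - mu_p) * (levels[None, :] - mu_q) * P).sum())
        correlation = cov / np.sqrt(var_p * var_q)
    return np.array([contrast, correlation, energy, homogeneity])
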
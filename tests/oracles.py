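"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal per-pixel / per-term enumeration,
deliberately sharing no code with the package.
"""

import math
from collections import Counter

import numpy as np

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def dft_frame(frame):
    """O(N^2) DFT of one frame."""
    n = len(frame)
    out = []
    for k in range(n):
        acc = 0j
        for m, x in enumerate(frame):
            acc += x * np.exp(-2j * np.pi * k * m / n)
        out.append(acc)
    return np.array(out)


def glcm_counts_brute(img, delta, theta, levels):
    """Exhaustive double-loop pair enumeration."""
    img = np.asarray(img)
    dr, dc = (delta * o for o in ANGLE_OFFSETS[theta])
    counts = np.zeros((levels, levels), dtype=int)
    rows, cols = img.shape
    for i in range(rows):
        for j in range(cols):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < rows and 0 <= j2 < cols:
                counts[img[i, j], img[i2, j2]] += 1
    return counts


def glcm_features_brute(counts):
    """Literal summation of the four statistics from raw counts."""
    counts = np.asarray(counts, dtype=float)
    P = counts / counts.sum()
    L = P.shape[0]
    mu_p = sum(p * P[p, q] for p in range(L) for q in range(L))
    mu_q = sum(q * P[p, q] for p in range(L) for q in range(L))
    var_p = sum((p - mu_p) ** 2 * P[p, q] for p in range(L) for q in range(L))
    var_q = sum((q - mu_q) ** 2 * P[p, q] for p in range(L) for q in range(L))
    contrast = sum((p - q) ** 2 * P[p, q] for p in range(L) for q in range(L))
    energy = sum(P[p, q] ** 2 for p in range(L) for q in range(L))
    homogeneity = sum(P[p, q] / (1 + abs(p - q)) for p in range(L) for q in range(L))
    if var_p <= 0 or var_q <= 0:
        correlation = 0.0
    else:
        cov = sum((p - mu_p) * (q - mu_q) * P[p, q] for p in range(L) for q in range(L))
        correlation = cov / math.sqrt(var_p * var_q)
    return np.array([contrast, correlation, energy, homogeneity])


def lbp_image_brute(img):
    """Per-pixel 3x3 LBP, neighbours clockwise from top-left, f(0)=1."""
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    out = np.zeros((rows - 2, cols - 2), dtype=int)
    for i in range(1, rows - 1):
        for j in range(1, cols - 1):
            code = 0
            for bit, (dr, dc) in enumerate(offsets):
                if img[i + dr, j + dc] - img[i, j] >= 0:
                    code += 2**bit
            out[i - 1, j - 1] = code
    return out


# --- TFCM ------------------------------------------------------------------

_PAIR_RANK = {
    (1, 1): 1, (1, 2): 2, (1, 3): 3, (1, 4): 4, (2, 2): 5,
    (2, 3): 6, (2, 4): 7, (3, 3): 8, (3, 4): 9, (4, 4): 10,
}


def _quant(d, tol):
    if d > tol:
        return 1
    if d < -tol:
        return -1
    return 0


def _variation_class(v):
    a, b = v
    if a == 0 and b == 0:
        return 1
    if (a == 0) != (b == 0):
        return 2
    return 3 if a * b < 0 else 4


def tfcm_codes_brute(img, tol):
    """Straight-line re-implementation of the TFN encoding."""
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    out = np.zeros((rows - 2, cols - 2), dtype=int)
    for i in range(1, rows - 1):
        for j in range(1, cols - 1):
            c = img[i, j]
            h = (_quant(img[i, j - 1] - c, tol), _quant(img[i, j + 1] - c, tol))
            v = (_quant(img[i - 1, j] - c, tol), _quant(img[i + 1, j] - c, tol))
            d1 = (_quant(img[i - 1, j - 1] - c, tol), _quant(img[i + 1, j + 1] - c, tol))
            d2 = (_quant(img[i - 1, j + 1] - c, tol), _quant(img[i + 1, j - 1] - c, tol))
            a1 = _PAIR_RANK[tuple(sorted((_variation_class(h), _variation_class(v))))]
            a2 = _PAIR_RANK[tuple(sorted((_variation_class(d1), _variation_class(d2))))]
            out[i - 1, j - 1] = (a1 - 1) * 10 + (a2 - 1)
    return out


def tfcm_features_brute(codes):
    """Literal summation of the 12 TFN statistics."""
    codes = np.asarray(codes)
    n = codes.size
    hist = Counter(int(c) for c in codes.ravel())
    H = {t: cnt / n for t, cnt in hist.items()}
    mu = sum(t * h for t, h in H.items())
    f1 = sum(h * abs(t - mu) for t, h in H.items())
    f2 = sum(h * (t - mu) ** 2 for t, h in H.items())
    f3 = -sum(h * math.log2(h) for h in H.values() if h > 0)
    f4 = sum(h**2 for h in H.values())

    rows, cols = codes.shape
    P_dirs = []
    for theta in (0, 45, 90, 135):
        dr, dc = ANGLE_OFFSETS[theta]
        pairs = Counter()
        for i in range(rows):
            for j in range(cols):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < rows and 0 <= j2 < cols:
                    pairs[(int(codes[i, j]), int(codes[i2, j2]))] += 1
        total = sum(pairs.values())
        P_dirs.append({k: v / total for k, v in pairs.items()})

    pbar = Counter()
    for P in P_dirs:
        for k, v in P.items():
            pbar[k] += v / 4
    f5 = sum(abs(t1 - t2) * p for (t1, t2), p in pbar.items())
    f6 = sum(p / (1 + abs(t1 - t2)) for (t1, t2), p in pbar.items())
    f7 = sum((t1 - t2) ** 2 * p for (t1, t2), p in pbar.items())
    f8 = sum(p / (1 + (t1 - t2) ** 2) for (t1, t2), p in pbar.items())
    energies = [sum(v**2 for v in P.values()) for P in P_dirs]
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, *energies])


def chi2_kernel_brute(x, y):
    """Additive chi-squared kernel, term by term."""
    acc = 0.0
    for a, b in zip(x, y):
        if a + b > 0:
            acc += 2 * a * b / (a + b)
    return acc
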
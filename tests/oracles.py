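"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths (box filters, FFT
transfer functions): window statistics come from explicit slicing, the
guided-filter fit from solving each window's 2x2 normal equations, and
convolution from a direct sliding-window sum.
"""

import numpy as np


def guided_filter_bruteforce(g: np.ndarray, p: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Per-window regularized least squares + averaging of overlapping estimates.

    Every (2r+1)^2 window (replicate padded, full count) solves
    ``min_{a,b} sum (a g_i + b - p_i)^2 + eps * |w| * a^2`` via its normal
    equations; a zero-variance window with eps = 0 takes a = 0, b = mean(p).
    The output pixel averages a and b over every window covering it.
    """
    g = np.asarray(g, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    h, w = g.shape
    gp = np.pad(g, r, mode="edge")
    pp = np.pad(p, r, mode="edge")
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    n = (2 * r + 1) ** 2
    for i in range(h):
        for j in range(w):
            wg = gp[i : i + 2 * r + 1, j : j + 2 * r + 1].ravel()
            wp = pp[i : i + 2 * r + 1, j : j + 2 * r + 1].ravel()
            var = np.mean(wg * wg) - np.mean(wg) ** 2
            if eps == 0.0 and var <= 1e-12:
                a[i, j] = 0.0
                b[i, j] = wp.mean()
                continue
            lhs = np.array(
                [[np.sum(wg * wg) + eps * n, wg.sum()], [wg.sum(), float(n)]]
            )
            rhs = np.array([np.sum(wg * wp), wp.sum()])
            a[i, j], b[i, j] = np.linalg.solve(lhs, rhs)
    ap = np.pad(a, r, mode="edge")
    bp = np.pad(b, r, mode="edge")
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            abar = ap[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
            bbar = bp[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
            out[i, j] = abar * g[i, j] + bbar
    return out


def convolve_bruteforce(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct sliding-window 2-D convolution under replicate padding."""
    image = np.asarray(image, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)[::-1, ::-1]  # convolution flips
    r = k.shape[0] // 2
    padded = np.pad(image, r, mode="edge")
    out = np.zeros_like(image)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(padded[i : i + k.shape[0], j : j + k.shape[1]] * k)
    return out


def box_mean_bruteforce(image: np.ndarray, r: int) -> np.ndarray:
    """Replicate-padded full-count box mean via explicit slicing."""
    padded = np.pad(np.asarray(image, dtype=np.float64), r, mode="edge")
    out = np.zeros_like(np.asarray(image, dtype=np.float64))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = padded[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
    return out
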
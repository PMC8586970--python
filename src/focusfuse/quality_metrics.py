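"""Objective quality metrics for image fusion.

Full-reference fusion metrics compare the fused image F against a pair of
source images (A, B):

* ``qmi`` — normalized mutual information,
  ``2 [MI(A,F)/(H(A)+H(F)) + MI(B,F)/(H(B)+H(F))]``; 2 when F carries all
  the information of both sources, ~0 when it is independent of them.
* ``qncie`` — nonlinear correlation information entropy, built from the
  eigenvalues of the 3x3 nonlinear-correlation matrix of (A, B, F); 1 for
  perfectly dependent triples, ``1 + log_256(1/3) ~= 0.8019`` for mutually
  independent ones.
* ``qg`` — the Xydeas-Petrovic gradient-preservation metric (edge strength
  and orientation preservation weighted by source edge strength); in [0, 1].

Reference-based metrics (``psnr``, ``ssim``) need a ground-truth image and
are reported only in the full-reference condition.  ``mscn`` and ``fit_ggd``
are the natural-scene-statistics building blocks used by no-reference
quality models: locally mean-subtracted, contrast-normalized coefficients
and a moment-matching generalized-Gaussian fit of their distribution.

Undefined cases (zero entropy, zero MSE, zero gradients) surface as flagged
sentinels (NaN / inf plus a warning), never silent exceptions, so batch
evaluation over stacks keeps running.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from scipy.special import gammaln

from .errors import DimensionMismatchError, InputError

__all__ = [
    "MetricReport",
    "qmi",
    "qncie",
    "qg",
    "psnr",
    "ssim",
    "mscn",
    "fit_ggd",
    "evaluate",
]

# Xydeas-Petrovic preservation-model constants (edge strength / orientation).
QG_CONSTANTS = {
    "gamma_g": 0.9994,
    "kappa_g": -15.0,
    "sigma_g": 0.5,
    "gamma_alpha": 0.9879,
    "kappa_alpha": -22.0,
    "sigma_alpha": 0.8,
    "normalized": True,  # sigmoids rescaled so perfect preservation scores 1
}


@dataclass
class MetricReport:
    """Per-pair and aggregate metric values plus every constant used."""

    per_pair: list = field(default_factory=list)  # [((i, j), {name: value}), ...]
    aggregate: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def _check_shapes(*images: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(im, dtype=np.float64) for im in images]
    for arr in arrs[1:]:
        if arr.shape != arrs[0].shape:
            raise DimensionMismatchError(
                f"image shapes differ: {arr.shape} vs {arrs[0].shape}"
            )
    return arrs


# --- information-theoretic metrics ------------------------------------------


def _digitize01(arr: np.ndarray, bins: int) -> np.ndarray:
    idx = np.floor(np.clip(arr, 0.0, 1.0) * bins).astype(np.intp)
    return np.minimum(idx, bins - 1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _joint_hist(a: np.ndarray, b: np.ndarray, bins: int) -> np.ndarray:
    flat = _digitize01(a, bins).ravel() * bins + _digitize01(b, bins).ravel()
    return np.bincount(flat, minlength=bins * bins).reshape(bins, bins) / flat.size


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> tuple[float, float, float]:
    joint = _joint_hist(a, b, bins)
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    return ha + hb - _entropy(joint.ravel()), ha, hb


def qmi(a: np.ndarray, b: np.ndarray, f: np.ndarray, bins: int = 256) -> float:
    """Normalized mutual-information fusion metric, in [0, 2].

    Entropies and mutual informations come from equal-width joint histograms
    over [0, 1]; the log base cancels in the ratios.  A constant input has
    zero entropy, which makes the ratio undefined — flagged as NaN.
    """
    if bins < 2:
        raise InputError("bins must be >= 2")
    a, b, f = _check_shapes(a, b, f)
    mi_af, ha, hf = _mutual_information(a, f, bins)
    mi_bf, hb, _ = _mutual_information(b, f, bins)
    if ha == 0.0 or hb == 0.0 or hf == 0.0:
        warnings.warn("qmi undefined: constant input (zero entropy)", stacklevel=2)
        return float("nan")
    return 2.0 * (mi_af / (ha + hf) + mi_bf / (hb + hf))


def _rank_codes(arr: np.ndarray, bins: int) -> np.ndarray:
    """Equal-count (rank-uniform) bin codes: each of ``bins`` bins holds ~K/bins pixels."""
    flat = arr.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(flat.size, dtype=np.intp)
    ranks[order] = np.arange(flat.size)
    return ranks * bins // flat.size


def nonlinear_correlation(a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    """Nonlinear correlation coefficient ``2 + sum p_ij log_b p_ij``.

    Computed on the joint histogram of equal-count ``bins``-level codes, so
    the marginals are uniform by construction: identical inputs score exactly
    1, independent inputs approach 0.
    """
    ca = _rank_codes(np.asarray(a, dtype=np.float64), bins)
    cb = _rank_codes(np.asarray(b, dtype=np.float64), bins)
    joint = np.bincount(ca * bins + cb, minlength=bins * bins) / ca.size
    # 2 + sum p log_b p  ==  2 - H(joint) in base-b units
    return 2.0 - _entropy(joint) / np.log(bins)


def qncie(a: np.ndarray, b: np.ndarray, f: np.ndarray, bins: int = 256) -> float:
    """Nonlinear correlation information entropy of the triple (A, B, F).

    Builds the 3x3 matrix R with unit diagonal and pairwise nonlinear
    correlation coefficients off-diagonal, then returns
    ``1 + sum_i (lam_i / 3) log_256 (lam_i / 3)`` over its eigenvalues.
    """
    a, b, f = _check_shapes(a, b, f)
    for name, im in (("a", a), ("b", b), ("f", f)):
        if np.ptp(im) == 0.0:
            warnings.warn(f"qncie undefined: constant input {name!r}", stacklevel=2)
            return float("nan")
    images = [a, b, f]
    r = np.eye(3)
    for i, j in combinations(range(3), 2):
        r[i, j] = r[j, i] = nonlinear_correlation(images[i], images[j], bins)
    lam = np.clip(np.linalg.eigvalsh(r), 0.0, None) / 3.0
    nz = lam[lam > 0]
    return float(1.0 + (nz * np.log(nz)).sum() / np.log(bins))


# --- gradient preservation ---------------------------------------------------


def _sobel_polar(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = ndi.sobel(image, axis=1, mode="nearest")
    sy = ndi.sobel(image, axis=0, mode="nearest")
    g = np.hypot(sx, sy)
    alpha = np.arctan2(sy, sx)
    # fold orientation into (-pi/2, pi/2] (edge orientation has no sign)
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _preservation(g_x: np.ndarray, a_x: np.ndarray, g_f: np.ndarray, a_f: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            g_x > g_f,
            np.divide(g_f, g_x, out=np.zeros_like(g_f), where=g_x > 0),
            np.divide(g_x, g_f, out=np.zeros_like(g_x), where=g_f > 0),
        )
    both_zero = (g_x == 0) & (g_f == 0)
    ratio = np.where(both_zero, 0.0, ratio)
    angle = 1.0 - np.abs(a_x - a_f) / (np.pi / 2.0)
    angle = np.where(both_zero, 0.0, angle)

    c = QG_CONSTANTS

    def sigmoid(v, gamma, kappa, sigma):
        q = gamma / (1.0 + np.exp(kappa * (v - sigma)))
        # normalize so perfect preservation (v = 1) scores exactly 1
        return q / (gamma / (1.0 + np.exp(kappa * (1.0 - sigma))))

    qg_ = sigmoid(ratio, c["gamma_g"], c["kappa_g"], c["sigma_g"])
    qa_ = sigmoid(angle, c["gamma_alpha"], c["kappa_alpha"], c["sigma_alpha"])
    return qg_ * qa_


def qg(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Xydeas-Petrovic gradient-preservation metric ``Q^{AB/F}`` in [0, 1].

    Sobel gradient magnitude/orientation per image; per-pixel edge-strength
    and orientation preservation through the (normalized) sigmoid model;
    source edge strengths as weights.  Symmetric in A and B.
    """
    a, b, f = _check_shapes(a, b, f)
    g_f, al_f = _sobel_polar(f)
    total_w = 0.0
    total_q = 0.0
    for src in (a, b):
        g_s, al_s = _sobel_polar(src)
        q = _preservation(g_s, al_s, g_f, al_f)
        total_q += float((q * g_s).sum())
        total_w += float(g_s.sum())
    if total_w == 0.0:
        warnings.warn("qg undefined: both sources have zero gradient", stacklevel=2)
        return float("nan")
    return total_q / total_w


# --- reference metrics -------------------------------------------------------


def psnr(reference: np.ndarray, test: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf (flagged) when MSE is zero."""
    reference, test = _check_shapes(reference, test)
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        warnings.warn("psnr undefined: zero MSE (identical images)", stacklevel=2)
        return float("inf")
    return 10.0 * np.log10(max_value**2 / mse)


def _gaussian_blur(arr: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    k /= k.sum()
    out = ndi.correlate1d(arr, k, axis=0, mode="nearest")
    return ndi.correlate1d(out, k, axis=1, mode="nearest")


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window_size: int = 11,
    sigma: float = 1.5,
    c1: float | None = None,
    c2: float | None = None,
    L: float = 1.0,
    return_map: bool = False,
):
    """Structural similarity index under a Gaussian window.

    Local means, variances and covariance are taken under an
    ``window_size x window_size`` Gaussian window (sigma 1.5); stabilizers
    default to ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2`` with ``L = 1`` for
    normalized intensities.  Returns the mean of the per-pixel map (and the
    map itself with ``return_map``).
    """
    a, b = _check_shapes(a, b)
    if window_size % 2 == 0 or window_size < 3:
        raise InputError("window_size must be odd and >= 3")
    if c1 is None:
        c1 = (0.01 * L) ** 2
    if c2 is None:
        c2 = (0.03 * L) ** 2
    radius = window_size // 2
    mu_a = _gaussian_blur(a, sigma, radius)
    mu_b = _gaussian_blur(b, sigma, radius)
    var_a = _gaussian_blur(a * a, sigma, radius) - mu_a**2
    var_b = _gaussian_blur(b * b, sigma, radius) - mu_b**2
    cov = _gaussian_blur(a * b, sigma, radius) - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    smap = num / den
    value = float(smap.mean())
    if return_map:
        return value, smap
    return value


# --- natural-scene-statistics building blocks --------------------------------


def mscn(
    image: np.ndarray,
    window_size: int = 7,
    sigma: float = 7.0 / 6.0,
    c: float = 1.0 / 255.0,
) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients ``(I - mu) / (sd + c)``.

    Local mean and standard deviation are Gaussian-weighted (7x7, sigma 7/6);
    ``c`` keeps the division stable in flat regions.
    """
    arr = np.asarray(image, dtype=np.float64)
    radius = window_size // 2
    mu = _gaussian_blur(arr, sigma, radius)
    var = np.clip(_gaussian_blur(arr * arr, sigma, radius) - mu**2, 0.0, None)
    return (arr - mu) / (np.sqrt(var) + c)


def _ggd_ratio(nu: np.ndarray) -> np.ndarray:
    # E[x^2] / E[|x|]^2 = Gamma(1/nu) Gamma(3/nu) / Gamma(2/nu)^2
    return np.exp(gammaln(1.0 / nu) + gammaln(3.0 / nu) - 2.0 * gammaln(2.0 / nu))


def fit_ggd(samples: np.ndarray, grid: tuple[float, float, int] = (0.2, 10.0, 4000)) -> tuple[float, float]:
    """Moment-matching generalized-Gaussian fit; returns (shape, scale).

    The shape ``nu`` solves ``E[x^2]/E[|x|]^2 = Gamma(1/nu) Gamma(3/nu) /
    Gamma(2/nu)^2`` by inversion on a log-spaced lookup grid; ``nu = 2``
    recovers the normal distribution, ``nu = 1`` the Laplace.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 100:
        raise InputError(f"need >= 100 samples, got {x.size}")
    m_abs = float(np.mean(np.abs(x)))
    m_sq = float(np.mean(x**2))
    if m_sq == 0.0 or np.ptp(x) == 0.0:
        raise InputError("zero-variance samples: GGD fit undefined")
    rho = m_sq / (m_abs**2)
    nus = np.geomspace(grid[0], grid[1], grid[2])
    ratios = _ggd_ratio(nus)  # decreasing in nu
    nu = float(np.interp(rho, ratios[::-1], nus[::-1]))
    scale = float(np.sqrt(m_sq * np.exp(gammaln(1.0 / nu) - gammaln(3.0 / nu))))
    return nu, scale


# --- aggregation -------------------------------------------------------------


def evaluate(
    fused: np.ndarray,
    sources,
    reference: np.ndarray | None = None,
    bins: int = 256,
    max_value: float = 1.0,
) -> MetricReport:
    """Fusion-quality report over every unordered source pair.

    QMI/QNCIE/QG are computed per pair of source frames against the fused
    image and averaged; PSNR/SSIM are added when a ground-truth reference is
    available (the full-reference condition).
    """
    frames = getattr(sources, "frames", None)
    if frames is None:
        frames = np.asarray(sources, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise InputError("need at least 2 source frames")
    fused = np.asarray(fused, dtype=np.float64)
    report = MetricReport(
        params={
            "bins": bins,
            "ssim_window": 11,
            "ssim_sigma": 1.5,
            "C1": (0.01 * max_value) ** 2,
            "C2": (0.03 * max_value) ** 2,
            "mscn_window": 7,
            "mscn_sigma": 7.0 / 6.0,
            "mscn_c": 1.0 / 255.0,
            "max_value": max_value,
            **{f"qg_{k}": v for k, v in QG_CONSTANTS.items()},
        }
    )
    accum: dict[str, list[float]] = {"qmi": [], "qncie": [], "qg": []}
    for i, j in combinations(range(frames.shape[0]), 2):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            values = {
                "qmi": qmi(frames[i], frames[j], fused, bins=bins),
                "qncie": qncie(frames[i], frames[j], fused, bins=bins),
                "qg": qg(frames[i], frames[j], fused),
            }
        for w in caught:
            report.flags.setdefault(f"pair_{i}_{j}", []).append(str(w.message))
        report.per_pair.append(((i, j), values))
        for name, val in values.items():
            accum[name].append(val)
    report.aggregate = {name: float(np.mean(vals)) for name, vals in accum.items()}
    report.metrics = dict(report.aggregate)
    if reference is not None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report.metrics["psnr"] = psnr(reference, fused, max_value=max_value)
            report.metrics["ssim"] = ssim(reference, fused, L=max_value)
        for w in caught:
            report.flags.setdefault("reference", []).append(str(w.message))
    return report
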
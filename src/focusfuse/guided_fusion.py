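"""Guided-filter weighting and pixel-wise weighted-average fusion.

The dilated focus masks are hard-edged; fusing with them directly leaves
visible seams.  Each mask is therefore softened with a guided filter whose
guidance is the mask itself and whose input is the masked source frame: the
filtered map stays ~1 deep inside the focus area, decays smoothly across the
boundary, and is ~0 far outside.  Those per-frame maps are used as weights in
a per-pixel weighted average, which preserves the intensity range (the fused
pixel is a convex combination of the source pixels).

The guided-filter window radius follows the arithmetic schedule
``r_n = 1 + (n - 1) * s`` (s = 2 by default), capped at one quarter of the
image size.  In ``auto`` mode the first radius whose weights cover nearly the
whole image is selected — a too-small window leaves gaps between fused areas,
a too-large one blends in out-of-focus content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigError, DimensionMismatchError, InputError
from .focus_detect import FocusMask, detect_focus

if TYPE_CHECKING:  # pragma: no cover
    from .stack_io import FusionConfig, ImageStack

__all__ = [
    "GuidedFilterParams",
    "WeightStack",
    "FusionResult",
    "guided_filter",
    "window_schedule",
    "max_window",
    "select_window",
    "compute_weights",
    "fuse",
    "fuse_stack",
]

_VAR_FLOOR = 1e-12  # zero-variance detection when eps == 0


@dataclass(frozen=True)
class GuidedFilterParams:
    """Parameters of the self-adjusting guided filter.

    ``window`` is either a fixed radius (half-width; the window is
    ``(2r+1) x (2r+1)``) or ``"auto"``, in which case the schedule
    ``r_n = 1 + (n-1) * scale_factor`` is walked until the weight maps cover
    a ``coverage_frac`` fraction of pixels above ``coverage_tau``, capped at
    ``min(H, W) // 4``.
    """

    eps: float = 1e-3
    window: int | str = "auto"
    scale_factor: int = 2
    coverage_tau: float = 1e-3
    coverage_frac: float = 0.999
    guidance_mode: str = "mask"  # "mask" (default) | "image"

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ConfigError("eps must be >= 0")
        if self.scale_factor < 1:
            raise ConfigError("scale_factor must be >= 1")
        if isinstance(self.window, str):
            if self.window != "auto":
                raise ConfigError(f"window must be 'auto' or an integer radius")
        elif self.window < 1:
            raise ConfigError("fixed window radius must be >= 1")
        if self.guidance_mode not in ("mask", "image"):
            raise ConfigError(f"unknown guidance_mode {self.guidance_mode!r}")


@dataclass
class WeightStack:
    """Per-frame continuous weight maps produced by the guided filter."""

    weights: np.ndarray  # (N, H, W), >= 0
    normalized: bool = False
    chosen_window: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise InputError("weights must be (N, H, W)")

    def normalize(self) -> "WeightStack":
        """Per-pixel sum-normalized view (sum over frames = 1 where any weight > 0)."""
        total = self.weights.sum(axis=0)
        safe = np.where(total > 0, total, 1.0)
        return WeightStack(
            self.weights / safe, normalized=True, chosen_window=self.chosen_window
        )


@dataclass
class FusionResult:
    """Fused all-in-focus image plus per-pixel provenance."""

    fused: np.ndarray
    weight_stack: WeightStack
    index_map: np.ndarray  # per-pixel argmax frame (ties -> lower index)
    fallback_mask: np.ndarray  # pixels where no frame had weight > 0


def _box(arr: np.ndarray, radius: int) -> np.ndarray:
    # replicate-padded box mean => every pixel averages a full (2r+1)^2 window
    return ndi.uniform_filter(arr, size=2 * radius + 1, mode="nearest")


def guided_filter(
    guidance: np.ndarray, input: np.ndarray, r: int, eps: float
) -> np.ndarray:
    """Classic two-coefficient guided filter.

    In every ``(2r+1) x (2r+1)`` window the input is regressed on the
    guidance, ``a = cov(G, p) / (var(G) + eps)``, ``b = mean(p) - a mean(G)``,
    and the output averages the overlapping per-window estimates
    ``a G + b``.  With ``eps = 0`` a zero-variance window takes ``a = 0``
    (limit convention), i.e. falls back to the window mean.
    """
    g = np.asarray(guidance, dtype=np.float64)
    p = np.asarray(input, dtype=np.float64)
    if g.shape != p.shape:
        raise DimensionMismatchError(
            f"guidance shape {g.shape} != input shape {p.shape}"
        )
    if r < 1:
        raise ConfigError("window radius must be >= 1")
    if eps < 0:
        raise ConfigError("eps must be >= 0")
    mean_g = _box(g, r)
    mean_p = _box(p, r)
    cov_gp = _box(g * p, r) - mean_g * mean_p
    var_g = _box(g * g, r) - mean_g * mean_g
    if eps == 0.0:
        nonzero = var_g > _VAR_FLOOR
        a = np.where(nonzero, cov_gp / np.where(nonzero, var_g, 1.0), 0.0)
    else:
        a = cov_gp / (var_g + eps)
    b = mean_p - a * mean_g
    return _box(a, r) * g + _box(b, r)


def window_schedule(n: int, s: int) -> int:
    """n-th window radius of the arithmetic schedule ``1 + (n - 1) * s``."""
    if n < 1:
        raise ConfigError(f"schedule index must be >= 1, got {n}")
    if s < 1:
        raise ConfigError(f"scale factor must be >= 1, got {s}")
    return 1 + (n - 1) * s

def max_window(shape: Sequence[int]) -> int:
    """Radius cap: one quarter of the image size (smaller spatial dimension)."""
    return max(1, min(shape[0], shape[1]) // 4)


def _weights_at(
    frames: np.ndarray, masks: Sequence[FocusMask], r: int, params: GuidedFilterParams
) -> np.ndarray:
    out = np.empty_like(frames)
    for n, mask in enumerate(masks):
        m = mask.mask.astype(np.float64)
        guidance = frames[n] if params.guidance_mode == "image" else m
        out[n] = np.maximum(guided_filter(guidance, frames[n] * m, r, params.eps), 0.0)
    return out


def select_window(
    stack: "ImageStack", masks: Sequence[FocusMask], params: GuidedFilterParams
) -> int:
    """Walk the window schedule and return the first radius with full coverage.

    Coverage at radius r = fraction of pixels whose max-over-frames weight
    exceeds ``coverage_tau``; the first r reaching ``coverage_frac`` wins,
    else the cap ``min(H, W) // 4``.  Deterministic.
    """
    frames = stack.frames
    cap = max_window(stack.shape)
    n = 1
    while True:
        r = window_schedule(n, params.scale_factor)
        if r >= cap:
            return cap
        weights = _weights_at(frames, masks, r, params)
        covered = float((weights.max(axis=0) > params.coverage_tau).mean())
        if covered >= params.coverage_frac:
            return r
        n += 1


def compute_weights(
    stack: "ImageStack",
    masks: Sequence[FocusMask],
    params: GuidedFilterParams,
    r: int | None = None,
) -> WeightStack:
    """Guided-filter each masked frame into a continuous weight map.

    For frame n the filter input is ``I_n * mask_n`` (the masked source) and
    the guidance is the dilated mask itself; the output is clamped below at 0.
    ``r`` overrides the params' window (used after :func:`select_window`).
    """
    if len(masks) != len(stack):
        raise InputError(f"{len(masks)} masks for {len(stack)} frames")
    for mask in masks:
        if mask.mask.shape != stack.shape:
            raise DimensionMismatchError(
                f"mask shape {mask.mask.shape} != frame shape {stack.shape}"
            )
    if r is None:
        if params.window == "auto":
            r = select_window(stack, masks, params)
        else:
            r = min(int(params.window), max_window(stack.shape))
    weights = _weights_at(stack.frames, masks, r, params)
    return WeightStack(weights, normalized=False, chosen_window=r)


def fuse(stack: "ImageStack", weights: WeightStack) -> FusionResult:
    """Pixel-wise weighted-average fusion.

    Per pixel the raw weights are sum-normalized and the fused value is the
    resulting convex combination of the frame values; ``index_map`` records
    the dominant frame (stable argmax, lower index wins ties).  Pixels where
    every frame has zero weight take the unweighted mean over frames and are
    flagged in ``fallback_mask``.
    """
    frames = stack.frames
    w = weights.weights
    if w.shape != frames.shape:
        raise DimensionMismatchError(
            f"weights shape {w.shape} != stack shape {frames.shape}"
        )
    total = w.sum(axis=0)
    fallback = total <= 0.0
    safe_total = np.where(fallback, 1.0, total)
    fused = (w * frames).sum(axis=0) / safe_total
    if fallback.any():
        fused = np.where(fallback, frames.mean(axis=0), fused)
    index_map = w.argmax(axis=0)
    return FusionResult(
        fused=np.clip(fused, 0.0, 1.0),
        weight_stack=weights,
        index_map=index_map,
        fallback_mask=fallback,
    )


def fuse_stack(stack: "ImageStack", config: "FusionConfig" = None) -> FusionResult:
    """Full pipeline: focus detection per frame, weighting, weighted fusion."""
    from .stack_io import FusionConfig  # local import avoids a cycle

    if config is None:
        config = FusionConfig()
    if len(stack) < 2:
        raise InputError("fusion needs at least 2 frames")
    masks = [
        detect_focus(stack.frames[n], config, frame_index=n)
        for n in range(len(stack))
    ]
    if not any(m.mask.any() for m in masks):
        warnings.warn(
            "no focus detected in any frame; returning the mean image", stacklevel=2
        )
        zeros = WeightStack(np.zeros_like(stack.frames), chosen_window=1)
        return fuse(stack, zeros)
    weights = compute_weights(stack, masks, config.guided)
    return fuse(stack, weights)
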
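"""Focus-area detection for individual frames of a focal stack.

An in-focus region carries more mid/high spatial-frequency energy than a
defocused one, so each frame is first enhanced with a DC-free Gaussian
band-pass filter in the Fourier domain, then edge-enhanced with a zero-sum
Laplacian mask.  Two-sided thresholding of the response extracts candidate
focus pixels; small connected components are discarded and the surviving
regions are dilated, because the Laplacian marks only the center line of an
intensity transition and the true focus area extends beyond it.

The full composition is :func:`detect_focus`; every stage is public so that
intermediate results can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .errors import ConfigError, DimensionMismatchError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .stack_io import FusionConfig

__all__ = [
    "BandpassSpec",
    "FocusMask",
    "bandpass_filter",
    "laplacian_filter",
    "laplacian_kernel",
    "threshold_focus",
    "remove_small_regions",
    "dilate_mask",
    "detect_focus",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Gaussian band-pass transfer function on normalized spatial frequency.

    ``H(D) = exp(-D^2 / (2 high_cut^2)) - exp(-D^2 / (2 low_cut^2))`` on the
    centered radial frequency ``D`` in cycles/pixel (Nyquist at 0.5, corner at
    ~0.707).  The DC gain is exactly 0, so constant offsets and slow
    illumination gradients are rejected; frequencies above ``high_cut``
    (sensor noise scale) are attenuated.
    """

    low_cut: float = 0.02
    high_cut: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.low_cut < self.high_cut):
            raise ConfigError(
                f"need 0 < low_cut < high_cut, got {self.low_cut}, {self.high_cut}"
            )
        if self.high_cut > 0.7072:
            raise ConfigError("high_cut must be <= 0.7071 (frequency-plane corner)")

    def transfer(self, d: np.ndarray) -> np.ndarray:
        """Evaluate the transfer function at radial frequency ``d``."""
        d2 = np.square(np.asarray(d, dtype=np.float64))
        return np.exp(-d2 / (2.0 * self.high_cut**2)) - np.exp(
            -d2 / (2.0 * self.low_cut**2)
        )


@dataclass
class FocusMask:
    """Binary focus map for one frame, tagged with its processing stage."""

    mask: np.ndarray
    frame_index: int = 0
    stage: str = "thresholded"  # "thresholded" | "cleaned" | "dilated"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    return np.hypot(fy[:, None], fx[None, :])


def bandpass_filter(image: np.ndarray, spec: BandpassSpec | None = None) -> np.ndarray:
    """Apply the Gaussian band-pass in the Fourier domain.

    Returns the real part of the inverse DFT of ``H(u, v) * F(u, v)``; the
    response is signed and has the same shape as the input.
    """
    spec = spec or BandpassSpec()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InputError(f"expected 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError("image contains non-finite pixels")
    h = spec.transfer(_radial_frequency(arr.shape))
    return np.fft.ifft2(np.fft.fft2(arr) * h).real


def laplacian_kernel(mask_size: int) -> np.ndarray:
    """The r x r zero-sum Laplacian mask: off-center 1, center ``-(r^2 - 1)``."""
    if mask_size < 3 or mask_size % 2 == 0:
        raise ConfigError(f"mask_size must be odd and >= 3, got {mask_size}")
    kernel = np.ones((mask_size, mask_size), dtype=np.float64)
    kernel[mask_size // 2, mask_size // 2] = -(mask_size**2 - 1)
    return kernel


def laplacian_filter(image: np.ndarray, mask_size: int = 3) -> np.ndarray:
    """Convolve with the zero-sum Laplacian mask under replicate padding."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InputError(f"expected 2-D image, got shape {arr.shape}")
    return ndi.convolve(arr, laplacian_kernel(mask_size), mode="nearest")


def threshold_focus(
    response: np.ndarray,
    tau_low: float,
    tau_high: float,
    mode: str = "absolute",
    operand: str = "magnitude",
    frame_index: int = 0,
) -> FocusMask:
    """Two-sided strict threshold of the edge response.

    A pixel is marked in-focus iff ``tau_low < v < tau_high`` where ``v`` is
    the response magnitude (default) or the signed response.  In percentile
    mode the taus are percentiles (0-100) of the magnitude distribution,
    making the threshold adaptive per frame.  The upper bound suppresses
    impulsive noise spikes.
    """
    if not tau_low < tau_high:
        raise ConfigError(
            f"empty threshold interval: tau_low={tau_low} >= tau_high={tau_high}"
        )
    if operand not in ("magnitude", "signed"):
        raise ConfigError(f"unknown operand {operand!r}")
    resp = np.asarray(response, dtype=np.float64)
    values = np.abs(resp) if operand == "magnitude" else resp
    if mode == "percentile":
        if not (0 <= tau_low <= 100 and 0 <= tau_high <= 100):
            raise ConfigError("percentile taus must lie in [0, 100]")
        tau_low, tau_high = np.percentile(np.abs(resp), [tau_low, tau_high])
    elif mode != "absolute":
        raise ConfigError(f"unknown threshold mode {mode!r}")
    mask = (values > tau_low) & (values < tau_high)
    return FocusMask(mask, frame_index=frame_index, stage="thresholded")


def remove_small_regions(
    mask: FocusMask, min_region_area: int, connectivity: int = 8
) -> FocusMask:
    """Drop connected components with fewer than ``min_region_area`` pixels."""
    if connectivity not in (4, 8):
        raise ConfigError("connectivity must be 4 or 8")
    cleaned = mask.mask.copy()
    if min_region_area > 1 and cleaned.any():
        labels = measure.label(cleaned, connectivity=1 if connectivity == 4 else 2)
        counts = np.bincount(labels.ravel())
        small = counts < min_region_area
        small[0] = False
        cleaned[small[labels]] = False
    return FocusMask(cleaned, frame_index=mask.frame_index, stage="cleaned")


def dilate_mask(mask: FocusMask, radius: int, shape: str = "disk") -> FocusMask:
    """Binary dilation with a disk or square structuring element; radius 0 is identity."""
    if radius < 0:
        raise ConfigError("dilation radius must be >= 0")
    if radius == 0:
        out = mask.mask.copy()
    else:
        if shape == "disk":
            footprint = morphology.disk(radius)
        elif shape == "square":
            footprint = morphology.footprint_rectangle((2 * radius + 1,) * 2)
        else:
            raise ConfigError(f"unknown structuring element shape {shape!r}")
        out = morphology.dilation(mask.mask, footprint)
    return FocusMask(out, frame_index=mask.frame_index, stage="dilated")


def detect_focus(
    image: np.ndarray,
    config: "FusionConfig",
    frame_index: int = 0,
    return_stages: bool = False,
):
    """Full focus-detection chain for one frame.

    band-pass -> Laplacian -> two-sided threshold -> small-region removal ->
    dilation.  With ``return_stages`` the intermediate responses and masks are
    returned as a dict for debugging/visualization.
    """
    arr = np.asarray(image, dtype=np.float64)
    bp = bandpass_filter(arr, config.bandpass)
    lap = laplacian_filter(bp, config.laplacian_mask_size)
    th = threshold_focus(
        lap,
        config.tau_low,
        config.tau_high,
        mode=config.threshold_mode,
        operand=config.threshold_operand,
        frame_index=frame_index,
    )
    cleaned = remove_small_regions(
        th, config.resolved_min_area(arr.shape), connectivity=config.connectivity
    )
    dilated = dilate_mask(
        cleaned, config.resolved_dilation_radius(), shape=config.dilation_shape
    )
    if return_stages:
        return dilated, {
            "bandpass": bp,
            "laplacian": lap,
            "thresholded": th,
            "cleaned": cleaned,
            "dilated": dilated,
        }
    return dilated
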
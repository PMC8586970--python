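"""Reading, writing and configuration for focal stacks.

A focal stack (z-stack) is an ordered set of co-registered grayscale frames,
each focused at a different axial depth.  On ingest every frame is normalized
to ``[0, 1]``: integer samples are divided by their type maximum (so an 8-bit
255 becomes 1.0 and a 16-bit 65535 becomes 1.0), float samples are clipped.
This makes every downstream threshold independent of the source bit depth.

Frame order is a pure function of the inputs and the order policy —
lexicographic filename sort by default, page order for multipage TIFF —
never of filesystem enumeration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigError, DimensionMismatchError, EmptyStackError, InputError
from .focus_detect import BandpassSpec
from .guided_fusion import GuidedFilterParams

__all__ = [
    "ImageStack",
    "FusionConfig",
    "read_stack",
    "write_result",
    "load_config",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class ImageStack:
    """Ordered set of N co-registered grayscale frames, intensities in [0, 1].

    Parameters
    ----------
    frames
        ``(N, H, W)`` float64 array.
    source_ids
        Per-frame label (filename, or ``"page:k"`` for multipage TIFF).
    bit_depth_in
        Sample depth of the original data, kept for round-trip writing.
    """

    frames: np.ndarray
    source_ids: list[str] = field(default_factory=list)
    bit_depth_in: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InputError(
                f"stack must be (N, H, W) with N >= 1, got shape {self.frames.shape}"
            )
        if not self.source_ids:
            self.source_ids = [f"frame:{i}" for i in range(len(self))]
        if len(self.source_ids) != len(self):
            raise InputError("source_ids length must match frame count")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0.0 or hi > 1.0:
            raise InputError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) of every frame."""
        return self.frames.shape[1:]


@dataclass
class FusionConfig:
    """All tunable parameters of the fusion pipeline.

    Defaults follow the package's calibrated operating point: a DC-free
    Gaussian band-pass (0.02–0.25 cycles/pixel), a 3x3 zero-sum Laplacian,
    per-frame percentile thresholds on the response magnitude, removal of
    components below 0.05% of the frame area, and a disk dilation whose
    radius equals the Laplacian mask size.
    """

    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    laplacian_mask_size: int = 3
    threshold_mode: str = "percentile"  # "percentile" | "absolute"
    threshold_operand: str = "magnitude"  # "magnitude" | "signed"
    tau_low: float = 70.0
    tau_high: float = 99.9
    min_region_area: float | None = None  # None -> 0.0005 * H * W at run time
    connectivity: int = 8
    dilation_radius: int | None = None  # None -> laplacian_mask_size
    dilation_shape: str = "disk"  # "disk" | "square"
    guided: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.laplacian_mask_size < 3 or self.laplacian_mask_size % 2 == 0:
            raise ConfigError(
                f"laplacian_mask_size must be odd and >= 3, got {self.laplacian_mask_size}"
            )
        if not self.tau_low < self.tau_high:
            raise ConfigError(
                f"tau_low must be < tau_high, got {self.tau_low} >= {self.tau_high}"
            )
        if self.min_region_area is not None and self.min_region_area < 0:
            raise ConfigError("min_region_area must be >= 0")
        if self.dilation_radius is not None and self.dilation_radius < 0:
            raise ConfigError("dilation_radius must be >= 0")
        if self.threshold_mode not in ("percentile", "absolute"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_operand not in ("magnitude", "signed"):
            raise ConfigError(f"unknown threshold_operand {self.threshold_operand!r}")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.dilation_shape not in ("disk", "square"):
            raise ConfigError(f"unknown dilation_shape {self.dilation_shape!r}")

    def resolved_min_area(self, shape: tuple[int, int]) -> int:
        if self.min_region_area is not None:
            return int(self.min_region_area)
        return int(round(5e-4 * shape[0] * shape[1]))

    def resolved_dilation_radius(self) -> int:
        if self.dilation_radius is not None:
            return int(self.dilation_radius)
        return int(self.laplacian_mask_size)


# --- ingest -----------------------------------------------------------------


def _normalize(frame: np.ndarray, source: str) -> tuple[np.ndarray, int]:
    """Normalize one decoded frame to float64 in [0, 1]; return (frame, bit depth)."""
    arr = np.asarray(frame)
    if arr.ndim == 3:
        if arr.shape[-1] not in (3, 4):
            raise InputError(f"{source}: unsupported sample layout {arr.shape}")
        warnings.warn(
            f"{source}: color input converted to luma grayscale", stacklevel=3
        )
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.2125, 0.7154, 0.0721])
        if np.issubdtype(frame.dtype, np.integer):
            arr = arr / np.iinfo(frame.dtype).max
        return np.clip(arr, 0.0, 1.0), _bit_depth(frame.dtype)
    if arr.ndim != 2:
        raise InputError(f"{source}: expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        out = arr.astype(np.float64) / info.max
        return np.clip(out, 0.0, 1.0), _bit_depth(arr.dtype)
    if arr.dtype == bool:
        return arr.astype(np.float64), 1
    out = arr.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise InputError(f"{source}: non-finite pixel values")
    return np.clip(out, 0.0, 1.0), 32


def _bit_depth(dtype: np.dtype) -> int:
    if np.issubdtype(dtype, np.integer):
        return np.iinfo(dtype).bits
    return 32


def _decode(path: Path) -> list[np.ndarray]:
    """Decode a file into one or more raw frames (multipage TIFF -> pages)."""
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(str(path)) as tf:
            return [page.asarray() for page in tf.pages]
    import imageio.v3 as iio

    return [iio.imread(str(path))]


def read_stack(
    paths: str | Path | Sequence[str | Path],
    order_policy: str = "lexicographic",
) -> ImageStack:
    """Read a focal stack from a multipage TIFF or an ordered set of files.

    Parameters
    ----------
    paths
        One file (possibly multipage TIFF) or a sequence of single-frame files.
    order_policy
        ``lexicographic`` sorts file names; ``explicit`` keeps the given
        order; ``page_order`` (single multipage file) keeps page order.
    """
    if isinstance(paths, (str, Path)):
        path_list = [Path(paths)]
    else:
        path_list = [Path(p) for p in paths]
    if not path_list:
        raise EmptyStackError("no input files given")
    if order_policy == "lexicographic":
        path_list = sorted(path_list, key=lambda p: p.name)
    elif order_policy not in ("explicit", "page_order"):
        raise ConfigError(f"unknown order policy {order_policy!r}")

    frames: list[np.ndarray] = []
    ids: list[str] = []
    depth = 8
    for path in path_list:
        if not path.exists():
            raise InputError(f"input file not found: {path}")
        raw = _decode(path)
        for k, page in enumerate(raw):
            norm, depth = _normalize(page, str(path))
            label = f"{path.name}:page{k}" if len(raw) > 1 else path.name
            if frames and norm.shape != frames[0].shape:
                raise DimensionMismatchError(
                    f"{label}: frame shape {norm.shape} differs from "
                    f"{ids[0]} shape {frames[0].shape}"
                )
            frames.append(norm)
            ids.append(label)
    if not frames:
        raise EmptyStackError("zero readable frames")
    return ImageStack(np.stack(frames), source_ids=ids, bit_depth_in=depth)


# --- output -----------------------------------------------------------------


def _quantize(image: np.ndarray, bit_depth: int) -> np.ndarray:
    """Quantize [0,1] floats to unsigned integers, rounding half up."""
    if bit_depth == 8:
        dtype, peak = np.uint8, 255
    elif bit_depth == 16:
        dtype, peak = np.uint16, 65535
    else:
        raise ConfigError(f"bit_depth must be 8 or 16, got {bit_depth}")
    return np.floor(np.clip(image, 0.0, 1.0) * peak + 0.5).astype(dtype)


def write_result(
    result,
    path: str | Path,
    bit_depth: int = 16,
    save_weights: str | Path | None = None,
    save_index_map: str | Path | None = None,
) -> None:
    """Write a fused image (TIFF or PNG by extension) plus optional sidecars.

    Sidecars: per-frame weight maps as a multipage 32-bit float TIFF, and the
    dominant-frame index map as a 16-bit single-page TIFF.
    """
    path = Path(path)
    fused = np.asarray(result.fused, dtype=np.float64)
    if fused.min() < 0 or fused.max() > 1:
        raise InputError("fused image values must lie in [0, 1]")
    sample = _quantize(fused, bit_depth)
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            tifffile.imwrite(str(path), sample)
        else:
            import imageio.v3 as iio

            iio.imwrite(str(path), sample)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise InputError(f"cannot write {path}: {exc}") from exc
    if save_weights is not None:
        tifffile.imwrite(
            str(save_weights), result.weight_stack.weights.astype(np.float32)
        )
    if save_index_map is not None:
        tifffile.imwrite(str(save_index_map), result.index_map.astype(np.uint16))


# --- configuration ----------------------------------------------------------

_CONFIG_KEYS = {
    "bandpass.low_cut": ("bandpass", "low_cut", float),
    "bandpass.high_cut": ("bandpass", "high_cut", float),
    "laplacian.mask_size": (None, "laplacian_mask_size", int),
    "threshold.mode": (None, "threshold_mode", str),
    "threshold.operand": (None, "threshold_operand", str),
    "threshold.tau_low": (None, "tau_low", float),
    "threshold.tau_high": (None, "tau_high", float),
    "clean.min_area": (None, "min_region_area", float),
    "clean.connectivity": (None, "connectivity", int),
    "dilate.radius": (None, "dilation_radius", int),
    "dilate.shape": (None, "dilation_shape", str),
    "guided.eps": ("guided", "eps", float),
    "guided.scale_factor": ("guided", "scale_factor", int),
    "guided.window": ("guided", "window", None),
    "guided.coverage_tau": ("guided", "coverage_tau", float),
    "guided.coverage_frac": ("guided", "coverage_frac", float),
    "guided.guidance_mode": ("guided", "guidance_mode", str),
    "seed": (None, "seed", int),
}


def load_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> FusionConfig:
    """Build a :class:`FusionConfig` from a flat YAML file plus overrides.

    The file is a flat mapping with dotted keys (``guided.eps: 0.001``);
    ``overrides`` uses the same keys and wins over the file.
    """
    flat: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(loaded, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        flat.update(loaded)
    if overrides:
        flat.update({k: v for k, v in overrides.items() if v is not None})

    top: dict = {}
    bandpass: dict = {}
    guided: dict = {}
    for key, value in flat.items():
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"unknown config key {key!r}")
        group, name, cast = _CONFIG_KEYS[key]
        if cast is not None and value is not None:
            try:
                value = cast(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key!r}: {value!r}") from exc
        target = {"bandpass": bandpass, "guided": guided, None: top}[group]
        target[name] = value
    if "window" in guided and isinstance(guided["window"], str) and guided[
        "window"
    ] != "auto":
        try:
            guided["window"] = int(guided["window"])
        except ValueError as exc:
            raise ConfigError(f"guided.window must be 'auto' or int") from exc
    kwargs = dict(top)
    if bandpass:
        kwargs["bandpass"] = BandpassSpec(**bandpass)
    if guided:
        kwargs["guided"] = GuidedFilterParams(**guided)
    return FusionConfig(**kwargs)
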
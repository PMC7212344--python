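"""Image standardization chain for QA-network inputs.

The chain mirrors a typical radiotherapy CT pipeline: slices are resampled
to an isotropic pixel spacing (default 1.00 mm), center-cropped or
zero-padded to a uniform 512x512 grid, contrast-enhanced with CLAHE
(intensity channel only), and finally downsampled to the QA-network input
size (default 224x224).  Ground-truth masks are resampled with
nearest-neighbor interpolation and never pass through CLAHE or the QA
downsampling step: DSC labels are computed at full resolution.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage import exposure, transform

__all__ = [
    "resample_isotropic",
    "normalize_size",
    "enhance_contrast",
    "downsample_for_qa",
]

DEFAULT_SPACING_MM = 1.0
DEFAULT_GRID = 512
DEFAULT_QA_SIZE = 224
DEFAULT_CLIP_LIMIT = 0.01
DEFAULT_TILE_GRID = 8


def _is_binary(a: np.ndarray) -> bool:
    return a.dtype == bool or np.isin(np.unique(a), (0, 1)).all()


def resample_isotropic(
    values: np.ndarray,
    pixel_spacing: float | tuple[float, float],
    target_spacing: float = DEFAULT_SPACING_MM,
    *,
    mask: bool = False,
) -> np.ndarray:
    """Resample a slice to isotropic pixel spacing.

    The output grid has ``round(n * spacing / target)`` pixels per axis.
    Intensity channels are interpolated bilinearly; with ``mask=True``
    nearest-neighbor interpolation is used and the output stays binary.
    """
    spacing = np.broadcast_to(np.asarray(pixel_spacing, dtype=float), (2,))
    if (spacing <= 0).any() or target_spacing <= 0:
        raise ValueError(f"pixel spacing must be positive, got {spacing} -> {target_spacing}")
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {values.shape}")

    out_shape = tuple(int(round(n * s / target_spacing)) for n, s in zip(values.shape, spacing))
    if out_shape == values.shape and np.allclose(spacing, target_spacing):
        return values.copy()

    if mask:
        out = transform.resize(
            values.astype(np.float32), out_shape, order=0,
            preserve_range=True, anti_aliasing=False,
        )
        return (out > 0.5).astype(values.dtype if values.dtype != bool else np.uint8)
    out = transform.resize(
        values.astype(np.float64), out_shape, order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return out


def normalize_size(values: np.ndarray, size: int = DEFAULT_GRID) -> np.ndarray:
    """Center-crop or zero-pad a slice to ``size x size``.

    Odd remainders place the extra cropped/padded pixel on the bottom and
    right.  A total function: any input shape is accepted.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {values.shape}")
    out = values
    for axis in (0, 1):
        n = out.shape[axis]
        if n > size:
            lo = (n - size) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(lo, lo + size)
            out = out[tuple(sl)]
        elif n < size:
            lo = (size - n) // 2
            hi = size - n - lo
            pad = [(0, 0), (0, 0)]
            pad[axis] = (lo, hi)
            out = np.pad(out, pad, mode="constant")
    return out


def enhance_contrast(
    values: np.ndarray,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tile_grid: int = DEFAULT_TILE_GRID,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a CT slice.

    Applies to the intensity channel only — never to masks or probability
    maps.  The output is rescaled to [0, 1].  A constant image is returned
    unchanged (as zeros) rather than dividing by a zero range.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {values.shape}")
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        return np.zeros_like(values)
    scaled = (values - lo) / (hi - lo)
    kernel = max(1, min(values.shape) // tile_grid)
    out = exposure.equalize_adapthist(scaled, kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def downsample_for_qa(
    channels: Sequence[np.ndarray],
    size: int = DEFAULT_QA_SIZE,
    ranges: Sequence[tuple[float, float] | None] | None = None,
) -> list[np.ndarray]:
    """Resize each channel to ``size x size`` for the QA network.

    All channels must share one shape.  Interpolation is bilinear with
    anti-aliasing when shrinking (area-style); each channel for which a
    valid range is given (e.g. (0, 1) for probabilities, (0, 0.5) for
    uncertainties) is clipped back into it afterwards.
    """
    shapes = {np.asarray(c).shape for c in channels}
    if len(shapes) > 1:
        raise ValueError(f"channel shapes differ: {sorted(shapes)}")
    if ranges is not None and len(ranges) != len(channels):
        raise ValueError("ranges must align with channels")
    out = []
    for k, chan in enumerate(channels):
        chan = np.asarray(chan, dtype=np.float64)
        if chan.shape == (size, size):
            resized = chan.copy()
        else:
            resized = transform.resize(
                chan, (size, size), order=1, preserve_range=True,
                anti_aliasing=chan.shape[0] > size,
            )
        if ranges is not None and ranges[k] is not None:
            resized = np.clip(resized, *ranges[k])
        out.append(resized)
    return out
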
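"""Image ingestion and preprocessing for B-scans.

Raw exports from OCT instruments arrive as 8- or 16-bit PNG/BMP/TIFF,
sometimes with redundant color channels.  The preprocessing pipeline is:
grayscale conversion (BT.601 luminance), normalization to [0, 1],
rectangular crop to the working region, and median filtering to knock
down speckle before edge detection.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import scipy.ndimage as ndi

from .phantom import BoundaryTrace

__all__ = ["load_image", "crop", "crop_traces", "median_filter"]

# ITU-R BT.601 luminance weights for RGB -> gray.
_BT601 = np.array([0.299, 0.587, 0.114])


def load_image(path) -> np.ndarray:
    """Read a PNG/BMP/TIFF B-scan as a float image in [0, 1].

    Multi-channel inputs are reduced to BT.601 luminance; 8- and 16-bit
    integer ranges are rescaled to [0, 1]; float inputs are clipped to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    raw = iio.imread(path)
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        if info.bits not in (8, 16):
            raise ValueError(f"unsupported bit depth: {info.bits}-bit {raw.dtype}")
        scaled = raw.astype(float) / float(info.max)
    elif np.issubdtype(raw.dtype, np.floating):
        scaled = np.clip(raw.astype(float), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported pixel dtype: {raw.dtype}")
    if scaled.ndim == 3:
        if scaled.shape[2] < 3:
            out = scaled[:, :, 0]
        else:
            out = np.tensordot(scaled[:, :, :3], _BT601, axes=([2], [0]))
    elif scaled.ndim == 2:
        out = scaled
    else:
        raise ValueError(f"expected a 2-D image, got shape {raw.shape}")
    if not np.all(np.isfinite(out)):
        raise ValueError(f"non-finite pixel values in {path}")
    return np.clip(out, 0.0, 1.0)


def crop(image: np.ndarray, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Extract the (height, width) window whose corner is (top, left).

    Output pixel (r, c) equals input pixel (top + r, left + c).  The
    (top, left) offset is the record needed to shift boundary traces into
    the cropped frame (see :func:`crop_traces`).
    """
    image = np.asarray(image)
    if top < 0 or left < 0:
        raise ValueError(f"crop origin must be non-negative, got top={top}, left={left}")
    if top + height > image.shape[0]:
        raise ValueError(
            f"crop bottom {top + height} exceeds image height {image.shape[0]}"
        )
    if left + width > image.shape[1]:
        raise ValueError(
            f"crop right {left + width} exceeds image width {image.shape[1]}"
        )
    return image[top : top + height, left : left + width]


def crop_traces(
    traces: Sequence[BoundaryTrace], top: int, left: int, width: int
) -> list[BoundaryTrace]:
    """Shift boundary traces into the frame of a crop window."""
    return [
        BoundaryTrace(name=t.name, rows=t.rows[left : left + width] - top)
        for t in traces
    ]


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter with a window x window neighborhood, edges replicated.

    The standard speckle-reduction step before edge detection; window=1 is
    the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    image = np.asarray(image, dtype=float)
    if window == 1:
        return image.copy()
    return ndi.median_filter(image, size=window, mode="nearest")
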
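"""Canny edge detection.

The classic multi-step pipeline: Gaussian smoothing at scale sigma,
central-difference derivatives, root-sum-of-squares gradient magnitude
(normalized to a peak of 1), nonmaximal suppression along the 8-way
quantized gradient direction, and double-threshold hysteresis.  The
T1/T2 thresholds apply to the normalized magnitude, which is what makes
values like 0.005 and 0.1 transferable across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from ._common import hysteresis, normalize_response

__all__ = ["CannyParams", "canny", "gradient_field"]


@dataclass(frozen=True)
class CannyParams:
    """Gaussian width and hysteresis thresholds of the Canny detector.

    Defaults are the tuned operating point for macular B-scans:
    sigma = 3 px, T1 = 0.005, T2 = 0.1 on the normalized gradient.
    """

    sigma: float = 3.0
    t_low: float = 0.005
    t_high: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.t_low < self.t_high:
            raise ValueError(
                f"need 0 <= t_low < t_high, got {self.t_low} and {self.t_high}"
            )


def gradient_field(image: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized gradient magnitude and direction of the smoothed image.

    Magnitude is the root sum of squares of the central-difference
    derivatives, rescaled to max 1; direction is atan2(d/drow, d/dcol).
    """
    smoothed = ndi.gaussian_filter(np.asarray(image, dtype=float), sigma, mode="nearest")
    g_row, g_col = np.gradient(smoothed)
    magnitude = normalize_response(np.hypot(g_row, g_col))
    direction = np.arctan2(g_row, g_col)
    return magnitude, direction


# Neighbor offsets (drow, dcol) of the four gradient sectors: 0 deg
# (horizontal gradient), 45, 90 (vertical), 135.
_SECTOR_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def _directional_nms(magnitude: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Suppress pixels that are not local maxima along the gradient.

    The gradient direction is quantized to 45-degree sectors; a pixel
    survives only if its magnitude exceeds the neighbor ahead and is at
    least the neighbor behind (asymmetric tie-break -> one-pixel-thin
    ridges).  Out-of-image neighbors count as -inf.
    """
    sector = np.round(direction / (np.pi / 4.0)).astype(int) % 4
    padded = np.pad(magnitude, 1, constant_values=-np.inf)
    keep = np.zeros(magnitude.shape, dtype=bool)
    for s, (dr, dc) in enumerate(_SECTOR_OFFSETS):
        ahead = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        behind = padded[1 - dr : padded.shape[0] - 1 - dr, 1 - dc : padded.shape[1] - 1 - dc]
        in_sector = sector == s
        keep |= in_sector & (magnitude > ahead) & (magnitude >= behind)
    keep &= magnitude > 0
    return np.where(keep, magnitude, 0.0)


def canny(image: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Detect edges with the Canny pipeline; returns a boolean edge map."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    params = params or CannyParams()
    magnitude, direction = gradient_field(image, params.sigma)
    thinned = _directional_nms(magnitude, direction)
    return hysteresis(thinned, params.t_low, params.t_high)
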
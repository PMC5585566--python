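"""Two-pass derivative-of-Gaussian edge detection for layered images.

Retinal layer boundaries run near-horizontally, alternating between
bright-above-dark and dark-above-bright transitions.  The detector
correlates the image with a vertical first-derivative-of-Gaussian kernel

    L(x, y) = -p * x / (pi * sigma^2) * exp(-(x^2 + y^2) / (2 sigma^2)),

where x is the vertical (depth) offset and p in {+1, -1} selects the edge
polarity.  The kernel is applied twice with alternating p: the p = +1
pass responds to boundaries with the bright band on top, the p = -1 pass
to boundaries with the dark band on the anterior side.  Each pass is
normalized to a peak of 1, thinned by per-column nonmaximal suppression,
and cleaned by hysteresis; the final map is the union of the two passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import scipy.ndimage as ndi

from ._common import hysteresis, normalize_response, vertical_nms

__all__ = ["TwoPassParams", "two_pass_kernel", "two_pass_responses",
           "two_pass_passes", "two_pass_detect"]


@dataclass(frozen=True)
class TwoPassParams:
    """Scale, hysteresis thresholds, and kernel truncation radius.

    Defaults are the tuned operating point for macular B-scans:
    sigma = 3 px, T1 = 0.005, T2 = 0.15.  ``kernel_radius`` defaults to
    ceil(3 * sigma).
    """

    sigma: float = 3.0
    t_low: float = 0.005
    t_high: float = 0.15
    kernel_radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.t_low < self.t_high:
            raise ValueError(
                f"need 0 <= t_low < t_high, got {self.t_low} and {self.t_high}"
            )
        if self.kernel_radius is not None and self.kernel_radius < ceil(3 * self.sigma):
            raise ValueError(
                f"kernel_radius must be >= ceil(3*sigma) = {ceil(3 * self.sigma)}"
            )

    @property
    def radius(self) -> int:
        return self.kernel_radius if self.kernel_radius is not None else ceil(3 * self.sigma)


def two_pass_kernel(sigma: float, p: int, radius: int) -> np.ndarray:
    """Evaluate the polarity-p vertical derivative-of-Gaussian kernel.

    Sampled at integer offsets on a (2*radius+1)^2 grid, with x the
    vertical (row) offset; no normalization beyond the formula itself.
    The kernel is odd in x, so every full kernel sums to zero.
    """
    if p not in (+1, -1):
        raise ValueError(f"polarity p must be +1 or -1, got {p}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius < ceil(3 * sigma):
        raise ValueError(f"radius must be >= ceil(3*sigma) = {ceil(3 * sigma)}")
    x = np.arange(-radius, radius + 1, dtype=float)[:, None]  # vertical offset
    y = np.arange(-radius, radius + 1, dtype=float)[None, :]  # horizontal offset
    return -p * x / (np.pi * sigma**2) * np.exp(-(x**2 + y**2) / (2.0 * sigma**2))


def two_pass_responses(
    image: np.ndarray, params: TwoPassParams | None = None
) -> dict[int, np.ndarray]:
    """Raw (signed) correlation response of each polarity pass.

    The p = -1 response is exactly the negation of the p = +1 response;
    both are returned for symmetry of the downstream per-pass pipeline.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    params = params or TwoPassParams()
    pos = ndi.correlate(image, two_pass_kernel(params.sigma, +1, params.radius), mode="nearest")
    return {+1: pos, -1: -pos}


def two_pass_passes(
    image: np.ndarray, params: TwoPassParams | None = None
) -> dict[int, np.ndarray]:
    """Binary edge map of each polarity pass separately.

    Each pass keeps its positive response, normalizes it to max 1, thins it
    per column, and applies hysteresis with (t_low, t_high).
    """
    params = params or TwoPassParams()
    responses = two_pass_responses(image, params)
    maps = {}
    for p, resp in responses.items():
        positive = normalize_response(np.clip(resp, 0.0, None))
        thinned = vertical_nms(positive)
        maps[p] = hysteresis(thinned, params.t_low, params.t_high)
    return maps


def two_pass_detect(image: np.ndarray, params: TwoPassParams | None = None) -> np.ndarray:
    """Union of the two polarity passes; returns a boolean edge map."""
    maps = two_pass_passes(image, params)
    return maps[+1] | maps[-1]
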
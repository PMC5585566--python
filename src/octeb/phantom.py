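"""Synthetic layered-retina B-scan phantoms with exact ground truth.

A macular OCT B-scan shows a stack of retinal layers of distinct mean
reflectivity separated by smooth, gently undulating, non-crossing
boundaries that span every A-scan (image column).  This module generates
such images synthetically: piecewise-constant layer bands perturbed by
smoothed noise and corrupted by multiplicative gamma speckle, together
with the exact boundary traces, the rasterized edge mask, and the
ILM-to-RPE region-of-interest mask that downstream evaluation needs.

Conventions: row 0 is the anterior (top) side, indices are 0-based,
intensities live in [0, 1], and trace rows are real-valued until
rasterization, which rounds half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PhantomSpec",
    "BoundaryTrace",
    "GroundTruth",
    "generate_boundaries",
    "render_bscan",
    "add_speckle",
    "rasterize_ground_truth",
    "make_phantom",
    "DEFAULT_BOUNDARY_NAMES",
]

#: Anatomical names of the six boundaries delimiting the macular layers,
#: anterior to posterior: inner limiting membrane, nerve fiber / ganglion
#: cell, inner plexiform / inner nuclear, outer plexiform / outer nuclear,
#: outer nuclear / inner photoreceptor segment, RPE / choroid.
DEFAULT_BOUNDARY_NAMES = (
    "ILM",
    "NFL-GCL",
    "IPL-INL",
    "OPL-ONL",
    "ONL-IPS",
    "RPE-choroid",
)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from the anterior (up in value)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic layered B-scan.

    The defaults emulate the working conditions of a cropped macular
    OCT region of interest: a 200 x 400 px window holding six layer
    boundaries with alternating bright/dark bands.

    Parameters
    ----------
    height, width
        Image size in pixels (rows = depth, columns = A-scans).
    mean_depths
        Mean row position of each boundary, strictly increasing,
        anterior to posterior.
    layer_intensities
        Reflectivity of each of the ``n_boundaries + 1`` bands, in [0, 1].
    undulation_amplitude
        Maximum absolute deviation (px) of a boundary from its mean depth.
    undulation_smoothness
        Correlation length (columns) of the boundary perturbation.
    min_gap
        Smallest allowed per-column distance between adjacent boundaries.
    speckle_looks
        Number of looks ``L`` of the unit-mean gamma multiplicative
        speckle model; larger means less noise (variance 1/L).
    seed
        Seed for boundary perturbation and speckle draw.
    """

    height: int = 200
    width: int = 400
    mean_depths: tuple[float, ...] = (25.0, 55.0, 85.0, 110.0, 135.0, 170.0)
    layer_intensities: tuple[float, ...] = (0.08, 0.62, 0.30, 0.55, 0.22, 0.75, 0.12)
    undulation_amplitude: float = 4.0
    undulation_smoothness: float = 40.0
    min_gap: float = 8.0
    speckle_looks: float = 16.0
    seed: int = 0

    @property
    def n_boundaries(self) -> int:
        return len(self.mean_depths)

    def __post_init__(self) -> None:
        depths = np.asarray(self.mean_depths, dtype=float)
        if depths.ndim != 1 or depths.size < 1:
            raise ValueError("mean_depths must be a non-empty 1-D sequence")
        if np.any(np.diff(depths) <= 0):
            raise ValueError("mean_depths must be strictly increasing")
        if len(self.layer_intensities) != depths.size + 1:
            raise ValueError(
                f"layer_intensities must have length n_boundaries + 1 = "
                f"{depths.size + 1}, got {len(self.layer_intensities)}"
            )
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1 pixel")
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be > 0")
        if self.undulation_amplitude < 0:
            raise ValueError("undulation_amplitude must be >= 0")
        if depths[0] < 0 or depths[-1] > self.height - 1:
            raise ValueError(
                f"mean_depths must lie within [0, {self.height - 1}] "
                f"(got range [{depths[0]}, {depths[-1]}])"
            )
        if np.any(np.diff(depths) < self.min_gap):
            k = int(np.argmax(np.diff(depths) < self.min_gap))
            raise ValueError(
                f"mean_depths gap between boundaries {k} and {k + 1} is "
                f"{depths[k + 1] - depths[k]:g} px, below min_gap={self.min_gap:g}; "
                "the spec cannot satisfy min_gap within the image"
            )


@dataclass(frozen=True)
class BoundaryTrace:
    """One named layer boundary: a real-valued row position per column."""

    name: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))
        if self.rows.ndim != 1:
            raise ValueError("trace rows must be 1-D (one row per column)")

    def rounded(self) -> np.ndarray:
        """Integer row per column under half-up rounding."""
        return _round_half_up(self.rows)


@dataclass(frozen=True)
class GroundTruth:
    """Exact reference for one phantom: traces, edge mask, and ROI mask.

    The ROI is the inclusive band between the first (ILM) and the last
    (RPE) trace in each column — the region evaluation is restricted to.
    """

    traces: tuple[BoundaryTrace, ...]
    edge_mask: np.ndarray
    roi_mask: np.ndarray

    @classmethod
    def from_masks(cls, edge_mask: np.ndarray, roi_mask: np.ndarray) -> "GroundTruth":
        """Build a ground truth directly from binary masks (no traces)."""
        edge_mask = np.asarray(edge_mask, dtype=bool)
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if edge_mask.shape != roi_mask.shape:
            raise ValueError(
                f"edge mask shape {edge_mask.shape} != roi mask shape {roi_mask.shape}"
            )
        return cls(traces=(), edge_mask=edge_mask, roi_mask=roi_mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.edge_mask.shape


def generate_boundaries(spec: PhantomSpec) -> list[BoundaryTrace]:
    """Draw the smooth, non-crossing boundary traces of a phantom.

    Each trace is its mean depth plus a zero-mean perturbation obtained by
    Gaussian-smoothing per-column white noise (correlation length
    ``undulation_smoothness``) and rescaling to the requested amplitude.
    Adjacent traces closer than ``min_gap`` are pushed apart symmetrically
    (iterative projection), which is deterministic and terminates for any
    feasible spec.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n, width = spec.n_boundaries, spec.width
    rows = np.empty((n, width), dtype=float)
    for k in range(n):
        noise = rng.standard_normal(width)
        if spec.undulation_amplitude > 0:
            smooth = gaussian_filter1d(noise, sigma=spec.undulation_smoothness, mode="reflect")
            peak = np.max(np.abs(smooth))
            pert = smooth * (spec.undulation_amplitude / peak) if peak > 0 else np.zeros(width)
        else:
            pert = np.zeros(width)
        rows[k] = spec.mean_depths[k] + pert

    # Non-crossing / minimum-gap enforcement by symmetric projection.
    for _ in range(1000):
        changed = False
        for k in range(n - 1):
            gap = rows[k + 1] - rows[k]
            short = gap < spec.min_gap
            if np.any(short):
                push = (spec.min_gap - gap[short]) / 2.0
                rows[k, short] -= push
                rows[k + 1, short] += push
                changed = True
        lo = np.clip(rows[0], 0.0, None)
        hi = np.clip(rows[-1], None, float(spec.height - 1))
        if np.any(lo != rows[0]) or np.any(hi != rows[-1]):
            rows[0], rows[-1] = lo, hi
            changed = True
        if not changed:
            break
    else:  # pragma: no cover - feasibility is validated in PhantomSpec
        raise RuntimeError("boundary projection failed to converge")

    names = (
        DEFAULT_BOUNDARY_NAMES
        if n == len(DEFAULT_BOUNDARY_NAMES)
        else tuple(f"boundary-{k}" for k in range(n))
    )
    return [BoundaryTrace(name=names[k], rows=rows[k]) for k in range(n)]


def render_bscan(
    traces: Sequence[BoundaryTrace],
    layer_intensities: Sequence[float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Render the noiseless piecewise-constant B-scan for given traces.

    A pixel at (r, c) takes the intensity of the band containing it: band
    ``k`` starts at the rounded row of trace ``k`` (the boundary row itself
    belongs to the deeper band), so the intensity change happens exactly at
    the rasterized ground-truth edge row.
    """
    if len(layer_intensities) != len(traces) + 1:
        raise ValueError(
            f"layer_intensities must have length {len(traces) + 1} "
            f"(n_boundaries + 1), got {len(layer_intensities)}"
        )
    height, width = shape
    intensities = np.asarray(layer_intensities, dtype=float)
    if len(traces) == 0:
        return np.full(shape, intensities[0])
    rounded = np.stack([t.rounded() for t in traces])  # (n, width)
    row_idx = np.arange(height)[None, :, None]  # (1, height, 1)
    band = (row_idx >= rounded[:, None, :]).sum(axis=0)  # (height, width)
    return intensities[band]


def add_speckle(image: np.ndarray, looks: float, seed) -> np.ndarray:
    """Corrupt an image with unit-mean multiplicative gamma speckle.

    Each pixel is multiplied by an independent gamma variate with shape
    ``looks`` and mean 1 (variance ``1/looks``) — the standard fully
    developed speckle model for L-look coherent imaging.  Deterministic
    given ``seed``; output clipped to be non-negative.
    """
    if looks <= 0:
        raise ValueError("looks must be > 0")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    mult = rng.gamma(shape=looks, scale=1.0 / looks, size=image.shape)
    return np.clip(image * mult, 0.0, None)


def rasterize_ground_truth(
    traces: Sequence[BoundaryTrace], shape: tuple[int, int]
) -> GroundTruth:
    """Rasterize traces into the binary edge mask and inclusive ROI mask.

    Rounding is half-up.  Each trace contributes exactly one edge pixel per
    column; the ROI spans rounded ILM row to rounded RPE row inclusive.
    """
    height, width = shape
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    rounded = np.stack([t.rounded() for t in traces])  # (n, width)
    if rounded.min() < 0 or rounded.max() > height - 1:
        raise ValueError("trace rows fall outside the image bounds")
    for k in range(len(traces) - 1):
        bad = np.nonzero(rounded[k] >= rounded[k + 1])[0]
        if bad.size:
            raise ValueError(
                f"traces {k} and {k + 1} cross (or collide after rounding) "
                f"first at column {int(bad[0])}"
            )
    cols = np.arange(width)
    edge_mask = np.zeros(shape, dtype=bool)
    for k in range(len(traces)):
        edge_mask[rounded[k], cols] = True
    row_idx = np.arange(height)[:, None]
    roi_mask = (row_idx >= rounded[0][None, :]) & (row_idx <= rounded[-1][None, :])
    return GroundTruth(traces=tuple(traces), edge_mask=edge_mask, roi_mask=roi_mask)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one complete phantom: speckled B-scan plus ground truth."""
    traces = generate_boundaries(spec)
    clean = render_bscan(traces, spec.layer_intensities, (spec.height, spec.width))
    noisy = add_speckle(clean, spec.speckle_looks, seed=[spec.seed, 1])
    truth = rasterize_ground_truth(traces, (spec.height, spec.width))
    return noisy, truth


def phantom_series(spec: PhantomSpec, n_images: int, base_seed: int) -> list[tuple[np.ndarray, GroundTruth]]:
    """A reproducible set of phantoms with per-image seeds base_seed + i."""
    return [make_phantom(replace(spec, seed=base_seed + i)) for i in range(n_images)]
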
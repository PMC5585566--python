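"""Reading and writing the artifact formats.

Phantom images go out as 16-bit PNG (intensities scaled to [0, 65535]),
binary masks as 8-bit 0/255 PNG, and boundary traces as a long-format
CSV with columns ``boundary, column, row``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import BoundaryTrace, GroundTruth, rasterize_ground_truth

__all__ = [
    "save_image",
    "save_mask",
    "load_mask",
    "traces_to_csv",
    "traces_from_csv",
    "ground_truth_from_csv",
]


def save_image(path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 16-bit PNG."""
    scaled = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 65535.0 + 0.5).astype(np.uint16))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 8-bit PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a 0/255 mask PNG back to boolean (any nonzero is True)."""
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return raw > 0


def traces_to_csv(traces: Sequence[BoundaryTrace], path) -> None:
    """Write traces in long format: one (boundary, column, row) per pixel."""
    frames = [
        pd.DataFrame(
            {"boundary": t.name, "column": np.arange(t.rows.size), "row": t.rows}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path) -> list[BoundaryTrace]:
    """Read traces written by :func:`traces_to_csv`, preserving order."""
    df = pd.read_csv(path)
    traces = []
    for name in df["boundary"].unique():
        sub = df[df["boundary"] == name].sort_values("column")
        cols = sub["column"].to_numpy()
        if not np.array_equal(cols, np.arange(cols.size)):
            raise ValueError(
                f"trace {name!r} must cover columns 0..{cols.size - 1} exactly"
            )
        traces.append(BoundaryTrace(name=str(name), rows=sub["row"].to_numpy(dtype=float)))
    return traces


def ground_truth_from_csv(path, shape: tuple[int, int]) -> GroundTruth:
    """Load a trace CSV and rasterize it for an image of the given shape."""
    return rasterize_ground_truth(traces_from_csv(path), shape)
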
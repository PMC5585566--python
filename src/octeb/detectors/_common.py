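"""Shared pieces of the edge-detection pipelines: response normalization,
nonmaximal suppression, and double-threshold hysteresis."""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

# Responses whose peak falls below this are treated as identically zero,
# so constant images yield empty maps instead of amplified roundoff.
_ZERO_RESPONSE = 1e-12

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def normalize_response(response: np.ndarray) -> np.ndarray:
    """Scale a non-negative response map so its maximum is 1.

    A map with no appreciable response (peak < 1e-12) comes back all-zero;
    thresholds T1/T2 are specified on this normalized scale.
    """
    response = np.asarray(response, dtype=float)
    peak = response.max(initial=0.0)
    if peak < _ZERO_RESPONSE:
        return np.zeros_like(response)
    return response / peak


def hysteresis(strength: np.ndarray, t_low: float, t_high: float) -> np.ndarray:
    """Double-threshold edge retention with 8-connected linking.

    Pixels with strength > t_high are kept; pixels with strength > t_low
    are kept only if 8-connected to a kept pixel through other candidates.
    """
    if not 0 <= t_low < t_high:
        raise ValueError(f"need 0 <= t_low < t_high, got t_low={t_low}, t_high={t_high}")
    strength = np.asarray(strength, dtype=float)
    candidates = strength > t_low
    strong = strength > t_high
    if not strong.any():
        return np.zeros_like(candidates)
    labels, n_labels = ndi.label(candidates, structure=_EIGHT_CONN)
    keep = np.zeros(n_labels + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def vertical_nms(response: np.ndarray) -> np.ndarray:
    """Per-column nonmaximal suppression of a non-negative response.

    A pixel survives if its response is positive, >= its upper neighbor and
    > its lower neighbor (the asymmetric tie-break keeps ridges one pixel
    thick).  Missing neighbors at the image border count as -inf.
    """
    response = np.asarray(response, dtype=float)
    padded = np.pad(response, ((1, 1), (0, 0)), constant_values=-np.inf)
    up, down = padded[:-2], padded[2:]
    keep = (response >= up) & (response > down) & (response > 0)
    return np.where(keep, response, 0.0)
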
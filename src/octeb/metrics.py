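"""Ground-truth evaluation metrics for binary edge maps.

The suite quantifies how well a detected edge map matches expert (or
phantom) layer boundaries inside the ILM-to-RPE region of interest:

* Pratt's figure of merit  FOM = 1/max(N_I, N_A) * sum_i 1/(1 + alpha d_i^2),
  with N_I ideal and N_A detected edge pixels, d_i the distance from the
  i-th detected pixel to its correct position, and alpha normally 1/9.
* Exact-overlap presence rates  TPR = TP/N_I,  ACC = (TP+TN)/N, and the
  redefined false positive rate  FPR = FP/N_A (the classical FP/(N - N_I)
  is nearly zero for thin boundaries and is kept only as an option).
* Mean localization deviation  MLD: for each ground-truth pixel, the mean
  distance to detected pixels within a +/-3 px window along its A-scan
  (column), averaged over ground-truth pixels with at least one match.
* Shift-adjusted variants FOM_ADJ, TPR_ADJ, FPR_ADJ, ACC_ADJ that accept
  detected pixels within a small per-column shift (2 px by default) of the
  ground truth as true positives, since a small constant boundary shift
  does not perturb layer-thickness measurements.

All metrics are evaluated strictly inside the ROI mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .phantom import GroundTruth

__all__ = [
    "MatchResult",
    "MetricReport",
    "match_exact",
    "match_adjusted",
    "tpr",
    "fpr",
    "fpr_classical",
    "acc",
    "fom",
    "mld",
    "adjusted_metrics",
    "evaluate",
]

DEFAULT_ALPHA = 1.0 / 9.0
DEFAULT_MLD_NEIGHBORHOOD = 3
DEFAULT_ADJUST_RADIUS = 2


@dataclass(frozen=True)
class MatchResult:
    """Pixel-level confusion counts and per-detected-pixel distances.

    ``distances`` holds one entry per detected pixel inside the ROI (its
    distance to the correct position; 0 for an exact true positive).  For
    exact matching tp + fp == n_actual and tp + fn == n_ideal; adjusted
    matching counts tp against the ground truth side, so only the bounds
    tp <= n_ideal and fp <= n_actual are guaranteed there.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_roi: int
    n_ideal: int
    n_actual: int
    distances: np.ndarray = field(repr=False)


def _roi_views(detected: np.ndarray, truth: GroundTruth):
    detected = np.asarray(detected, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError(
            f"detected map shape {detected.shape} != ground truth shape {truth.shape}"
        )
    roi = truth.roi_mask
    det = detected & roi
    ideal = truth.edge_mask & roi
    return det, ideal, roi


def _nearest_distances(det: np.ndarray, ideal: np.ndarray) -> np.ndarray:
    """Euclidean distance from each detected pixel to the nearest ideal pixel."""
    if not ideal.any():
        return np.full(int(det.sum()), np.inf)
    edt = distance_transform_edt(~ideal)
    return edt[det]


def _column_distances(det: np.ndarray, ideal: np.ndarray) -> np.ndarray:
    """Distance from each detected pixel to the nearest ideal pixel in its column."""
    height, _ = det.shape
    rows_det, cols_det = np.nonzero(det)
    out = np.full(rows_det.size, np.inf)
    ideal_rows_by_col = [np.nonzero(ideal[:, c])[0] for c in range(det.shape[1])]
    for i, (r, c) in enumerate(zip(rows_det, cols_det)):
        rows = ideal_rows_by_col[c]
        if rows.size:
            out[i] = np.abs(rows - r).min()
    return out


def match_exact(
    detected: np.ndarray, truth: GroundTruth, distance: str = "nearest"
) -> MatchResult:
    """Exact-overlap confusion counts inside the ROI.

    ``distance`` selects how a detected pixel's deviation d(i) is measured
    for the FOM: "nearest" (Euclidean distance to the nearest ground-truth
    pixel, the default) or "column" (distance along the pixel's A-scan).
    """
    det, ideal, roi = _roi_views(detected, truth)
    tp = int((det & ideal).sum())
    fp = int((det & ~ideal).sum())
    fn = int((ideal & ~det).sum())
    n_roi = int(roi.sum())
    if distance == "nearest":
        dists = _nearest_distances(det, ideal)
    elif distance == "column":
        dists = _column_distances(det, ideal)
    else:
        raise ValueError(f"distance must be 'nearest' or 'column', got {distance!r}")
    return MatchResult(
        tp=tp, fp=fp, tn=n_roi - tp - fp - fn, fn=fn,
        n_roi=n_roi, n_ideal=tp + fn, n_actual=tp + fp,
        distances=dists,
    )


def tpr(m: MatchResult) -> float:
    """True positive rate TP / N_I."""
    if m.n_ideal == 0:
        raise ValueError("no ground-truth edge pixels: TPR is undefined")
    return m.tp / m.n_ideal


def fpr(m: MatchResult) -> float:
    """Redefined false positive rate FP / N_A (0 for an empty detection)."""
    if m.n_actual == 0:
        return 0.0
    return m.fp / m.n_actual


def fpr_classical(m: MatchResult) -> float:
    """Classical FP / (N - N_I); kept for completeness, not used by default."""
    denom = m.n_roi - m.n_ideal
    if denom == 0:
        raise ValueError("ROI holds only edge pixels: classical FPR is undefined")
    return m.fp / denom


def acc(m: MatchResult) -> float:
    """Accuracy (TP + TN) / N over the ROI."""
    if m.n_roi == 0:
        raise ValueError("empty ROI: ACC is undefined")
    return (m.tp + m.tn) / m.n_roi


def fom(m: MatchResult, alpha: float = DEFAULT_ALPHA) -> float:
    """Pratt's figure of merit; 0 for an empty detection."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if m.n_ideal == 0:
        raise ValueError("no ground-truth edge pixels: FOM is undefined")
    if m.n_actual == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        terms = 1.0 / (1.0 + alpha * np.square(m.distances))
    return float(terms.sum() / max(m.n_ideal, m.n_actual))


def mld(
    detected: np.ndarray,
    truth: GroundTruth,
    max_dist: int = DEFAULT_MLD_NEIGHBORHOOD,
) -> float:
    """Mean localization deviation with a per-A-scan search window.

    For each ground-truth edge pixel, the detected pixels in the same
    column within ``max_dist`` rows form its neighborhood (N_b pixels);
    the inner term is their mean distance.  MLD averages the inner terms
    over ground-truth pixels with N_b > 0 and is NaN when every
    neighborhood is empty (no detection near any boundary).
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    det, ideal, _ = _roi_views(detected, truth)
    rows_gt, cols_gt = np.nonzero(ideal)
    if rows_gt.size == 0:
        raise ValueError("no ground-truth edge pixels: MLD is undefined")
    height = det.shape[0]
    counts = np.zeros(rows_gt.size)
    sums = np.zeros(rows_gt.size)
    for k in range(-max_dist, max_dist + 1):
        r = rows_gt + k
        valid = (r >= 0) & (r < height)
        hit = np.zeros(rows_gt.size, dtype=bool)
        hit[valid] = det[r[valid], cols_gt[valid]]
        counts += hit
        sums += hit * abs(k)
    matched = counts > 0
    if not matched.any():
        return float("nan")
    return float(np.mean(sums[matched] / counts[matched]))


def match_adjusted(
    detected: np.ndarray,
    truth: GroundTruth,
    radius: int = DEFAULT_ADJUST_RADIUS,
) -> MatchResult:
    """Shift-tolerant matching: accept detections within ``radius`` rows.

    A detected pixel matches if some ground-truth pixel lies within
    ``radius`` rows in its column.  TP_ADJ counts ground-truth pixels with
    at least one matching detection (so TP_ADJ <= N_I, no double credit);
    FP_ADJ counts detected pixels matching no ground-truth neighborhood;
    TN_ADJ equals the exact-matching TN, which the adjustment cannot
    affect.  The adjusted distance of a detected pixel is the smaller of
    its exact distance and its within-radius column residual, so adjusted
    metrics are never worse than their exact counterparts.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    exact = match_exact(detected, truth)
    det, ideal, roi = _roi_views(detected, truth)
    height = det.shape[0]

    def _vdilate(mask: np.ndarray, r: int) -> np.ndarray:
        out = mask.copy()
        for k in range(1, r + 1):
            out[k:] |= mask[:-k]
            out[:-k] |= mask[k:]
        return out

    matched_det = det & _vdilate(ideal, radius)
    tp_adj = int((ideal & _vdilate(det, radius)).sum())
    fp_adj = int(det.sum() - matched_det.sum())

    # per-detected-pixel column residual within the radius (inf if none)
    rows_det, cols_det = np.nonzero(det)
    col_resid = np.full(rows_det.size, np.inf)
    for k in sorted(range(-radius, radius + 1), key=abs):
        r = rows_det + k
        valid = (r >= 0) & (r < height)
        hit = np.zeros(rows_det.size, dtype=bool)
        hit[valid] = ideal[r[valid], cols_det[valid]]
        col_resid = np.where(np.isinf(col_resid) & hit, abs(k), col_resid)
    d_adj = np.minimum(exact.distances, col_resid)

    return MatchResult(
        tp=tp_adj, fp=fp_adj, tn=exact.tn, fn=exact.n_ideal - tp_adj,
        n_roi=exact.n_roi, n_ideal=exact.n_ideal, n_actual=exact.n_actual,
        distances=d_adj,
    )


def adjusted_metrics(
    m_adj: MatchResult, alpha: float = DEFAULT_ALPHA
) -> tuple[float, float, float, float]:
    """(FOM_ADJ, TPR_ADJ, FPR_ADJ, ACC_ADJ) from an adjusted match.

    FOM_ADJ reuses the FOM form with the adjusted distances; TPR_ADJ and
    FPR_ADJ are both normalized by N_I; ACC_ADJ = (TP_ADJ + TN_ADJ) / N.
    """
    if m_adj.n_ideal == 0:
        raise ValueError("no ground-truth edge pixels: adjusted metrics undefined")
    fom_adj = fom(m_adj, alpha)
    tpr_adj = m_adj.tp / m_adj.n_ideal
    fpr_adj = m_adj.fp / m_adj.n_ideal
    acc_adj = (m_adj.tp + m_adj.tn) / m_adj.n_roi
    return fom_adj, tpr_adj, fpr_adj, acc_adj


@dataclass(frozen=True)
class MetricReport:
    """All nine metrics for one (image, detector) pair plus raw counts."""

    fom: float
    tpr: float
    fpr: float
    acc: float
    fom_adj: float
    tpr_adj: float
    fpr_adj: float
    acc_adj: float
    mld: float
    exact: MatchResult = field(repr=False)
    adjusted: MatchResult = field(repr=False)
    alpha: float = DEFAULT_ALPHA
    mld_neighborhood: int = DEFAULT_MLD_NEIGHBORHOOD
    adjust_radius: int = DEFAULT_ADJUST_RADIUS

    def to_dict(self) -> dict:
        """Flat dict of metrics and counts (for tables and JSON reports)."""
        return {
            "fom": self.fom, "tpr": self.tpr, "fpr": self.fpr, "acc": self.acc,
            "fom_adj": self.fom_adj, "tpr_adj": self.tpr_adj,
            "fpr_adj": self.fpr_adj, "acc_adj": self.acc_adj, "mld": self.mld,
            "tp": self.exact.tp, "fp": self.exact.fp,
            "tn": self.exact.tn, "fn": self.exact.fn,
            "tp_adj": self.adjusted.tp, "fp_adj": self.adjusted.fp,
            "n_roi": self.exact.n_roi, "n_ideal": self.exact.n_ideal,
            "n_actual": self.exact.n_actual,
            "alpha": self.alpha, "mld_neighborhood": self.mld_neighborhood,
            "adjust_radius": self.adjust_radius,
        }


def evaluate(
    detected: np.ndarray,
    truth: GroundTruth,
    alpha: float = DEFAULT_ALPHA,
    mld_neighborhood: int = DEFAULT_MLD_NEIGHBORHOOD,
    adjust_radius: int = DEFAULT_ADJUST_RADIUS,
    distance: str = "nearest",
) -> MetricReport:
    """Compute the full metric suite for one detected edge map."""
    m = match_exact(detected, truth, distance=distance)
    m_adj = match_adjusted(detected, truth, radius=adjust_radius)
    fom_adj, tpr_adj, fpr_adj, acc_adj = adjusted_metrics(m_adj, alpha)
    return MetricReport(
        fom=fom(m, alpha), tpr=tpr(m), fpr=fpr(m), acc=acc(m),
        fom_adj=fom_adj, tpr_adj=tpr_adj, fpr_adj=fpr_adj, acc_adj=acc_adj,
        mld=mld(detected, truth, mld_neighborhood),
        exact=m, adjusted=m_adj,
        alpha=alpha, mld_neighborhood=mld_neighborhood, adjust_radius=adjust_radius,
    )
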
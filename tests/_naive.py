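"""Brute-force double-loop reference for the metric suite.

Deliberately slow and literal: every definition is spelled out with
explicit loops over pixel coordinates so it shares no code path with the
library implementation.  Used only on tiny masks.
"""

import math

import numpy as np


def naive_metrics(detected, gt_edge, roi, alpha=1.0 / 9.0, mld_dist=3, adj_radius=2):
    """All nine metrics computed by exhaustive enumeration.

    Returns a dict with keys fom, tpr, fpr, acc, fom_adj, tpr_adj,
    fpr_adj, acc_adj, mld (mld is NaN when undefined).
    """
    H, W = detected.shape
    det = [(r, c) for r in range(H) for c in range(W) if detected[r, c] and roi[r, c]]
    gt = [(r, c) for r in range(H) for c in range(W) if gt_edge[r, c] and roi[r, c]]
    n_roi = int(sum(roi[r, c] for r in range(H) for c in range(W)))
    gt_set = set(gt)
    n_ideal, n_actual = len(gt), len(det)

    tp = sum(1 for p in det if p in gt_set)
    fp = n_actual - tp
    fn = n_ideal - tp
    tn = n_roi - tp - fp - fn

    # distance of each detected pixel to the nearest ground-truth pixel
    dists = []
    for (r, c) in det:
        best = math.inf
        for (gr, gc) in gt:
            best = min(best, math.hypot(r - gr, c - gc))
        dists.append(best)

    if n_actual == 0:
        fom = 0.0
    else:
        fom = sum(1.0 / (1.0 + alpha * d * d) for d in dists) / max(n_ideal, n_actual)
    tpr = tp / n_ideal
    fpr = 0.0 if n_actual == 0 else fp / n_actual
    acc = (tp + tn) / n_roi

    # MLD: per ground-truth pixel, mean |row offset| of detected pixels in
    # the same column within mld_dist rows; averaged over non-empty cases
    inner = []
    for (gr, gc) in gt:
        hits = [abs(k) for k in range(-mld_dist, mld_dist + 1)
                if 0 <= gr + k < H and detected[gr + k, gc] and roi[gr + k, gc]]
        if hits:
            inner.append(sum(hits) / len(hits))
    mld = sum(inner) / len(inner) if inner else float("nan")

    # adjusted matching: per-column neighborhoods of half-width adj_radius
    tp_adj = 0
    for (gr, gc) in gt:
        if any(0 <= gr + k < H and detected[gr + k, gc] and roi[gr + k, gc]
               for k in range(-adj_radius, adj_radius + 1)):
            tp_adj += 1
    matched = 0
    d_adj = []
    for (r, c), d_exact in zip(det, dists):
        resid = math.inf
        for (gr, gc) in gt:
            if gc == c and abs(gr - r) <= adj_radius:
                resid = min(resid, abs(gr - r))
        if resid < math.inf:
            matched += 1
        d_adj.append(min(d_exact, resid))
    fp_adj = n_actual - matched

    if n_actual == 0:
        fom_adj = 0.0
    else:
        fom_adj = sum(1.0 / (1.0 + alpha * d * d) for d in d_adj) / max(n_ideal, n_actual)
    tpr_adj = tp_adj / n_ideal
    fpr_adj = fp_adj / n_ideal
    acc_adj = (tp_adj + tn) / n_roi

    return {
        "fom": fom, "tpr": tpr, "fpr": fpr, "acc": acc,
        "fom_adj": fom_adj, "tpr_adj": tpr_adj, "fpr_adj": fpr_adj,
        "acc_adj": acc_adj, "mld": mld,
    }


def random_mask_pair(rng, shape=(16, 16)):
    """A random (detected, gt_edge, roi) triple with a non-empty ground truth."""
    H, W = shape
    r0 = int(rng.integers(0, H // 2))
    r1 = int(rng.integers(H // 2, H))
    roi = np.zeros(shape, dtype=bool)
    roi[r0 : r1 + 1] = True
    gt = (rng.random(shape) < 0.08) & roi
    if not gt.any():
        gt[int(rng.integers(r0, r1 + 1)), int(rng.integers(0, W))] = True
    detected = rng.random(shape) < rng.uniform(0.02, 0.25)
    return detected, gt, roi
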
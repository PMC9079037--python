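"""Independent reference implementations used as test oracles.

These deliberately re-derive results from first principles (straight loops,
textbook formulas, the canonical COCO evaluation procedure) without calling
the package's own vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# canonical per-keypoint annotation sigmas (17 COCO points + neck = shoulder)
_SIGMAS = [0.026, 0.025, 0.025, 0.035, 0.035, 0.079, 0.079, 0.072, 0.072,
           0.062, 0.062, 0.107, 0.107, 0.087, 0.087, 0.089, 0.089, 0.079]


def ref_oks(gt_xyv, det_xyv, area):
    """OKS of one GT/detection pair from (x, y, v) triplet lists."""
    total = 0.0
    n = 0
    for i, ((gx, gy, gv), (dx, dy, dv)) in enumerate(zip(gt_xyv, det_xyv)):
        if gv < 1:
            continue
        n += 1
        if dv < 1:
            continue
        d2 = (gx - dx) ** 2 + (gy - dy) ** 2
        kappa = 2.0 * _SIGMAS[i]
        total += math.exp(-d2 / (2.0 * area * kappa**2))
    if n == 0:
        raise ValueError("no labeled gt keypoints")
    return total / n


def _kps_to_triplets(kps):
    return [(float(kps.x[i]), float(kps.y[i]), int(kps.visibility[i]))
            for i in range(len(kps.x))]


def _score(kps):
    vals = [float(c) for c, v in zip(kps.confidence, kps.visibility) if v >= 1]
    return sum(vals) / len(vals) if vals else 0.0


def ref_evaluate_ap_ar(gt_frames, det_frames, max_dets=20):
    """Reference COCO keypoint AP / AP75 / AR following the canonical
    evaluation procedure (greedy confidence-ordered matching per threshold,
    101-point interpolated PR, thresholds .50:.05:.95)."""
    thresholds = [0.5 + 0.05 * i for i in range(10)]
    rec_grid = [i / 100.0 for i in range(101)]
    gt_frames = [[f] if not isinstance(f, list) else f for f in gt_frames]
    det_frames = [[f] if not isinstance(f, list) else f for f in det_frames]
    n_gt = sum(len(f) for f in gt_frames)
    aps, recalls = [], []
    for t in thresholds:
        records = []  # (score, tp)
        for gts, dets in zip(gt_frames, det_frames):
            dets_sorted = sorted(dets, key=_score, reverse=True)[:max_dets]
            taken = set()
            for det in dets_sorted:
                best_oks, best_g = -1.0, None
                for g, gt in enumerate(gts):
                    if g in taken:
                        continue
                    o = ref_oks(_kps_to_triplets(gt), _kps_to_triplets(det),
                                gt.scale_area)
                    if o > best_oks:
                        best_oks, best_g = o, g
                tp = best_g is not None and best_oks >= t
                if tp:
                    taken.add(best_g)
                records.append((_score(det), tp))
        records.sort(key=lambda r: -r[0])
        tps = 0
        prec, rec = [], []
        for k, (_, tp) in enumerate(records, start=1):
            tps += 1 if tp else 0
            prec.append(tps / k)
            rec.append(tps / n_gt)
        # monotone interpolated precision
        for k in range(len(prec) - 2, -1, -1):
            prec[k] = max(prec[k], prec[k + 1])
        q = []
        for r in rec_grid:
            idx = next((k for k, rv in enumerate(rec) if rv >= r), None)
            q.append(prec[idx] if idx is not None else 0.0)
        aps.append(sum(q) / len(q))
        recalls.append(rec[-1] if rec else 0.0)
    return {
        "AP": 100.0 * sum(aps) / len(aps),
        "AP75": 100.0 * aps[5],
        "AR": 100.0 * sum(recalls) / len(recalls),
    }


def brute_force_matching(gts, dets, threshold):
    """Best-total-OKS assignment of detections to GTs by exhausting
    permutations; returns the number of true positives."""
    n_d, n_g = len(dets), len(gts)
    best = (-1, -1.0)
    # try every assignment of detections to distinct gts (including leaving
    # detections unmatched), maximizing (tp count, total OKS)
    for det_subset in itertools.permutations(range(n_d), min(n_d, n_g)):
        for perm in itertools.permutations(range(n_g), len(det_subset)):
            total, tp = 0.0, 0
            for d, g in zip(det_subset, perm):
                o = ref_oks(_kps_to_triplets(gts[g]), _kps_to_triplets(dets[d]),
                            gts[g].scale_area)
                if o >= threshold:
                    tp += 1
                    total += o
            best = max(best, (tp, total))
    return best[0]


def ref_mae_sd(est, gt):
    errs = [abs(e - g) for e, g in zip(est, gt)]
    mae = sum(errs) / len(errs)
    if len(errs) < 2:
        return mae, 0.0
    mean = mae
    var = sum((e - mean) ** 2 for e in errs) / (len(errs) - 1)
    return mae, math.sqrt(var)


def ref_bland_altman(est, gt):
    diffs = [g - e for e, g in zip(est, gt)]
    means = [(g + e) / 2.0 for e, g in zip(est, gt)]
    md = sum(diffs) / len(diffs)
    var = sum((d - md) ** 2 for d in diffs) / (len(diffs) - 1)
    sd = math.sqrt(var)
    return md, sd, md - 1.96 * sd, md + 1.96 * sd, means, diffs


def ref_resample_mean(image, rmap, irt_size):
    """Brute-force bilinear resampling mean over the valid mask."""
    w_irt, h_irt = irt_size
    h, w = image.shape
    vals = []
    for v in range(h_irt):
        for u in range(w_irt):
            x, y = rmap.apply_inverse([[u, v]])[0]
            if not (rmap.crop_x <= x <= w - 1 - rmap.crop_x
                    and rmap.crop_y <= y <= h - 1 - rmap.crop_y):
                continue
            x0, y0 = int(math.floor(x)), int(math.floor(y))
            x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
            fx, fy = x - x0, y - y0
            val = (image[y0, x0] * (1 - fx) * (1 - fy)
                   + image[y0, x1] * fx * (1 - fy)
                   + image[y1, x0] * (1 - fx) * fy
                   + image[y1, x1] * fx * fy)
            vals.append(val)
    return (sum(vals) / len(vals)) if vals else float("nan"), len(vals)
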
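"""Detection-side pure math: the ECIoU box-regression loss, the
precision/recall/AP/mAP evaluation chain, greedy IoU matching, and a
deterministic forward pass of bi-level routing attention (BRA).

Nothing here trains or differentiates; these are reference computations
on plain numpy arrays.

ECIoU loss
----------
Combines the CIoU aspect-ratio penalty with EIoU's separate width and
height distance terms::

    loss = 1 - IoU + alpha * v
           + rho2(b_gt, b) / c^2 + rho2(h_gt, h) / c_h^2 + rho2(w_gt, w) / c_w^2

with v = (4 / pi^2) * (arctan(w_gt / h_gt) - arctan(w / h))^2 and
alpha = v / ((1 - IoU) + v) (the CIoU trade-off weight; 0 when v = 0),
and c, c_w, c_h the diagonal/width/height of the smallest enclosing box.
The CIoU penalty first drives the aspect ratio into range; the per-edge
EIoU terms then tune each side, which speeds up box regression.

Average precision
-----------------
AP is the all-point interpolated area under the precision-recall curve
(detections sorted by descending score, ties kept in input order); mAP is
the unweighted mean of the per-class APs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in corner format with continuous coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class EclouTerms:
    iou: float
    v: float
    alpha: float
    rho2_center: float
    rho2_w: float
    rho2_h: float
    c2: float
    c2_w: float
    c2_h: float


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 for disjoint boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def eclou_loss(pred: Box, gt: Box) -> tuple[float, EclouTerms]:
    """ECIoU loss between a predicted and a ground-truth box."""
    i = iou(pred, gt)
    v = (4.0 / math.pi**2) * (math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - i) + v)
    pc, gc = pred.center, gt.center
    rho2_center = (pc[0] - gc[0]) ** 2 + (pc[1] - gc[1]) ** 2
    rho2_w = (pred.width - gt.width) ** 2
    rho2_h = (pred.height - gt.height) ** 2
    enc_w = max(pred.x_max, gt.x_max) - min(pred.x_min, gt.x_min)
    enc_h = max(pred.y_max, gt.y_max) - min(pred.y_min, gt.y_min)
    c2 = enc_w**2 + enc_h**2
    terms = EclouTerms(i, v, alpha, rho2_center, rho2_w, rho2_h, c2, enc_w**2, enc_h**2)
    loss = (1.0 - i) + alpha * v + rho2_center / c2 + rho2_h / enc_h**2 + rho2_w / enc_w**2
    return loss, terms


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float, bool]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); 0/0 reported as 0 with a flag."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    undefined = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, True
    return precision, recall, undefined


def average_precision(detections: list[tuple[float, bool]], n_gt: int) -> float:
    """All-point interpolated AP from (score, is_tp) pairs.

    Detections are sorted by descending score (stable, so ties keep input
    order); AP = sum_i (r_i - r_{i-1}) * max_{j >= i} p_j.
    """
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    if not detections:
        return 0.0
    order = sorted(range(len(detections)), key=lambda i: -detections[i][0])
    flags = np.array([bool(detections[i][1]) for i in order])
    cum_tp = np.cumsum(flags)
    cum_fp = np.cumsum(~flags)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # right-to-left running max gives the interpolated precision envelope
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(class_aps: dict[str, float] | list[float]) -> float:
    """Unweighted mean of the per-class APs."""
    vals = list(class_aps.values()) if isinstance(class_aps, dict) else list(class_aps)
    if not vals:
        raise ValueError("no classes")
    return float(np.mean(vals))


def match_detections(
    pred_boxes: list[Box],
    scores: list[float],
    pred_labels: list,
    gt_boxes: list[Box],
    gt_labels: list,
    iou_thresh: float = 0.5,
) -> list[bool]:
    """Greedy per-class matching by descending score.

    A detection is a true positive iff its best-IoU unmatched ground-truth
    box of the same class reaches ``iou_thresh``; each ground truth
    matches at most once.  Returns one flag per detection, input order.
    """
    flags = [False] * len(pred_boxes)
    for cls in set(pred_labels) | set(gt_labels):
        det_idx = [i for i, l in enumerate(pred_labels) if l == cls]
        det_idx.sort(key=lambda i: -scores[i])
        gt_idx = [j for j, l in enumerate(gt_labels) if l == cls]
        used = set()
        for i in det_idx:
            best_j, best_iou = None, 0.0
            for j in gt_idx:
                if j in used:
                    continue
                ov = iou(pred_boxes[i], gt_boxes[j])
                if ov > best_iou:
                    best_j, best_iou = j, ov
            if best_j is not None and best_iou >= iou_thresh:
                flags[i] = True
                used.add(best_j)
    return flags


def evaluate_detections(pred_df: pd.DataFrame, gt_df: pd.DataFrame, iou_thresh: float = 0.5) -> pd.DataFrame:
    """Per-class AP (and counts) from prediction/ground-truth tables.

    Both tables use the annotation CSV schema: columns image, class,
    x_min, y_min, x_max, y_max and (predictions only) score.  Returns one
    row per class plus a summary mAP row.
    """
    classes = sorted(set(gt_df["class"]))
    rows = []
    aps = {}
    for cls in classes:
        dets: list[tuple[float, bool]] = []
        n_gt = 0
        for image in sorted(set(gt_df["image"]) | set(pred_df["image"])):
            g = gt_df[(gt_df["image"] == image) & (gt_df["class"] == cls)]
            p = pred_df[(pred_df["image"] == image) & (pred_df["class"] == cls)]
            gtb = [Box(r.x_min, r.y_min, r.x_max, r.y_max) for r in g.itertuples()]
            pb = [Box(r.x_min, r.y_min, r.x_max, r.y_max) for r in p.itertuples()]
            sc = list(p["score"])
            flags = match_detections(pb, sc, [cls] * len(pb), gtb, [cls] * len(gtb), iou_thresh)
            dets.extend(zip(sc, flags))
            n_gt += len(gtb)
        ap = average_precision(dets, n_gt) if n_gt > 0 else 0.0
        aps[cls] = ap
        tp = sum(1 for _, f in dets if f)
        rows.append({"class": cls, "n_gt": n_gt, "n_det": len(dets), "tp": tp, "ap": ap})
    rows.append({"class": "mAP", "n_gt": sum(r["n_gt"] for r in rows), "n_det": sum(r["n_det"] for r in rows),
                 "tp": sum(r["tp"] for r in rows), "ap": mean_average_precision(aps)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bi-level routing attention forward pass
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BraSpec:
    """Inputs of one BRA forward pass.

    x : H x W x C feature map
    regions : S regions per side (S must divide H and W)
    top_k : number of routed regions per query region (1 <= k <= S^2)
    wq, wk, wv : C x C projection weights
    lce_kernel : 5 x 5 x C depthwise kernel for local context enhancement
    """

    x: np.ndarray
    regions: int
    top_k: int
    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    lce_kernel: np.ndarray

    def __post_init__(self):
        h, w, c = self.x.shape
        s = self.regions
        if h % s or w % s:
            raise ValueError(f"region count {s} must divide H={h} and W={w}")
        if not (1 <= self.top_k <= s * s):
            raise ValueError(f"top_k {self.top_k} out of range for S^2={s * s}")
        for name, m in (("wq", self.wq), ("wk", self.wk), ("wv", self.wv)):
            if m.shape != (c, c) or not np.isfinite(m).all():
                raise ValueError(f"{name} must be a finite {c}x{c} matrix")
        if self.lce_kernel.shape != (5, 5, c):
            raise ValueError("lce_kernel must be 5 x 5 x C")


def _softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _depthwise_conv5(v_map: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Depthwise 5x5 cross-correlation with zero padding, per channel."""
    h, w, c = v_map.shape
    pad = np.zeros((h + 4, w + 4, c))
    pad[2:-2, 2:-2] = v_map
    out = np.zeros_like(v_map)
    for dy in range(5):
        for dx in range(5):
            out += pad[dy : dy + h, dx : dx + w] * kernel[dy, dx]
    return out


def _to_regions(x: np.ndarray, s: int) -> np.ndarray:
    """H x W x C -> (S^2, HW/S^2, C), region-major, row-major tokens."""
    h, w, c = x.shape
    rh, rw = h // s, w // s
    return x.reshape(s, rh, s, rw, c).transpose(0, 2, 1, 3, 4).reshape(s * s, rh * rw, c)


def _from_regions(r: np.ndarray, s: int, h: int, w: int) -> np.ndarray:
    rh, rw = h // s, w // s
    c = r.shape[-1]
    return r.reshape(s, s, rh, rw, c).transpose(0, 2, 1, 3, 4).reshape(h, w, c)


def bra_forward(spec: BraSpec) -> np.ndarray:
    """Deterministic bi-level routing attention forward pass.

    Region-level affinities route each query region to its top-k key
    regions (ties broken toward the lower region index); token-to-token
    scaled-dot-product attention then runs over the gathered key/value
    pairs, and a depthwise-convolution local-context term on V is added.
    """
    h, w, c = spec.x.shape
    s = spec.regions
    xr = _to_regions(spec.x, s)  # (S^2, T, C)
    q = xr @ spec.wq
    k = xr @ spec.wk
    v = xr @ spec.wv

    qr = q.mean(axis=1)  # (S^2, C) region descriptors
    kr = k.mean(axis=1)
    ar = qr @ kr.T  # (S^2, S^2) region affinity

    # top-k routed regions per query region, ties to the lower index
    order = np.argsort(-ar, axis=1, kind="stable")
    routed = order[:, : spec.top_k]  # (S^2, k)

    n_regions = s * s
    out_r = np.empty_like(q)
    scale = 1.0 / math.sqrt(c)
    for r in range(n_regions):
        kg = k[routed[r]].reshape(-1, c)  # (k*T, C)
        vg = v[routed[r]].reshape(-1, c)
        attn = _softmax(q[r] @ kg.T * scale, axis=1)
        out_r[r] = attn @ vg
    out = _from_regions(out_r, s, h, w)
    v_map = _from_regions(v, s, h, w)
    return out + _depthwise_conv5(v_map, spec.lce_kernel)


def dense_attention_with_lce(spec: BraSpec) -> np.ndarray:
    """Full (unrouted) attention over all tokens plus the LCE term.

    Independent reference for :func:`bra_forward`: with k = S^2 routing is
    vacuous and both must agree.
    """
    h, w, c = spec.x.shape
    tokens = spec.x.reshape(-1, c)
    q = tokens @ spec.wq
    k = tokens @ spec.wk
    v = tokens @ spec.wv
    attn = _softmax(q @ k.T / math.sqrt(c), axis=1)
    out = (attn @ v).reshape(h, w, c)
    return out + _depthwise_conv5(v.reshape(h, w, c), spec.lce_kernel)
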
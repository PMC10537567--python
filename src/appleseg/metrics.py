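"""Segmentation objectives and evaluation metrics.

The training objective is the Focal Tversky Loss for the defect class:

    TI  = (sum p*g + eps) / (sum p*g + a*sum (1-p)*g + (1-a)*sum p*(1-g) + eps)
    FTL = (1 - TI)^(1/gamma)

where ``p`` is the predicted defect probability per pixel, ``g`` the
binary ground truth, sums run over all pixels of one image.  ``alpha``
trades the false-negative against the false-positive penalty (larger
alpha -> more recall-oriented), ``gamma`` focuses the loss on poorly
segmented images, and ``eps`` stabilises the empty-defect case.

Evaluation reports the pixel-wise f-score / precision / recall and the
Class-Specific Recognition Error

    CSRE = (FN/(TP+FN) + FP/(TN+FP)) / 2,

the mean of the false-negative and false-positive rates (one minus
balanced accuracy), which stays informative for very small defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core_data import MACRO_CLASSES, SUB_CLASSES


@dataclass
class LossConfig:
    alpha: float = 0.5
    gamma: float = 0.75
    epsilon: float = 1e-6
    include_background: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0,1]")
        if self.gamma <= 0 or self.epsilon <= 0:
            raise ValueError("gamma and epsilon must be positive")


@dataclass
class ConfusionCounts:
    """Pixel tallies; TP+FP+TN+FN equals the number of scored pixels."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def n(self):
        return self.tp + self.fp + self.tn + self.fn


class FScore(NamedTuple):
    f: float
    precision: float
    recall: float


def _check_pair(prob, gt):
    prob = np.asarray(prob, dtype=np.float64)
    gt = np.asarray(gt)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {gt.shape}")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    u = np.unique(gt)
    if not np.isin(u, (0, 1)).all():
        raise ValueError("ground truth must be binary")
    return prob, gt.astype(np.float64)


def tversky_index(prob, gt, cfg: LossConfig | None = None) -> float:
    """Tversky overlap of a probability map with a binary mask (defect class)."""
    cfg = cfg or LossConfig()
    prob, gt = _check_pair(prob, gt)
    a, eps = cfg.alpha, cfg.epsilon
    tp = float((prob * gt).sum())
    fn = float(((1.0 - prob) * gt).sum())
    fp = float((prob * (1.0 - gt)).sum())
    return (tp + eps) / (tp + a * fn + (1.0 - a) * fp + eps)


def focal_tversky_loss(prob, gt, cfg: LossConfig | None = None) -> float:
    """Focal Tversky Loss ``(1-TI)^(1/gamma)`` for one image.

    With ``include_background`` the complementary (healthy-class) term is
    added, mirroring the multi-class sum; the default scores the defect
    class only, matching the binary sigmoid head.
    """
    cfg = cfg or LossConfig()
    loss = (1.0 - tversky_index(prob, gt, cfg)) ** (1.0 / cfg.gamma)
    if cfg.include_background:
        prob, gt = _check_pair(prob, gt)
        bg = LossConfig(alpha=cfg.alpha, gamma=cfg.gamma, epsilon=cfg.epsilon)
        loss += (1.0 - tversky_index(1.0 - prob, 1.0 - gt, bg)) ** (1.0 / cfg.gamma)
    return loss


def focal_tversky_loss_grad(prob, gt, cfg: LossConfig | None = None):
    """Loss value and its analytic gradient w.r.t. ``prob`` (defect class)."""
    cfg = cfg or LossConfig()
    prob, gt = _check_pair(prob, gt)
    a, eps, gamma = cfg.alpha, cfg.epsilon, cfg.gamma
    tp = (prob * gt).sum()
    fn = ((1.0 - prob) * gt).sum()
    fp = (prob * (1.0 - gt)).sum()
    num = tp + eps
    den = tp + a * fn + (1.0 - a) * fp + eps
    ti = num / den
    one_minus = max(1.0 - ti, 1e-12)
    loss = one_minus ** (1.0 / gamma)
    dl_dti = -(1.0 / gamma) * one_minus ** (1.0 / gamma - 1.0)
    # d ti / d p_i = (g_i * den - num * dden_i) / den^2,
    # dden_i = g_i - a*g_i + (1-a)*(1-g_i)
    dden = gt - a * gt + (1.0 - a) * (1.0 - gt)
    dti = (gt * den - num * dden) / (den * den)
    return float(loss), dl_dti * dti


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact pixel tallies of a binary prediction against a binary mask."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for arr, name in ((pred, "prediction"), (gt, "ground truth")):
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    return ConfusionCounts(
        tp=int((pred & gt).sum()), fp=int((pred & ~gt).sum()),
        tn=int((~pred & ~gt).sum()), fn=int((~pred & gt).sum()))


def _rate(num, den):
    return num / den if den > 0 else 0.0


def csre(c: ConfusionCounts) -> float:
    """Class-Specific Recognition Error: mean of FN-rate and FP-rate."""
    return 0.5 * (_rate(c.fn, c.tp + c.fn) + _rate(c.fp, c.tn + c.fp))


def f_score(c: ConfusionCounts) -> FScore:
    """Pixel-wise (f, precision, recall); 0/0 terms are defined as 0."""
    precision = _rate(c.tp, c.tp + c.fp)
    recall = _rate(c.tp, c.tp + c.fn)
    f = _rate(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return FScore(f=f, precision=precision, recall=recall)


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvaluatedSample:
    """A test image with its binarized prediction, ready for scoring."""

    sample_id: str
    pred_mask: np.ndarray
    gt_mask: np.ndarray
    defects: list = field(default_factory=list)  # DefectAnnotation list

    @property
    def is_healthy(self):
        return not np.any(self.gt_mask)


def _image_row(c: ConfusionCounts):
    fs = f_score(c)
    return {"csre": csre(c), "f_score": fs.f,
            "precision": fs.precision, "recall": fs.recall}


@dataclass
class MetricReport:
    """Overall + per-class metric tables (per-image means and pooled counts)."""

    overall: pd.DataFrame
    per_image: pd.DataFrame
    macro: pd.DataFrame | None = None
    sub: pd.DataFrame | None = None

    def save(self, outdir):
        import json
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.overall.to_csv(outdir / "overall.csv", index=False)
        self.per_image.to_csv(outdir / "per_image.csv", index=False)
        blob = {"overall": self.overall.to_dict(orient="records")}
        for name in ("macro", "sub"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"per_class_{name}.csv", index=False)
                blob[name] = df.to_dict(orient="records")
        (outdir / "report.json").write_text(json.dumps(blob, indent=2))


def overall_report(samples: list[EvaluatedSample],
                   include_healthy: bool = False) -> MetricReport:
    """Score a set of evaluated images.

    By default only defective images are scored (the per-class defect
    tables are the primary readout); ``include_healthy`` opts healthy
    test images into the pool.
    """
    scored = [s for s in samples if include_healthy or not s.is_healthy]
    if not scored:
        raise ValueError("no images to score")
    rows, pooled = [], ConfusionCounts()
    for s in scored:
        c = confusion(s.pred_mask, s.gt_mask)
        pooled = pooled + c
        rows.append({"sample_id": s.sample_id, **_image_row(c)})
    per_image = pd.DataFrame(rows)
    mean_row = {"aggregation": "mean_per_image",
                **per_image[["csre", "f_score", "precision", "recall"]]
                .mean().to_dict()}
    pooled_row = {"aggregation": "pooled_counts", **_image_row(pooled)}
    return MetricReport(overall=pd.DataFrame([mean_row, pooled_row]),
                        per_image=per_image)


def per_class_report(samples: list[EvaluatedSample], level: str = "macro"
                     ) -> pd.DataFrame:
    """Per-defect-class metric table.

    For each class, images containing that class are scored with the
    ground-truth positives restricted to the class's own pixels; pixels
    of *other* defect classes are excluded from the tallies (ignore
    label), so a detection there counts neither for nor against.
    Per-image metrics are averaged.  Classes absent from the set are
    omitted with a warning.
    """
    import warnings

    if level not in ("macro", "sub"):
        raise ValueError("level must be 'macro' or 'sub'")
    attr = "macro_class" if level == "macro" else "sub_class"
    universe = MACRO_CLASSES if level == "macro" else SUB_CLASSES
    rows = []
    for cls in universe:
        per_image = []
        for s in samples:
            anns = [a for a in s.defects if getattr(a, attr) == cls]
            if not anns:
                continue
            cls_mask = np.zeros_like(s.gt_mask, dtype=bool)
            for a in anns:
                cls_mask |= a.defect_mask.astype(bool)
            ignore = s.gt_mask.astype(bool) & ~cls_mask
            keep = ~ignore
            c = confusion(s.pred_mask.astype(bool)[keep].astype(np.uint8),
                          cls_mask[keep].astype(np.uint8))
            per_image.append(_image_row(c))
        if not per_image:
            warnings.warn(f"class {cls!r} absent from the evaluated set; "
                          "row omitted")
            continue
        df = pd.DataFrame(per_image)
        rows.append({"class": cls, "n_images": len(per_image),
                     **df.mean().to_dict()})
    return pd.DataFrame(rows)
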
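"""Evaluation: confusion-matrix metrics, one-way ANOVA, class-activation maps.

Per-class metrics follow the one-vs-rest accounting: precision TP/(TP+FP),
recall TP/(TP+FN), F1 the harmonic mean of the two; accuracy is the trace
over the total.  Aggregates are reported in three modes — unweighted class
mean, support-weighted mean, and the harmonic mean applied to the aggregate
precision/recall — because published tables mix these conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .nn import Module, Tensor

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "AnovaResult",
    "confusion",
    "metrics_report",
    "harmonic_f1",
    "one_way_anova",
    "grad_cam",
]


class InvalidInputError(ValueError):
    pass


# ----------------------------------------------------------------- confusion
@dataclass(frozen=True)
class ConfusionMatrix:
    matrix: np.ndarray  # (i, j): true i, predicted j
    class_names: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def per_class(self, c: int) -> dict[str, int]:
        m = self.matrix
        tp = int(m[c, c])
        fp = int(m[:, c].sum() - tp)
        fn = int(m[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}

    @property
    def supports(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def confusion(labels_true, labels_pred, n_classes: int, class_names=None) -> ConfusionMatrix:
    yt = np.asarray(labels_true, dtype=int)
    yp = np.asarray(labels_pred, dtype=int)
    if yt.shape != yp.shape:
        raise InvalidInputError("label sequences must have equal length")
    if yt.size and (
        yt.min() < 0 or yp.min() < 0 or yt.max() >= n_classes or yp.max() >= n_classes
    ):
        raise InvalidInputError("label out of range")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (yt, yp), 1)
    names = tuple(class_names) if class_names else tuple(str(i) for i in range(n_classes))
    return ConfusionMatrix(matrix=m, class_names=names)


# ------------------------------------------------------------------- metrics
def _pct(x: float) -> float:
    return round(100.0 * x, 2)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("degenerate class: zero denominator for %s, reporting 0", what)
        return 0.0
    return num / den


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2·P·R/(P+R) on whatever scale P and R share (here: percent)."""
    if precision + recall == 0:
        return 0.0
    return round(2.0 * precision * recall / (precision + recall), 2)


@dataclass(frozen=True)
class MetricsReport:
    class_names: tuple[str, ...]
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    per_class_f1: dict[str, float]
    accuracy: float
    aggregates: dict[str, dict[str, float]]  # mode -> {precision, recall, f1}
    default_mode: str = "harmonic_of_aggregates"

    @property
    def precision(self) -> float:
        return self.aggregates[self.default_mode]["precision"]

    @property
    def recall(self) -> float:
        return self.aggregates[self.default_mode]["recall"]

    @property
    def f1(self) -> float:
        return self.aggregates[self.default_mode]["f1"]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                name: {
                    "precision": self.per_class_precision[name],
                    "recall": self.per_class_recall[name],
                    "f1": self.per_class_f1[name],
                }
                for name in self.class_names
            },
            "aggregates": self.aggregates,
        }


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise InvalidInputError("empty confusion matrix")
    precisions, recalls, f1s = [], [], []
    for c in range(cm.n_classes):
        counts = cm.per_class(c)
        p = _safe_div(counts["TP"], counts["TP"] + counts["FP"], f"precision[{c}]")
        r = _safe_div(counts["TP"], counts["TP"] + counts["FN"], f"recall[{c}]")
        precisions.append(p)
        recalls.append(r)
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    supports = cm.supports / cm.total
    agg = {}
    macro_p, macro_r = float(np.mean(precisions)), float(np.mean(recalls))
    agg["macro"] = {
        "precision": _pct(macro_p),
        "recall": _pct(macro_r),
        "f1": _pct(float(np.mean(f1s))),
    }
    w_p = float(np.dot(supports, precisions))
    w_r = float(np.dot(supports, recalls))
    agg["weighted"] = {
        "precision": _pct(w_p),
        "recall": _pct(w_r),
        "f1": _pct(float(np.dot(supports, f1s))),
    }
    agg["harmonic_of_aggregates"] = {
        "precision": _pct(w_p),
        "recall": _pct(w_r),
        "f1": harmonic_f1(_pct(w_p), _pct(w_r)),
    }
    names = cm.class_names
    return MetricsReport(
        class_names=names,
        per_class_precision={n: _pct(p) for n, p in zip(names, precisions)},
        per_class_recall={n: _pct(r) for n, r in zip(names, recalls)},
        per_class_f1={n: _pct(f) for n, f in zip(names, f1s)},
        accuracy=_pct(np.trace(cm.matrix) / cm.total),
        aggregates=agg,
    )


# --------------------------------------------------------------------- ANOVA
@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    f_crit: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    alpha: float = 0.05

    def to_row(self) -> dict:
        return {
            "F": self.F,
            "p_value": self.p_value,
            "F_crit": self.f_crit,
            "df_between": self.df_between,
            "df_within": self.df_within,
        }


def one_way_anova(groups, alpha: float = 0.05) -> AnovaResult:
    """Between/within sum-of-squares decomposition with the F test.

    A zero within-group variance with identical group means yields F = 0; a
    zero within-group variance with distinct means is reported as F = inf
    with p = 0 rather than an error.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    f_crit = float(stats.f.ppf(1 - alpha, df_b, df_w))
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, f_crit, df_b, df_w, 0.0, 0.0, 0.0, alpha)
        return AnovaResult(
            float("inf"), 0.0, f_crit, df_b, df_w, ss_between, 0.0, ss_between, alpha
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        float(F), p, f_crit, df_b, df_w,
        float(ss_between), float(ss_within), float(ss_between + ss_within), alpha,
    )


# ------------------------------------------------------------------ Grad-CAM
def grad_cam(
    model: Module,
    image: np.ndarray,
    target_layer: str | None = None,
    target_class: int | None = None,
) -> np.ndarray:
    """Gradient-weighted activation heatmap, upsampled to the input size.

    Channel weights are the spatial means of the class-score gradient at the
    target layer; the weighted activation sum is ReLU-rectified, min-max
    normalized to [0, 1] and bilinearly resized to the input resolution.
    Default target layer: the last block of the last stage.
    """
    names = dict(model.named_modules())
    if target_layer is None:
        stage_blocks = [n for n in names if n.startswith("stage4.") and n.count(".") == 1]
        if not stage_blocks:
            raise InvalidInputError("model has no stage4; pass target_layer explicitly")
        target_layer = sorted(stage_blocks)[-1]
    if target_layer not in names:
        available = [n for n in names if n and n.count(".") <= 1]
        raise InvalidInputError(
            f"unknown layer {target_layer!r}; available: {available}"
        )
    target = names[target_layer]

    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    was_training = model.training
    model.eval()
    object.__setattr__(target, "_record_output", True)
    try:
        logits = model(Tensor(x))
        if target_class is None:
            target_class = int(np.argmax(logits.data[0]))
        model.zero_grad()
        grad = np.zeros_like(logits.data)
        grad[0, target_class] = 1.0
        logits.backward(grad)
        act: Tensor = target._last_output
        weights = act.grad.mean(axis=(2, 3), keepdims=True)  # (1, C, 1, 1)
        cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
    finally:
        object.__setattr__(target, "_record_output", False)
        object.__setattr__(target, "_last_output", None)
        model.train(was_training)

    H, W = x.shape[2], x.shape[3]
    if cam.shape != (H, W):
        zoom = (H / cam.shape[0], W / cam.shape[1])
        cam = ndimage.zoom(cam, zoom, order=1)
        cam = np.maximum(cam, 0.0)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return cam.astype(np.float32)
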
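"""Classification metrics, binary collapse, Grad-CAM and ROI agreement.

Metrics are computed on argmax-of-logits predictions: overall accuracy,
per-class precision/recall/F1 (zero-division reported as 0 with a flag,
since minority classes can receive no predictions at all), a truth-by-
prediction confusion matrix, and the accuracy of the collapsed binary task
(any-pneumonia vs healthy).  Grad-CAM heatmaps are built from the same
last-convolutional-block feature map the distillation loss uses, and the
agreement between a heatmap and an expert lesion mask is summarized as the
fraction of heatmap mass falling inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .data import preprocess
from .models import FeatureClassifier
from .synthetic import HEALTHY


@dataclass
class EvaluationReport:
    overall_accuracy: float          # percent
    precision: np.ndarray            # per class, fractions
    recall: np.ndarray
    f1: np.ndarray
    confusion_matrix: np.ndarray     # (n_classes, n_classes) ints, rows = truth
    binary_accuracy: float           # percent, pneumonia vs healthy
    n_samples: int
    n_classes: int = 5
    zero_division_classes: list = field(default_factory=list)


def evaluate_predictions(y_true, y_pred, n_classes: int = 5) -> EvaluationReport:
    """Metrics from label/prediction vectors (the model-free core)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    labels = np.arange(n_classes)
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    zero_div = [int(c) for c in labels
                if cm[:, c].sum() == 0 or cm[c, :].sum() == 0]
    acc = 100.0 * float((y_true == y_pred).mean())
    return EvaluationReport(
        overall_accuracy=acc, precision=prec, recall=rec, f1=f1,
        confusion_matrix=cm,
        binary_accuracy=binary_collapse_accuracy(y_true, y_pred),
        n_samples=int(y_true.size), n_classes=n_classes,
        zero_division_classes=zero_div,
    )


def predict(model: FeatureClassifier, batch: np.ndarray,
            batch_size: int = 64) -> np.ndarray:
    """Argmax predictions for a preprocessed (N, C, H, W) tensor."""
    preds = []
    for i in range(0, len(batch), batch_size):
        logits, _ = model.forward(batch[i:i + batch_size], train=False)
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: FeatureClassifier, batch: np.ndarray, labels,
             n_classes: int | None = None) -> EvaluationReport:
    """Evaluate a trained model on a preprocessed validation tensor."""
    if len(batch) == 0:
        raise ValueError("cannot evaluate on an empty validation set")
    n_classes = n_classes if n_classes is not None else model.config.n_classes
    return evaluate_predictions(np.asarray(labels), predict(model, batch), n_classes)


def binary_collapse_accuracy(y_true, y_pred) -> float:
    """Accuracy (%) after collapsing every disease class to 'pneumonia'.

    Never below the multiclass accuracy: collapsing can only merge errors
    among disease classes into correct binary calls.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return 100.0 * float(((y_true != HEALTHY) == (y_pred != HEALTHY)).mean())


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass
class AttributionMap:
    """Non-negative heatmap at input resolution, max-normalized to [0, 1]."""

    heatmap: np.ndarray
    target_class: int
    feature_shape: tuple


def gradcam(model: FeatureClassifier, image: np.ndarray,
            target_class: int) -> AttributionMap:
    """Grad-CAM at the last convolutional block.

    Channel weights are the spatially averaged gradients of the target
    logit w.r.t. the feature map; the heatmap is the rectified weighted sum
    of channels, bilinearly upsampled to the input size and max-normalized
    (an all-zero map stays all-zero).

    ``image`` is either an (H, W, 3) image (preprocessed internally at its
    own resolution) or an already-preprocessed (C, H, W) tensor.
    """
    if not 0 <= target_class < model.config.n_classes:
        raise ValueError(f"target_class {target_class} out of range for "
                         f"{model.config.n_classes} classes")
    if image.ndim == 3 and image.shape[2] == 3 and image.shape[0] != 3:
        x = preprocess(image, target_size=image.shape[0])[None]
    elif image.ndim == 3:
        x = image[None].astype(np.float32)
    else:
        raise ValueError(f"expected an image, got shape {image.shape}")

    logits, fmap = model.forward(x, train=False)
    onehot = np.zeros_like(logits)
    onehot[0, target_class] = 1.0
    dfmap = model.head_feature_gradient(onehot)          # (1, C, H', W')
    weights = dfmap.mean(axis=(2, 3))                    # (1, C)
    cam = np.maximum((weights[:, :, None, None] * fmap).sum(axis=1)[0], 0.0)

    from skimage.transform import resize

    h, w = x.shape[2], x.shape[3]
    heat = resize(cam, (h, w), order=1, anti_aliasing=False,
                  preserve_range=True).astype(np.float32)
    heat = np.maximum(heat, 0.0)
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return AttributionMap(heatmap=heat, target_class=int(target_class),
                          feature_shape=tuple(fmap.shape[1:]))


def attribution_roi_overlap(attribution: AttributionMap | np.ndarray,
                            lesion_mask: np.ndarray) -> float:
    """Fraction of heatmap mass inside the lesion mask, in [0, 1]."""
    heat = attribution.heatmap if isinstance(attribution, AttributionMap) else attribution
    if heat.shape != lesion_mask.shape:
        raise ValueError(f"heatmap {heat.shape} vs mask {lesion_mask.shape} size mismatch")
    total = float(heat.sum())
    if total == 0.0:
        return 0.0
    return float(heat[lesion_mask.astype(bool)].sum()) / total


def save_heatmap_overlay(image: np.ndarray, attribution: AttributionMap,
                         path) -> None:
    """Write a PNG of the image with the heatmap blended on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image)
    ax.imshow(attribution.heatmap, cmap="jet", alpha=0.4)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def format_report(report: EvaluationReport, class_names=None) -> str:
    """Render a report as a delimited metrics table plus confusion matrix."""
    names = list(class_names) if class_names is not None else [
        f"class_{i}" for i in range(report.n_classes)]
    lines = ["label\tprecision\trecall\tf1"]
    for i, name in enumerate(names):
        lines.append(f"{name}\t{report.precision[i]:.4f}\t"
                     f"{report.recall[i]:.4f}\t{report.f1[i]:.4f}")
    lines.append(f"overall_accuracy\t{report.overall_accuracy:.2f}%")
    lines.append(f"binary_accuracy\t{report.binary_accuracy:.2f}%")
    lines.append("confusion_matrix (rows = truth)")
    for row in report.confusion_matrix:
        lines.append("\t".join(str(int(v)) for v in row))
    return "\n".join(lines)
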
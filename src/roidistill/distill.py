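"""Consistency-weight schedule and the combined distillation loss.

The combined loss is a convex combination of a feature-map consistency
term and the usual classification term,

    L_C = alpha_e * MSE(f_t, f_s) + (1 - alpha_e) * CE(logits_s, Y),

where ``f_t``/``f_s`` are the last-convolutional-layer feature maps of the
frozen teacher (fed the ROI image) and the student (fed the raw image).
The weight decays linearly from 0.5 at epoch 0 to 0 at ``e_distill``:

    alpha_e = 0.5 * (1 - e / e_distill)   for e < e_distill,   else 0.

Epochs at or beyond ``e_distill`` are therefore plain cross-entropy
fine-tuning.  The MSE reduction is the global mean over batch, channel and
spatial axes; the CE reduction is the batch mean.  Teacher quantities are
treated as constants: no gradient flows into the teacher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class DistillationSchedule:
    """Distillation epoch budget: ``e_distill`` guided epochs within
    ``e_total`` total student epochs."""

    e_distill: int
    e_total: int

    def __post_init__(self):
        if self.e_distill < 1:
            raise ValueError(
                "e_distill must be a positive integer; a schedule with 0 "
                "guided epochs degenerates to plain CE training"
            )
        if self.e_total < self.e_distill:
            raise ValueError("e_total must be >= e_distill")


def alpha_weight(e: int, schedule: DistillationSchedule) -> float:
    """Consistency weight at epoch ``e`` (0-based); in [0, 0.5], 0 after
    the distillation phase, strictly decreasing before it."""
    if e < 0:
        raise ValueError("epoch index must be >= 0")
    if e < schedule.e_distill:
        return 0.5 * (1.0 - e / schedule.e_distill)
    return 0.0


def consistency_mse(teacher_map: np.ndarray, student_map: np.ndarray) -> float:
    """Mean squared difference over all feature-map elements."""
    if teacher_map.shape != student_map.shape:
        raise ValueError(
            f"feature-map shape mismatch: teacher {teacher_map.shape} vs "
            f"student {student_map.shape}"
        )
    d = teacher_map.astype(np.float64) - student_map.astype(np.float64)
    return float(np.mean(d * d))


def classification_ce(logits: np.ndarray, labels) -> float:
    """Batch-mean cross-entropy between softmax(logits) and labels."""
    loss, _ = nn.softmax_cross_entropy(np.asarray(logits, dtype=np.float64), labels)
    return loss


@dataclass
class LossBreakdown:
    """The combined loss with its two components and the weight used."""

    total: float
    consistency_mse: float
    classification_ce: float
    alpha: float

    def __post_init__(self):
        expect = self.alpha * self.consistency_mse + (1.0 - self.alpha) * self.classification_ce
        if abs(self.total - expect) > 1e-6 * max(1.0, abs(expect)):
            raise ValueError(
                f"inconsistent LossBreakdown: total={self.total} but "
                f"alpha*mse+(1-alpha)*ce={expect}"
            )


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 0.5:
        raise ValueError(f"alpha must be in [0, 0.5], got {alpha}")


def combined_loss(teacher_map: np.ndarray, student_logits: np.ndarray,
                  student_map: np.ndarray, labels, alpha: float) -> LossBreakdown:
    """Evaluate L_C; the MSE term is skipped entirely when ``alpha`` is 0
    (the fine-tuning stage never evaluates the teacher)."""
    _check_alpha(alpha)
    ce = classification_ce(student_logits, labels)
    mse = consistency_mse(teacher_map, student_map) if alpha > 0.0 else 0.0
    return LossBreakdown(total=alpha * mse + (1.0 - alpha) * ce,
                         consistency_mse=mse, classification_ce=ce, alpha=alpha)


def combined_loss_grads(teacher_map: np.ndarray, student_logits: np.ndarray,
                        student_map: np.ndarray, labels, alpha: float,
                        consistency_mask: np.ndarray | None = None):
    """Loss breakdown plus gradients w.r.t. the student's logits and
    feature map.  Teacher inputs are constants.

    ``consistency_mask`` (per-sample bool) restricts the MSE term to
    annotated samples when only part of the dataset carries ROI variants;
    masked-out samples contribute only to the CE term.
    """
    _check_alpha(alpha)
    ce, dlogits = nn.softmax_cross_entropy(student_logits, labels)
    dlogits = (1.0 - alpha) * dlogits
    if alpha > 0.0:
        if teacher_map.shape != student_map.shape:
            raise ValueError(
                f"feature-map shape mismatch: teacher {teacher_map.shape} vs "
                f"student {student_map.shape}"
            )
        diff = (student_map - teacher_map).astype(np.float32)
        if consistency_mask is not None:
            diff *= np.asarray(consistency_mask, dtype=np.float32)[:, None, None, None]
        mse = float(np.mean(diff.astype(np.float64) ** 2))
        dmap = (2.0 * alpha / diff.size) * diff
    else:
        mse = 0.0
        dmap = None
    breakdown = LossBreakdown(total=alpha * mse + (1.0 - alpha) * ce,
                              consistency_mse=mse, classification_ce=ce, alpha=alpha)
    return breakdown, dlogits, dmap
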
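"""Differentiable scalar targets for attribution.

Every attribution method explains one scalar.  For classification that is the
selected class's score (logit by default, or its softmax probability).  For
semantic segmentation the voxel-wise class map is reduced to a scalar by
global average pooling of the chosen class channel — optionally restricted to
a spatial mask — which converts the segmentation task into a multi-label
classification task that the classification-era attribution methods can
explain unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import softmax

__all__ = ["ScalarTarget", "classification_target", "segmentation_target"]

LOGIT = "logit"
PROBABILITY = "probability"
IDENTITY = "identity"
GLOBAL_AVERAGE_POOL = "global_average_pool"


@dataclass(frozen=True)
class ScalarTarget:
    """A rule reducing a model's output to one differentiable scalar.

    Attributes
    ----------
    class_index : int
        Which output class the scalar tracks.
    mode : {"logit", "probability"}
        Explain the raw score or its softmax probability.  Logit is the
        default: softmax gradients saturate for confident predictions.
    reduction : {"identity", "global_average_pool"}
        ``identity`` selects a class score (classification);
        ``global_average_pool`` averages one class channel of a voxel map
        (segmentation).
    mask : ndarray of bool, optional
        Restrict the segmentation average to a spatial region.  Must match
        the model's output spatial shape and be non-empty.
    """

    class_index: int
    mode: str = LOGIT
    reduction: str = IDENTITY
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.class_index < 0:
            raise ValueError("class_index must be >= 0")
        if self.mode not in (LOGIT, PROBABILITY):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reduction not in (IDENTITY, GLOBAL_AVERAGE_POOL):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if not mask.any():
                raise ValueError("mask selects no voxels (degenerate region)")
            object.__setattr__(self, "mask", mask)

    def validate_for(self, output_kind: str) -> None:
        needs = VOXEL_KIND if self.reduction == GLOBAL_AVERAGE_POOL else CLASS_KIND
        if output_kind != needs:
            raise ValueError(
                f"target with reduction {self.reduction!r} requires a model "
                f"with output_kind {needs!r}, got {output_kind!r}"
            )


CLASS_KIND = "class_scores"
VOXEL_KIND = "voxel_map"


def classification_target(class_index: int, mode: str = LOGIT) -> ScalarTarget:
    """Target = the selected class's score (or softmax probability)."""
    return ScalarTarget(class_index=class_index, mode=mode, reduction=IDENTITY)


def segmentation_target(
    class_index: int, mask: Optional[np.ndarray] = None, mode: str = LOGIT
) -> ScalarTarget:
    """Target = spatial mean of one class channel of the prediction map.

    The mean runs over all voxels, or over ``mask`` when given.  By default it
    is taken on the pre-activation (logit) map; ``mode="probability"`` applies
    a voxel-wise softmax across class channels first.
    """
    return ScalarTarget(
        class_index=class_index,
        mode=mode,
        reduction=GLOBAL_AVERAGE_POOL,
        mask=mask,
    )


def _check_output(target: ScalarTarget, output: np.ndarray) -> None:
    n_classes = output.shape[-1]
    if target.class_index >= n_classes:
        raise IndexError(
            f"class_index {target.class_index} out of range for "
            f"{n_classes} output classes"
        )
    if target.mask is not None and target.mask.shape != output.shape[:-1]:
        raise ValueError(
            f"mask shape {target.mask.shape} does not match output spatial "
            f"shape {output.shape[:-1]}"
        )


def target_scalar(target: ScalarTarget, output: np.ndarray) -> float:
    """Apply the target rule to a model output, returning the scalar."""
    _check_output(target, output)
    c = target.class_index
    if target.reduction == IDENTITY:
        if output.ndim != 1:
            raise ValueError("identity reduction expects a class-score vector")
        if target.mode == PROBABILITY:
            return float(softmax(output)[c])
        return float(output[c])
    # global average pool over a voxel map
    chan = softmax(output, axis=-1)[..., c] if target.mode == PROBABILITY else output[..., c]
    if target.mask is not None:
        return float(chan[target.mask].mean())
    return float(chan.mean())


def output_gradient(target: ScalarTarget, output: np.ndarray) -> np.ndarray:
    """d(scalar)/d(output), shaped like the model output."""
    _check_output(target, output)
    c = target.class_index
    grad = np.zeros_like(output, dtype=np.float64)
    if target.reduction == IDENTITY:
        if target.mode == PROBABILITY:
            p = softmax(output)
            grad = -p[c] * p
            grad[c] += p[c]
        else:
            grad[c] = 1.0
        return grad
    if target.mask is not None:
        weight = np.zeros(output.shape[:-1])
        weight[target.mask] = 1.0 / target.mask.sum()
    else:
        n = int(np.prod(output.shape[:-1]))
        weight = np.full(output.shape[:-1], 1.0 / n)
    if target.mode == PROBABILITY:
        p = softmax(output, axis=-1)
        # voxel-wise softmax Jacobian row for class c, weighted by the mean
        grad = -p[..., c : c + 1] * p
        grad[..., c] += p[..., c]
        grad *= weight[..., None]
    else:
        grad[..., c] = weight
    return grad
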
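"""Uniform contract over differentiable models.

Every attribution method is written once against :class:`ModelHandle`:
``forward`` evaluation, gradients of a scalar target with respect to the input
(:func:`input_gradient`) or any named layer's activation
(:func:`layer_forward_backward`), and a guided-ReLU backward variant
(:func:`guided_variant`).  The handle is dimension-agnostic: 2D images and 3D
volumes flow through the same code paths.

The bundled backend is the numpy layer stack in :mod:`voxattr._backend`; any
object exposing the same ``forward_backward`` / ``shape_trace`` interface can
stand behind a handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .targets import ScalarTarget, output_gradient, target_scalar

__all__ = [
    "ModelHandle",
    "LayerRef",
    "LayerTensor",
    "forward",
    "input_gradient",
    "layer_forward_backward",
    "guided_variant",
]

CLASS_SCORES = "class_scores"
VOXEL_MAP = "voxel_map"


@dataclass(frozen=True)
class LayerRef:
    """A named, inspectable layer: its activation-map geometry.

    ``spatial_shape`` is ``()`` for dense/flattened layers (no spatial extent);
    such layers cannot be used for CAM-style localization.
    """

    name: str
    spatial_shape: tuple
    channel_count: int

    @property
    def has_spatial_extent(self) -> bool:
        return len(self.spatial_shape) > 0


@dataclass
class LayerTensor:
    """Activation of one layer and the backpropagated signal at it.

    ``activation`` is the layer's forward feature map; ``backsignal`` is the
    gradient of the chosen scalar target with respect to that activation.
    Both share one shape: ``spatial_shape + (channel_count,)``.
    """

    activation: np.ndarray
    backsignal: np.ndarray

    def __post_init__(self):
        if self.activation.shape != self.backsignal.shape:
            raise ValueError(
                "activation and backsignal shapes differ: "
                f"{self.activation.shape} vs {self.backsignal.shape}"
            )


@dataclass(frozen=True)
class ModelHandle:
    """Opaque handle to a differentiable model.

    ``input_shape`` is spatial dims + channel count (channels last);
    ``output_kind`` is ``"class_scores"`` (a vector of per-class scores) or
    ``"voxel_map"`` (input-resolution per-class prediction maps).
    """

    input_shape: tuple
    output_kind: str
    backend_ref: Any
    guided: bool = False
    name: str = "model"
    _layer_refs: tuple = field(default=(), repr=False)

    def __post_init__(self):
        if self.output_kind not in (CLASS_SCORES, VOXEL_MAP):
            raise ValueError(f"unknown output_kind {self.output_kind!r}")
        if not self._layer_refs:
            refs = tuple(
                LayerRef(name, shape[:-1] if len(shape) > 1 else (), shape[-1])
                for name, shape in self.backend_ref.shape_trace(self.input_shape)
            )
            if not refs:
                raise ValueError("model exposes no layers")
            object.__setattr__(self, "_layer_refs", refs)

    @property
    def layer_names(self) -> list:
        return [r.name for r in self._layer_refs]

    @property
    def layer_refs(self) -> list:
        return list(self._layer_refs)

    def layer(self, name: str) -> LayerRef:
        for ref in self._layer_refs:
            if ref.name == name:
                return ref
        raise KeyError(
            f"model has no layer {name!r}; valid layers: {self.layer_names}"
        )

    @property
    def n_classes(self) -> int:
        out_shape = self.backend_ref.shape_trace(self.input_shape)[-1][1]
        return out_shape[-1]


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=np.float64)


def _check_shape(model: ModelHandle, arr: np.ndarray) -> None:
    if arr.shape != tuple(model.input_shape):
        raise ValueError(
            f"input shape {arr.shape} does not match model input shape "
            f"{tuple(model.input_shape)}"
        )


def forward(model: ModelHandle, x) -> np.ndarray:
    """Deterministic forward pass: class scores or a voxel-wise class map."""
    arr = _values(x)
    _check_shape(model, arr)
    return model.backend_ref.forward(arr)


def input_gradient(model: ModelHandle, target: ScalarTarget, x) -> np.ndarray:
    """Gradient of the target scalar with respect to the input, shaped like x."""
    arr = _values(x)
    _check_shape(model, arr)
    target.validate_for(model.output_kind)
    _, gx, _, _ = model.backend_ref.forward_backward(
        arr, lambda out: output_gradient(target, out), guided=model.guided
    )
    return gx


def layer_forward_backward(
    model: ModelHandle, target: ScalarTarget, layer, x
) -> LayerTensor:
    """Activation of ``layer`` and the target's gradient at that activation."""
    arr = _values(x)
    _check_shape(model, arr)
    target.validate_for(model.output_kind)
    ref = layer if isinstance(layer, LayerRef) else model.layer(layer)
    if ref.name not in model.layer_names:
        raise KeyError(
            f"layer {ref.name!r} not in model; valid layers: {model.layer_names}"
        )
    _, _, acts, backs = model.backend_ref.forward_backward(
        arr, lambda out: output_gradient(target, out), guided=model.guided
    )
    return LayerTensor(activation=acts[ref.name], backsignal=backs[ref.name])


def guided_variant(model: ModelHandle) -> ModelHandle:
    """A handle whose backward pass applies the guided-ReLU rule.

    At every ReLU the backpropagated signal is zeroed wherever the forward
    activation was non-positive (the plain ReLU gradient) *or* the incoming
    backward signal is non-positive (the guidance mask).  Forward behaviour is
    bit-identical to the original model; non-ReLU activations are unaffected.
    """
    return replace(model, guided=True)


def evaluate_scalar(model: ModelHandle, target: ScalarTarget, x) -> float:
    """The scalar the attribution methods explain: target applied to forward."""
    return target_scalar(target, forward(model, x))
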
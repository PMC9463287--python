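"""Layer-wise information-flow visualization.

Sweeping Grad-CAM over an ordered set of internal layers of a (segmentation)
network shows where each stage of the model focuses: encoder layers react to
coarse context (brain outline), decoder layers to the structure being
segmented.  Each map is computed at the layer's native resolution and
upsampled to the input grid so the panels are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .attribution import AttributionMap, grad_cam, upsample_to_input
from .model_adapter import LayerRef, ModelHandle
from .targets import ScalarTarget

logger = logging.getLogger(__name__)

__all__ = ["LayerSweepResult", "inspect_layers", "default_layer_set"]

MAX_DEFAULT_LAYERS = 12


@dataclass
class LayerSweepResult:
    """Ordered (layer, input-resolution Grad-CAM map) pairs for one input."""

    entries: List[Tuple[LayerRef, AttributionMap]]
    target_descr: ScalarTarget

    @property
    def layers(self) -> List[LayerRef]:
        return [ref for ref, _ in self.entries]

    @property
    def maps(self) -> List[AttributionMap]:
        return [m for _, m in self.entries]


def default_layer_set(model: ModelHandle, max_layers: int = MAX_DEFAULT_LAYERS):
    """All spatial (convolutional-stage) layers, subsampled to a readable count."""
    spatial = [r for r in model.layer_refs if r.has_spatial_extent]
    if len(spatial) <= max_layers:
        return spatial
    idx = np.linspace(0, len(spatial) - 1, max_layers).round().astype(int)
    return [spatial[i] for i in sorted(set(idx))]


def inspect_layers(
    model: ModelHandle,
    target: ScalarTarget,
    x,
    layers: Optional[Sequence] = None,
) -> LayerSweepResult:
    """One upsampled Grad-CAM map per requested layer, in request order.

    Layers without spatial extent (dense/flattened) are skipped with a logged
    notice rather than aborting the sweep.  Each map's metadata records the
    layer's native resolution.
    """
    if layers is None:
        layers = default_layer_set(model)
    entries = []
    for layer in layers:
        ref = layer if isinstance(layer, LayerRef) else model.layer(layer)
        if not ref.has_spatial_extent:
            logger.info("skipping dense layer %r (no spatial extent)", ref.name)
            continue
        cam = grad_cam(model, target, x, layer=ref)
        entries.append((ref, upsample_to_input(cam, x)))
    return LayerSweepResult(entries=entries, target_descr=target)
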
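"""Seven gradient-based attribution methods, dimension-agnostic (2D and 3D).

Pixel-space methods (input resolution, signed, per input channel):

* :func:`vanilla_gradient` — one backward pass of the target scalar.
* :func:`guided_backprop` — the same pass with the guided-ReLU rule: every
  ReLU zeroes the backward signal where its forward activation or the
  incoming signal is non-positive.
* :func:`integrated_gradients` — path integral of gradients along the
  straight line from a baseline (default: all-zero "black" image) to the
  input; satisfies the completeness axiom Σattribution = F(x) − F(baseline).
* :func:`guided_integrated_gradients` — an adaptive path: at each step the
  currently least-important unconverged features are moved toward the input,
  so the path avoids directions of spurious gradient.
* :func:`smoothgrad` — averages any of the other methods over noisy copies
  of the input.
* :func:`guided_grad_cam` — guided backprop masked by an upsampled Grad-CAM.

Layer-space localization:

* :func:`grad_cam` — channel weights are the spatial mean of the target's
  gradient at a chosen convolutional layer; the map is the ReLU of the
  weighted activation sum, at that layer's native resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from skimage.transform import resize

from .model_adapter import (
    LayerRef,
    ModelHandle,
    guided_variant,
    input_gradient,
    layer_forward_backward,
)
from .targets import ScalarTarget

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionMap",
    "IGConfig",
    "GIGState",
    "SmoothGradConfig",
    "vanilla_gradient",
    "guided_backprop",
    "integrated_gradients",
    "guided_integrated_gradients",
    "smoothgrad",
    "grad_cam",
    "upsample_to_input",
    "guided_grad_cam",
    "METHODS",
]


@dataclass
class AttributionMap:
    """An attribution array plus provenance.

    ``resolution`` is ``"input"`` for pixel-space methods (values shaped like
    the explained input) or ``"layer"`` for Grad-CAM before upsampling.
    """

    values: np.ndarray
    method: str
    target_descr: ScalarTarget
    resolution: str = "input"
    layer: Optional[LayerRef] = None
    meta: dict = field(default_factory=dict)


@dataclass
class IGConfig:
    """Path-integral discretization.

    ``baseline`` is the reference image (``None`` = black, all zeros);
    ``steps`` the number of points on the α-grid; ``rule`` the Riemann rule.
    """

    baseline: Optional[np.ndarray] = None
    steps: int = 64
    rule: str = "midpoint"

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.rule not in ("left", "midpoint", "trapezoid"):
            raise ValueError(f"unknown Riemann rule {self.rule!r}")

    def resolve_baseline(self, x: np.ndarray) -> np.ndarray:
        if self.baseline is None:
            return np.zeros_like(x)
        b = np.asarray(self.baseline, dtype=np.float64)
        if b.shape != x.shape:
            raise ValueError(
                f"baseline shape {b.shape} does not match input shape {x.shape}"
            )
        if not np.all(np.isfinite(b)):
            raise ValueError("baseline must be finite")
        return b


@dataclass
class GIGState:
    """One step of the adaptive path: diagnostics for tests and tracing."""

    current_point: np.ndarray
    frontier: np.ndarray  # flat indices not yet equal to the input
    selected: np.ndarray  # flat indices moved this step (least importance)
    importance: np.ndarray  # per-feature |gradient|, inf off the frontier


@dataclass
class SmoothGradConfig:
    """Noise-averaging parameters: sample count, noise scale, seed.

    ``noise_fraction`` is the Gaussian σ expressed as a fraction of the input
    intensity range ``max(x) − min(x)``.
    """

    n_samples: int = 25
    noise_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=np.float64)


def vanilla_gradient(model: ModelHandle, target: ScalarTarget, x) -> AttributionMap:
    """Signed saliency: one backward pass of the target w.r.t. the input."""
    g = input_gradient(model, target, _values(x))
    return AttributionMap(values=g, method="vanilla_gradient", target_descr=target)


def guided_backprop(model: ModelHandle, target: ScalarTarget, x) -> AttributionMap:
    """Saliency through the guided-ReLU backward pass."""
    g = input_gradient(guided_variant(model), target, _values(x))
    return AttributionMap(values=g, method="guided_backprop", target_descr=target)


def integrated_gradients(
    model: ModelHandle,
    target: ScalarTarget,
    x,
    config: Optional[IGConfig] = None,
) -> AttributionMap:
    """Straight-line path integral of gradients from baseline to input.

    ``values_i ≈ (x_i − baseline_i) × mean_α ∂F/∂γ_i(α)`` with the α-grid
    given by ``config.rule`` and ``config.steps``.
    """
    config = config or IGConfig()
    arr = _values(x)
    baseline = config.resolve_baseline(arr)
    delta = arr - baseline
    if config.rule == "left":
        alphas = np.arange(config.steps) / config.steps
        weights = np.full(config.steps, 1.0 / config.steps)
    elif config.rule == "midpoint":
        alphas = (np.arange(config.steps) + 0.5) / config.steps
        weights = np.full(config.steps, 1.0 / config.steps)
    else:  # trapezoid
        alphas = np.linspace(0.0, 1.0, config.steps + 1)
        weights = np.full(config.steps + 1, 1.0 / config.steps)
        weights[0] = weights[-1] = 0.5 / config.steps
    avg = np.zeros_like(arr)
    for a, w in zip(alphas, weights):
        avg += w * input_gradient(model, target, baseline + a * delta)
    return AttributionMap(
        values=delta * avg,
        method="integrated_gradients",
        target_descr=target,
        meta={"steps": config.steps, "rule": config.rule},
    )


def guided_integrated_gradients(
    model: ModelHandle,
    target: ScalarTarget,
    x,
    config: Optional[IGConfig] = None,
    step_fraction: Optional[float] = None,
    atol: float = 1e-9,
    trace: Optional[list] = None,
) -> AttributionMap:
    """Adaptive-path integrated gradients.

    At each step the per-feature importance is ``|∂F/∂x_i|`` at the current
    path point (infinite for features already equal to the input).  The
    least-important frontier features are moved toward their input values
    until the step's quota of L1 distance — ``step_fraction`` of the initial
    L1 gap, a linear schedule that completes the path exactly at the step
    budget — is covered, the quota-boundary feature moving partially.  The
    moved delta times the local gradient is accumulated into the
    attribution.  If the budget is exhausted before convergence the walk
    snaps to the input, accumulates the final deltas, and records a warning
    in the map metadata.

    ``trace``, if a list, receives one :class:`GIGState` per step.
    """
    config = config or IGConfig()
    if step_fraction is None:
        step_fraction = 1.0 / config.steps
    arr = _values(x)
    baseline = config.resolve_baseline(arr)
    flat_x = arr.ravel()
    cur = baseline.ravel().copy()
    accum = np.zeros_like(flat_x)
    truncated = False
    total_gap0 = np.abs(flat_x - cur).sum()
    for _ in range(config.steps):
        frontier = np.flatnonzero(np.abs(cur - flat_x) > atol)
        if frontier.size == 0:
            break
        g = input_gradient(model, target, cur.reshape(arr.shape)).ravel()
        importance = np.full_like(flat_x, np.inf)
        importance[frontier] = np.abs(g[frontier])
        gap = np.abs(flat_x - cur)
        order = frontier[np.argsort(importance[frontier], kind="stable")]
        covered = np.cumsum(gap[order])
        quota = min(step_fraction * total_gap0, covered[-1])
        # least-important prefix whose combined distance covers the quota
        n_sel = min(int(np.searchsorted(covered, quota)) + 1, order.size)
        selected = order[:n_sel]
        if trace is not None:
            trace.append(
                GIGState(
                    current_point=cur.reshape(arr.shape).copy(),
                    frontier=frontier,
                    selected=selected.copy(),
                    importance=importance.copy(),
                )
            )
        move = gap[selected].copy()
        overshoot = covered[n_sel - 1] - quota
        move[-1] -= overshoot  # boundary feature moves partially
        delta = np.sign(flat_x[selected] - cur[selected]) * move
        accum[selected] += delta * g[selected]
        cur[selected] += delta
    frontier = np.flatnonzero(np.abs(cur - flat_x) > atol)
    if frontier.size:
        residual = np.abs(flat_x[frontier] - cur[frontier]).sum()
        # float dust from partial moves is not a truncated path
        truncated = residual > 1e-6 * max(total_gap0, 1.0)
        g = input_gradient(model, target, cur.reshape(arr.shape)).ravel()
        delta = flat_x[frontier] - cur[frontier]
        accum[frontier] += delta * g[frontier]
        cur[frontier] = flat_x[frontier]
    meta = {"steps": config.steps, "step_fraction": step_fraction}
    if truncated:
        meta["warning"] = "step budget exhausted before convergence; snapped to input"
        logger.warning("guided IG: %s", meta["warning"])
    return AttributionMap(
        values=accum.reshape(arr.shape),
        method="guided_integrated_gradients",
        target_descr=target,
        meta=meta,
    )


def smoothgrad(
    base_method: Union[str, Callable],
    model: ModelHandle,
    target: ScalarTarget,
    x,
    config: Optional[SmoothGradConfig] = None,
    **base_kwargs,
) -> AttributionMap:
    """Average ``base_method`` over Gaussian-perturbed copies of the input.

    Noise std = ``noise_fraction × (max(x) − min(x))``; seeded, reproducible.
    ``base_method`` may be any method of this module except smoothgrad
    itself, given as the callable or its registry name.
    """
    config = config or SmoothGradConfig()
    if isinstance(base_method, str):
        if base_method in ("smoothgrad", "sg"):
            raise ValueError("smoothgrad cannot be its own base method")
        base_method = METHODS[base_method]
    if base_method is smoothgrad:
        raise ValueError("smoothgrad cannot be its own base method")
    arr = _values(x)
    sigma = config.noise_fraction * (arr.max() - arr.min())
    rng = np.random.default_rng(config.seed)
    acc = None
    for _ in range(config.n_samples):
        noisy = arr if sigma == 0 else arr + rng.normal(0.0, sigma, size=arr.shape)
        m = base_method(model, target, noisy, **base_kwargs)
        acc = m.values if acc is None else acc + m.values
    return AttributionMap(
        values=acc / config.n_samples,
        method="smoothgrad",
        target_descr=target,
        resolution=m.resolution,
        layer=m.layer,
        meta={
            "base_method": m.method,
            "n_samples": config.n_samples,
            "noise_fraction": config.noise_fraction,
            "seed": config.seed,
        },
    )


def _resolve_layer(model: ModelHandle, layer) -> LayerRef:
    if layer is None:
        spatial = [r for r in model.layer_refs if r.has_spatial_extent]
        if not spatial:
            raise ValueError("model has no layer with spatial extent")
        return spatial[-1]
    return layer if isinstance(layer, LayerRef) else model.layer(layer)


def grad_cam(
    model: ModelHandle, target: ScalarTarget, x, layer=None
) -> AttributionMap:
    """Class-activation localization at a chosen layer's native resolution.

    Channel weight ``α_k = (1/N) Σ_spatial ∂(target)/∂A_k``; the map is
    ``ReLU(Σ_k α_k A_k)``, nonnegative by construction.  ``layer`` defaults
    to the deepest layer with spatial extent.
    """
    ref = _resolve_layer(model, layer)
    if not ref.has_spatial_extent:
        raise ValueError(
            f"layer {ref.name!r} has no spatial extent; Grad-CAM needs a "
            "convolutional/spatial layer"
        )
    lt = layer_forward_backward(model, target, ref, _values(x))
    nsp = lt.activation.ndim - 1
    alphas = lt.backsignal.mean(axis=tuple(range(nsp)))  # one weight per channel
    cam = np.maximum(np.tensordot(lt.activation, alphas, axes=([-1], [0])), 0.0)
    return AttributionMap(
        values=cam,
        method="grad_cam",
        target_descr=target,
        resolution="layer",
        layer=ref,
    )


def upsample_to_input(map_: AttributionMap, x) -> AttributionMap:
    """Linearly interpolate a layer-resolution map to the input's spatial dims.

    Bilinear in 2D, trilinear in 3D; values stay within the coarse map's
    range (convex interpolation), so nonnegativity is preserved.
    """
    if map_.resolution != "layer":
        raise ValueError("upsample_to_input expects a layer-resolution map")
    arr = _values(x)
    out_shape = arr.shape[:-1] if arr.ndim > map_.values.ndim else arr.shape
    up = resize(
        map_.values,
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return AttributionMap(
        values=up,
        method=map_.method,
        target_descr=map_.target_descr,
        resolution="input",
        layer=map_.layer,
        meta={**map_.meta, "native_shape": map_.values.shape},
    )


def guided_grad_cam(
    model: ModelHandle, target: ScalarTarget, x, layer=None
) -> AttributionMap:
    """Guided backprop masked by the upsampled Grad-CAM.

    The single-channel upsampled CAM multiplies every input channel of the
    guided-backprop map, yielding a high-resolution, class-localized map.
    """
    arr = _values(x)
    gbp = guided_backprop(model, target, arr)
    cam = upsample_to_input(grad_cam(model, target, arr, layer=layer), arr)
    values = gbp.values * cam.values[..., None]
    return AttributionMap(
        values=values,
        method="guided_grad_cam",
        target_descr=target,
        layer=cam.layer,
    )


METHODS = {
    "vg": vanilla_gradient,
    "vanilla_gradient": vanilla_gradient,
    "gbp": guided_backprop,
    "guided_backprop": guided_backprop,
    "ig": integrated_gradients,
    "integrated_gradients": integrated_gradients,
    "gig": guided_integrated_gradients,
    "guided_integrated_gradients": guided_integrated_gradients,
    "sg": smoothgrad,
    "smoothgrad": smoothgrad,
    "gcam": grad_cam,
    "grad_cam": grad_cam,
    "ggcam": guided_grad_cam,
    "guided_grad_cam": guided_grad_cam,
}
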
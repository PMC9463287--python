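"""Synthetic data and analytic models for exercising every attribution method.

Nothing here requires a download or a GPU.  The phantom generator emulates
the statistical shape of multi-modal brain MRI: an ellipsoidal "brain" with
smooth background texture and one or more blob "tumors" of elevated,
channel-specific intensity, with a ground-truth mask and a two-way grading
label (low- vs high-contrast blob, the HGG/LGG analogue).  The model builders
produce :class:`~voxattr.model_adapter.ModelHandle` fixtures ranging from a
pure linear map (closed-form oracle for the path methods) to a hand-set blob
detector (analytic ground truth for Grad-CAM localization) and desk-scale
classifier / encoder-decoder segmenter stand-ins.

:func:`finite_difference_gradient` is the independent gradient oracle used by
the test suite against every backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from . import _backend as B
from .model_adapter import CLASS_SCORES, VOXEL_MAP, ModelHandle, forward
from .targets import ScalarTarget, target_scalar

__all__ = [
    "PhantomSample",
    "make_phantom",
    "make_linear_model",
    "make_blob_detector",
    "make_toy_models",
    "make_smooth_cnn",
    "build_classifier_head",
    "finite_difference_gradient",
    "fit_classifier_head",
    "fixture_model_suite",
    "build_architecture",
    "ARCHITECTURES",
    "write_phantom_dataset",
]

N_MODALITIES = 4
MODALITY_NAMES = ("T1W", "T1Gd", "T2W", "FLAIR")

#: per-modality visibility of the tumor blob (FLAIR-like channels see more)
CHANNEL_CONTRAST_WEIGHTS = (0.6, 1.0, 0.8, 1.2)

LOW_GRADE_CONTRAST = 0.4
HIGH_GRADE_CONTRAST = 1.2


@dataclass
class PhantomSample:
    """One synthetic subject: 4-channel volume, tumor mask, grading label."""

    volume: np.ndarray  # (X, Y, Z, 4)
    tumor_mask: np.ndarray  # (X, Y, Z) bool
    label: int  # 0 = low-contrast blob, 1 = high-contrast blob
    seed: int


def _ellipsoid_mask(shape, center, radii):
    coords = np.indices(shape, dtype=np.float64)
    acc = np.zeros(shape)
    for ax in range(len(shape)):
        acc += ((coords[ax] - center[ax]) / radii[ax]) ** 2
    return acc <= 1.0


def make_phantom(
    shape: tuple = (32, 32, 32),
    tumor_params: Optional[dict] = None,
    seed: int = 0,
) -> PhantomSample:
    """Generate one phantom subject, reproducible for a fixed seed.

    ``tumor_params`` keys: ``center`` (defaults to an off-center position
    inside the brain), ``radii`` (default ~1/6 of each axis), ``contrast``
    (blob intensity elevation; default the high-grade value, 1.2).  The label
    is 1 when contrast is at least the midpoint of the low/high defaults.
    """
    rng = np.random.default_rng(seed)
    tumor_params = dict(tumor_params or {})
    shape = tuple(shape)
    brain_radii = tuple(0.42 * s for s in shape)
    brain_center = tuple((s - 1) / 2 for s in shape)
    radii = tumor_params.get("radii", tuple(max(2.0, s / 6.5) for s in shape))
    contrast = float(tumor_params.get("contrast", HIGH_GRADE_CONTRAST))
    if "center" in tumor_params:
        center = tuple(float(c) for c in tumor_params["center"])
    else:
        # random placement, strictly inside the brain ellipsoid
        frac = rng.uniform(-0.35, 0.35, size=len(shape))
        center = tuple(
            bc + f * br for bc, f, br in zip(brain_center, frac, brain_radii)
        )
    # contract: the tumor ellipsoid must sit strictly inside the brain
    for c, r, bc, br in zip(center, radii, brain_center, brain_radii):
        if abs(c - bc) + r >= br:
            raise ValueError(
                f"tumor blob (center {center}, radii {radii}) extends outside "
                "the brain ellipsoid"
            )
    brain = _ellipsoid_mask(shape, brain_center, brain_radii)
    tumor = _ellipsoid_mask(shape, center, radii) & brain
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=2.0)
    texture /= max(texture.std(), 1e-12)
    volume = np.zeros(shape + (N_MODALITIES,))
    for ch, w in enumerate(CHANNEL_CONTRAST_WEIGHTS):
        chan = np.where(brain, 1.0 + 0.1 * texture, 0.0)
        chan = chan + np.where(tumor, w * contrast, 0.0)
        volume[..., ch] = chan
    label = int(contrast >= (LOW_GRADE_CONTRAST + HIGH_GRADE_CONTRAST) / 2)
    return PhantomSample(volume=volume, tumor_mask=tumor, label=label, seed=seed)


def make_linear_model(weights) -> ModelHandle:
    """F(x) = Σ w_i x_i — closed-form oracle for the path methods."""
    w = np.asarray(weights, dtype=np.float64)
    net = B.Network([("flatten", B.Flatten()), ("score", B.Dense(w.ravel()[None, :]))])
    return ModelHandle(
        input_shape=w.shape, output_kind=CLASS_SCORES, backend_ref=net, name="linear"
    )


def _avg_kernel(radius, ndim):
    k = 2 * radius + 1
    return np.full((k,) * ndim, 1.0 / k**ndim)


def make_blob_detector(
    kernel_radius: int = 1,
    input_shape: tuple = (32, 32, 32, N_MODALITIES),
    threshold: float = 1.5,
    head: str = "classification",
) -> ModelHandle:
    """Hand-set detector whose most activating region is the brightest blob.

    Channel mean → local averaging convolution (cubic kernel of the given
    radius) with bias ``-threshold`` → ReLU, so only voxels whose local mean
    exceeds the threshold survive.  The default threshold sits between the
    phantom background level (~1.0) and a high-grade blob (~1.0 + contrast).
    Heads: ``classification`` (two class scores, class 1 = mean evidence for
    a supra-threshold blob) or ``segmentation`` (a threshold-free linear
    per-class map).
    """
    nsp = len(input_shape) - 1
    kernel = _avg_kernel(kernel_radius, nsp)[None, None]
    layers = [
        ("channel_mean", B.ChannelMean()),
        ("detect", B.Conv(kernel, bias=[-threshold])),
        ("evidence", B.ReLU()),
    ]
    if head == "classification":
        # class 0 = absence (negative evidence), class 1 = presence
        layers += [
            ("gap", B.GlobalAvgPool()),
            ("scores", B.Dense(np.array([[-10.0], [10.0]]))),
        ]
        kind = CLASS_SCORES
    elif head == "segmentation":
        w = np.zeros((2, 1, *(3,) * nsp))
        cidx = (1,) * nsp
        w[(0, 0) + cidx] = -1.0  # background score falls with evidence
        w[(1, 0) + cidx] = 1.0  # tumor score rises with evidence
        layers += [("class_map", B.Conv(w, bias=[0.5, 0.0]))]
        kind = VOXEL_MAP
    else:
        raise ValueError(f"unknown head {head!r}")
    net = B.Network(layers)
    return ModelHandle(
        input_shape=tuple(input_shape),
        output_kind=kind,
        backend_ref=net,
        name=f"blob_detector_{head}",
    )


def _he_conv(rng, c_out, c_in, k, nsp):
    fan_in = c_in * k**nsp
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, *(k,) * nsp))


def make_toy_models(
    seed: int = 0,
    clf_shape: tuple = (8, 8, 8, N_MODALITIES),
    seg_shape: tuple = (16, 16, 16, N_MODALITIES),
    n_classes: int = 2,
) -> dict:
    """Desk-scale ReLU classifier and encoder-decoder segmenter stand-ins.

    Both are small (≪ 10⁵ parameters), with every layer named and
    inspectable.  Weights are seeded random (He-scaled); the classifier head
    can be fitted on phantoms with :func:`fit_classifier_head`.
    """
    rng = np.random.default_rng(seed)
    nsp = len(clf_shape) - 1
    c_in = clf_shape[-1]
    clf = B.Network(
        [
            ("conv1", B.Conv(_he_conv(rng, 6, c_in, 3, nsp))),
            ("relu1", B.ReLU()),
            ("pool1", B.AvgPool(2)),
            ("conv2", B.Conv(_he_conv(rng, 8, 6, 3, nsp))),
            ("relu2", B.ReLU()),
            ("gap", B.GlobalAvgPool()),
            ("fc1", B.Dense(rng.normal(0, 0.5, size=(16, 8)))),
            ("relu3", B.ReLU()),
            ("scores", B.Dense(rng.normal(0, 0.5, size=(n_classes, 16)))),
        ]
    )
    classifier = ModelHandle(
        input_shape=tuple(clf_shape),
        output_kind=CLASS_SCORES,
        backend_ref=clf,
        name="toy_classifier",
    )
    nsp = len(seg_shape) - 1
    c_in = seg_shape[-1]
    seg = B.Network(
        [
            ("enc1_conv", B.Conv(_he_conv(rng, 6, c_in, 3, nsp))),
            ("enc1_relu", B.ReLU()),
            ("enc1_pool", B.AvgPool(2)),
            ("enc2_conv", B.Conv(_he_conv(rng, 8, 6, 3, nsp))),
            ("enc2_relu", B.ReLU()),
            ("enc2_pool", B.AvgPool(2)),
            ("bottleneck_conv", B.Conv(_he_conv(rng, 8, 8, 3, nsp))),
            ("bottleneck_relu", B.ReLU()),
            ("dec1_up", B.Upsample(2)),
            ("dec1_conv", B.Conv(_he_conv(rng, 6, 8, 3, nsp))),
            ("dec1_relu", B.ReLU()),
            ("dec2_up", B.Upsample(2)),
            ("dec2_conv", B.Conv(_he_conv(rng, 6, 6, 3, nsp))),
            ("dec2_relu", B.ReLU()),
            ("class_map", B.Conv(_he_conv(rng, n_classes, 6, 1, nsp))),
        ]
    )
    segmenter = ModelHandle(
        input_shape=tuple(seg_shape),
        output_kind=VOXEL_MAP,
        backend_ref=seg,
        name="toy_segmenter",
    )
    return {"classifier": classifier, "segmenter": segmenter}


def make_smooth_cnn(
    seed: int = 0, input_shape: tuple = (16, 16, 16, 2), n_classes: int = 2
) -> ModelHandle:
    """Small tanh CNN: a smooth fixture for path-integral convergence checks.

    With a smooth nonlinearity the integrand of the attribution path integral
    is smooth, so the midpoint-rule error decays at its textbook O(steps⁻²)
    rate — the fixture of choice when checking that the completeness residual
    shrinks as the α-grid refines.
    """
    rng = np.random.default_rng(seed)
    nsp = len(input_shape) - 1
    c_in = input_shape[-1]
    net = B.Network(
        [
            ("conv1", B.Conv(_he_conv(rng, 4, c_in, 3, nsp))),
            ("tanh1", B.Tanh()),
            ("pool1", B.AvgPool(2)),
            ("conv2", B.Conv(_he_conv(rng, 6, 4, 3, nsp))),
            ("tanh2", B.Tanh()),
            ("gap", B.GlobalAvgPool()),
            ("scores", B.Dense(rng.normal(0, 1.0, size=(n_classes, 6)))),
        ]
    )
    return ModelHandle(
        input_shape=tuple(input_shape),
        output_kind=CLASS_SCORES,
        backend_ref=net,
        name="smooth_cnn",
    )


def build_classifier_head(
    backbone_output_shape: tuple = (4, 4, 512),
    pool: int = 2,
    dropout_rate: float = 0.5,
    n_classes: int = 2,
    hidden: int = 256,
    seed: int = 0,
) -> ModelHandle:
    """Transfer-learning top layers on a 2D backbone feature map.

    Layer sequence: 2D average pooling → flatten → dense(256) → dropout →
    dense(2).  On the standard 4×4×512 backbone output with pool 2 the
    flatten width is 2×2×512 = 2048.  Every layer's output size is available
    via the handle's ``layer_refs``.
    """
    h, w, c = backbone_output_shape
    if h % pool or w % pool:
        raise ValueError(
            f"backbone spatial dims {(h, w)} not divisible by pool size {pool}"
        )
    rng = np.random.default_rng(seed)
    flat = (h // pool) * (w // pool) * c
    net = B.Network(
        [
            ("avg_pool_2d", B.AvgPool(pool)),
            ("flatten", B.Flatten()),
            ("dense_1", B.Dense(rng.normal(0, np.sqrt(1.0 / flat), size=(hidden, flat)))),
            ("dropout", B.Dropout(dropout_rate)),
            ("dense_2", B.Dense(rng.normal(0, np.sqrt(1.0 / hidden), size=(n_classes, hidden)))),
        ]
    )
    return ModelHandle(
        input_shape=tuple(backbone_output_shape),
        output_kind=CLASS_SCORES,
        backend_ref=net,
        name="classifier_head",
    )


def finite_difference_gradient(model, target: ScalarTarget, x, step: float = 1e-4):
    """Central-difference gradient oracle, O(step²) accurate, per coordinate."""
    arr = np.array(getattr(x, "values", x), dtype=np.float64)
    grad = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + step
        f_plus = target_scalar(target, forward(model, arr))
        arr[idx] = orig - step
        f_minus = target_scalar(target, forward(model, arr))
        arr[idx] = orig
        grad[idx] = (f_plus - f_minus) / (2 * step)
    return grad


def fit_classifier_head(model: ModelHandle, samples, labels) -> ModelHandle:
    """Fit the final dense layer by logistic regression on frozen features.

    Features are the activations feeding the final dense layer; the fitted
    two-class weights are written into that layer.  Returns the same handle
    (weights are updated in place).
    """
    from sklearn.linear_model import LogisticRegression

    net = model.backend_ref
    feat_layer = net.layer_names[-2]
    feats = []
    for s in samples:
        arr = np.asarray(getattr(s, "volume", s), dtype=np.float64)
        _, _, acts, _ = net.forward_backward(arr, lambda out: np.zeros_like(out))
        feats.append(acts[feat_layer])
    X = np.stack(feats)
    clf = LogisticRegression(max_iter=2000).fit(X, np.asarray(labels))
    final = net.get_layer(net.layer_names[-1])
    final.weights = np.vstack([-clf.coef_ / 2, clf.coef_ / 2])
    final.bias = np.array([-clf.intercept_[0] / 2, clf.intercept_[0] / 2])
    return model


def fixture_model_suite(seed: int = 0) -> list:
    """Every fixture model at oracle-friendly (small) input sizes.

    Returns ``(name, handle, example_input, target)`` tuples; used by the
    gradient-oracle equivalence sweep.
    """
    from .targets import classification_target, segmentation_target

    rng = np.random.default_rng(seed)
    toy = make_toy_models(seed, clf_shape=(8, 8, 8, 2), seg_shape=(8, 8, 8, 2))
    smooth = make_smooth_cnn(seed, input_shape=(8, 8, 8, 2))
    det = make_blob_detector(kernel_radius=1, input_shape=(8, 8, 8, 2))
    head = build_classifier_head(backbone_output_shape=(4, 4, 8), seed=seed)
    linear = make_linear_model(rng.normal(size=(4, 4, 1)))
    suite = []
    for name, handle in [
        ("linear", linear),
        ("smooth_cnn", smooth),
        ("toy_classifier", toy["classifier"]),
        ("toy_segmenter", toy["segmenter"]),
        ("blob_detector", det),
        ("classifier_head", head),
    ]:
        x = rng.normal(0.5, 0.7, size=handle.input_shape)
        if handle.output_kind == VOXEL_MAP:
            tgt = segmentation_target(1)
        else:
            tgt = classification_target(min(1, handle.n_classes - 1))
        suite.append((name, handle, x, tgt))
    return suite


ARCHITECTURES = {
    "linear": lambda seed=0, **kw: make_linear_model(
        kw.get("weights", np.array([1.0, 2.0, 3.0]))
    ),
    "toy_classifier": lambda seed=0, **kw: make_toy_models(seed, **kw)["classifier"],
    "toy_segmenter": lambda seed=0, **kw: make_toy_models(seed, **kw)["segmenter"],
    "blob_detector": lambda seed=0, **kw: make_blob_detector(**kw),
    "blob_detector_seg": lambda seed=0, **kw: make_blob_detector(
        head="segmentation", **kw
    ),
    "smooth_cnn": lambda seed=0, **kw: make_smooth_cnn(seed, **kw),
    "classifier_head": lambda seed=0, **kw: build_classifier_head(seed=seed, **kw),
}


def build_architecture(name: str, seed: int = 0, weights_path=None, **kw) -> ModelHandle:
    """Instantiate a registered architecture, optionally loading saved weights."""
    if name not in ARCHITECTURES:
        raise KeyError(
            f"unknown architecture {name!r}; registered: {sorted(ARCHITECTURES)}"
        )
    model = ARCHITECTURES[name](seed=seed, **kw)
    if weights_path is not None:
        load_weights(model, weights_path)
    return model


def save_weights(model: ModelHandle, path) -> None:
    """Save all layer weights/biases to an .npz file."""
    arrays = {}
    for name, layer in model.backend_ref.layers:
        if hasattr(layer, "weights"):
            arrays[f"{name}.weights"] = layer.weights
            arrays[f"{name}.bias"] = layer.bias
    np.savez(path, **arrays)


def load_weights(model: ModelHandle, path) -> ModelHandle:
    """Load weights saved by :func:`save_weights` into a matching architecture."""
    data = np.load(path)
    for name, layer in model.backend_ref.layers:
        key = f"{name}.weights"
        if key in data:
            if layer.weights.shape != data[key].shape:
                raise ValueError(
                    f"weight shape mismatch at layer {name!r}: "
                    f"{layer.weights.shape} vs {data[key].shape}"
                )
            layer.weights = data[key]
            layer.bias = data[f"{name}.bias"]
    return model


def write_phantom_dataset(
    out_dir, n_samples: int = 4, shape: tuple = (32, 32, 32), seed: int = 0
) -> Path:
    """Generate a phantom dataset directory: NIfTI volumes + masks + manifest CSV."""
    import csv

    from .imaging_io import AttributionInput, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        s = int(rng.integers(0, 2**31 - 1))
        contrast = HIGH_GRADE_CONTRAST if i % 2 else LOW_GRADE_CONTRAST
        ph = make_phantom(shape, {"contrast": contrast}, seed=s)
        vol_path = out_dir / f"phantom_{i:03d}.nii.gz"
        mask_path = out_dir / f"phantom_{i:03d}_mask.nii.gz"
        write_volume(
            AttributionInput(ph.volume, channel_names=MODALITY_NAMES),
            vol_path,
            force=True,
        )
        write_volume(ph.tumor_mask.astype(np.float32)[..., None], mask_path, force=True)
        rows.append((vol_path.name, mask_path.name, ph.label, s))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["volume", "mask", "label", "seed"])
        writer.writerows(rows)
    return out_dir
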
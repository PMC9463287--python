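"""Volume I/O, MRI preprocessing, and rendering of attribution maps.

Volumes travel as :class:`AttributionInput`: a channels-last float array (2 or
3 spatial dims) with a NIfTI affine and channel names (e.g. the four MRI
modalities T1W / T1Gd / T2W / FLAIR).  Preprocessing follows the standard
brain-MRI recipe: per-modality z-score over the nonzero (brain) support, a
center crop/pad to a fixed grid, and optional patch extraction.  Rendering
covers the two conventions used for attribution figures: grayscale magnitude
("contributing features in white") and a red heat overlay on an anatomical
background ("red = high score").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from matplotlib import colormaps

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionInput",
    "RenderSpec",
    "read_volume",
    "write_volume",
    "zscore_normalize",
    "crop_or_pad",
    "extract_patch",
    "to_grayscale_map",
    "to_heatmap_overlay",
]

CROP_SHAPE = (192, 224, 160)
PATCH_SHAPE = (128, 128, 128)


@dataclass
class AttributionInput:
    """A 2D or 3D multi-channel image with geometric metadata."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    channel_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (3, 4):
            raise ValueError(
                "expected (spatial..., channels) with 2 or 3 spatial dims, "
                f"got array of ndim {self.values.ndim}"
            )
        if self.values.shape[-1] < 1:
            raise ValueError("need at least one channel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("input contains non-finite values")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape[:-1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size per spatial axis, from the affine."""
        n = len(self.spatial_shape)
        return np.linalg.norm(self.affine[:3, :n], axis=0)[:n]


@dataclass
class RenderSpec:
    """Rendering convention for attribution panels.

    ``grayscale_white`` shows attribution magnitude in white on black;
    ``red_overlay`` blends a red-dominant heatmap onto an anatomical slice.
    ``percentile_clip`` sets the normalization ceiling (robust to outliers).
    """

    style: str = "grayscale_white"
    percentile_clip: float = 99.0
    alpha: float = 0.5
    slice_axis: int = 2
    slice_index: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.percentile_clip <= 100:
            raise ValueError("percentile_clip must be in (0, 100]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.style not in ("grayscale_white", "red_overlay"):
            raise ValueError(f"unknown render style {self.style!r}")


def read_volume(
    path: Union[str, Path, Sequence[Union[str, Path]]],
    channel_names: Optional[Sequence[str]] = None,
) -> AttributionInput:
    """Read NIfTI (3D, one file per modality or one 4D file) or PNG (2D).

    A list of paths is stacked channel-wise; every file must share one shape.
    """
    if isinstance(path, (list, tuple)):
        vols = [read_volume(p) for p in path]
        shapes = {v.spatial_shape for v in vols}
        if len(shapes) > 1:
            raise ValueError(f"modality shapes differ across files: {sorted(shapes)}")
        values = np.concatenate([v.values for v in vols], axis=-1)
        return AttributionInput(values, affine=vols[0].affine, channel_names=channel_names)
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() == ".png":
        img = np.asarray(iio.imread(path), dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        return AttributionInput(img, channel_names=channel_names)
    try:
        nii = nib.load(str(path))
    except Exception as exc:  # corrupt or unreadable
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(nii.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    elif data.ndim != 4:
        raise ValueError(f"{path}: expected a 3D or 4D NIfTI, got ndim {data.ndim}")
    return AttributionInput(data, affine=np.asarray(nii.affine), channel_names=channel_names)


def write_volume(x, path: Union[str, Path], force: bool = False) -> None:
    """Write an input or attribution map as float32 NIfTI with its affine."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    values = np.asarray(getattr(x, "values", x), dtype=np.float32)
    affine = np.asarray(getattr(x, "affine", np.eye(4)))
    nib.save(nib.Nifti1Image(values, affine), str(path))


def zscore_normalize(
    x: AttributionInput,
    support: str = "nonzero",
    minmax_rescale: bool = False,
    eps: float = 1e-8,
) -> AttributionInput:
    """Per-channel z-score over the normalization support.

    ``support="nonzero"`` (default) normalizes over nonzero voxels only — the
    brain, for skull-stripped MRI — leaving padding at zero mean influence;
    ``support="all"`` uses every voxel.  ``minmax_rescale`` optionally maps
    the result to [0, 1] afterwards (off by default).  An all-zero channel is
    returned unchanged with a warning.
    """
    out = x.values.copy()
    for c in range(x.n_channels):
        chan = out[..., c]
        mask = chan != 0 if support == "nonzero" else np.ones_like(chan, bool)
        if not mask.any():
            warnings.warn(f"channel {c} is all zero; left unchanged")
            continue
        if mask.sum() < 2:
            raise ValueError("normalization support must contain >= 2 voxels")
        vals = chan[mask]
        chan[mask] = (vals - vals.mean()) / (vals.std() + eps)
        if minmax_rescale:
            lo, hi = chan.min(), chan.max()
            if hi > lo:
                out[..., c] = (chan - lo) / (hi - lo)
    return AttributionInput(out, affine=x.affine.copy(), channel_names=x.channel_names)


def crop_or_pad(x: AttributionInput, target_shape: tuple = CROP_SHAPE) -> AttributionInput:
    """Center-crop or symmetrically zero-pad a 3D volume to ``target_shape``.

    The affine translation is shifted so world coordinates of retained voxels
    are unchanged.
    """
    if len(x.spatial_shape) != 3:
        raise ValueError("crop_or_pad expects a 3D volume")
    starts = []
    out = x.values
    for axis, (s, t) in enumerate(zip(x.spatial_shape, target_shape)):
        if s >= t:
            start = (s - t) // 2
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(start, start + t)
            out = out[tuple(sl)]
        else:
            pad = t - s
            before = pad // 2
            width = [(0, 0)] * out.ndim
            width[axis] = (before, pad - before)
            out = np.pad(out, width)
            start = -before
        starts.append(start)
    affine = x.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ np.asarray(starts, dtype=float)
    return AttributionInput(out, affine=affine, channel_names=x.channel_names)


def extract_patch(
    x: AttributionInput,
    size: tuple = PATCH_SHAPE,
    origin: Optional[tuple] = None,
    seed: Optional[int] = None,
) -> AttributionInput:
    """Contiguous sub-volume of ``size``, at ``origin`` or a seeded random one."""
    sp = x.spatial_shape
    if any(s < t for s, t in zip(sp, size)):
        raise ValueError(f"patch size {size} exceeds volume shape {sp}")
    if origin is None:
        rng = np.random.default_rng(seed)
        origin = tuple(int(rng.integers(0, s - t + 1)) for s, t in zip(sp, size))
    sl = tuple(slice(o, o + t) for o, t in zip(origin, size))
    out = x.values[sl]
    affine = x.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ np.asarray(origin, dtype=float)
    return AttributionInput(out, affine=affine, channel_names=x.channel_names)


def _slice_2d(arr: np.ndarray, spec: RenderSpec) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    idx = spec.slice_index if spec.slice_index is not None else arr.shape[spec.slice_axis] // 2
    return np.take(arr, idx, axis=spec.slice_axis)


def _has_channel_axis(map_, values: np.ndarray) -> bool:
    res = getattr(map_, "resolution", None)
    if res == "layer":
        return False  # CAM maps carry no channel axis
    if res == "input":
        method = getattr(map_, "method", "")
        base = getattr(map_, "meta", {}).get("base_method", "")
        return "grad_cam" not in (method, base)
    return values.ndim == 4  # bare 3D array with trailing channels


def to_grayscale_map(
    map_, spec: Optional[RenderSpec] = None, channel_axis: Optional[bool] = None
) -> np.ndarray:
    """Attribution magnitude as a [0, 1] grayscale image (white = salient).

    Per-voxel magnitude is the max over channels of |value|, normalized by the
    ``percentile_clip`` percentile and clipped to 1.  ``channel_axis`` forces
    whether the trailing axis is treated as channels (inferred by default).
    """
    spec = spec or RenderSpec()
    values = np.asarray(getattr(map_, "values", map_), dtype=np.float64)
    arr = np.abs(values)
    if channel_axis is None:
        channel_axis = _has_channel_axis(map_, values)
    if channel_axis:
        arr = arr.max(axis=-1)
    img = _slice_2d(arr, spec)
    top = np.percentile(img, spec.percentile_clip)
    if top <= 0:
        top = img.max()  # sparse map: the clip percentile can be zero
    if top <= 0:
        warnings.warn("all-zero attribution map; rendering black image")
        return np.zeros_like(img)
    return np.clip(img / top, 0.0, 1.0)


def to_heatmap_overlay(
    map_, background: np.ndarray, spec: Optional[RenderSpec] = None
) -> np.ndarray:
    """Red-dominant heatmap over a grayscale anatomical slice, as RGB in [0,1].

    ``background`` is one modality slice (2D) or volume (sliced per spec);
    geometry must match the map after slicing.
    """
    spec = spec or RenderSpec(style="red_overlay")
    heat = to_grayscale_map(map_, spec)
    bg = np.asarray(background, dtype=np.float64)
    bg = _slice_2d(bg, spec)
    if bg.shape != heat.shape:
        raise ValueError(
            f"background slice shape {bg.shape} does not match map slice {heat.shape}"
        )
    lo, hi = bg.min(), bg.max()
    bg01 = (bg - lo) / (hi - lo) if hi > lo else np.zeros_like(bg)
    rgb_bg = np.stack([bg01] * 3, axis=-1)
    rgb_heat = colormaps["hot"](heat)[..., :3]
    w = spec.alpha * heat[..., None]  # opacity scales with score
    return (1 - w) * rgb_bg + w * rgb_heat
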
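"""Specimen masking, bone segmentation, cropping and bone volume fraction.

The segmentation chain mirrors the standard microCT workflow for whole
vertebral bodies: a generous specimen mask (low threshold + dilation +
hole filling), a single global grey threshold inside the mask, a
face-connectivity filter that keeps the largest 6-connected bone
component, a centred axial crop, and BV/TV as bone voxels over mask
voxels.  An automated morphological split separates the cortical shell
from the trabecular interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .errors import DegenerateDataError, ParameterError, SegmentationError
from .io import GreyVolume


@dataclass
class MaskVolume:
    """Binary specimen mask; 1 = inside the specimen envelope."""

    data: np.ndarray
    voxel_size: float
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(np.uint8)
        if self.data.ndim != 3:
            raise ParameterError("mask must be 3D")
        if not self.voxel_size > 0:
            raise ParameterError("voxel size must be positive")
        if int(self.data.sum()) == 0:
            raise SegmentationError("mask is empty")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class BinaryVolume:
    """Segmented bone voxels (1 = bone) plus the grey threshold that produced them."""

    data: np.ndarray
    voxel_size: float
    threshold_used: float = float("nan")
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(np.uint8)
        if self.data.ndim != 3:
            raise ParameterError("binary volume must be 3D")
        if not self.voxel_size > 0:
            raise ParameterError("voxel size must be positive")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class CropSpec:
    """Centred axial crop keeping ``fraction`` of the slices along ``axis``."""

    fraction: float
    axis: int = 0

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ParameterError(f"crop fraction must be in (0, 1], got {self.fraction}")


def crop_slices(n: int, fraction: float) -> slice:
    """Half-open slice of the centred slab keeping ``round(fraction * n)`` slices.

    The number kept is ``floor(fraction * n + 0.5)`` (round-half-up, so the
    result is independent of banker's rounding) and the offset is
    ``floor((n - kept) / 2)``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ParameterError(f"crop fraction must be in (0, 1], got {fraction}")
    kept = int(np.floor(fraction * n + 0.5))
    if kept < 1:
        raise ParameterError(f"crop of fraction {fraction} on {n} slices keeps no slice")
    offset = (n - kept) // 2
    return slice(offset, offset + kept)


def build_mask(vol: GreyVolume, low_threshold: float, dilation_radius: int = 2) -> MaskVolume:
    """Build the specimen mask: threshold low, dilate, fill holes.

    Hole filling is applied slice-by-slice along the axial (z) axis first,
    so the tube-like specimen cross-sections become solid, then once in 3D.

    Raises :class:`SegmentationError` if no voxel reaches ``low_threshold``.
    """
    if dilation_radius < 0:
        raise ParameterError("dilation radius must be >= 0")
    core = vol.data >= low_threshold
    if not core.any():
        raise SegmentationError(f"no voxel of {vol.name!r} reaches the low threshold {low_threshold}")
    if dilation_radius > 0:
        core = ndimage.binary_dilation(core, structure=morphology.ball(dilation_radius))
    filled = np.empty_like(core)
    for k in range(core.shape[0]):
        filled[k] = ndimage.binary_fill_holes(core[k])
    filled = ndimage.binary_fill_holes(filled)
    return MaskVolume(filled.astype(np.uint8), vol.voxel_size, vol.name)


def suggest_threshold(vol: GreyVolume, mask: MaskVolume) -> float:
    """Between-class-variance-maximising (Otsu) threshold inside the mask.

    Deterministic for a fixed input; raises :class:`DegenerateDataError`
    if the masked grey values are constant.
    """
    if vol.shape != mask.shape:
        raise ParameterError("volume and mask dimensions differ")
    values = vol.data[mask.data > 0]
    if values.min() == values.max():
        raise DegenerateDataError("masked grey values are constant; no threshold exists")
    return float(threshold_otsu(values, nbins=256))


def segment(vol: GreyVolume, mask: MaskVolume, threshold: float) -> BinaryVolume:
    """Bone = (grey >= threshold) AND mask.  No connectivity filtering yet."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    if vol.shape != mask.shape:
        raise ParameterError("volume and mask dimensions differ")
    bone = (vol.data >= threshold) & (mask.data > 0)
    if not bone.any():
        raise SegmentationError(f"threshold {threshold} leaves no bone voxel in {vol.name!r}")
    return BinaryVolume(bone.astype(np.uint8), vol.voxel_size, float(threshold), vol.name)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-neighbourhood


def connectivity_filter(bin_vol: BinaryVolume) -> BinaryVolume:
    """Keep only the largest face-connected (6-connected) bone component.

    Ties in component size are broken by the lowest component label, which
    corresponds to the component containing the first bone voxel in (z, y, x)
    scan order.
    """
    if bin_vol.count() == 0:
        raise SegmentationError("binary volume is empty")
    labels, n = ndimage.label(bin_vol.data, structure=_FACE_STRUCT)
    if n <= 1:
        return BinaryVolume(bin_vol.data.copy(), bin_vol.voxel_size, bin_vol.threshold_used, bin_vol.name)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))  # argmax returns the first (lowest) label on ties
    out = (labels == keep).astype(np.uint8)
    return BinaryVolume(out, bin_vol.voxel_size, bin_vol.threshold_used, bin_vol.name)


def crop_fraction(vol, spec: CropSpec):
    """Centred contiguous slab along ``spec.axis`` keeping ``spec.fraction`` of slices.

    Works on :class:`~microval.io.GreyVolume`, :class:`BinaryVolume` and
    :class:`MaskVolume`; returns the same type.  ``crop_fraction(v, CropSpec(1.0))``
    is the identity (a copy).
    """
    n = vol.data.shape[spec.axis]
    sl = crop_slices(n, spec.fraction)
    index = [slice(None)] * 3
    index[spec.axis] = sl
    data = vol.data[tuple(index)].copy()
    if isinstance(vol, BinaryVolume):
        return BinaryVolume(data, vol.voxel_size, vol.threshold_used, vol.name)
    if isinstance(vol, MaskVolume):
        return MaskVolume(data, vol.voxel_size, vol.name)
    return GreyVolume(data, vol.voxel_size, vol.name)


def bone_volume_fraction(bin_vol: BinaryVolume, mask: MaskVolume) -> float:
    """BV/TV: bone voxels divided by total voxels inside the mask."""
    if bin_vol.shape != mask.shape:
        raise ParameterError("binary volume and mask dimensions differ")
    tv = int(mask.data.sum())
    if tv == 0:
        raise SegmentationError("mask is empty; BV/TV undefined")
    bv = int((bin_vol.data & (mask.data > 0)).sum())
    if bv > int((bin_vol.data > 0).sum()):
        raise ParameterError("bone voxels must lie inside the mask")
    return bv / tv


BACKGROUND, TRABECULAR, CORTICAL = 0, 1, 2


def split_cortical_trabecular(bin_vol: BinaryVolume, closing_radius: int = 5, shell_depth: int = 5) -> np.ndarray:
    """Label bone voxels as cortical shell (2) or trabecular interior (1).

    The outer envelope is obtained by a per-axial-slice morphological
    closing of the bone cross-section (plus 2D hole filling); bone within
    ``shell_depth`` voxels of the envelope boundary is cortical, the rest
    trabecular.  The two labels partition the bone voxels exactly.
    """
    if shell_depth <= 0:
        raise ParameterError("shell depth must be positive")
    if closing_radius < 0:
        raise ParameterError("closing radius must be >= 0")
    bone = bin_vol.data > 0
    disk = morphology.disk(closing_radius) if closing_radius > 0 else None
    envelope = np.empty_like(bone)
    for k in range(bone.shape[0]):
        sl = bone[k]
        if disk is not None:
            sl = ndimage.binary_closing(sl, structure=disk)
        envelope[k] = ndimage.binary_fill_holes(sl)
    # distance (in voxels) from the envelope boundary, measured inside it,
    # per slice so the top/bottom faces of the slab do not count as boundary
    labels = np.zeros(bone.shape, dtype=np.uint8)
    for k in range(bone.shape[0]):
        depth = ndimage.distance_transform_edt(envelope[k])
        shell_band = envelope[k] & (depth <= shell_depth)
        labels[k][bone[k] & shell_band] = CORTICAL
        labels[k][bone[k] & ~shell_band] = TRABECULAR
    return labels
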
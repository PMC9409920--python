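"""Image preprocessing: ROI intersection, grid alignment, background removal
and fixed-bin-number histogram normalization.

The pipeline order is fixed: intersect reader ROIs, resample every modality
onto the reference (CET1WI) grid, zero everything outside the brain mask, then
discretize in-mask intensities to integer levels ``1..n_bins`` by equal-width
binning over the in-mask min-max range.  Level 0 is reserved as the background
sentinel.  Normalization statistics are taken over the whole brain mask, not
just the tumor ROI, because the images are normalized before any transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyROIError, InputError, ShapeMismatchError
from .phantom import MODALITIES, MultimodalStudy


@dataclass(frozen=True)
class NormalizationConfig:
    n_bins: int = 100
    reference_modality: str = "CET1WI"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise InputError("n_bins must be >= 2")
        if self.reference_modality not in MODALITIES:
            raise InputError(f"unknown reference modality {self.reference_modality!r}")


def intersect_rois(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixelwise AND of two reader masks; errors on an empty intersection."""
    if mask_a.shape != mask_b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    out = np.logical_and(mask_a != 0, mask_b != 0)
    if not out.any():
        raise EmptyROIError("ROI intersection is empty")
    return out


def resample_to_reference(image: np.ndarray, ref_shape: tuple) -> np.ndarray:
    """Bilinear resampling onto the reference grid.

    Both grids span the same field of view with pixel centers at
    ``(i + 0.5) / n`` of the extent.  Cells are linearly extrapolated at the
    border (target centers can fall outside the range of source centers when
    upsampling), which keeps the operation exact for planar intensity fields.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or len(ref_shape) != 2:
        raise InputError("resample_to_reference expects 2D grids")
    if min(image.shape) < 2 or min(ref_shape) < 2:
        raise InputError("grids must be >= 2 in each dimension")
    if not np.all(np.isfinite(image)):
        raise InputError("non-finite input values")
    if tuple(image.shape) == tuple(ref_shape):
        return image.copy()

    out = image
    for axis, (n_src, n_ref) in enumerate(zip(image.shape, ref_shape)):
        if n_src == n_ref:
            continue
        # source coordinate of each reference pixel center
        x = (np.arange(n_ref) + 0.5) * n_src / n_ref - 0.5
        i0 = np.clip(np.floor(x).astype(int), 0, n_src - 2)
        frac = x - i0  # may leave [0, 1] at the border -> linear extrapolation
        lo = np.take(out, i0, axis=axis)
        hi = np.take(out, i0 + 1, axis=axis)
        shape = [1, 1]
        shape[axis] = n_ref
        w = frac.reshape(shape)
        out = lo * (1.0 - w) + hi * w
    return out


def remove_background(image: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the brain mask; in-mask values unchanged."""
    if image.shape != brain_mask.shape:
        raise ShapeMismatchError(f"shapes differ: {image.shape} vs {brain_mask.shape}")
    out = np.array(image, dtype=float, copy=True)
    out[brain_mask == 0] = 0.0
    return out


def normalize_histogram(
    image: np.ndarray,
    brain_mask: np.ndarray,
    config: NormalizationConfig = NormalizationConfig(),
) -> np.ndarray:
    """Discretize in-mask intensities to integer levels ``1..n_bins``.

    Equal-width binning over the in-mask [min, max]:
    ``level = floor((v - lo) / (hi - lo) * n_bins) + 1`` clipped to ``n_bins``;
    a constant in-mask image maps entirely to level 1.  Out-of-mask pixels
    stay 0.  Both extreme levels 1 and ``n_bins`` are always attained, so the
    operation is idempotent and invariant under positive affine rescaling of
    the input.
    """
    if image.shape != brain_mask.shape:
        raise ShapeMismatchError(f"shapes differ: {image.shape} vs {brain_mask.shape}")
    mask = brain_mask != 0
    if not mask.any():
        raise EmptyROIError("empty brain mask")
    vals = np.asarray(image, dtype=float)[mask]
    if not np.all(np.isfinite(vals)):
        raise InputError("non-finite in-mask values")
    lo, hi = vals.min(), vals.max()
    out = np.zeros(image.shape, dtype=float)
    if hi == lo:
        out[mask] = 1.0
        return out
    levels = np.floor((vals - lo) / (hi - lo) * config.n_bins) + 1.0
    out[mask] = np.minimum(levels, float(config.n_bins))
    return out


def preprocess_study(
    study: MultimodalStudy,
    config: NormalizationConfig = NormalizationConfig(),
    second_roi: np.ndarray | None = None,
) -> MultimodalStudy:
    """Run the fixed preprocessing chain on one study.

    Optionally intersects the study ROI with a second reader's mask, aligns
    every modality to the reference grid, removes the background and
    normalizes each modality over the brain mask.
    """
    roi = study.roi_mask != 0
    if second_roi is not None:
        roi = intersect_rois(roi, second_roi)
    ref_shape = study.images[config.reference_modality].shape
    if study.brain_mask.shape != ref_shape:
        raise ShapeMismatchError("brain mask must live on the reference grid")
    images = {}
    for name in MODALITIES:
        img = resample_to_reference(study.images[name], ref_shape)
        img = remove_background(img, study.brain_mask)
        images[name] = normalize_histogram(img, study.brain_mask, config)
    return MultimodalStudy(
        patient_id=study.patient_id,
        label=study.label,
        images=images,
        roi_mask=roi,
        brain_mask=study.brain_mask != 0,
    )
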
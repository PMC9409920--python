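"""Synthetic multimodal brain-tumor phantoms.

Generates seeded cohorts of 2D "patients" with the statistical structure the
downstream radiomics pipeline assumes: four co-registered modalities
(CET1WI, T2FLAIR, DWI, ADC), a tumor ROI and a brain mask, and a binary class
label.  The two classes differ only in

* the CET1WI rim-enhancement intensity (a first-order, pre-transform signal),
  shifted by ``rim_contrast_delta`` for the positive (GBM-like) class, and
* oriented fine texture inside the T2FLAIR ROI (an oriented sinusoidal grating
  at ``texture_angle_deg``), present only in the positive class,

so that pre-transform statistics carry the first signal family and oriented
wavelet subbands the second.  DWI and ADC are smoothed companions with
independent noise and carry no class signal at all.

The anatomy is deliberately minimal - piecewise-constant ellipse "brain",
ring "skull", disk tumor with an enhancing rim, Gaussian pixel noise.  The
point is contract coverage and controllable effect sizes, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

import numpy as np

from .errors import ConfigurationError

#: Canonical modality names, in fixed order.
MODALITIES = ("CET1WI", "T2FLAIR", "DWI", "ADC")

#: Short modality labels used in feature names.
MODALITY_SHORT = {"CET1WI": "T1", "T2FLAIR": "T2", "DWI": "DWI", "ADC": "ADC"}


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation parameters.

    Defaults emulate the 51-patient study layout (27 positive GBM-like,
    24 negative SBM-like) on a 128 px grid with moderate class effects
    (rim shift 3x the pixel noise, grating amplitude 2x the pixel noise).
    The default grating period (3 px) lies inside the level-1 wavelet detail
    band (periods of roughly 2-4 px); longer periods fall into the
    approximation band, where no oriented subband can see them.
    """

    n_class_pos: int = 27
    n_class_neg: int = 24
    image_size: int = 128
    tumor_radius_range: Tuple[float, float] = (12.0, 20.0)
    rim_contrast_delta: float = 15.0
    texture_angle_deg: float = 15.0
    texture_amplitude: float = 10.0
    texture_period_px: float = 3.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class_pos < 1 or self.n_class_neg < 1:
            raise ConfigurationError("each class needs at least one patient")
        if self.image_size < 64 or self.image_size % 2 != 0:
            raise ConfigurationError("image_size must be even and >= 64")
        rmin, rmax = self.tumor_radius_range
        if rmin < 8:
            raise ConfigurationError("minimum tumor radius is 8 px")
        if rmax < rmin:
            raise ConfigurationError("tumor_radius_range must be (min, max) with min <= max")
        if self.texture_period_px < 2:
            raise ConfigurationError("texture_period_px must be >= 2 (Nyquist)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be nonnegative")
        # tumor (incl. rim margin) must fit inside the inner brain ellipse
        if rmax + _RIM_WIDTH >= 0.36 * self.image_size:
            raise ConfigurationError("tumor larger than brain for this image_size")


@dataclass
class MultimodalStudy:
    """One patient: four co-registered modality slices, masks and a label."""

    patient_id: str
    label: int  # 1 = positive (GBM-like), 0 = negative (SBM-like)
    images: Dict[str, np.ndarray]
    roi_mask: np.ndarray
    brain_mask: np.ndarray

    def validate(self) -> None:
        if set(self.images) != set(MODALITIES):
            raise ConfigurationError(
                f"{self.patient_id}: modalities must be exactly {MODALITIES}"
            )
        ref = self.roi_mask.shape
        if self.brain_mask.shape != ref:
            raise ConfigurationError(f"{self.patient_id}: mask shapes differ")
        if np.any(self.roi_mask & ~self.brain_mask):
            raise ConfigurationError(f"{self.patient_id}: ROI extends outside brain mask")
        if int(self.roi_mask.sum()) < 64:
            raise ConfigurationError(f"{self.patient_id}: ROI smaller than 64 pixels")
        for name, img in self.images.items():
            if not np.all(np.isfinite(img)):
                raise ConfigurationError(f"{self.patient_id}/{name}: non-finite intensities")


_RIM_WIDTH = 3.0  # px, enhancing rim thickness on CET1WI


def oriented_grating(
    shape: Tuple[int, int], angle_deg: float, period_px: float, amplitude: float
) -> np.ndarray:
    """Zero-mean sinusoid varying along ``angle_deg``.

    The angle is measured from the horizontal axis, counter-clockwise as
    displayed (image row index increasing downward), so the direction of
    variation is ``(dx, dy) = (cos a, -sin a)`` in (column, row) steps.
    At 0 deg rows are constant and columns sinusoidal; the 90 deg pattern is
    the transpose of the 0 deg pattern on square grids.  Peak value is
    exactly ``amplitude`` (cosine phase zero at the origin).

    Periods down to the two-pixel Nyquist limit are allowed: diagonal
    gratings only enter the level-1 wavelet detail band (per-axis frequency
    above pi/2) for periods below 2*sqrt(2) px, and the orientation
    selectivity suite probes exactly that regime.
    """
    if period_px < 2:
        raise ConfigurationError("period_px must be >= 2 (Nyquist)")
    rows, cols = shape
    i, j = np.mgrid[0:rows, 0:cols]
    theta = np.deg2rad(angle_deg)
    phase = 2.0 * np.pi * (j * np.cos(theta) - i * np.sin(theta)) / period_px
    return amplitude * np.cos(phase)


def _disk(shape: Tuple[int, int], center: Tuple[float, float], radius: float) -> np.ndarray:
    i, j = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (i - center[0]) ** 2 + (j - center[1]) ** 2 <= radius**2


def _ellipse(shape: Tuple[int, int], center: Tuple[float, float], semi: Tuple[float, float]) -> np.ndarray:
    i, j = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((i - center[0]) / semi[0]) ** 2 + ((j - center[1]) / semi[1]) ** 2 <= 1.0


def _generate_study(config: PhantomConfig, index: int, label: int, rng: np.random.Generator) -> MultimodalStudy:
    s = config.image_size
    shape = (s, s)
    center = (s / 2.0, s / 2.0)
    inner_semi = (0.36 * s, 0.42 * s)  # brain tissue ellipse (rows, cols)
    outer_semi = (0.40 * s, 0.46 * s)  # includes the skull ring

    brain_mask = _ellipse(shape, center, outer_semi)
    tissue = _ellipse(shape, center, inner_semi)
    skull = brain_mask & ~tissue

    # tumor geometry: radius and an offset that keeps the disk inside tissue
    rmin, rmax = config.tumor_radius_range
    radius = rng.uniform(rmin, rmax)
    margin = radius + _RIM_WIDTH
    max_off_r = inner_semi[0] - margin
    max_off_c = inner_semi[1] - margin
    if max_off_r <= 0 or max_off_c <= 0:
        raise ConfigurationError("tumor larger than brain")
    off_r = rng.uniform(-0.6, 0.6) * max_off_r
    off_c = rng.uniform(-0.6, 0.6) * max_off_c
    tcenter = (center[0] + off_r, center[1] + off_c)
    roi_mask = _disk(shape, tcenter, radius)
    core = _disk(shape, tcenter, max(radius - _RIM_WIDTH, 1.0))
    rim = roi_mask & ~core

    # per-patient baseline jitter, class-independent
    base_jitter = rng.normal(0.0, 2.0)

    def noise() -> np.ndarray:
        return rng.normal(0.0, config.noise_sigma, shape)

    # CET1WI: tissue 100, skull 160, necrotic core 70, enhancing rim 140
    # (+rim_contrast_delta in the positive class)
    rim_level = 140.0 + (config.rim_contrast_delta if label == 1 else 0.0)
    cet1 = np.zeros(shape)
    cet1[tissue] = 100.0 + base_jitter
    cet1[skull] = 160.0 + base_jitter
    cet1[core] = 70.0 + base_jitter
    cet1[rim] = rim_level + base_jitter
    cet1 += noise()

    # T2FLAIR: tissue 90, skull 40, tumor 130; positive class adds the
    # oriented grating inside the ROI only.
    t2 = np.zeros(shape)
    t2[tissue] = 90.0 + base_jitter
    t2[skull] = 40.0 + base_jitter
    t2[roi_mask] = 130.0 + base_jitter
    if label == 1 and config.texture_amplitude != 0.0:
        grating = oriented_grating(
            shape, config.texture_angle_deg, config.texture_period_px, config.texture_amplitude
        )
        t2[roi_mask] += grating[roi_mask]
    t2 += noise()

    # DWI / ADC: smoothed anatomy companions, independent noise, no class signal
    from scipy.ndimage import gaussian_filter

    dwi_base = np.zeros(shape)
    dwi_base[tissue] = 80.0 + base_jitter
    dwi_base[skull] = 30.0 + base_jitter
    dwi_base[roi_mask] = 120.0 + base_jitter
    dwi = gaussian_filter(dwi_base, 2.0) + noise()

    adc_base = np.zeros(shape)
    adc_base[tissue] = 110.0 + base_jitter
    adc_base[skull] = 50.0 + base_jitter
    adc_base[roi_mask] = 60.0 + base_jitter
    adc = gaussian_filter(adc_base, 2.0) + noise()

    study = MultimodalStudy(
        patient_id=f"P{index:03d}",
        label=label,
        images={"CET1WI": cet1, "T2FLAIR": t2, "DWI": dwi, "ADC": adc},
        roi_mask=roi_mask,
        brain_mask=brain_mask,
    )
    study.validate()
    return study


def generate_cohort(config: PhantomConfig) -> List[MultimodalStudy]:
    """Generate ``n_class_pos + n_class_neg`` studies, positives first.

    Each patient draws from an independent child stream of
    ``SeedSequence(config.seed)``, so the cohort is bit-identical across runs
    and individual patients are reproducible regardless of cohort size order.
    """
    labels = [1] * config.n_class_pos + [0] * config.n_class_neg
    children = np.random.SeedSequence(config.seed).spawn(len(labels))
    return [
        _generate_study(config, idx, lab, np.random.default_rng(child))
        for idx, (lab, child) in enumerate(zip(labels, children))
    ]


def null_config(config: PhantomConfig) -> PhantomConfig:
    """The same cohort conditions with every class effect switched off."""
    return replace(config, rim_contrast_delta=0.0, texture_amplitude=0.0)
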
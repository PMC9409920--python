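"""First-order statistics over ROI pixels and the 264-column feature table.

Six statistics per derived image (mean, coefficient of variation, skewness,
kurtosis, energy, entropy) over the ROI pixel values, for each of the 11
derived images (1 pre-transform + 4 Haar DWT + 6 DTCWT magnitudes) of each of
the 4 modalities: 4 x 11 x 6 = 264 features per patient.

Conventions (population moments, matching common MATLAB defaults):

* ``mean``      sample mean
* ``cv``        population sd / mean (0 when the mean is 0)
* ``skewness``  third standardized population moment
* ``kurtosis``  fourth standardized population moment, *raw* (Gaussian -> 3)
* ``energy``    plain sum of squared values
* ``entropy``   Shannon entropy (bits) of a 100-bin equal-width histogram
                spanning [min, max] of the values

Degenerate inputs give defined sentinels instead of NaN: a constant vector
has cv per its definition, and skewness = kurtosis = entropy = 0, so the
feature matrix is always complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyROIError, InputError
from .phantom import MODALITIES, MODALITY_SHORT, MultimodalStudy
from .wavelets import DTCWT_ORIENTATIONS, DWT_COMPONENTS, DerivedImage, derive_images

STATISTICS = ("mean", "cv", "skewness", "kurtosis", "energy", "entropy")

ENTROPY_BINS = 100  # reuses the normalization bin count for internal consistency

#: transform -> component labels, in canonical order
TRANSFORM_COMPONENTS = {
    "PRE": ("-",),
    "DWT": DWT_COMPONENTS,
    "DTCWT": DTCWT_ORIENTATIONS,
}


@dataclass(frozen=True)
class FeatureName:
    """One column of the feature table; canonical form ``T2/DTCWT/+45/kurtosis``."""

    modality: str
    transform: str
    component: str
    statistic: str

    def __str__(self) -> str:
        return f"{self.modality}/{self.transform}/{self.component}/{self.statistic}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        parts = name.split("/")
        if len(parts) != 4:
            raise InputError(f"not a canonical feature name: {name!r}")
        return cls(*parts)


def feature_catalogue() -> List[FeatureName]:
    """The 264 canonical feature names in fixed column order:
    modality, then transform (PRE < DWT < DTCWT), then component, then
    statistic (mean < cv < skewness < kurtosis < energy < entropy)."""
    names = [
        FeatureName(MODALITY_SHORT[mod], transform, comp, stat)
        for mod in MODALITIES
        for transform, comps in TRANSFORM_COMPONENTS.items()
        for comp in comps
        for stat in STATISTICS
    ]
    assert len(names) == 264
    return names


def roi_values(image: DerivedImage) -> np.ndarray:
    """ROI pixel values of a derived image, row-major order."""
    mask = image.roi != 0
    if mask.shape != image.pixels.shape:
        raise InputError(f"{image.tag}: ROI grid does not match pixel grid")
    if not mask.any():
        raise EmptyROIError(f"{image.tag}: empty ROI")
    return np.asarray(image.pixels, dtype=float)[mask]


def compute_statistics(values: Sequence[float]) -> Dict[str, float]:
    """The six first-order statistics of a value vector."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise EmptyROIError("empty value vector")
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite values")
    n = x.size
    mu = float(x.mean())
    sigma = float(x.std())  # population (1/n)
    energy = float(np.sum(x**2))
    cv = sigma / mu if mu != 0.0 else 0.0
    if sigma == 0.0:
        return {"mean": mu, "cv": cv, "skewness": 0.0, "kurtosis": 0.0,
                "energy": energy, "entropy": 0.0}
    z = (x - mu) / sigma
    skewness = float(np.mean(z**3))
    kurtosis = float(np.mean(z**4))
    lo, hi = float(x.min()), float(x.max())
    counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(lo, hi))
    p = counts[counts > 0] / n
    entropy = float(-np.sum(p * np.log2(p)))
    return {"mean": mu, "cv": cv, "skewness": skewness, "kurtosis": kurtosis,
            "energy": energy, "entropy": entropy}


def study_features(study: MultimodalStudy) -> Dict[str, float]:
    """All 264 named features of one preprocessed study."""
    row: Dict[str, float] = {}
    for img in derive_images(study):
        stats = compute_statistics(roi_values(img))
        for stat, value in stats.items():
            row[f"{img.tag}/{stat}"] = value
    return row


def build_feature_table(cohort: Iterable[MultimodalStudy]) -> pd.DataFrame:
    """Patients x 264 table; index = patient ids, first column ``label``.

    Rows follow cohort order; columns follow the canonical catalogue order.
    Any per-study failure is re-raised with the patient id attached.
    """
    columns = [str(n) for n in feature_catalogue()]
    rows, labels, ids = [], [], []
    for study in cohort:
        try:
            feats = study_features(study)
        except Exception as exc:
            raise type(exc)(f"{study.patient_id}: {exc}") from exc
        rows.append([feats[c] for c in columns])
        labels.append(int(study.label))
        ids.append(study.patient_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"), columns=columns)
    table.insert(0, "label", labels)
    if table.isna().any().any():
        raise InputError("feature table contains missing values")
    return table


def feature_matrix(table: pd.DataFrame, features: Sequence[str] | None = None):
    """Split a feature table into (X, y, feature names)."""
    names = [c for c in table.columns if c != "label"] if features is None else list(features)
    return table[names].to_numpy(dtype=float), table["label"].to_numpy(dtype=int), names
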
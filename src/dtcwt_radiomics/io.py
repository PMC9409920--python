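"""Readers and writers: NIfTI/PNG images, cohort manifests, feature tables,
selection and evaluation reports.

Cohorts live in a directory tree with one folder per patient (one file per
modality plus ``roi`` and ``brain`` masks) and a cohort-level ``manifest.csv``
(patient_id, label, per-file paths, generator seed).  Intensity images are
stored as float32 NIfTI by default; PNG output is 16-bit and min-max rescaled,
so it is for inspection, not for lossless round trips.  Coordinates are
row-major, origin at the top-left, 0-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .phantom import MODALITIES, MultimodalStudy

_MODALITY_FILES = {m: m.lower() for m in MODALITIES}


def write_image(path: Path, array: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".png":
        import imageio.v3 as iio

        arr = np.asarray(array, dtype=float)
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), np.eye(4)), path)
    else:
        raise InputError(f"unsupported image format: {path.name}")


def read_image(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=float)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asarray(nib.load(path).get_fdata(), dtype=float)
        return np.squeeze(data)
    raise InputError(f"unsupported image format: {path.name}")


def write_cohort(
    studies: Iterable[MultimodalStudy],
    out_dir: Path,
    fmt: str = "nifti",
    seed: Optional[int] = None,
) -> Path:
    """Write a cohort tree and return the manifest path."""
    if fmt not in ("nifti", "png"):
        raise InputError("fmt must be 'nifti' or 'png'")
    ext = ".nii.gz" if fmt == "nifti" else ".png"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in studies:
        pdir = out_dir / study.patient_id
        pdir.mkdir(exist_ok=True)
        row = {"patient_id": study.patient_id, "label": int(study.label)}
        for modality, stem in _MODALITY_FILES.items():
            p = pdir / f"{stem}{ext}"
            write_image(p, study.images[modality])
            row[modality.lower()] = str(p.relative_to(out_dir))
        for name, mask in [("roi", study.roi_mask), ("brain", study.brain_mask)]:
            p = pdir / f"{name}{ext}"
            write_image(p, mask.astype(np.float32))
            row[name] = str(p.relative_to(out_dir))
        if seed is not None:
            row["seed"] = seed
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: Path) -> List[MultimodalStudy]:
    """Load a cohort from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "label", "roi", "brain"} | {m.lower() for m in MODALITIES}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"manifest missing columns: {sorted(missing)}")
    studies = []
    for _, row in df.iterrows():
        try:
            images = {m: read_image(base / row[m.lower()]) for m in MODALITIES}
            roi = read_image(base / row["roi"]) != 0
            brain = read_image(base / row["brain"]) != 0
        except Exception as exc:
            raise InputError(f"patient {row['patient_id']}: {exc}") from exc
        studies.append(
            MultimodalStudy(
                patient_id=str(row["patient_id"]),
                label=int(row["label"]),
                images=images,
                roi_mask=roi,
                brain_mask=brain,
            )
        )
    return studies


def write_feature_table(table: pd.DataFrame, path: Path) -> None:
    """CSV round trip at 17 significant digits (bit-identical re-read)."""
    table.to_csv(path, float_format="%.17g")


def read_feature_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id", float_precision="round_trip")


def config_fingerprint(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
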
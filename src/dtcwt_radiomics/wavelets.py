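"""Single-level 2D wavelet analysis: orthonormal Haar DWT and the level-1
dual-tree complex wavelet transform (DTCWT), with exact inverses.

Haar DWT
    Separable orthonormal Haar on non-overlapping 2x2 blocks
    (low = (a+b)/sqrt2, high = (a-b)/sqrt2 along rows then columns), giving
    approximation A and H/V/D detail bands at half resolution.  Energy is
    conserved exactly and the inverse is exact.

DTCWT, level 1
    The standard first-level dual-tree construction: one real biorthogonal
    wavelet tree plus a second tree whose filters are the same pair delayed by
    one sample.  Because a one-sample delay before decimation is equivalent to
    taking the other polyphase component, the two trees are computed at once
    as an *undecimated* separable filtering (LeGall 5/3 analysis pair,
    zero-phase, whole-sample mirror extension) followed by a 2x2 polyphase
    split.  Per detail direction the four (row-tree x column-tree) quads are
    combined into two complex subbands by the unitary quad-to-complex map

        p = (a + j b) / sqrt2,   q = (d - j c) / sqrt2,   z = p -/+ q

    yielding six complex subbands oriented at {+15, +45, +75, -75, -45, -15}
    degrees.  The combination is unitary, so the six magnitude images jointly
    conserve the detail-band energy, and the whole analysis inverts exactly
    (synthesis 5/3 pair, inverse quad map, average over trees).

Angles follow the display convention used throughout the package: measured
from the horizontal axis, counter-clockwise as displayed, with the image row
index increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import correlate1d

from .errors import InputError, ShapeMismatchError
from .phantom import MODALITIES, MODALITY_SHORT, MultimodalStudy

# ---------------------------------------------------------------------------
# filters: LeGall 5/3 biorthogonal pair, zero-phase (odd length, symmetric).
# h0*g0 + h1*g1 = 2*delta, so the undecimated analysis/synthesis round trip
# is exact; with mirror extension it is exact including boundaries.
ANALYSIS_LO = np.array([-1.0, 2.0, 6.0, 2.0, -1.0]) / 8.0
ANALYSIS_HI = np.array([-1.0, 2.0, -1.0]) / 2.0
SYNTHESIS_LO = np.array([1.0, 2.0, 1.0]) / 2.0
SYNTHESIS_HI = np.array([-1.0, -2.0, 6.0, -2.0, -1.0]) / 8.0

#: Fixed orientation labels, in canonical order.
DTCWT_ORIENTATIONS = ("+15", "+45", "+75", "-75", "-45", "-15")

DWT_COMPONENTS = ("A", "H", "V", "D")

_MIN_DTCWT_SIZE = 8


def _filt(x: np.ndarray, h: np.ndarray, axis: int) -> np.ndarray:
    """Zero-phase correlation with whole-sample mirror extension."""
    return correlate1d(x, h, axis=axis, mode="mirror", output=np.float64)


def _pad_even(image: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Edge-replicate odd dimensions to even; report the padding."""
    pr = image.shape[0] % 2
    pc = image.shape[1] % 2
    if pr or pc:
        image = np.pad(image, ((0, pr), (0, pc)), mode="edge")
    return image, (pr, pc)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError("expected a 2D grid")
    if not np.all(np.isfinite(image)):
        raise InputError("non-finite input values")
    return image


# ---------------------------------------------------------------------------
# Haar DWT


@dataclass
class DwtSubbands:
    """One-level orthonormal Haar decomposition (A/H/V/D at half resolution)."""

    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray
    padding: Tuple[int, int] = (0, 0)

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)


def dwt2_haar(image: np.ndarray) -> DwtSubbands:
    """Single-level separable orthonormal Haar analysis."""
    image = _check_image(image)
    image, padding = _pad_even(image)
    a = image[0::2, 0::2]
    b = image[0::2, 1::2]
    c = image[1::2, 0::2]
    d = image[1::2, 1::2]
    return DwtSubbands(
        A=(a + b + c + d) / 2.0,
        H=(a + b - c - d) / 2.0,
        V=(a - b + c - d) / 2.0,
        D=(a - b - c + d) / 2.0,
        padding=padding,
    )


def idwt2_haar(subbands: DwtSubbands) -> np.ndarray:
    """Exact inverse of :func:`dwt2_haar`; crops any recorded padding."""
    A, H, V, D = subbands.A, subbands.H, subbands.V, subbands.D
    if not (A.shape == H.shape == V.shape == D.shape):
        raise ShapeMismatchError("subband shapes differ")
    rows, cols = A.shape
    out = np.empty((2 * rows, 2 * cols), dtype=float)
    out[0::2, 0::2] = (A + H + V + D) / 2.0
    out[0::2, 1::2] = (A + H - V - D) / 2.0
    out[1::2, 0::2] = (A - H + V - D) / 2.0
    out[1::2, 1::2] = (A - H - V + D) / 2.0
    pr, pc = subbands.padding
    if pr or pc:
        out = out[: out.shape[0] - pr, : out.shape[1] - pc]
    return out


# ---------------------------------------------------------------------------
# DTCWT level 1


@dataclass
class DtcwtSubbands:
    """Level-1 dual-tree decomposition.

    ``oriented`` maps the six fixed orientation labels to complex subbands at
    half resolution.  ``lowpass`` is the full-resolution undecimated lowpass
    image; its 2x2 polyphase quads are the per-tree lowpass grids (the two
    pure-tree ones are exposed by :meth:`lowpass_pair`) and all four phases
    are required for exact inversion.
    """

    oriented: Dict[str, np.ndarray]
    lowpass: np.ndarray
    padding: Tuple[int, int] = (0, 0)

    def magnitude(self, label: str) -> np.ndarray:
        return np.abs(self.oriented[label])

    def lowpass_pair(self) -> Tuple[np.ndarray, np.ndarray]:
        """The two pure-tree lowpass grids (tree A = even phase, B = odd)."""
        return self.lowpass[0::2, 0::2], self.lowpass[1::2, 1::2]


def _q2c(y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Unitary quad-to-complex combination of one undecimated detail band."""
    a = y[0::2, 0::2]
    b = y[0::2, 1::2]
    c = y[1::2, 0::2]
    d = y[1::2, 1::2]
    s = np.sqrt(0.5)
    p = (a + 1j * b) * s
    q = (d - 1j * c) * s
    return p - q, p + q


def _c2q(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_q2c`."""
    p = (z1 + z2) / 2.0
    q = (z2 - z1) / 2.0
    rows, cols = z1.shape
    y = np.empty((2 * rows, 2 * cols), dtype=float)
    s = np.sqrt(2.0)
    y[0::2, 0::2] = s * p.real
    y[0::2, 1::2] = s * p.imag
    y[1::2, 1::2] = s * q.real
    y[1::2, 0::2] = -s * q.imag
    return y


def dtcwt2_level1(image: np.ndarray) -> DtcwtSubbands:
    """Level-1 dual-tree complex wavelet analysis (six oriented subbands)."""
    image = _check_image(image)
    if min(image.shape) < _MIN_DTCWT_SIZE:
        raise InputError(f"image smaller than filter support (min dim {_MIN_DTCWT_SIZE})")
    image, padding = _pad_even(image)

    lo_v = _filt(image, ANALYSIS_LO, axis=0)
    hi_v = _filt(image, ANALYSIS_HI, axis=0)
    ll = _filt(lo_v, ANALYSIS_LO, axis=1)
    lh = _filt(lo_v, ANALYSIS_HI, axis=1)  # highpass along columns (x)
    hl = _filt(hi_v, ANALYSIS_LO, axis=1)  # highpass along rows (y)
    hh = _filt(hi_v, ANALYSIS_HI, axis=1)

    # q2c of each detail band yields the two subbands of opposite-sign angle;
    # the mapping of (band, z1/z2) to angle labels is fixed by the grating
    # selectivity suite.
    z_lh = _q2c(lh)
    z_hh = _q2c(hh)
    z_hl = _q2c(hl)
    by_label = {
        "+15": z_lh[1], "-15": z_lh[0],
        "+45": z_hh[1], "-45": z_hh[0],
        "+75": z_hl[1], "-75": z_hl[0],
    }
    oriented = {k: by_label[k] for k in DTCWT_ORIENTATIONS}
    return DtcwtSubbands(oriented=oriented, lowpass=ll, padding=padding)


def idtcwt2_level1(subbands: DtcwtSubbands) -> np.ndarray:
    """Exact inverse of :func:`dtcwt2_level1`; crops any recorded padding."""
    try:
        z = {k: subbands.oriented[k] for k in DTCWT_ORIENTATIONS}
    except KeyError as exc:
        raise InputError(f"missing orientation {exc}") from exc
    shapes = {v.shape for v in z.values()}
    if len(shapes) != 1:
        raise ShapeMismatchError("oriented subband shapes differ")
    (half,) = shapes
    if subbands.lowpass.shape != (2 * half[0], 2 * half[1]):
        raise ShapeMismatchError("lowpass shape inconsistent with subbands")

    lh = _c2q(z["-15"], z["+15"])
    hh = _c2q(z["-45"], z["+45"])
    hl = _c2q(z["-75"], z["+75"])

    lo_v = (_filt(subbands.lowpass, SYNTHESIS_LO, axis=1) + _filt(lh, SYNTHESIS_HI, axis=1)) / 2.0
    hi_v = (_filt(hl, SYNTHESIS_LO, axis=1) + _filt(hh, SYNTHESIS_HI, axis=1)) / 2.0
    out = (_filt(lo_v, SYNTHESIS_LO, axis=0) + _filt(hi_v, SYNTHESIS_HI, axis=0)) / 2.0

    pr, pc = subbands.padding
    if pr or pc:
        out = out[: out.shape[0] - pr, : out.shape[1] - pc]
    return out


# ---------------------------------------------------------------------------
# derived-image catalogue


def downsample_mask(mask: np.ndarray, factor: int = 2) -> np.ndarray:
    """Any-overlap downsampling: output (i, j) is true iff any covered input
    pixel is true.  Odd dimensions follow the transforms' edge-replication
    padding rule."""
    if factor != 2:
        raise InputError("only factor 2 is supported")
    mask = np.asarray(mask) != 0
    mask, _ = _pad_even(mask.astype(float))
    mask = mask != 0
    return mask[0::2, 0::2] | mask[0::2, 1::2] | mask[1::2, 0::2] | mask[1::2, 1::2]


@dataclass
class DerivedImage:
    """One of the 11 per-modality feature images, with its provenance tag."""

    modality: str  # short label: T1 / T2 / DWI / ADC
    transform: str  # PRE / DWT / DTCWT
    component: str  # "-" | A/H/V/D | +15/+45/+75/-75/-45/-15
    pixels: np.ndarray
    roi: np.ndarray

    @property
    def tag(self) -> str:
        return f"{self.modality}/{self.transform}/{self.component}"


def derive_images(study: MultimodalStudy) -> List[DerivedImage]:
    """The 11 derived images per modality (1 PRE + 4 DWT + 6 DTCWT magnitude),
    44 in total for a four-modality study, each carrying the ROI on its grid."""
    missing = [m for m in MODALITIES if m not in study.images]
    if missing:
        raise InputError(f"{study.patient_id}: missing modalities {missing}")
    roi_full = study.roi_mask != 0
    roi_half = downsample_mask(roi_full)
    out: List[DerivedImage] = []
    for modality in MODALITIES:
        short = MODALITY_SHORT[modality]
        image = study.images[modality]
        out.append(DerivedImage(short, "PRE", "-", np.asarray(image, dtype=float), roi_full))
        dwt = dwt2_haar(image)
        for comp in DWT_COMPONENTS:
            out.append(DerivedImage(short, "DWT", comp, dwt.component(comp), roi_half))
        dt = dtcwt2_level1(image)
        for comp in DTCWT_ORIENTATIONS:
            out.append(DerivedImage(short, "DTCWT", comp, dt.magnitude(comp), roi_half))
    return out
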
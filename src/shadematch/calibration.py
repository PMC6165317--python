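"""Shade-tab-based color calibration.

Cameras that are nominally identical still differ in their electronics and
optics, so the same tab yields different RGB on different devices.  Rather
than a generic color chart, calibration uses a five-patch standard chart
whose colors are the mean colors of the 1M1, 2M2, 3M2, 4M2 and 5M2 tabs —
these span the tooth-color region of RGB space, which is the only region the
device needs to get right.

A 3x3 color correction matrix (CCM) M is fitted by least squares so that
M @ measured_i ~ reference_i over the chart patches, and is applied per pixel
(or per mean color) before conversion to CIELAB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .colorspace import LabColor, RGBColor, lab_to_rgb, rgb_to_lab
from .errors import CalibrationError, ValidationError

__all__ = [
    "CHART_TAB_LABELS",
    "StandardChart",
    "ColorCorrectionMatrix",
    "fit_ccm",
    "apply_ccm",
    "build_chart_from_palette",
]

logger = logging.getLogger(__name__)

#: The five tabs whose mean colors define the standard calibration chart.
CHART_TAB_LABELS: tuple[str, ...] = ("1M1", "2M2", "3M2", "4M2", "5M2")


@dataclass(frozen=True)
class StandardChart:
    """Ordered (label, reference RGB) pairs of the 5-patch chart."""

    entries: tuple[tuple[str, RGBColor], ...]

    def __post_init__(self) -> None:
        labels = tuple(lab for lab, _ in self.entries)
        if labels != CHART_TAB_LABELS:
            raise ValidationError(
                f"chart labels must be {CHART_TAB_LABELS}, got {labels}"
            )
        if np.linalg.matrix_rank(self.reference_array()) < 3:
            raise ValidationError("chart reference colors do not span 3-space")

    def reference_array(self) -> np.ndarray:
        return np.array([c.to_array() for _, c in self.entries])

    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.entries)


@dataclass(frozen=True)
class ColorCorrectionMatrix:
    """3x3 (or 3x4 affine) linear map from measured RGB to corrected RGB."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape not in ((3, 3), (3, 4)):
            raise ValidationError(f"CCM must be 3x3 or 3x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("CCM has non-finite entries")
        object.__setattr__(self, "m", m)

    @property
    def affine(self) -> bool:
        return self.m.shape == (3, 4)


def _as_matrix(colors: Sequence[RGBColor] | np.ndarray) -> np.ndarray:
    if isinstance(colors, np.ndarray):
        arr = np.asarray(colors, dtype=float)
    else:
        arr = np.array([c.to_array() for c in colors], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise CalibrationError(f"expected an (n, 3) color array, got {arr.shape}")
    return arr


def fit_ccm(
    measured: Sequence[RGBColor] | np.ndarray,
    reference: Sequence[RGBColor] | np.ndarray,
    *,
    affine: bool = False,
) -> ColorCorrectionMatrix:
    """Fit the color correction matrix by least squares.

    Solves min_M sum_i ||M @ measured_i - reference_i||^2, one independent
    regression per output channel.  The default model is a pure 3x3 linear
    map; ``affine=True`` appends a bias column (3x4).  Requires at least
    three colors spanning 3-space.
    """
    X = _as_matrix(measured)
    Y = _as_matrix(reference)
    if X.shape[0] != Y.shape[0]:
        raise CalibrationError(
            f"measured ({X.shape[0]}) and reference ({Y.shape[0]}) lengths differ"
        )
    if X.shape[0] < 3:
        raise CalibrationError("need at least 3 chart colors to fit a CCM")
    if np.linalg.matrix_rank(X, tol=1e-10) < 3:
        raise CalibrationError("measured colors are rank deficient; singular fit")
    if affine:
        X = np.hstack([X, np.ones((X.shape[0], 1))])
    sol, residuals, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("CCM design matrix rank %d < %d; minimum-norm solution", rank, X.shape[1])
    return ColorCorrectionMatrix(sol.T)


def apply_ccm(image_or_color, ccm: ColorCorrectionMatrix):
    """Apply a CCM to a single color or a pixel array.

    Accepts an :class:`RGBColor`, a float array with trailing axis 3 (unit
    scale), or a uint8 image; the corrected output is clamped to the valid
    range and returned in the same form.
    """
    if isinstance(image_or_color, RGBColor):
        v = image_or_color.to_array()
        out = _apply(v, ccm)
        return RGBColor(*np.clip(out, 0.0, 1.0))
    arr = np.asarray(image_or_color)
    if arr.shape[-1] != 3:
        raise ValidationError(f"expected trailing axis of size 3, got {arr.shape}")
    if arr.dtype == np.uint8:
        out = _apply(arr.astype(float) / 255.0, ccm)
        return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    out = _apply(arr.astype(float), ccm)
    return np.clip(out, 0.0, 1.0)


def _apply(arr: np.ndarray, ccm: ColorCorrectionMatrix) -> np.ndarray:
    if ccm.affine:
        return arr @ ccm.m[:, :3].T + ccm.m[:, 3]
    return arr @ ccm.m.T


def build_chart_from_palette(palette) -> StandardChart:
    """Build the 5-patch standard chart from a tab palette.

    ``palette`` is any object with a ``colors`` mapping (or a plain mapping)
    from tab label to :class:`LabColor`; references are the palette colors of
    the five chart tabs converted to camera RGB.
    """
    colors: Mapping[str, LabColor] = getattr(palette, "colors", palette)
    entries = []
    for label in CHART_TAB_LABELS:
        if label not in colors:
            raise KeyError(f"palette is missing chart tab {label!r}")
        entries.append((label, lab_to_rgb(colors[label])))
    return StandardChart(entries=tuple(entries))


def chart_delta_e(
    measured: Sequence[RGBColor], reference: Sequence[RGBColor]
) -> float:
    """Mean CIELAB dE between two equal-length RGB color lists."""
    from .colorspace import delta_e

    if len(measured) != len(reference):
        raise CalibrationError("length mismatch")
    des = [
        delta_e(rgb_to_lab(m), rgb_to_lab(r)).delta_e
        for m, r in zip(measured, reference)
    ]
    return float(np.mean(des))
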
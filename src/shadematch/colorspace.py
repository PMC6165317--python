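"""Color model of the shade-matching pipeline.

The device measures reflectance-like camera RGB (8-bit channels rescaled to
[0, 1], no gamma linearisation), converts it to D65-white-normalised
tristimulus values and then to CIE L*a*b*.  Shade comparison uses the
classical Euclidean color difference

    dE = sqrt(dL*^2 + da*^2 + db*^2)

so every downstream stage (calibration, database, matching) talks in terms of
the types defined here.

The XYZ values are stored *already divided* by the D65 white point
(X/0.95047, Y, Z/1.08883), which makes an equal-energy white map to
(1, 1, 1) and hence to L* = 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "RGBColor",
    "XYZColor",
    "LabColor",
    "ColorDifference",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "lab_to_rgb",
    "delta_e",
]

# Rows of the RGB -> XYZ matrix (sRGB primaries, D65), with the white-point
# division folded in so that converted XYZ is white-normalised.
_M_RGB_TO_XYZ = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)
_WHITE_DIVISORS = np.array([0.95047, 1.0, 1.08883])

# Threshold between the cube-root and the linear branch of the Lab transfer
# function; the two branches agree to < 1e-3 at the junction.
LAB_EPSILON = 0.008856
_LINEAR_SLOPE = 7.787
_LINEAR_OFFSET = 16.0 / 116.0


@dataclass(frozen=True)
class RGBColor:
    """A camera RGB color with unit-scaled channels.

    8-bit channel values are divided by 255 before constructing this type;
    each channel must lie in [0, 1].
    """

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise DomainError(
                    f"RGB channel {name!r} = {v} outside [0, 1]"
                )

    @classmethod
    def from_8bit(cls, r: float, g: float, b: float) -> "RGBColor":
        return cls(r / 255.0, g / 255.0, b / 255.0)

    def to_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


@dataclass(frozen=True)
class XYZColor:
    """White-normalised tristimulus values (X/0.95047, Y, Z/1.08883)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise DomainError(f"XYZ component {name!r} = {v} is negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class LabColor:
    """A CIE L*a*b* color: L* lightness, a* red-green, b* yellow-blue."""

    L: float
    a: float
    b: float

    def to_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class ColorDifference:
    """Signed component differences and their Euclidean norm dE."""

    delta_e: float
    delta_L: float
    delta_a: float
    delta_b: float


def _srgb_linearize(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def rgb_to_xyz(c: RGBColor, *, gamma_linearize: bool = False) -> XYZColor:
    """Convert unit-scaled camera RGB to white-normalised XYZ.

    By default the matrix is applied directly to the stored channels, i.e.
    camera RGB is treated as already linear; ``gamma_linearize=True`` applies
    the sRGB decoding curve first.
    """
    rgb = c.to_array()
    if gamma_linearize:
        rgb = _srgb_linearize(rgb)
    xyz = (_M_RGB_TO_XYZ @ rgb) / _WHITE_DIVISORS
    return XYZColor(*xyz)


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > LAB_EPSILON, np.cbrt(t), _LINEAR_SLOPE * t + _LINEAR_OFFSET)


def _f_inv(f: np.ndarray) -> np.ndarray:
    cube = f**3
    return np.where(cube > LAB_EPSILON, cube, (f - _LINEAR_OFFSET) / _LINEAR_SLOPE)


def xyz_to_lab(c: XYZColor, *, clamp_L: bool = False) -> LabColor:
    """Convert white-normalised XYZ to CIE L*a*b*.

    Each component goes through the cube-root transfer function, with the
    linear branch 7.787*t + 16/116 below t = 0.008856; then
    L* = 116*fy - 16, a* = 500*(fx - fy), b* = 200*(fy - fz).
    ``clamp_L`` clips L* to [0, 100]; by default the raw value is reported.
    """
    fx, fy, fz = _f(c.to_array())
    L = 116.0 * fy - 16.0
    if clamp_L:
        L = float(np.clip(L, 0.0, 100.0))
    return LabColor(float(L), float(500.0 * (fx - fy)), float(200.0 * (fy - fz)))


def rgb_to_lab(
    c: RGBColor, *, gamma_linearize: bool = False, clamp_L: bool = False
) -> LabColor:
    """Camera RGB to CIE L*a*b*: composition of the two conversion stages."""
    return xyz_to_lab(rgb_to_xyz(c, gamma_linearize=gamma_linearize), clamp_L=clamp_L)


def lab_to_rgb(c: LabColor, *, tol: float = 1e-6) -> RGBColor:
    """Invert the (no-gamma) RGB -> Lab conversion.

    Both stages are exactly invertible: the transfer function branchwise
    (cube vs. linear) and the 3x3 matrix by its inverse.  Raises
    :class:`DomainError` if the color is out of the camera gamut by more than
    ``tol``; tiny float excursions are clipped.
    """
    fy = (c.L + 16.0) / 116.0
    fx = fy + c.a / 500.0
    fz = fy - c.b / 200.0
    xyz = _f_inv(np.array([fx, fy, fz])) * _WHITE_DIVISORS
    rgb = np.linalg.solve(_M_RGB_TO_XYZ, xyz)
    if np.any(rgb < -tol) or np.any(rgb > 1.0 + tol):
        raise DomainError(f"Lab color {c} maps outside the RGB gamut: {rgb}")
    rgb = np.clip(rgb, 0.0, 1.0)
    return RGBColor(*rgb)


def delta_e(a: LabColor, b: LabColor) -> ColorDifference:
    """Euclidean CIELAB color difference between two colors.

    Component differences are signed (first minus second); the norm is
    symmetric in the arguments.
    """
    dL, da, db = a.L - b.L, a.a - b.a, a.b - b.b
    return ColorDifference(math.sqrt(dL * dL + da * da + db * db), dL, da, db)
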
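"""Edge-detection segmentation of the central tooth / shade tab.

The intraoral frame contains the target tab (or tooth) in the middle of the
field of view, surrounded by gum tissue and dark background.  The stages:

1. grayscale = G - |R - G|   (gum is much redder than tooth, so gum pixels
   collapse toward 0 while near-neutral tooth pixels keep ~G);
2. Canny edge detection (hysteresis thresholds 10/20 on the 8-bit scale)
   plus a morphological closing to seal small gaps in the edge band;
3. binarisation at the mean grayscale value over the edge pixels;
4. connected-component labeling;
5. selection of the component whose centroid is nearest the image center
   (subject to a minimum-area floor), then the channel-wise mean color of
   the selected region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import feature, measure, morphology

from .colorspace import RGBColor
from .errors import SegmentationError, ValidationError

__all__ = [
    "IntraoralImage",
    "GrayscaleMap",
    "RegionMask",
    "tooth_grayscale",
    "emphasize_edges",
    "binarize",
    "label_regions",
    "select_central_region",
    "mean_region_color",
    "segment_target",
]

logger = logging.getLogger(__name__)


@dataclass
class IntraoralImage:
    """H x W x 3 8-bit RGB frame, optionally tagged with device/tab metadata."""

    pixels: np.ndarray
    device_id: Optional[int] = None
    tab: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected an HxWx3 array, got {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValidationError(f"image too small: {px.shape[:2]} (min 32x32)")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px


@dataclass
class GrayscaleMap:
    """Per-pixel G - |R - G| values, clamped to [0, 255]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)


@dataclass
class RegionMask:
    """A labeled foreground, optionally narrowed to one selected component."""

    mask: np.ndarray
    label_count: int
    selected_label: Optional[int] = None
    labels: np.ndarray = field(default=None, repr=False)  # full label image


def tooth_grayscale(img: IntraoralImage) -> GrayscaleMap:
    """Map RGB to the tooth-emphasising grayscale G - |R - G|.

    Values are clamped below at 0; the blue channel is ignored.
    """
    px = img.pixels.astype(np.int32)
    r, g = px[..., 0], px[..., 1]
    gray = g - np.abs(r - g)
    return GrayscaleMap(np.clip(gray, 0, 255).astype(np.uint8))


def emphasize_edges(
    gray: GrayscaleMap,
    *,
    canny_low: float = 10.0,
    canny_high: float = 20.0,
    sigma: float = 1.0,
    morphology_enabled: bool = True,
    morphology_order: tuple[str, str] = ("dilate", "erode"),
    footprint_size: int = 3,
) -> np.ndarray:
    """Boolean edge map: Canny followed by a morphological closing.

    Hysteresis thresholds are in 8-bit grayscale units (defaults 10 and 20).
    The closing (one dilation then one erosion with a square footprint)
    seals single-pixel gaps so the edge band surrounds the target; the order
    is configurable.
    """
    edges = feature.canny(
        gray.values.astype(float),
        sigma=sigma,
        low_threshold=canny_low,
        high_threshold=canny_high,
    )
    if morphology_enabled:
        fp = np.ones((footprint_size, footprint_size), dtype=bool)
        ops = {
            "dilate": lambda a: morphology.dilation(a, fp),
            "erode": lambda a: morphology.erosion(a, fp),
        }
        for name in morphology_order:
            edges = ops[name](edges)
    return edges


def binarize(gray: GrayscaleMap, edges: np.ndarray) -> np.ndarray:
    """Threshold the grayscale at the mean gray value over the edge area.

    The edge *area* is the one-pixel neighborhood of the detected edge
    lines (a 3x3 dilation), so it straddles both sides of each boundary and
    the threshold lands strictly between the region and its surround even
    when the Canny line sits wholly on the brighter side.
    """
    if not np.any(edges):
        raise SegmentationError("empty edge map: cannot derive a threshold")
    band = morphology.dilation(edges, np.ones((3, 3), dtype=bool))
    t = float(gray.values[band].mean())
    logger.debug("binarize threshold = %.2f", t)
    return gray.values > t


def label_regions(binary: np.ndarray, *, connectivity: int = 2) -> RegionMask:
    """Connected-component labeling of the binary foreground.

    ``connectivity`` follows scikit-image: 1 = 4-connected, 2 = 8-connected.
    """
    labels, n = measure.label(
        binary.astype(bool), connectivity=connectivity, return_num=True
    )
    if n == 0:
        raise SegmentationError("no foreground component found")
    return RegionMask(mask=labels > 0, label_count=n, labels=labels)


def select_central_region(
    regions: RegionMask,
    image_shape: tuple[int, int],
    *,
    min_area_frac: float = 0.01,
) -> RegionMask:
    """Pick the component whose centroid is nearest the image center.

    Components smaller than ``min_area_frac`` of the image are rejected as
    specks; ties on centroid distance are broken by larger area, then by
    smaller label index.
    """
    if regions.labels is None:
        raise ValidationError("RegionMask has no label image; run label_regions first")
    h, w = image_shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    floor = min_area_frac * h * w

    best = None
    for prop in measure.regionprops(regions.labels):
        if prop.area < floor:
            continue
        dist = float(np.linalg.norm(np.array(prop.centroid) - center))
        key = (dist, -prop.area, prop.label)
        if best is None or key < best[0]:
            best = (key, prop.label)
    if best is None:
        raise SegmentationError(
            f"no component above the area floor ({floor:.0f} px)"
        )
    label = best[1]
    return RegionMask(
        mask=regions.labels == label,
        label_count=regions.label_count,
        selected_label=label,
        labels=regions.labels,
    )


def mean_region_color(
    img: IntraoralImage,
    region: RegionMask,
    *,
    glare_exclude: bool = False,
    glare_percentile: float = 99.0,
) -> RGBColor:
    """Channel-wise mean RGB over the masked pixels, scaled to [0, 1].

    With ``glare_exclude`` the brightest pixels (above the given percentile
    of the in-region grayscale sum) are dropped before averaging, which
    suppresses residual specular highlights.
    """
    if not np.any(region.mask):
        raise SegmentationError("empty region mask")
    px = img.pixels[region.mask].astype(float)
    if glare_exclude and px.shape[0] > 10:
        brightness = px.sum(axis=1)
        cut = np.percentile(brightness, glare_percentile)
        keep = brightness <= cut
        if keep.any():
            px = px[keep]
    mean = px.mean(axis=0) / 255.0
    return RGBColor(*np.clip(mean, 0.0, 1.0))


def segment_target(
    img: IntraoralImage,
    *,
    canny_low: float = 10.0,
    canny_high: float = 20.0,
    sigma: float = 1.0,
    connectivity: int = 2,
    min_area_frac: float = 0.01,
    glare_exclude: bool = False,
    glare_percentile: float = 99.0,
) -> tuple[RegionMask, RGBColor]:
    """Full segmentation: grayscale -> edges -> binarize -> label -> select -> mean.

    Stage failures are re-raised with the failing stage named.
    """
    stage = "grayscale"
    try:
        gray = tooth_grayscale(img)
        stage = "edges"
        edges = emphasize_edges(
            gray, canny_low=canny_low, canny_high=canny_high, sigma=sigma
        )
        stage = "binarize"
        binary = binarize(gray, edges)
        stage = "label"
        regions = label_regions(binary, connectivity=connectivity)
        logger.debug("found %d component(s)", regions.label_count)
        stage = "select"
        selected = select_central_region(
            regions, img.pixels.shape[:2], min_area_frac=min_area_frac
        )
        stage = "mean-color"
        color = mean_region_color(
            img,
            selected,
            glare_exclude=glare_exclude,
            glare_percentile=glare_percentile,
        )
    except SegmentationError as exc:
        raise SegmentationError(f"stage {stage!r}: {exc}") from exc
    logger.debug(
        "selected label %s, area %d px", selected.selected_label, int(selected.mask.sum())
    )
    return selected, color
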
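"""Synthetic stand-ins for everything the camera hardware produces.

Three generators:

* a canonical 26-tab palette laid out like the VITA 3D-Master — lightness
  falls with the group digit (1-5), b* (yellowness) rises with the chroma
  digit, and the L/M/R hue variants are ordered along a*;
* per-device measurement simulation: palette Lab -> camera RGB -> a
  near-identity 3x3 distortion + bias + Gaussian channel noise -> back to
  Lab, optionally with an extra *anisotropic* Lab perturbation along one
  shared direction, which mimics the elongated per-tab clusters produced by
  correlated inter-device variation;
* a scene renderer that paints a tab rectangle over gum-colored and dark
  regions, with an optional saturated glare disc, for segmentation tests.

Palette coordinates are invented under the structural constraints above and
version-tagged; they are not measured VITA values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .colorspace import LabColor, RGBColor, lab_to_rgb, rgb_to_lab
from .errors import ValidationError
from .segmentation import IntraoralImage
from .shade_db import TAB_LABELS, Measurement

__all__ = [
    "TabPalette",
    "DeviceProfile",
    "SceneSpec",
    "default_palette",
    "make_device_profiles",
    "simulate_rgb_reading",
    "simulate_measurement",
    "simulate_device_dataset",
    "render_scene",
    "three_teeth_spec",
    "two_cluster_fixture",
]

# Lab-noise scale: for tooth-range colors the conversion's local Jacobian
# turns an RGB channel sigma of 0.01 into roughly 0.6 CIELAB units, so
# anisotropic Lab noise uses a scale factor of 60 per unit RGB sigma.
_RGB_TO_LAB_NOISE_SCALE = 60.0


@dataclass(frozen=True)
class TabPalette:
    """Canonical noise-free Lab color per tab, with a version tag."""

    colors: dict[str, LabColor]
    version: str = "synthetic-1"

    def __getitem__(self, tab: str) -> LabColor:
        return self.colors[tab]

    def __contains__(self, tab: str) -> bool:
        return tab in self.colors

    def __len__(self) -> int:
        return len(self.colors)


def default_palette(seed: int = 0) -> TabPalette:
    """Deterministic 26-tab palette with 3D-Master-like structure.

    Base coordinates: L* = 84 - 5*group (the ~79 down to ~59 lightness
    range of natural teeth), b* = 8 + 7*(chroma - 1), a* = 2 - 4.5 for L
    variants / +0 for M / +4.5 for R, plus a small seeded jitter
    (|dL| <= 0.5, |da|, |db| <= 0.3) so different versions are not
    byte-identical.  Adjacent tabs end up dE ~ 5-7 apart, the spacing
    colorimetric surveys report for the physical guide.  The construction
    keeps within-group L* constant to well under +/-2, group lightness
    strictly decreasing, b* increasing in chroma, a* ordered L < M < R, and
    all pairwise dE >= 1.5.
    """
    rng = np.random.default_rng(seed)
    colors: dict[str, LabColor] = {}
    hue_offset = {"L": -4.5, "M": 0.0, "R": 4.5}
    for label in TAB_LABELS:
        group = int(label[0])
        hue = label[1]
        chroma = float(label[2:])
        L = 84.0 - 5.0 * group + rng.uniform(-0.5, 0.5)
        a = 2.0 + hue_offset[hue] + rng.uniform(-0.3, 0.3)
        b = 8.0 + 7.0 * (chroma - 1.0) + rng.uniform(-0.3, 0.3)
        colors[label] = LabColor(L, a, b)
    return TabPalette(colors=colors, version=f"synthetic-1/seed{seed}")


@dataclass(frozen=True)
class DeviceProfile:
    """Simulated hardware imperfection of one camera.

    ``distortion`` multiplies the true RGB (entries near identity within
    about +/-10%), ``bias`` adds a small RGB offset, ``noise_sd`` is the
    per-channel Gaussian sigma in unit-RGB terms.  ``aniso_direction`` /
    ``aniso_stretch`` add Lab-space noise elongated along one direction
    (stretch x the baseline Lab noise), emulating correlated inter-device
    variation that a 3x3 RGB correction cannot remove.
    """

    device_id: int
    distortion: np.ndarray
    bias: np.ndarray
    noise_sd: float = 0.01
    aniso_direction: Optional[np.ndarray] = None
    aniso_stretch: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.distortion, dtype=float)
        if d.shape != (3, 3):
            raise ValidationError(f"distortion must be 3x3, got {d.shape}")
        if abs(np.linalg.det(d)) < 1e-6:
            raise ValidationError("distortion matrix is singular")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        object.__setattr__(self, "distortion", d)
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float))
        if self.aniso_direction is not None:
            u = np.asarray(self.aniso_direction, dtype=float)
            u = u / np.linalg.norm(u)
            object.__setattr__(self, "aniso_direction", u)

    @classmethod
    def identity(cls, device_id: int = 0) -> "DeviceProfile":
        """A perfect device: no distortion, no bias, no noise."""
        return cls(
            device_id=device_id,
            distortion=np.eye(3),
            bias=np.zeros(3),
            noise_sd=0.0,
            aniso_direction=None,
        )


def make_device_profiles(
    n_devices: int,
    seed: int = 0,
    *,
    distortion_scale: float = 0.1,
    bias_scale: float = 0.005,
    noise_sd: float = 0.01,
    aniso_stretch: float = 3.0,
) -> list[DeviceProfile]:
    """Draw a family of device profiles sharing one anisotropy direction.

    Each device gets an independent near-identity distortion
    (identity + U(-scale, scale) entrywise) and RGB bias; the anisotropy
    direction in Lab is drawn once per family, so the per-tab clusters
    pooled over devices are elongated along a common axis.
    """
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    profiles = []
    for i in range(1, n_devices + 1):
        while True:
            d = np.eye(3) + rng.uniform(-distortion_scale, distortion_scale, (3, 3))
            if abs(np.linalg.det(d)) > 0.1:
                break
        profiles.append(
            DeviceProfile(
                device_id=i,
                distortion=d,
                bias=rng.uniform(-bias_scale, bias_scale, 3),
                noise_sd=noise_sd,
                aniso_direction=None if aniso_stretch == 0 else direction.copy(),
                aniso_stretch=aniso_stretch,
                seed=seed,
            )
        )
    return profiles


def simulate_rgb_reading(
    palette: TabPalette,
    tab: str,
    profile: DeviceProfile,
    rng: np.random.Generator,
) -> RGBColor:
    """One raw (uncorrected) RGB reading of a tab through a device.

    Palette Lab -> true RGB -> distortion @ rgb + bias + N(0, noise_sd) per
    channel, clamped to [0, 1].
    """
    if tab not in palette:
        raise KeyError(f"tab {tab!r} not in palette")
    rgb = lab_to_rgb(palette[tab]).to_array()
    v = profile.distortion @ rgb + profile.bias
    if profile.noise_sd > 0:
        v = v + rng.normal(0.0, profile.noise_sd, 3)
    return RGBColor(*np.clip(v, 0.0, 1.0))


def _aniso_noise(profile: DeviceProfile, rng: np.random.Generator) -> np.ndarray:
    if profile.aniso_direction is None or profile.noise_sd == 0:
        return np.zeros(3)
    sigma = profile.aniso_stretch * profile.noise_sd * _RGB_TO_LAB_NOISE_SCALE
    return profile.aniso_direction * rng.normal(0.0, sigma)


def simulate_measurement(
    palette: TabPalette,
    tab: str,
    profile: DeviceProfile,
    rng: np.random.Generator,
    *,
    repeat_index: int = 1,
    ccm=None,
) -> Measurement:
    """One Lab measurement of a tab: raw reading, optional CCM, Lab, anisotropy.

    The anisotropic Lab component is added after correction — it stands for
    inter-device variation that survives the 3x3 RGB correction.
    """
    reading = simulate_rgb_reading(palette, tab, profile, rng)
    if ccm is not None:
        from .calibration import apply_ccm

        reading = apply_ccm(reading, ccm)
    lab = rgb_to_lab(reading).to_array() + _aniso_noise(profile, rng)
    return Measurement(
        device_id=profile.device_id,
        repeat_index=repeat_index,
        tab=tab,
        color=LabColor(*lab),
    )


def simulate_device_dataset(
    palette: TabPalette,
    profile: DeviceProfile,
    n_repeats: int,
    rng: Optional[np.random.Generator] = None,
    *,
    ccm=None,
) -> list[Measurement]:
    """All 26 tabs x ``n_repeats`` measurements for one device."""
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    if rng is None:
        rng = np.random.default_rng(profile.seed + profile.device_id)
    out = []
    for rep in range(1, n_repeats + 1):
        for tab in TAB_LABELS:
            out.append(
                simulate_measurement(
                    palette, tab, profile, rng, repeat_index=rep, ccm=ccm
                )
            )
    return out


# ---------------------------------------------------------------------------
# scene rendering


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and photometry of a rendered intraoral-style frame.

    The tab rectangle (x0, y0, width, height, in pixels) must cover at least
    1% of the frame.  The gum band occupies the top ``gum_rows`` rows with a
    red-dominant color so the G - |R - G| grayscale suppresses it.  A glare
    disc, if given as (cx, cy, radius), is painted channel-saturated inside
    the tab.  ``flanks`` are optional extra (rect, 8-bit color) teeth for
    multi-tooth scenes.
    """

    width: int = 160
    height: int = 120
    tab_rect: tuple[int, int, int, int] = (56, 36, 48, 48)
    gum_color: tuple[int, int, int] = (185, 95, 95)
    gum_rows: int = 24
    background: tuple[int, int, int] = (20, 14, 16)
    glare: Optional[tuple[int, int, int]] = None
    glare_value: int = 254
    noise_sd: float = 0.0
    flanks: tuple[tuple[tuple[int, int, int, int], tuple[int, int, int]], ...] = ()

    def __post_init__(self) -> None:
        x0, y0, w, h = self.tab_rect
        if x0 < 0 or y0 < 0 or x0 + w > self.width or y0 + h > self.height:
            raise ValidationError("tab rectangle exceeds image bounds")
        if w * h < 0.01 * self.width * self.height:
            raise ValidationError("tab rectangle below 1% of the frame")
        for rect, _ in self.flanks:
            fx, fy, fw, fh = rect
            if fx < 0 or fy < 0 or fx + fw > self.width or fy + fh > self.height:
                raise ValidationError("flank rectangle exceeds image bounds")
        if self.glare is not None:
            cx, cy, r = self.glare
            if not (x0 <= cx - r and cx + r <= x0 + w and y0 <= cy - r and cy + r <= y0 + h):
                raise ValidationError("glare disc must lie inside the tab rectangle")


def render_scene(
    spec: SceneSpec,
    tab_color: RGBColor,
    rng: Optional[np.random.Generator] = None,
) -> tuple[IntraoralImage, np.ndarray]:
    """Render a frame and return it with the ground-truth tab mask.

    Painted regions: dark background, red gum band, optional flank teeth,
    the central tab in ``tab_color``, optional saturated glare disc, then
    per-pixel Gaussian noise (sigma in 8-bit units).
    """
    img = np.empty((spec.height, spec.width, 3), dtype=float)
    img[:] = spec.background
    img[: spec.gum_rows, :, :] = spec.gum_color

    for (fx, fy, fw, fh), color in spec.flanks:
        img[fy : fy + fh, fx : fx + fw, :] = color

    x0, y0, w, h = spec.tab_rect
    tab8 = np.round(tab_color.to_array() * 255.0)
    img[y0 : y0 + h, x0 : x0 + w, :] = tab8
    truth = np.zeros((spec.height, spec.width), dtype=bool)
    truth[y0 : y0 + h, x0 : x0 + w] = True

    if spec.glare is not None:
        cx, cy, r = spec.glare
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[disc] = spec.glare_value

    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return IntraoralImage(pixels=pixels), truth


def three_teeth_spec(
    tab_color: Optional[RGBColor] = None,
    *,
    width: int = 160,
    height: int = 120,
    noise_sd: float = 0.0,
    glare: bool = False,
    neighbor_color: Optional[tuple[int, int, int]] = None,
) -> SceneSpec:
    """Scene with a centered tab flanked by two neighbor teeth.

    The flanks are painted a slightly offset shade of the central tab color
    (neighboring teeth resemble the target) and are separated from it by
    background-colored gaps, so selection must rely on centroid distance,
    not uniqueness.  With neither ``tab_color`` nor ``neighbor_color``
    given, a mid-range tooth color is used for the flanks.
    """
    if neighbor_color is None:
        if tab_color is not None:
            base = np.round(tab_color.to_array() * 255.0)
            neighbor_color = tuple(
                int(v) for v in np.clip(base + np.array([10.0, 8.0, 5.0]), 0, 255)
            )
        else:
            neighbor_color = (150, 130, 100)
    tab_w, tab_h = 40, 52
    x0 = (width - tab_w) // 2
    y0 = (height - tab_h) // 2 + 6
    flank_w = 30
    gap = 10
    flanks = (
        ((x0 - gap - flank_w, y0 + 4, flank_w, tab_h - 8), neighbor_color),
        ((x0 + tab_w + gap, y0 + 4, flank_w, tab_h - 8), neighbor_color),
    )
    glare_spec = None
    if glare:
        # disc radius chosen so the patch covers < 5% of the tab area
        r = 5
        glare_spec = (x0 + tab_w // 2 + 6, y0 + tab_h // 2 - 8, r)
    return SceneSpec(
        width=width,
        height=height,
        tab_rect=(x0, y0, tab_w, tab_h),
        glare=glare_spec,
        noise_sd=noise_sd,
        flanks=flanks,
    )


# ---------------------------------------------------------------------------
# anisotropic two-cluster fixture


def two_cluster_fixture(
    seed: int = 0,
    *,
    n_per_cluster: int = 35,
) -> dict:
    """Two elongated neighboring shade clusters plus a tail-end probe.

    Cluster A ("3L2.5") is strongly elongated (sigma 3 along a fixed a*b*
    direction, 0.4 across); cluster B ("3R2.5") is compact (sigma 0.5) and
    sits beside A's tail.  The probe lies on A's elongation axis, inside A's
    point cloud but *closer in Euclidean terms to B's mean* — the situation
    where nearest-mean matching picks the wrong tab while a boundary that
    follows the cluster shapes does not.

    Returns a dict with ``X`` (n, 3 Lab features), ``y`` (labels), ``probe``
    (LabColor), ``probe_label`` (the generating cluster), and ``means``.
    """
    rng = np.random.default_rng(seed)
    mean_a = np.array([65.0, 0.0, 10.0])
    d = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)  # elongation axis
    n = np.array([0.0, 1.0, -1.0]) / np.sqrt(2)  # in-plane normal
    mean_b = mean_a + 3.0 * d + 2.2 * n

    pts_a = (
        mean_a
        + rng.normal(0, 3.0, (n_per_cluster, 1)) * d
        + rng.normal(0, 0.4, (n_per_cluster, 1)) * n
        + rng.normal(0, 0.4, (n_per_cluster, 1)) * np.array([1.0, 0, 0])
    )
    pts_b = mean_b + rng.normal(0, 0.5, (n_per_cluster, 3))

    probe = mean_a + 4.0 * d
    return {
        "X": np.vstack([pts_a, pts_b]),
        "y": ["3L2.5"] * n_per_cluster + ["3R2.5"] * n_per_cluster,
        "probe": LabColor(*probe),
        "probe_label": "3L2.5",
        "means": {
            "3L2.5": LabColor(*pts_a.mean(axis=0)),
            "3R2.5": LabColor(*pts_b.mean(axis=0)),
        },
    }
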
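"""Concentric circular scan paths around the optic disc.

The image is sampled along circles of integer-pixel radii, from one pixel
outside the OD boundary to two OD diameters from the centre (the edge of
the 4 D_OD region of interest).  Each circle yields a 1D intensity profile
— the substrate of the 1D fractal estimator — and is assigned to one of
three concentric zones by its offset from the OD margin, in units of the
OD diameter: A = (0, 0.5], B = (0.5, 1.0], C = (1.0, 1.5].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ParameterError
from .preprocess import ODAnnotation

__all__ = [
    "ZoneSpec",
    "CircleProfile",
    "circle_radii",
    "assign_zone",
    "sample_circle",
    "scan_all",
]

ZONE_ORDER = ("A", "B", "C")
COMBO_ORDER = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class ZoneSpec:
    """Concentric zone boundaries as margin offsets in units of D_OD.

    Bands are half-open, closed on the right; the defaults are contiguous,
    disjoint and ordered, with the outer edge of C at 1.5 D_OD from the OD
    margin (radius 2 D_OD from the centre).
    """

    bands: tuple[tuple[str, float, float], ...] = (
        ("A", 0.0, 0.5),
        ("B", 0.5, 1.0),
        ("C", 1.0, 1.5),
    )

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.bands:
            if not lo < hi:
                raise ParameterError(f"zone {label} bounds not increasing")
            if prev_hi is not None and lo != prev_hi:
                raise ParameterError("zone bands must be contiguous")
            prev_hi = hi

    @property
    def outer(self) -> float:
        return self.bands[-1][2]

    def label_for(self, offset_frac: float) -> str:
        """Zone label for a margin offset expressed in units of D_OD."""
        for label, lo, hi in self.bands:
            if lo < offset_frac <= hi:
                return label
        raise GeometryError(
            f"offset {offset_frac:.4f} D_OD outside the scanning band (0, {self.outer}]"
        )


@dataclass
class CircleProfile:
    """1D intensity series along one scan circle.

    Samples run counter-clockwise from angle 0 (positive x-axis) at equal
    angular steps, about one pixel of arc apart.
    """

    radius: float
    zone: str | None
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.samples.size < 16:
            raise ParameterError("a circle profile needs at least 16 samples")


def _n_samples(radius: float) -> int:
    """Sample count for a circle: ~1 px arc steps, a multiple of 4."""
    return 4 * max(4, int(round(np.pi * radius / 2.0)))


def circle_radii(od: ODAnnotation, image_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Integer-pixel scan radii: R_OD + 1, R_OD + 2, ..., 2 * D_OD.

    The innermost circle is one pixel outside the OD boundary (a fractional
    OD radius is rounded up first) and the outermost has diameter four OD
    diameters.  With ``image_shape`` given, the outermost circle is checked
    against the frame.
    """
    r_start = int(math.ceil(od.r_od)) + 1
    r_end = int(math.floor(2.0 * od.d_od))
    if r_end < r_start:
        raise GeometryError(f"OD diameter {od.d_od} leaves no room for scan circles")
    radii = np.arange(r_start, r_end + 1, dtype=np.float64)
    if image_shape is not None:
        h, w = image_shape
        r = radii[-1]
        # half-open extents: the image covers [-0.5, side - 0.5] in each axis
        if od.cx - r < -0.5 or od.cy - r < -0.5 or od.cx + r > w - 0.5 or od.cy + r > h - 0.5:
            raise GeometryError(
                f"outermost scan circle (radius {r:.0f}) exceeds the {w}x{h} frame"
            )
    return radii


def assign_zone(radius: float, od: ODAnnotation, zones: ZoneSpec = ZoneSpec()) -> str:
    """Zone label of a circle by its offset from the OD margin."""
    offset = radius - od.r_od
    if offset <= 0:
        raise GeometryError(f"radius {radius} is not outside the OD (R_OD={od.r_od})")
    return zones.label_for(offset / od.d_od)


def sample_circle(
    pixels: np.ndarray,
    od: ODAnnotation,
    radius: float,
    zone: str | None = None,
) -> CircleProfile:
    """Bilinear samples along one circle, ~1 px of arc per sample.

    About ``2 * pi * radius`` samples are taken counter-clockwise starting
    at angle 0; the count is rounded to the nearest multiple of four so a
    quarter-turn of the image maps sample positions exactly onto sample
    positions (the profile shifts by N/4).  The circle must lie fully
    inside the image.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    h, w = pixels.shape
    if (
        od.cx - radius < -0.5
        or od.cy - radius < -0.5
        or od.cx + radius > w - 0.5
        or od.cy + radius > h - 0.5
    ):
        raise GeometryError(f"circle of radius {radius} exits the {w}x{h} frame")
    n = _n_samples(radius)
    theta = 2.0 * np.pi * np.arange(n) / n
    x = od.cx + radius * np.cos(theta)
    y = od.cy + radius * np.sin(theta)
    samples = map_coordinates(pixels, np.vstack([y, x]), order=1, mode="nearest")
    return CircleProfile(radius=float(radius), zone=zone, samples=samples)


def scan_all(
    pixels: np.ndarray,
    od: ODAnnotation,
    zones: ZoneSpec = ZoneSpec(),
) -> list[CircleProfile]:
    """All zone-labelled circle profiles for an image.

    One profile per radius from :func:`circle_radii`; the zones partition
    the circle set.  For efficiency all circles are interpolated in a single
    pass.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    radii = circle_radii(od, image_shape=pixels.shape)
    counts = np.array([_n_samples(r) for r in radii])
    xs, ys = [], []
    for r, n in zip(radii, counts):
        theta = 2.0 * np.pi * np.arange(n) / n
        xs.append(od.cx + r * np.cos(theta))
        ys.append(od.cy + r * np.sin(theta))
    flat = map_coordinates(
        pixels, np.vstack([np.concatenate(ys), np.concatenate(xs)]), order=1, mode="nearest"
    )
    profiles: list[CircleProfile] = []
    pos = 0
    for r, n in zip(radii, counts):
        profiles.append(
            CircleProfile(
                radius=float(r),
                zone=assign_zone(float(r), od, zones),
                samples=flat[pos : pos + n],
            )
        )
        pos += n
    return profiles
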
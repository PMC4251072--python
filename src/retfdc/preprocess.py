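"""Preprocessing of optic-disc-centred fundus images.

The working representation used throughout the package is the *inverted
green channel* of the colour fundus photograph (vessels bright on a dark
background), cropped to a square region of interest of ``roi_factor``
optic-disc diameters centred on the disc, and downsampled to a fixed side
length.  All geometry downstream (scan circles, zones) is expressed in the
coordinates of this working image.

Coordinate convention: 0-based, pixel-centre.  Pixel ``(row=i, col=j)`` has
its centre at ``(x=j, y=i)``; image extents are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import FormatError, GeometryError

__all__ = [
    "ODAnnotation",
    "WorkingImage",
    "extract_inverted_green",
    "invert_grey",
    "crop_roi",
    "downsample",
    "preprocess_image",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class ODAnnotation:
    """Optic-disc centre and diameter, in pixels of a specific image.

    Attributes
    ----------
    cx, cy : float
        Disc centre (0-based pixel-centre coordinates; x = column, y = row).
    d_od : float
        Disc diameter in pixels.
    """

    cx: float
    cy: float
    d_od: float

    def __post_init__(self) -> None:
        if not self.d_od > 0:
            raise FormatError(f"OD diameter must be positive, got {self.d_od}")

    @property
    def r_od(self) -> float:
        """Disc radius in pixels."""
        return self.d_od / 2.0


@dataclass
class WorkingImage:
    """Square greyscale working image plus rescaled OD annotation.

    ``pixels`` is float with higher values more vessel-like (inverted green
    channel).  ``provenance`` records processing steps in order applied.
    """

    pixels: np.ndarray
    od: ODAnnotation
    provenance: list[str]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise FormatError("working image must be square 2D")


def _max_value(img: np.ndarray) -> float:
    if img.dtype == np.uint8:
        return 255.0
    if img.dtype == np.uint16:
        return 65535.0
    return 1.0  # float images are assumed scaled to [0, 1]


def extract_inverted_green(rgb: np.ndarray) -> np.ndarray:
    """Return ``max_value - green_channel`` so that vessels become bright.

    Parameters
    ----------
    rgb : ndarray, shape (H, W, 3)
        Colour image; uint8, uint16 or float in [0, 1].
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected a 3-channel RGB image, got shape {rgb.shape}")
    green = rgb[..., 1]
    return (_max_value(rgb) - green).astype(np.float64)


def invert_grey(img: np.ndarray) -> np.ndarray:
    """Invert a single-channel image (used for synthetic green-channel-like inputs)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"expected a 2D greyscale image, got shape {img.shape}")
    return (_max_value(img) - img).astype(np.float64)


def crop_roi(
    img: np.ndarray,
    od: ODAnnotation,
    roi_factor: float = 4.0,
    pad: bool = False,
) -> tuple[np.ndarray, ODAnnotation]:
    """Square crop of side ``roi_factor * d_od`` centred on the OD.

    The returned annotation is re-expressed in crop coordinates, with the
    disc centre at the crop midpoint.  If the window exceeds the frame the
    call fails with :class:`GeometryError` unless ``pad`` enables reflect
    padding (OD-centred photographs should never need it).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError("crop_roi expects a 2D greyscale image")
    side = int(round(roi_factor * od.d_od))
    x0 = int(round(od.cx - (side - 1) / 2.0))
    y0 = int(round(od.cy - (side - 1) / 2.0))
    h, w = img.shape
    if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
        if not pad:
            raise GeometryError(
                f"{side}x{side} ROI at OD ({od.cx:.1f}, {od.cy:.1f}) exceeds "
                f"the {w}x{h} frame; enable pad=True to reflect-pad"
            )
        px0, py0 = max(0, -x0), max(0, -y0)
        px1 = max(0, x0 + side - w)
        py1 = max(0, y0 + side - h)
        img = np.pad(img, ((py0, py1), (px0, px1)), mode="reflect")
        x0 += px0
        y0 += py0
    crop = img[y0 : y0 + side, x0 : x0 + side]
    new_od = replace(od, cx=od.cx - x0, cy=od.cy - y0)
    return crop, new_od


def downsample(
    img: np.ndarray,
    od: ODAnnotation,
    target_side: int = 400,
) -> WorkingImage:
    """Anti-aliased area-average resampling of a square image to ``target_side``.

    OD centre and diameter are rescaled with the image.  A constant image
    stays constant (interpolation weights sum to one), and an input already
    at the target side passes through unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise GeometryError(f"downsample expects a square image, got {img.shape}")
    side = img.shape[0]
    if side < target_side:
        raise GeometryError(f"input side {side} smaller than target {target_side}")
    if side == target_side:
        return WorkingImage(img, od, [f"downsample(identity, side={side})"])
    scale = target_side / side
    out = resize(
        img,
        (target_side, target_side),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
        mode="reflect",
    )
    # pixel-centre convention: x' = (x + 0.5) * scale - 0.5
    new_od = ODAnnotation(
        cx=(od.cx + 0.5) * scale - 0.5,
        cy=(od.cy + 0.5) * scale - 0.5,
        d_od=od.d_od * scale,
    )
    return WorkingImage(out, new_od, [f"downsample({side}->{target_side})"])


def preprocess_image(
    img: np.ndarray,
    od: ODAnnotation,
    roi_factor: float = 4.0,
    target_side: int = 400,
    pad: bool = False,
) -> WorkingImage:
    """Full chain: invert (green) channel, crop the OD-centred ROI, downsample.

    ``img`` may be RGB (the green channel is used) or already greyscale
    (treated as a green-channel-like image, e.g. a synthetic fundus).
    """
    steps = []
    if np.asarray(img).ndim == 3:
        grey = extract_inverted_green(img)
        steps.append("extract_inverted_green")
    else:
        grey = invert_grey(img)
        steps.append("invert_grey")
    if not np.all(np.isfinite(grey)):
        raise FormatError("image contains non-finite pixels")
    crop, od_c = crop_roi(grey, od, roi_factor=roi_factor, pad=pad)
    steps.append(f"crop_roi(factor={roi_factor})")
    work = downsample(crop, od_c, target_side=target_side)
    work.provenance = steps + work.provenance
    return work


def read_annotations(path: str | Path) -> dict[str, ODAnnotation]:
    """Read an annotation CSV with columns image_id, od_cx, od_cy, od_d."""
    df = pd.read_csv(path)
    required = {"image_id", "od_cx", "od_cy", "od_d"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation CSV must have columns {sorted(required)}")
    return {
        str(row.image_id): ODAnnotation(float(row.od_cx), float(row.od_cy), float(row.od_d))
        for row in df.itertuples()
    }


def write_annotations(annotations: dict[str, ODAnnotation], path: str | Path) -> None:
    """Write annotations in the CSV layout read by :func:`read_annotations`."""
    rows = [
        {"image_id": k, "od_cx": a.cx, "od_cy": a.cy, "od_d": a.d_od}
        for k, a in annotations.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
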
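"""Fractal dimension estimators.

* :func:`higuchi_fd` — Higuchi's 1D curve-length estimator, applied to each
  circular scan profile.
* :func:`fdc` — the zone-specific circular fractal dimension: per-circle
  Higuchi FDs averaged over the circles of each zone and of all seven zone
  combinations (A, B, C, AB, AC, BC, ABC).  A combination's value is the
  mean over *all* circles in its constituent zones.
* :func:`spectral_fd` — comparator: absolute log-log slope of the radially
  averaged Fourier magnitude spectrum of the greyscale image.
* :func:`box_counting_fd` — comparator: log-log slope of box counts over a
  dyadic grid on a binary (optionally skeletonised) vessel image.

Higuchi's estimator: for delay k and offset m (1-based, m = 1..k) the
normalised curve length is

    L_m(k) = [ sum_{i=1..M} |X(m+ik) - X(m+(i-1)k)| * (N-1) / (M k) ] / k,
    M = floor((N-m)/k),

and L(k) is the mean over m.  If L(k) ~ k^(-D), the series' graph has
fractal dimension D, estimated as minus the slope of log L(k) on log k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _skeletonize

from .errors import ConstantSeriesError, DegenerateInputError, ParameterError
from .scanpath import COMBO_ORDER, ZONE_ORDER, CircleProfile

__all__ = [
    "HiguchiParams",
    "FDCResult",
    "higuchi_fd",
    "fdc",
    "SpectralFDResult",
    "spectral_fd",
    "binarize_for_bc",
    "BoxCountResult",
    "box_counting_fd",
]


@dataclass(frozen=True)
class HiguchiParams:
    """Delay range of the Higuchi regression.

    ``k_max`` defaults to 8, small relative to the 300-1250 samples of a
    typical scan circle as the length regression requires; ``fit_range``
    restricts the delays used in the log-log fit (default: all of
    1..k_max).
    """

    k_max: int = 8
    fit_range: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ParameterError("k_max must be >= 2")
        if self.fit_range is not None:
            if len(self.fit_range) < 2:
                raise ParameterError("fit_range needs at least two delays")
            if any(not 1 <= k <= self.k_max for k in self.fit_range):
                raise ParameterError("fit_range delays must lie in [1, k_max]")

    @property
    def delays(self) -> tuple[int, ...]:
        return self.fit_range if self.fit_range is not None else tuple(range(1, self.k_max + 1))


def higuchi_fd(
    series: np.ndarray,
    params: HiguchiParams = HiguchiParams(),
    clamp: bool = True,
    periodic: bool = False,
) -> float:
    """Higuchi fractal dimension of a 1D series.

    The value lies in [1, 2] for the graph of a bounded series; estimates
    outside that range (possible at finite N) are clamped with a warning
    unless ``clamp=False``.

    By default the series is open (no wraparound), exactly as the
    curve-length construction defines it.  With ``periodic=True`` the
    normalised curve length at delay k aggregates all N wraparound lag-k
    increments, which differs from the open form only by O(k/N) terms but
    is exactly invariant to circular shifts — appropriate for profiles
    sampled along a closed path, where the cut point is arbitrary.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    n = x.size
    if n < 4 * params.k_max:
        raise ParameterError(f"series length {n} < 4 * k_max = {4 * params.k_max}")
    if np.all(x == x[0]):
        raise ConstantSeriesError("constant series has zero curve length; FD undefined")
    log_k, log_l = [], []
    for k in params.delays:
        if periodic:
            d = np.abs(np.roll(x, -k) - x)
            lk = float(d.mean() * (n - 1) / (k * k))
        else:
            # for offset m (0-based), the i-th increment is d[m + (i-1)k]
            # with d = |x[k:] - x[:-k]|; the offsets' index sets partition
            # d by residue class mod k, so all k curve lengths come from
            # one grouped sum of d
            d = np.abs(x[k:] - x[:-k])
            pad = (-d.size) % k
            if pad:
                d = np.concatenate([d, np.zeros(pad)])
            sums = d.reshape(-1, k).sum(axis=0)
            m_counts = (n - 1 - np.arange(k)) // k  # increments per offset
            valid = m_counts >= 1
            lengths = sums[valid] * (n - 1) / (m_counts[valid] * k * k)
            lk = float(lengths.mean())
        if lk <= 0.0:
            raise ConstantSeriesError(f"zero curve length at delay k={k}")
        log_k.append(np.log(k))
        log_l.append(np.log(lk))
    lx = np.asarray(log_k)
    ly = np.asarray(log_l)
    lx = lx - lx.mean()
    slope = float(lx @ (ly - ly.mean()) / (lx @ lx))
    fd = -slope
    if clamp and not 1.0 <= fd <= 2.0:
        warnings.warn(f"Higuchi FD {fd:.4f} outside [1, 2]; clamped", stacklevel=2)
        fd = min(max(fd, 1.0), 2.0)
    return fd


@dataclass
class FDCResult:
    """Per-circle Higuchi FDs and the seven zone-combination means.

    ``zone_means`` maps each of A, B, C, AB, AC, BC, ABC to the arithmetic
    mean FD over all circles in the combination's constituent zones (NaN
    and listed in ``missing`` when a zone has no valid circle).
    ``n_skipped`` counts constant-profile circles that were excluded.
    """

    per_circle: dict[float, float]
    zone_of_circle: dict[float, str]
    zone_means: dict[str, float]
    n_skipped: int = 0
    missing: tuple[str, ...] = ()


def fdc(
    profiles: list[CircleProfile],
    params: HiguchiParams = HiguchiParams(),
) -> FDCResult:
    """Zone-specific circular FD from zone-labelled circle profiles.

    Each profile is a closed path, so the periodic Higuchi form is used:
    the per-circle FD does not depend on the (arbitrary) angle at which
    the circle was cut open.
    """
    if not profiles:
        raise ParameterError("need at least one circle profile")
    per_circle: dict[float, float] = {}
    zone_of: dict[float, str] = {}
    by_zone: dict[str, list[float]] = {z: [] for z in ZONE_ORDER}
    skipped = 0
    for p in profiles:
        if p.zone not in by_zone:
            raise ParameterError(f"unknown zone label {p.zone!r}")
        try:
            v = higuchi_fd(p.samples, params, periodic=True)
        except ConstantSeriesError:
            skipped += 1
            continue
        per_circle[p.radius] = v
        zone_of[p.radius] = p.zone
        by_zone[p.zone].append(v)
    means: dict[str, float] = {}
    missing = []
    for combo in COMBO_ORDER:
        vals = [v for z in combo for v in by_zone[z]]
        if vals:
            means[combo] = float(np.mean(vals))
        else:
            means[combo] = float("nan")
            missing.append(combo)
    if skipped:
        warnings.warn(f"{skipped} constant circle profile(s) skipped", stacklevel=2)
    return FDCResult(
        per_circle=per_circle,
        zone_of_circle=zone_of,
        zone_means=means,
        n_skipped=skipped,
        missing=tuple(missing),
    )


@dataclass
class SpectralFDResult:
    """Spectral comparator output with its log-log regression diagnostics."""

    value: float  # absolute fitted slope of log magnitude vs log frequency
    slope: float
    intercept: float
    freqs: np.ndarray = field(repr=False)
    magnitudes: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)


def spectral_fd(
    img: np.ndarray,
    fit_band: tuple[float, float] | None = None,
    affine_map: tuple[float, float] | None = None,
) -> SpectralFDResult:
    """Spectral (Fourier) fractal measure of a greyscale image.

    The 2D Fourier magnitude is averaged over annuli of integer radial
    frequency (cycles/image) and regressed, log magnitude on log frequency,
    over ``fit_band`` (default 4 cycles/image to 0.45 x Nyquist).  The
    absolute slope is returned; ``affine_map=(offset, scale)`` optionally
    remaps it as ``offset + scale * |slope|`` for users who calibrate the
    slope to a dimension scale.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ParameterError("spectral_fd expects a square 2D image")
    n = img.shape[0]
    if n < 64:
        raise ParameterError("image side must be >= 64")
    if img.std() == 0:
        raise DegenerateInputError("constant image has a degenerate spectrum")
    F = np.fft.fftshift(np.fft.fft2(img))
    mag = np.abs(F)
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    rbin = np.rint(r).astype(int)
    nmax = c - 1
    sums = np.bincount(rbin.ravel(), weights=mag.ravel(), minlength=nmax + 1)
    cnts = np.bincount(rbin.ravel(), minlength=nmax + 1)
    freqs = np.arange(1, nmax + 1, dtype=np.float64)
    radial = sums[1 : nmax + 1] / cnts[1 : nmax + 1]
    if fit_band is None:
        fit_band = (4.0, 0.45 * (n / 2.0))
    lo, hi = fit_band
    sel = (freqs >= lo) & (freqs <= hi) & (radial > 0)
    if sel.sum() < 3:
        raise ParameterError("fit band leaves fewer than 3 spectral points")
    lx, ly = np.log(freqs[sel]), np.log(radial[sel])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    value = abs(float(slope))
    if affine_map is not None:
        value = affine_map[0] + affine_map[1] * value
    return SpectralFDResult(
        value=value,
        slope=float(slope),
        intercept=float(intercept),
        freqs=freqs[sel],
        magnitudes=radial[sel],
        residuals=resid,
    )


def binarize_for_bc(
    img: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    skeletonize: bool = True,
) -> np.ndarray:
    """Binarise a 0-255 posterior image for box counting.

    Default is a global Otsu threshold followed by morphological
    skeletonisation, matching common practice for box-counting vascular
    networks; both are configurable since the binarisation step is a known
    sensitivity of the box-counting comparator.
    """
    img = np.asarray(img)
    if method == "fixed":
        if threshold is None:
            raise ParameterError("fixed method requires a threshold")
        thr = threshold
    elif method == "otsu":
        if img.min() == img.max():
            raise DegenerateInputError("constant image cannot be thresholded")
        thr = threshold_otsu(img)
    else:
        raise ParameterError(f"unknown binarisation method {method!r}")
    binary = img > thr
    if not binary.any():
        raise DegenerateInputError("empty foreground after thresholding")
    if skeletonize:
        binary = _skeletonize(binary)
        if not binary.any():
            raise DegenerateInputError("empty skeleton")
    return binary


@dataclass
class BoxCountResult:
    """Box-counting output with grid sizes, counts and fit residuals."""

    value: float
    sizes: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)


def box_counting_fd(binary: np.ndarray) -> BoxCountResult:
    """Box-counting dimension of a binary structure.

    Box sides are powers of two from 2 up to a quarter of the (padded)
    image side, the grid anchored at the origin; the FD is the least-squares
    slope of log N(s) against log(1/s).
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 2:
        raise ParameterError("box_counting_fd expects a 2D binary image")
    if min(binary.shape) < 16:
        raise ParameterError("image side must be >= 16")
    nfg = int(binary.sum())
    if nfg == 0:
        raise DegenerateInputError("no foreground pixels")
    side = int(2 ** np.ceil(np.log2(max(binary.shape))))
    padded = np.zeros((side, side), dtype=bool)
    padded[: binary.shape[0], : binary.shape[1]] = binary
    sizes = 2 ** np.arange(1, int(np.log2(side)) - 1)  # 2 .. side/4
    counts = []
    for s in sizes:
        blocks = padded.reshape(side // s, s, side // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    sizes = np.asarray(sizes, dtype=np.float64)
    counts_arr = np.asarray(counts, dtype=np.float64)
    if nfg == 1:
        warnings.warn("single foreground pixel: box-counting FD is 0", stacklevel=2)
        return BoxCountResult(0.0, sizes, counts_arr, np.zeros_like(sizes))
    lx = np.log(1.0 / sizes)
    ly = np.log(counts_arr)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return BoxCountResult(float(slope), sizes, counts_arr, resid)
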
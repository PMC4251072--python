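"""Synthetic fixtures: signals and images of known fractal dimension, and
optic-disc-centred fundus phantoms with controllable vascular complexity.

Everything here is seeded: identical parameters and seed give bit-identical
output.  Random streams are derived from a single master seed through
``numpy.random.SeedSequence`` spawning, so per-image streams are independent
and reproducible regardless of generation order.

The fundus phantom emulates the acquisition geometry the circular-scan
method assumes: a bright optic disc (OD) at the image centre, primary
vessels leaving the OD boundary radially and bifurcating as they grow, a
gentle illumination gradient and additive sensor noise.  Vessels are dark on
a brighter background, as in the green channel of a real photograph; the
preprocessing chain inverts the image before analysis.  Case/control
contrast is carried *only* by complexity parameters (branching probability
and/or trunk count), never by contrast or noise, so that it isolates the
quantity the circular FD claims to measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .errors import ParameterError
from .preprocess import ODAnnotation, read_annotations, write_annotations

__all__ = [
    "FundusSynthParams",
    "SynthCohort",
    "gen_fbm_series",
    "gen_sierpinski",
    "gen_power_law_image",
    "gen_synthetic_fundus",
    "default_case_control_params",
    "gen_cohort",
    "write_cohort",
    "read_cohort",
]


# --------------------------------------------------------------------------
# 1D / 2D fixtures of known fractal dimension
# --------------------------------------------------------------------------

def _fgn_autocov(hurst: float, lags: np.ndarray) -> np.ndarray:
    k = np.abs(lags).astype(np.float64)
    return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))


def gen_fbm_series(hurst: float, n: int, seed: int | None = None) -> np.ndarray:
    """Fractional Brownian motion path of length ``n`` with Hurst exponent ``hurst``.

    Uses exact circulant embedding (Davies-Harte) of the fractional Gaussian
    noise covariance; falls back to a Cholesky factorisation for ``n <= 2048``
    in the rare event the embedding is not non-negative definite.  The graph
    of the returned path has fractal dimension ``2 - hurst``, and the
    variance of increments at lag ``k`` scales exactly as ``k**(2*hurst)``.
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    if n < 64:
        raise ParameterError(f"n must be >= 64, got {n}")
    rng = np.random.default_rng(seed)
    gamma = _fgn_autocov(hurst, np.arange(n + 1))
    # circulant embedding of size 2n
    c = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-9 * lam.max() and n <= 2048:
        cov = _fgn_autocov(hurst, np.subtract.outer(np.arange(n), np.arange(n)))
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        fgn = chol @ rng.standard_normal(n)
        return np.cumsum(fgn)
    lam = np.clip(lam, 0.0, None)
    m = lam.size  # 2n
    # Hermitian-symmetric complex Gaussian spectrum
    v = np.empty(m, dtype=np.complex128)
    v[0] = rng.standard_normal()
    v[m // 2] = rng.standard_normal()
    a = rng.standard_normal(m // 2 - 1)
    b = rng.standard_normal(m // 2 - 1)
    v[1 : m // 2] = (a + 1j * b) / np.sqrt(2.0)
    v[m // 2 + 1 :] = np.conj(v[1 : m // 2][::-1])
    fgn = np.fft.fft(np.sqrt(lam / m) * v).real[:n]
    return np.cumsum(fgn)


def gen_sierpinski(order: int) -> np.ndarray:
    """Sierpinski-triangle raster at side ``2**order`` (boolean image).

    Foreground pixel count is exactly ``3**order``; the set's similarity
    dimension is ``log 3 / log 2`` (about 1.585).
    """
    if not 1 <= int(order) <= 9 or int(order) != order:
        raise ParameterError(f"order must be an integer in [1, 9], got {order}")
    s = np.ones((1, 1), dtype=bool)
    for _ in range(int(order)):
        z = np.zeros_like(s)
        s = np.block([[s, z], [s, s]])
    return s


def gen_power_law_image(beta: float, size: int = 256, seed: int | None = None) -> np.ndarray:
    """Random-phase image whose radially averaged power spectrum falls as f^-beta.

    White spatial noise is shaped in the Fourier domain by the radial
    amplitude ``f**(-beta/2)`` (DC suppressed), then transformed back.  The
    log power vs log frequency regression slope of the result is ``-beta``
    in expectation, making it a construction-based oracle for the spectral
    FD estimator.  Output is standardised to zero mean, unit variance.
    """
    if size < 64:
        raise ParameterError(f"size must be >= 64, got {size}")
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((size, size))
    ft = np.fft.fft2(w)
    f1 = np.fft.fftfreq(size) * size  # cycles per image
    f = np.hypot(f1[:, None], f1[None, :])
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-beta / 2.0)
    img = np.fft.ifft2(ft * amp).real
    img -= img.mean()
    sd = img.std()
    if sd > 0:
        img /= sd
    return img


# --------------------------------------------------------------------------
# Synthetic fundus phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FundusSynthParams:
    """Parameters of the synthetic OD-centred fundus generator.

    Defaults match the working-image geometry of the analysis pipeline
    (400 px frame, 100 px OD, hence a 4 OD-diameter ROI filling the frame).
    ``branch_prob`` is the per-growth-step bifurcation probability and is
    the primary complexity dial; ``width0`` is the trunk half-width in
    pixels, decaying by ``width_decay`` at each bifurcation generation.
    """

    image_size: int = 400
    od_diameter: float = 100.0
    n_trunks: int = 6
    branch_prob: float = 0.10
    width0: float = 3.0
    width_decay: float = 0.70
    tortuosity: float = 6.0  # degrees of heading jitter per 1 px step
    contrast: float = 0.35  # vessel-to-background intensity gap in [0, 1]
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ParameterError(f"branch_prob must be in [0, 1], got {self.branch_prob}")
        if not 0.0 < self.width_decay < 1.0:
            raise ParameterError(f"width_decay must be in (0, 1), got {self.width_decay}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ParameterError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.n_trunks < 0:
            raise ParameterError("n_trunks must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        # the 4 x D_OD ROI (side 4*d_od) must fit inside the frame
        if self.image_size < 4 * self.od_diameter:
            raise ParameterError(
                f"image_size {self.image_size} too small for the 4x OD-diameter "
                f"ROI (needs >= {4 * self.od_diameter:.0f})"
            )


def _grow_tree(params: FundusSynthParams, rng: np.random.Generator):
    """Grow vessel centrelines as radially biased branching random walks.

    Returns (points_xy, sigmas, trunk_seeds): centreline sample points at
    1 px steps with their Gaussian cross-section sigma, and the trunk seed
    points on the OD boundary.
    """
    s = params.image_size
    c = (s - 1) / 2.0
    r_od = params.od_diameter / 2.0
    jitter_sd = np.deg2rad(params.tortuosity)
    min_width = 0.4
    max_steps_total = 40 * s  # hard cap against pathological growth
    # trunks: evenly spaced around the disc with angular jitter, seeded
    # exactly on the OD boundary circle
    base = rng.uniform(0, 2 * np.pi)
    angles = base + 2 * np.pi * np.arange(params.n_trunks) / max(params.n_trunks, 1)
    angles = angles + rng.normal(0, np.deg2rad(12.0), size=params.n_trunks)
    stack = []
    trunk_seeds = []
    for ang in angles:
        x = c + r_od * np.cos(ang)
        y = c + r_od * np.sin(ang)
        trunk_seeds.append((x, y))
        stack.append((x, y, ang, params.width0, 0))
    pts_x, pts_y, sig = [], [], []
    steps_done = 0
    chunk = 256  # pre-drawn randoms per growth stretch (scalar RNG calls are slow)
    while stack and steps_done < max_steps_total:
        x, y, ang, width, gen = stack.pop()
        if width < min_width:
            continue
        sigma = width / 1.2  # half-width ~ HWHM of the rendered Gaussian profile
        growing = True
        while growing and steps_done < max_steps_total:
            jit = rng.normal(0.0, jitter_sd, size=chunk)
            bra = rng.random(size=chunk) < params.branch_prob
            for t in range(chunk):
                steps_done += 1
                # radial bias keeps the tree pointing away from the disc
                radial = math.atan2(y - c, x - c)
                dang = math.atan2(math.sin(radial - ang), math.cos(radial - ang))
                ang = ang + 0.15 * dang + jit[t]
                x += math.cos(ang)
                y += math.sin(ang)
                if not (0.0 <= x <= s - 1 and 0.0 <= y <= s - 1):
                    growing = False
                    break
                pts_x.append(x)
                pts_y.append(y)
                sig.append(sigma)
                if bra[t]:
                    delta = math.radians(rng.uniform(20.0, 40.0))
                    w_child = width * params.width_decay
                    stack.append((x, y, ang + delta, w_child, gen + 1))
                    stack.append((x, y, ang - delta, w_child, gen + 1))
                    growing = False
                    break
    return np.array(pts_x), np.array(pts_y), np.array(sig), trunk_seeds


def _render_vessels(params: FundusSynthParams, px, py, sig) -> np.ndarray:
    """Render centrelines as tubes with Gaussian cross-section via an EDT.

    Centreline points are rasterised to their nearest pixel carrying the
    local sigma; the Euclidean distance transform to that raster gives each
    pixel its distance to (and sigma of) the nearest centreline point.
    """
    s = params.image_size
    v = np.zeros((s, s))
    if px.size == 0:
        return v
    ix = np.clip(np.rint(px).astype(int), 0, s - 1)
    iy = np.clip(np.rint(py).astype(int), 0, s - 1)
    sig_map = np.zeros((s, s))
    np.maximum.at(sig_map, (iy, ix), sig)
    fg = sig_map > 0
    dist, (ny, nx) = distance_transform_edt(~fg, return_indices=True)
    sigma_n = sig_map[ny, nx]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.exp(-(dist**2) / (2.0 * sigma_n**2))
    v[sigma_n == 0] = 0.0
    v[dist > 3.5 * sigma_n] = 0.0
    return v


@lru_cache(maxsize=8)
def _scene_base(s: int, od_diameter: float) -> np.ndarray:
    """Deterministic background + optic-disc layer (shared across seeds)."""
    c = (s - 1) / 2.0
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    r = np.hypot(xx - c, yy - c)
    background = 0.55 + 0.08 * (xx - c) / s - 0.05 * (r / (s / 2.0)) ** 2
    od_boost = 0.20 / (1.0 + np.exp((r - od_diameter / 2.0) / 2.0))
    return background + od_boost


def gen_synthetic_fundus(
    params: FundusSynthParams, return_tree: bool = False
) -> tuple[np.ndarray, ODAnnotation] | tuple[np.ndarray, ODAnnotation, dict]:
    """Synthesize a greyscale OD-centred fundus phantom.

    Returns a float image in [0, 1] (vessels dark, disc bright, background
    with a gentle gradient plus Gaussian noise) and the matching
    :class:`~retfdc.preprocess.ODAnnotation` (disc at the frame centre).
    With ``return_tree=True`` a third dict carries the trunk seed points and
    centreline samples for geometric tests.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    s = params.image_size
    c = (s - 1) / 2.0
    px, py, sig, seeds = _grow_tree(params, rng)
    vessels = _render_vessels(params, px, py, sig)

    img = _scene_base(s, float(params.od_diameter)) - params.contrast * vessels
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(s, s))
    img = np.clip(img, 0.0, 1.0)
    od = ODAnnotation(cx=c, cy=c, d_od=float(params.od_diameter))
    if return_tree:
        tree = {"trunk_seeds": seeds, "centreline": (px, py), "sigma": sig}
        return img, od, tree
    return img, od


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

def default_case_control_params(
    seed: int = 0,
) -> tuple[FundusSynthParams, FundusSynthParams]:
    """Default (case, control) parameter pair.

    Rarefaction of the microvasculature is modelled as a halved bifurcation
    probability in the cases (0.05 vs 0.10); every other parameter is
    shared, so group contrast is carried only by branching complexity.
    """
    control = FundusSynthParams(seed=seed)
    case = replace(control, branch_prob=0.05)
    return case, control


@dataclass
class SynthCohort:
    """A labelled set of synthetic fundus images with their annotations."""

    images: list[tuple[np.ndarray, ODAnnotation]]
    labels: list[str]
    ids: list[str]
    params_case: FundusSynthParams
    params_control: FundusSynthParams

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels) or len(self.images) != len(self.ids):
            raise ParameterError("images, labels and ids must have matching length")


def _child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def gen_cohort(
    n_case: int,
    n_control: int,
    params_case: FundusSynthParams | None = None,
    params_control: FundusSynthParams | None = None,
    seed: int = 0,
) -> SynthCohort:
    """Generate a labelled case/control image set with per-image derived seeds."""
    if n_case < 2 or n_control < 2:
        raise ParameterError("need at least 2 subjects per group")
    if params_case is None or params_control is None:
        d_case, d_control = default_case_control_params()
        params_case = params_case or d_case
        params_control = params_control or d_control
    seeds = _child_seeds(seed, n_case + n_control)
    images, labels, ids = [], [], []
    for i in range(n_case + n_control):
        group = "case" if i < n_case else "control"
        base = params_case if group == "case" else params_control
        img, od = gen_synthetic_fundus(replace(base, seed=seeds[i]))
        images.append((img, od))
        labels.append(group)
        ids.append(f"{group}_{i:03d}")
    return SynthCohort(images, labels, ids, params_case, params_control)


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> None:
    """Write a cohort as 16-bit PNGs plus annotation and label CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = {}
    rows = []
    for (img, od), label, image_id in zip(cohort.images, cohort.labels, cohort.ids):
        q = np.clip(np.rint(img * 65535.0), 0, 65535).astype(np.uint16)
        iio.imwrite(outdir / f"{image_id}.png", q)
        annotations[image_id] = od
        rows.append({"image_id": image_id, "group": label})
    write_annotations(annotations, outdir / "annotations.csv")
    pd.DataFrame(rows).to_csv(outdir / "labels.csv", index=False)


def read_cohort(indir: str | Path) -> SynthCohort:
    """Read a cohort written by :func:`write_cohort` (images back in [0, 1])."""
    indir = Path(indir)
    annotations = read_annotations(indir / "annotations.csv")
    labels_df = pd.read_csv(indir / "labels.csv")
    images, labels, ids = [], [], []
    for row in labels_df.itertuples():
        image_id = str(row.image_id)
        img = iio.imread(indir / f"{image_id}.png").astype(np.float64) / 65535.0
        images.append((img, annotations[image_id]))
        labels.append(str(row.group))
        ids.append(image_id)
    dummy = FundusSynthParams()
    return SynthCohort(images, labels, ids, dummy, dummy)
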
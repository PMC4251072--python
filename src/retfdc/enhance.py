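"""Vessel enhancement with a 2D Gabor wavelet matched-filter bank.

The analysing wavelet is the anisotropic complex exponential

    psi(x) = exp(i k0 . x) exp(-|A x|^2 / 2),   A = diag(eps^(-1/2), 1),

elongated along x by the factor ``eps`` and oscillating along y with wave
vector ``k0`` (default (0, 3)).  The continuous wavelet transform modulus is
evaluated in the frequency domain at a bank of scales and orientations; for
each scale the pixelwise maximum over orientations is the matched-filter
response to line-like structure at that calibre.  The per-scale responses
(optionally joined by the inverted-green intensity) are z-normalised and fed
to an unsupervised two-component Gaussian mixture; the posterior probability
of the vessel component (the component with the higher mean response at the
coarsest scale), mapped to integers 0-255, is the *posterior vessel image*
on which all fractal estimators operate.

The mixture replaces a supervised pixel classifier: no labelled vessel
pixels are assumed, and the two components play the roles of the vessel and
background class-conditional densities fitted per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft as sfft
from scipy.linalg import solve_triangular
from sklearn.mixture import GaussianMixture

from .errors import DegenerateInputError, FormatError, ParameterError
from .preprocess import ODAnnotation, WorkingImage

__all__ = [
    "GaborBankParams",
    "PosteriorVesselImage",
    "gabor_response",
    "max_orientation_features",
    "normalize_features",
    "posterior_image",
    "enhance",
]


@dataclass(frozen=True)
class GaborBankParams:
    """Filter-bank configuration.

    ``scales`` are wavelet dilation factors; ``n_orientations`` equally
    spaced angles cover [0, 180) degrees (18 gives 10-degree steps);
    ``elongation`` is the anisotropy eps >= 1 and ``k0`` the wave vector of
    the complex carrier.  ``include_intensity_feature`` appends the raw
    inverted-green intensity to the feature stack.
    """

    scales: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0)
    n_orientations: int = 18
    elongation: float = 4.0
    k0: tuple[float, float] = (0.0, 3.0)
    include_intensity_feature: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales) or not self.scales:
            raise ParameterError("scales must be positive and non-empty")
        if self.n_orientations < 1:
            raise ParameterError("n_orientations must be >= 1")
        if self.elongation < 1:
            raise ParameterError("elongation must be >= 1")

    @property
    def angles_deg(self) -> np.ndarray:
        return 180.0 * np.arange(self.n_orientations) / self.n_orientations


@dataclass
class PosteriorVesselImage:
    """0-255 vessel-likelihood image sharing geometry with its WorkingImage."""

    pixels: np.ndarray  # uint8
    od: ODAnnotation
    params: GaborBankParams

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8:
            raise FormatError("posterior pixels must be uint8 in [0, 255]")


@lru_cache(maxsize=8)
def _freq_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ky = (2 * np.pi * sfft.fftfreq(h)).astype(np.float32)
    kx = (2 * np.pi * sfft.fftfreq(w)).astype(np.float32)
    return np.broadcast_to(ky[:, None], (h, w)), np.broadcast_to(kx[None, :], (h, w))


@lru_cache(maxsize=128)
def _wavelet_ft(
    shape: tuple[int, int],
    scale: float,
    angle_deg: float,
    elongation: float,
    k0: tuple[float, float],
) -> np.ndarray:
    """Fourier transform of the rotated/dilated wavelet on the FFT grid.

    L1 scale normalisation: the spatial wavelet is a^-2 psi(x/a), whose
    transform is psi_hat(a k) with no prefactor, keeping the response to a
    matched structure comparable across scales.
    """
    KY, KX = _freq_grid(shape)
    th = np.deg2rad(angle_deg)
    # frequency coordinates in the rotated wavelet frame
    u = np.cos(th) * KX + np.sin(th) * KY
    v = -np.sin(th) * KX + np.cos(th) * KY
    au = scale * u
    av = scale * v
    k0x, k0y = k0
    # the transform is real (a Gaussian centred at k0), so conj(psi_hat) = psi_hat;
    # tails below 1e-30 are flushed to exact zero (they are negligible and
    # subnormal float32 values make the FFT path pathologically slow)
    ft = np.exp(-0.5 * (elongation * (au - k0x) ** 2 + (av - k0y) ** 2))
    ft = np.where(ft < 1e-30, 0.0, ft)
    return ft.astype(np.float32)


@lru_cache(maxsize=128)
def _wavelet_rows(
    shape: tuple[int, int],
    scale: float,
    angle_deg: float,
    elongation: float,
    k0: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero-row support of a kernel spectrum and the kernel on those rows."""
    psi = _wavelet_ft(shape, scale, angle_deg, elongation, k0)
    rows = np.flatnonzero(psi.any(axis=1))
    return rows, np.ascontiguousarray(psi[rows])


def gabor_response(
    img: np.ndarray,
    scale: float,
    angle_deg: float,
    elongation: float = 4.0,
    k0: tuple[float, float] = (0.0, 3.0),
) -> np.ndarray:
    """Modulus of the continuous Gabor wavelet transform at one scale/angle.

    Computed by frequency-domain multiplication with periodic (FFT-native)
    border handling; output is non-negative with the input's shape.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError("gabor_response expects a 2D image")
    if not np.all(np.isfinite(img)):
        raise FormatError("image contains non-finite pixels")
    if scale <= 0:
        raise ParameterError("scale must be positive")
    if not 0.0 <= angle_deg < 180.0:
        raise ParameterError("angle must be in [0, 180) degrees")
    F = sfft.fft2(img.astype(np.float32))
    psi = _wavelet_ft(img.shape, float(scale), float(angle_deg), float(elongation), tuple(k0))
    resp = sfft.ifft2(F * psi, overwrite_x=True)
    return np.abs(resp).astype(np.float64)


def max_orientation_features(
    img: np.ndarray, params: GaborBankParams = GaborBankParams()
) -> list[np.ndarray]:
    """Per-scale orientation-maximum response maps (plus optional intensity).

    For each scale the pixelwise maximum of the transform modulus over all
    orientations is taken, so line-like structure of any direction responds.
    """
    orig = np.asarray(img, dtype=np.float64)
    if orig.ndim != 2:
        raise FormatError("expected a 2D image")
    img = orig.astype(np.float32)
    F = sfft.fft2(img)
    buf = np.zeros(img.shape, dtype=np.complex64)
    features: list[np.ndarray] = []
    for scale in params.scales:
        best = None
        for ang in params.angles_deg:
            rows, psi_rows = _wavelet_rows(
                img.shape, float(scale), float(ang), params.elongation, params.k0
            )
            # the kernel spectrum is compactly supported: restrict the
            # row-wise IFFT pass to its nonzero rows, then transform columns
            buf[:] = 0.0
            buf[rows] = sfft.ifft(F[rows] * psi_rows, axis=1)
            resp = np.abs(sfft.ifft(buf, axis=0))
            best = resp if best is None else np.maximum(best, resp)
        features.append(best.astype(np.float64))
    if params.include_intensity_feature:
        features.append(orig)
    return features


def normalize_features(
    features: list[np.ndarray], mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """Shift/scale each feature to zero mean, unit variance over ``mask``.

    Zero-variance features are dropped with a warning.  Normalisation makes
    the feature stack invariant to positive affine transforms of any single
    feature, so upstream response-magnitude conventions are benign.
    """
    if not features:
        raise ParameterError("need at least one feature map")
    out = []
    for i, f in enumerate(features):
        sel = f[mask] if mask is not None else f
        mu = float(sel.mean())
        sd = float(sel.std())
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"feature {i} has zero variance; dropped", stacklevel=2)
            continue
        out.append((f - mu) / sd)
    if not out:
        raise DegenerateInputError("all features were constant")
    return out


def _gaussian_posterior(x: np.ndarray, gmm: GaussianMixture) -> np.ndarray:
    """Component responsibilities of a fitted full-covariance 2-class mixture.

    Equivalent to ``gmm.predict_proba`` but evaluated directly (Cholesky
    whitening + log-sum-exp), which is substantially faster on whole-image
    pixel stacks.
    """
    n, d = x.shape
    logp = np.empty((n, gmm.n_components))
    for c in range(gmm.n_components):
        chol = np.linalg.cholesky(gmm.covariances_[c])
        white = solve_triangular(chol, (x - gmm.means_[c]).T, lower=True).T
        maha = np.einsum("ij,ij->i", white, white)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        logp[:, c] = (
            np.log(gmm.weights_[c])
            - 0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
        )
    m = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - m)
    return w / w.sum(axis=1, keepdims=True)


def posterior_image(
    features: list[np.ndarray],
    od: ODAnnotation,
    params: GaborBankParams = GaborBankParams(),
    seed: int = 0,
    vessel_feature_index: int | None = None,
    fit_subsample: int = 8192,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PosteriorVesselImage:
    """Two-class Gaussian-mixture posterior of the vessel class, on 0-255.

    The mixture is fitted (EM, k-means init, fixed seed) on a deterministic
    pixel subsample and evaluated on every pixel.  The vessel component is
    the one with the higher mean along ``vessel_feature_index`` (default:
    the coarsest-scale response, where vessels respond most strongly).  If
    the fit degenerates, a percentile-stretch of that feature is used
    instead, with a warning.
    """
    stack = np.stack([np.asarray(f, dtype=np.float64).ravel() for f in features], axis=1)
    npix, nfeat = stack.shape
    shape = features[0].shape
    if vessel_feature_index is None:
        vessel_feature_index = min(len(params.scales), nfeat) - 1
    rng = np.random.default_rng(seed)
    if npix > fit_subsample:
        idx = rng.choice(npix, size=fit_subsample, replace=False)
        fit_x = stack[idx]
    else:
        fit_x = stack
    post = None
    try:
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            max_iter=max_iter,
            tol=tol,
            reg_covar=1e-6,
            init_params="kmeans",
            n_init=1,
            random_state=int(seed) % (2**31),
        )
        gmm.fit(fit_x)
        if gmm.weights_.min() > 1e-4:
            vessel = int(np.argmax(gmm.means_[:, vessel_feature_index]))
            post = _gaussian_posterior(stack, gmm)[:, vessel]
    except Exception:  # pragma: no cover - numerical fit failure
        post = None
    if post is None:
        warnings.warn(
            "Gaussian mixture fit degenerate; falling back to percentile stretch",
            stacklevel=2,
        )
        f = stack[:, vessel_feature_index]
        lo, hi = np.percentile(f, [2.0, 98.0])
        post = np.clip((f - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    pixels = np.rint(255.0 * post).astype(np.uint8).reshape(shape)
    return PosteriorVesselImage(pixels=pixels, od=od, params=params)


def enhance(
    working: WorkingImage,
    params: GaborBankParams = GaborBankParams(),
    seed: int = 0,
) -> PosteriorVesselImage:
    """Full enhancement: filter bank -> z-normalisation -> mixture posterior.

    Features are normalised over the circular ROI (radius 2 OD diameters
    around the disc centre) so statistics are not diluted by frame corners
    outside the scanned region.
    """
    h, w = working.pixels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    roi = np.hypot(xx - working.od.cx, yy - working.od.cy) <= 2.0 * working.od.d_od
    features = max_orientation_features(working.pixels, params)
    features = normalize_features(features, mask=roi)
    return posterior_image(features, working.od, params=params, seed=seed)
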
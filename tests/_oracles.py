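"""Independent reference implementations used only as test oracles.

These are deliberately naive, loop-based transcriptions kept separate from
the package code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def higuchi_bruteforce(x, k_max):
    """Literal triple-loop transcription of the 1988 curve-length estimator.

    For delay k and 1-based offset m: M = floor((N-m)/k);
    L_m(k) = [sum_{i=1..M} |X(m+ik) - X(m+(i-1)k)| * (N-1)/(M k)] / k;
    L(k) = mean_m L_m(k); FD = -slope of log L(k) on log k.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    log_k, log_l = [], []
    for k in range(1, k_max + 1):
        lm = []
        for m in range(1, k + 1):  # 1-based offset
            big_m = (n - m) // k
            if big_m < 1:
                continue
            total = 0.0
            for i in range(1, big_m + 1):
                total += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            lm.append(total * (n - 1) / (big_m * k) / k)
        log_k.append(np.log(k))
        log_l.append(np.log(np.mean(lm)))
    slope = np.polyfit(log_k, log_l, 1)[0]
    return -float(slope)


def kw_h_direct(groups):
    """Tie-corrected Kruskal-Wallis H from first principles (own midranks)."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # midrank, 1-based
        i = j + 1
    h = 0.0
    pos = 0
    for g in groups:
        ng = len(g)
        rsum = ranks[pos : pos + ng].sum()
        h += rsum**2 / ng
        pos += ng
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if corr <= 0:
        return 0.0
    return h / corr


def kw_permutation_p(a, b, h_func=None):
    """Exact permutation p-value of the two-group rank statistic H."""
    h_func = h_func or kw_h_direct
    pooled = list(a) + list(b)
    na = len(a)
    h_obs = h_func([a, b])
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        sel = set(idx)
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        if h_func([ga, gb]) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def radial_power_slope(img, f_lo, f_hi):
    """Direct radially averaged log-power slope (pixel-loop binning)."""
    img = np.asarray(img, dtype=float)
    n = img.shape[0]
    power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    c = n // 2
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(n):
        for j in range(n):
            rb = int(round(np.hypot(i - c, j - c)))
            sums[rb] = sums.get(rb, 0.0) + power[i, j]
            counts[rb] = counts.get(rb, 0) + 1
    fs, ps = [], []
    for rb in sorted(sums):
        if f_lo <= rb <= f_hi:
            fs.append(np.log(rb))
            ps.append(np.log(sums[rb] / counts[rb]))
    return float(np.polyfit(fs, ps, 1)[0])


def gabor_spatial_response(img, scale, angle_deg, elongation=4.0, k0=(0.0, 3.0)):
    """Spatial-domain wrap-mode convolution with the sampled wavelet.

    Builds the rotated, dilated, L1-normalised complex wavelet on the pixel
    grid and convolves real and imaginary parts with periodic boundary via
    scipy.ndimage, taking the modulus — a different computational route
    from frequency-domain multiplication.
    """
    from scipy.ndimage import convolve

    img = np.asarray(img, dtype=float)
    # the envelope decays as exp(-x^2 / (2 eps scale^2)) along the elongated
    # axis, so the support must extend well past 6 scale units
    half = int(np.ceil(10 * scale))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    th = np.deg2rad(angle_deg)
    # rotate sample coordinates into the wavelet frame, then dilate
    xr = (np.cos(th) * x + np.sin(th) * y) / scale
    yr = (-np.sin(th) * x + np.cos(th) * y) / scale
    envelope = np.exp(-0.5 * (xr**2 / elongation + yr**2))
    carrier = np.exp(1j * (k0[0] * xr + k0[1] * yr))
    psi = (envelope * carrier) / scale**2  # L1 scale normalisation
    # matched filtering correlates with conj(psi); convolution needs the flip
    kern = np.conj(psi)[::-1, ::-1]
    re = convolve(img, kern.real, mode="wrap")
    im = convolve(img, kern.imag, mode="wrap")
    return np.hypot(re, im)
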
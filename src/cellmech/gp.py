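"""Laurdan generalized-polarization (GP) membrane-fluidity analysis.

GP is the ratiometric index ``(I420 - I473) / (I420 + I473)`` computed
per pixel from two registered laurdan emission channels; it lies in
[-1, 1], with higher values indicating a more ordered (less fluid)
membrane.  This module computes per-pixel GP maps, their frequency
distributions with single-Gaussian fits, condition-difference curves,
summary GP, and overlap of high-GP regions with a nanoparticle channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .errors import MaskError


@dataclass(frozen=True)
class RatiometricImagePair:
    """Two registered emission-channel grids plus an optional NP channel."""

    i420: np.ndarray
    i473: np.ndarray
    np_channel: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        a, b = np.asarray(self.i420), np.asarray(self.i473)
        if a.shape != b.shape:
            raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if self.np_channel is not None and np.asarray(self.np_channel).shape != a.shape:
            raise ValueError("np_channel shape must match the emission channels")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("channel intensities must be non-negative")


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    mean: float
    sd: float
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class GPMap:
    """Per-pixel GP values valid where ``mask`` is true (NaN elsewhere)."""

    gp: np.ndarray
    mask: np.ndarray
    intensity_threshold: float

    @property
    def values(self) -> np.ndarray:
        """Masked-in GP values as a flat array."""
        return self.gp[self.mask]


@dataclass(frozen=True)
class GPDistribution:
    """Normalized GP histogram over [-1, 1] with an optional Gaussian fit."""

    bin_centers: np.ndarray
    frequencies: np.ndarray
    n_pixels: int
    gaussian_fit: GaussianFit | None = None

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class GPDifferenceCurve:
    bin_centers: np.ndarray
    delta_frequency: np.ndarray
    minuend: str  # which condition the curve is "minuend - subtrahend" of


def compute_gp_map(
    pair: RatiometricImagePair,
    intensity_threshold: float | None = None,
    mask: np.ndarray | None = None,
) -> GPMap:
    """Compute ``GP = (I420 - I473) / (I420 + I473)`` per pixel.

    Pixels are masked in where ``I420 + I473`` exceeds
    ``intensity_threshold``.  When no threshold is given, Otsu's
    threshold of the sum image is used; pass an explicit ``mask`` to
    override thresholding entirely.

    Raises
    ------
    MaskError
        If every pixel is masked out (e.g. a blank image).
    """
    i420 = np.asarray(pair.i420, dtype=float)
    i473 = np.asarray(pair.i473, dtype=float)
    total = i420 + i473
    if mask is not None:
        valid = mask.astype(bool) & (total > 0)
        threshold = 0.0
    else:
        if intensity_threshold is None:
            if np.ptp(total) == 0:
                raise MaskError("flat sum image; cannot derive an Otsu threshold")
            intensity_threshold = float(threshold_otsu(total))
        valid = total > intensity_threshold
        threshold = float(intensity_threshold)
    if not np.any(valid):
        raise MaskError(
            "no pixel exceeds the intensity threshold "
            f"({threshold:g}); the image may be background only"
        )
    gp = np.full(total.shape, np.nan)
    np.divide(i420 - i473, total, out=gp, where=valid)
    return GPMap(gp=gp, mask=valid, intensity_threshold=threshold)


def gp_frequency_distribution(gp_map: GPMap, n_bins: int = 100) -> GPDistribution:
    """Bin masked-in GP values over [-1, 1] into a normalized histogram."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = gp_map.values
    if values.size == 0:
        raise MaskError("GP map has no valid pixels")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    freqs = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    return GPDistribution(bin_centers=centers, frequencies=freqs, n_pixels=int(values.size))


def _gauss(x: np.ndarray, amplitude: float, mean: float, sd: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mean) ** 2) / (2 * sd**2))


def fit_gaussian(dist: GPDistribution) -> GPDistribution:
    """Least-squares single-Gaussian fit of the GP histogram.

    Non-convergence (including degenerate histograms with fewer than
    five occupied bins) is reported through ``gaussian_fit.converged``
    rather than raised, so batch analyses keep going.
    """
    x, y = dist.bin_centers, dist.frequencies
    occupied = int(np.count_nonzero(y))
    if occupied < 5:
        fit = GaussianFit(np.nan, np.nan, np.nan, np.nan, converged=False)
        return replace(dist, gaussian_fit=fit)
    mean0 = float(np.sum(x * y))
    sd0 = float(np.sqrt(max(np.sum((x - mean0) ** 2 * y), 1e-8)))
    p0 = (float(y.max()), mean0, sd0)
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=p0,
            bounds=([0.0, -1.5, 1e-4], [np.inf, 1.5, 4.0]),
            maxfev=10000,
        )
        resid = float(np.sqrt(np.mean((_gauss(x, *popt) - y) ** 2)))
        fit = GaussianFit(float(popt[0]), float(popt[1]), float(popt[2]), resid, converged=True)
    except RuntimeError:
        fit = GaussianFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    return replace(dist, gaussian_fit=fit)


def gp_difference_curve(
    dist_a: GPDistribution, dist_b: GPDistribution, minuend: str = "a"
) -> GPDifferenceCurve:
    """Per-bin frequency difference between two conditions.

    The default orientation subtracts ``b`` from ``a`` (``minuend="a"``);
    in the study's usage ``a`` is the untreated control and ``b`` the
    treated condition.  The orientation travels with the result and can
    be flipped with ``minuend="b"``.
    """
    if dist_a.bin_centers.shape != dist_b.bin_centers.shape or not np.allclose(
        dist_a.bin_centers, dist_b.bin_centers
    ):
        raise ValueError("distributions must share identical binning")
    if minuend not in ("a", "b"):
        raise ValueError("minuend must be 'a' or 'b'")
    delta = dist_a.frequencies - dist_b.frequencies
    if minuend == "b":
        delta = -delta
    return GPDifferenceCurve(
        bin_centers=dist_a.bin_centers.copy(), delta_frequency=delta, minuend=minuend
    )


def total_mean_gp(gp_map: GPMap) -> float:
    """Arithmetic mean GP over masked-in pixels."""
    values = gp_map.values
    if values.size == 0:
        raise MaskError("GP map has no valid pixels")
    return float(values.mean())


@dataclass(frozen=True)
class ColocalizationResult:
    """Fraction of high-GP pixels that are also nanoparticle-positive."""

    fraction: float
    n_high_gp: int
    n_overlap: int
    defined: bool


def high_gp_colocalization(
    gp_map: GPMap,
    np_channel: np.ndarray,
    gp_threshold: float,
    np_threshold: float,
) -> ColocalizationResult:
    """Overlap fraction of nanoparticle signal with high-GP (rigid) regions.

    ``fraction = |{GP > gp_threshold and NP > np_threshold}| /
    |{GP > gp_threshold}|`` over masked-in pixels.  With no high-GP
    pixels the fraction is undefined and returned as NaN with
    ``defined=False``.
    """
    np_channel = np.asarray(np_channel)
    if np_channel.shape != gp_map.gp.shape:
        raise ValueError("np_channel must be registered to the GP map")
    high = gp_map.mask & (np.nan_to_num(gp_map.gp, nan=-np.inf) > gp_threshold)
    n_high = int(high.sum())
    if n_high == 0:
        return ColocalizationResult(float("nan"), 0, 0, defined=False)
    overlap = int((high & (np_channel > np_threshold)).sum())
    return ColocalizationResult(overlap / n_high, n_high, overlap, defined=True)
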
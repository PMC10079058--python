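"""Fourier utilities for frequency-bias analysis of images.

Everything in this module works on centered (fftshift) 2-D discrete Fourier
transforms of real images. Two normalization conventions for frequency
coordinates are supported and always carried explicitly:

``sampling``
    frequencies in cycles/pixel, i.e. normalized by the sampling rate;
    axes span [-0.5, 0.5) and the radial maximum is sqrt(2)/2.
``nyquist``
    frequencies normalized by the Nyquist rate (half the sampling rate);
    axes span [-1, 1) and the radial maximum is sqrt(2). Bin-for-bin these
    are exactly twice the sampling-mode values.

The central summary statistic is the half-power frequency ``f_half``: the
radial frequency below which half of the total spectral power lies. For a
classifier's minimal adversarial perturbations, a small ``f_half`` means the
model's decision boundary is sensitive to low-spatial-frequency structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np

GridMode = Literal["sampling", "nyquist"]

__all__ = [
    "FrequencyGrid",
    "PowerSpectrum",
    "RadialProfile",
    "frequency_grid",
    "power_spectrum",
    "mean_spectrum",
    "radial_profile",
    "half_power_frequency",
    "band_power_fraction",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Centered 2-D DFT frequency coordinates for an H x W image.

    Attributes
    ----------
    height, width : int
        Grid shape in bins.
    mode : {"sampling", "nyquist"}
        Frequency normalization convention.
    fx, fy : ndarray of shape (height, width)
        Per-bin normalized frequency coordinates (fx varies along columns,
        fy along rows). The DC bin sits at index (H//2, W//2).
    radius : ndarray of shape (height, width)
        Euclidean norm sqrt(fx**2 + fy**2) per bin.
    """

    height: int
    width: int
    mode: GridMode
    fx: np.ndarray = field(repr=False)
    fy: np.ndarray = field(repr=False)
    radius: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def frequency_grid(height: int, width: int, mode: GridMode = "sampling") -> FrequencyGrid:
    """Build the centered frequency grid for an ``height x width`` image."""
    if height < 1 or width < 1:
        raise ValueError("grid dimensions must be positive")
    if mode not in ("sampling", "nyquist"):
        raise ValueError(f"unknown grid mode {mode!r}")
    scale = 1.0 if mode == "sampling" else 2.0
    fx_1d = np.fft.fftshift(np.fft.fftfreq(width)) * scale
    fy_1d = np.fft.fftshift(np.fft.fftfreq(height)) * scale
    fx, fy = np.meshgrid(fx_1d, fy_1d)
    radius = np.hypot(fx, fy)
    return FrequencyGrid(height, width, mode, fx, fy, radius)


@dataclass(frozen=True)
class PowerSpectrum:
    """Centered per-bin spectral power of one or more images.

    ``values`` holds squared DFT magnitudes under the unnormalized transform
    convention, so Parseval's identity reads ``values.sum() == H*W*sum(x**2)``
    for a single real image. ``n_averaged`` counts the images averaged in.
    """

    values: np.ndarray
    grid: FrequencyGrid
    n_averaged: int = 1

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim not in (2, 3):
        raise ValueError(f"image must be HxW or HxWxC, got ndim={image.ndim}")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    return image


def power_spectrum(
    image: np.ndarray,
    mode: GridMode = "sampling",
    kind: Literal["power", "amplitude"] = "power",
) -> PowerSpectrum:
    """Centered 2-D spectrum of a single image.

    Multichannel images are handled by averaging per-channel spectra, matching
    the treatment of RGB perturbations elsewhere in the package. ``kind``
    selects squared magnitude (default) or plain magnitude.
    """
    image = _validate_image(image)
    if image.ndim == 2:
        image = image[:, :, None]
    spectra = np.abs(np.fft.fftshift(np.fft.fft2(image, axes=(0, 1)), axes=(0, 1))) ** 2
    values = spectra.mean(axis=2)
    if kind == "amplitude":
        values = np.sqrt(values)
    elif kind != "power":
        raise ValueError(f"unknown spectrum kind {kind!r}")
    grid = frequency_grid(image.shape[0], image.shape[1], mode)
    return PowerSpectrum(values, grid, n_averaged=1)


def mean_spectrum(
    images: Sequence[np.ndarray],
    mode: GridMode = "sampling",
    kind: Literal["power", "amplitude"] = "power",
) -> PowerSpectrum:
    """Arithmetic mean of per-image power spectra.

    All images must share a shape; the count of averaged images is recorded on
    the result.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    shape = np.asarray(images[0]).shape
    for i, img in enumerate(images):
        if np.asarray(img).shape != shape:
            raise ValueError(f"image {i} has shape {np.asarray(img).shape}, expected {shape}")
    spectra = [power_spectrum(img, mode=mode, kind=kind) for img in images]
    values = np.mean([s.values for s in spectra], axis=0)
    return PowerSpectrum(values, spectra[0].grid, n_averaged=len(images))


@dataclass(frozen=True)
class RadialProfile:
    """Cumulative radial power profile with its half-power frequency.

    ``cum_fraction[i]`` is the fraction of total power at radial frequencies
    ``<= radii[i]``; it is nondecreasing and ends at 1. ``f_half`` is the
    radius below which half of the power lies, on the scale of ``mode``.
    """

    radii: np.ndarray
    cum_fraction: np.ndarray
    f_half: float
    mode: GridMode


def _f_half_from_cumulative(
    radii: np.ndarray, cum: np.ndarray, interpolation: Literal["step", "linear"]
) -> float:
    idx = int(np.searchsorted(cum, 0.5, side="left"))
    idx = min(idx, len(radii) - 1)
    if interpolation == "step" or idx == 0 or cum[idx - 1] >= 0.5:
        return float(radii[idx])
    lo, hi = cum[idx - 1], cum[idx]
    t = (0.5 - lo) / (hi - lo)
    return float(radii[idx - 1] + t * (radii[idx] - radii[idx - 1]))


def radial_profile(
    spectrum: PowerSpectrum,
    interpolation: Literal["step", "linear"] = "step",
) -> RadialProfile:
    """Cumulative power fraction versus radial frequency.

    For each distinct radius ``r`` on the grid (DC included at ``r = 0``) the
    profile records the fraction of total power carried by bins with
    ``||f|| <= r``. ``f_half`` is the smallest distinct radius at which the
    cumulative fraction reaches one half — the median of the power-weighted
    radius distribution. With ``interpolation="linear"`` the 0.5 crossing is
    instead interpolated between adjacent distinct radii.

    Raises
    ------
    ValueError
        If the spectrum carries no power (the profile is undefined).
    """
    total = spectrum.values.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: radial profile undefined")
    # Round before grouping so radii that are equal up to float noise share a bin.
    r = np.round(spectrum.grid.radius.ravel(), 12)
    radii, inverse = np.unique(r, return_inverse=True)
    power = np.bincount(inverse, weights=spectrum.values.ravel(), minlength=len(radii))
    cum = np.cumsum(power) / total
    f_half = _f_half_from_cumulative(radii, cum, interpolation)
    return RadialProfile(radii, cum, f_half, spectrum.grid.mode)


class HalfPowerResult(NamedTuple):
    f_half: float
    spread: float


def half_power_frequency(
    images: Sequence[np.ndarray],
    mode: GridMode = "sampling",
    interpolation: Literal["step", "linear"] = "step",
) -> HalfPowerResult:
    """Half-power frequency of a set of images (e.g. adversarial perturbations).

    The point estimate is ``f_half`` of the mean power spectrum; the spread is
    the standard deviation of per-image ``f_half`` values (zero for a single
    image).
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    mean_prof = radial_profile(mean_spectrum(images, mode=mode), interpolation)
    per_image = [
        radial_profile(power_spectrum(img, mode=mode), interpolation).f_half for img in images
    ]
    spread = float(np.std(per_image, ddof=1)) if len(per_image) > 1 else 0.0
    return HalfPowerResult(mean_prof.f_half, spread)


def band_power_fraction(image: np.ndarray, cutoff: float, mode: GridMode = "nyquist") -> float:
    """Fraction of an image's spectral power at radial frequencies <= cutoff."""
    spec = power_spectrum(image, mode=mode)
    total = spec.values.sum()
    if total <= 0:
        raise ValueError("image has no spectral power")
    return float(spec.values[spec.grid.radius <= cutoff].sum() / total)
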
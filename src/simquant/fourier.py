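"""Centered 2-D DFT engine: power spectra, concentric-square bands,
circular windowing and band-limited inverse-transform reconstruction.

Conventions
-----------
* Forward transform is the unnormalized DFT; the inverse carries the
  ``1/N**2`` factor, so Parseval reads
  ``sum(|pixels|**2) == sum(|coeffs|**2) / N**2``.
* Spectra are stored centered ("shifted"): for even side ``N`` the DC bin
  sits at array index ``(N/2, N/2)``. The centered integer frequency of
  array index ``(i, j)`` is ``(v, u) = (i - N/2, j - N/2)`` with ``u`` the
  horizontal (column / x) frequency and ``v`` the vertical one. The
  Nyquist row and column are the unpaired ``u = -N/2`` / ``v = -N/2``
  lines at shifted index 0.
* Concentric-square bands are defined by two side-length fractions
  ``(f_outer, f_inner)``: a bin belongs to the band iff
  ``f_inner*N/2 <= max(|u|, |v|) < f_outer*N/2``. The half-open rule makes
  nested bands tile the plane; the DC bin is never a band member.

No apodization window is applied before the FFT; spectral leakage of
non-integer-period structures is part of the measured quantity and is
covered by tolerance-based validation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .images import GrayImage

__all__ = [
    "ComplexSpectrum",
    "PowerSpectrum",
    "BandSpec",
    "FOOT_PROCESS_BAND",
    "forward_spectrum",
    "power_spectrum",
    "band_mask",
    "reconstruct_from_band",
    "circular_window",
    "PlaneWaveFit",
    "fit_plane_wave",
]


@dataclasses.dataclass(frozen=True)
class ComplexSpectrum:
    """Centered complex DFT coefficients of a square even-sided image."""

    coeffs: np.ndarray
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=complex)
        if c.shape != (self.n, self.n):
            raise ValueError(f"coeffs shape {c.shape} does not match n={self.n}")
        if self.n % 2 != 0:
            raise ValueError("ComplexSpectrum is defined for even side lengths")
        object.__setattr__(self, "coeffs", c)

    @property
    def dc_index(self) -> tuple[int, int]:
        return (self.n // 2, self.n // 2)


@dataclasses.dataclass(frozen=True)
class PowerSpectrum:
    """Centered magnitude spectrum |F| (the radiology-style "PS")."""

    magnitudes: np.ndarray
    n: int

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.shape != (self.n, self.n):
            raise ValueError(f"magnitudes shape {m.shape} does not match n={self.n}")
        if np.any(m < 0):
            raise ValueError("spectral magnitudes must be nonnegative")
        object.__setattr__(self, "magnitudes", m)


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """Concentric-square annulus in frequency space.

    ``f_outer`` and ``f_inner`` are fractions of the full side length; the
    annulus lies between the centered squares of sides ``f_inner*N`` and
    ``f_outer*N`` (inner bound inclusive, outer exclusive).
    """

    f_outer: float
    f_inner: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_inner < self.f_outer <= 1.0):
            raise ValueError(
                f"require 0 <= f_inner < f_outer <= 1, got "
                f"({self.f_outer}, {self.f_inner})"
            )


#: The band that captures healthy foot-process periodicity at N=128:
#: concentric squares of sides N/4 and N/16 (centered half-widths 16 and 4).
FOOT_PROCESS_BAND = BandSpec(f_outer=1 / 4, f_inner=1 / 16)


def centered_frequencies(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (u, v) integer frequency grids for the centered layout.

    ``u`` varies along columns (x frequency), ``v`` along rows.
    """
    freqs = np.arange(n) - n // 2
    v, u = np.meshgrid(freqs, freqs, indexing="ij")
    return u, v


def forward_spectrum(img: GrayImage) -> ComplexSpectrum:
    """Unnormalized forward DFT, shifted so DC sits at the array center."""
    img.require_square_even()
    coeffs = np.fft.fftshift(np.fft.fft2(img.pixels))
    return ComplexSpectrum(coeffs, img.pixels.shape[0])


def power_spectrum(spec: ComplexSpectrum) -> PowerSpectrum:
    """Magnitude |F| per bin, same grid and centering as the input."""
    return PowerSpectrum(np.abs(spec.coeffs), spec.n)


def band_mask(n: int, band: BandSpec) -> np.ndarray:
    """Boolean membership grid of the concentric-square annulus.

    True exactly where ``f_inner*N/2 <= max(|u|,|v|) < f_outer*N/2``; the
    DC bin is always False.
    """
    if n % 2 != 0 or n < 8:
        raise ValueError(f"band masks require an even side >= 8, got n={n}")
    u, v = centered_frequencies(n)
    cheb = np.maximum(np.abs(u), np.abs(v))
    mask = (cheb >= band.f_inner * n / 2) & (cheb < band.f_outer * n / 2)
    mask[n // 2, n // 2] = False
    return mask


def reconstruct_from_band(
    spec: ComplexSpectrum,
    band: BandSpec,
    *,
    complement: bool = False,
    keep_dc: bool = False,
) -> GrayImage:
    """Inverse DFT keeping only the coefficients inside (or outside) a band.

    Coefficients outside the selected region and the DC term are zeroed
    before the inverse transform (``keep_dc=True`` restores the mean).
    With ``complement=True`` the kept region is every non-DC bin *not* in
    the band, including the Nyquist row/column. The output is the real
    part; the imaginary residual is checked to be negligible.
    """
    mask = band_mask(spec.n, band)
    if complement:
        mask = ~mask
        mask[spec.n // 2, spec.n // 2] = False
    coeffs = np.where(mask, spec.coeffs, 0.0)
    if keep_dc:
        coeffs[spec.n // 2, spec.n // 2] = spec.coeffs[spec.n // 2, spec.n // 2]
    out = np.fft.ifft2(np.fft.ifftshift(coeffs))
    scale = np.abs(out.real).max()
    if scale > 0 and np.abs(out.imag).max() > 1e-8 * scale:
        raise AssertionError("inverse transform produced a non-negligible imaginary part")
    return GrayImage(out.real)


_FILL_STRATEGIES = ("mean", "zero")


def circular_window(img: GrayImage, fill: str = "mean") -> GrayImage:
    """Replace pixels outside the inscribed disc of a square image.

    Square ROIs produce cross-shaped leakage along the frequency axes
    (the sharp edges are horizontal/vertical steps); cutting the spatial
    ROI into a circle suppresses it. Pixels at Euclidean distance
    > N/2 from the image center ((N-1)/2, (N-1)/2) are replaced by the
    mean intensity inside the disc (``fill="mean"``, the default, which
    avoids reintroducing a step edge) or by zero (``fill="zero"``).
    """
    if fill not in _FILL_STRATEGIES:
        raise ValueError(f"unknown fill strategy {fill!r}; choose from {_FILL_STRATEGIES}")
    if img.height != img.width:
        raise ValueError("circular_window requires a square image")
    n = img.height
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    outside = np.hypot(xx - c, yy - c) > n / 2.0
    pixels = img.pixels.copy()
    fill_value = 0.0 if fill == "zero" else float(pixels[~outside].mean())
    pixels[outside] = fill_value
    return GrayImage(pixels, img.pixel_size_nm)


@dataclasses.dataclass(frozen=True)
class PlaneWaveFit:
    """Least-squares fit of ``offset + A*sin(wx*x + wy*y + phase)``."""

    omega_x: float
    omega_y: float
    amplitude: float
    phase: float
    offset: float
    residual_rms: float


def _plane_wave_residual(omega: np.ndarray, x: np.ndarray, y: np.ndarray, z: np.ndarray):
    """Variable-projection residual: amplitude/phase/offset solved linearly."""
    arg = omega[0] * x + omega[1] * y
    design = np.column_stack([np.sin(arg), np.cos(arg), np.ones_like(arg)])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    return design @ coef - z, coef


def fit_plane_wave(img: GrayImage) -> PlaneWaveFit:
    """Recover the angular frequency of a (near-)plane-wave image.

    The dominant non-DC spectral peak seeds the per-axis angular
    frequencies (radians per pixel); they are then refined by nonlinear
    least squares of the plane-wave model, with amplitude, phase and
    offset projected out linearly at each step. The peak in the upper
    half-plane (v > 0, or v == 0 and u > 0) is used so the reported
    frequencies have a consistent sign.
    """
    spec = forward_spectrum(img)
    n = spec.n
    mags = np.abs(spec.coeffs)
    u, v = centered_frequencies(n)
    half = (v > 0) | ((v == 0) & (u > 0))
    search = np.where(half, mags, 0.0)
    i, j = np.unravel_index(np.argmax(search), search.shape)
    omega0 = np.array([u[i, j], v[i, j]], dtype=float) * (2 * np.pi / n)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    x, y, z = xx.ravel(), yy.ravel(), img.pixels.ravel()
    result = least_squares(
        lambda w: _plane_wave_residual(w, x, y, z)[0],
        omega0,
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
    )
    res, coef = _plane_wave_residual(result.x, x, y, z)
    b_sin, b_cos, offset = coef
    amplitude = float(np.hypot(b_sin, b_cos))
    phase = float(np.arctan2(b_cos, b_sin))
    wx, wy = result.x
    if amplitude > 0 and (wx + wy) < 0:  # sign convention: point into +x/+y
        wx, wy, phase = -wx, -wy, np.pi - phase
    return PlaneWaveFit(
        omega_x=float(wx),
        omega_y=float(wy),
        amplitude=amplitude,
        phase=float(np.arctan2(np.sin(phase), np.cos(phase))),
        offset=float(offset),
        residual_rms=float(np.sqrt(np.mean(res**2))),
    )
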
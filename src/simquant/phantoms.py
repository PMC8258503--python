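"""Seeded synthetic phantoms with ground-truth degradation labels.

Clinical super-resolution micrographs of kidney sections are not generally
shareable, so every metric in this package is validated on synthetic
textures that emulate the structures being quantified:

* plane waves — the didactic sine images used to demonstrate which
  spectral region carries which periodicity;
* foot-process phantoms — periodic ridges mixed toward a smooth
  low-frequency field by an "effacement" parameter ``lambda``;
* rod fields — anti-aliased line segments with von Mises orientation
  dispersion, emulating tube-like vs fragmented mitochondria;
* membrane traces — 1-D lognormal intensity profiles with tunable
  irregularity.

Every generator is a pure function of its spec (including the seed): the
same spec always yields a bit-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .images import GrayImage
from .membrane import TraceProfile

__all__ = [
    "PlaneWaveSpec",
    "FootProcessPhantomSpec",
    "RodFieldSpec",
    "MembraneTraceSpec",
    "make_plane_wave",
    "make_foot_process_phantom",
    "make_rod_field",
    "make_membrane_trace",
    "make_ring_phantom",
]


@dataclasses.dataclass(frozen=True)
class PlaneWaveSpec:
    """z(x, y) = offset + amplitude * sin(omega_x*x + omega_y*y + phase)."""

    n: int = 128
    omega_x: float = 0.4
    omega_y: float = 0.4
    phase: float = 0.0
    offset: float = 1.0
    amplitude: float = 1.0


@dataclasses.dataclass(frozen=True)
class FootProcessPhantomSpec:
    """Periodic foot-process-like ridges degraded by effacement.

    ``effacement`` = 0 gives pure ridges of the given period; 1 gives a
    pure smooth low-frequency field; intermediate values mix linearly.
    The default 12-px stripe period places the ridge fundamental inside
    the (1/4, 1/16) concentric-square band at n = 128 (centered index
    ~10.7); users changing ``n`` should rescale the period accordingly.
    The default 45-degree orientation keeps the ridge spectrum off the
    frequency axes, where leakage from the image boundary concentrates.
    """

    n: int = 128
    stripe_period: float = 12.0
    orientation: float = np.pi / 4
    effacement: float = 0.0
    noise_sd: float = 0.02
    offset: float = 1.0
    amplitude: float = 0.4
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class RodFieldSpec:
    """Field of anti-aliased rods with von Mises orientation dispersion.

    ``orientation_kappa`` is the concentration of an axial (180-degree
    periodic) von Mises law: large kappa = aligned tube-like field, 0 =
    uniformly oriented. Short ``rod_length_mean`` with kappa = 0 emulates
    a fragmented (damaged) mitochondrial texture.
    """

    n: int = 128
    n_rods: int = 40
    rod_length_mean: float = 100.0
    rod_width: float = 2.0
    orientation_mode: float = 0.0
    orientation_kappa: float = 100.0
    background: float = 0.1
    rod_intensity: float = 1.0
    noise_sd: float = 0.01
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class MembraneTraceSpec:
    """1-D membrane intensity trace with lognormal irregularity.

    ``irregularity`` is the standard deviation of the smoothed zero-mean
    Gaussian field ``g``; the trace is ``base_intensity * exp(g)``, so it
    stays positive and its CV grows monotonically with the parameter
    (CV ~ irregularity for small values). ``irregularity = 0`` yields a
    constant trace with CV exactly 0.
    """

    length: int = 180
    base_intensity: float = 100.0
    irregularity: float = 0.1
    smoothing_scale: float = 3.0
    seed: int = 0


def make_plane_wave(spec: PlaneWaveSpec) -> GrayImage:
    """Evaluate a plane wave on the integer pixel grid (x = column)."""
    if spec.n < 8:
        raise ValueError("plane-wave phantom requires n >= 8")
    if abs(spec.omega_x) >= np.pi or abs(spec.omega_y) >= np.pi:
        raise ValueError(
            "angular frequency magnitude must be < pi rad/px (Nyquist); "
            f"got ({spec.omega_x}, {spec.omega_y})"
        )
    yy, xx = np.mgrid[0 : spec.n, 0 : spec.n]
    z = spec.offset + spec.amplitude * np.sin(
        spec.omega_x * xx + spec.omega_y * yy + spec.phase
    )
    return GrayImage(z)


def make_foot_process_phantom(spec: FootProcessPhantomSpec) -> GrayImage:
    """Ridges mixed toward a smooth field by the effacement parameter."""
    if not (0.0 <= spec.effacement <= 1.0):
        raise ValueError(f"effacement must lie in [0, 1], got {spec.effacement}")
    if spec.stripe_period <= 2:
        raise ValueError("stripe_period must exceed 2 px (Nyquist)")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    yy, xx = np.mgrid[0:n, 0:n]
    coord = np.cos(spec.orientation) * xx + np.sin(spec.orientation) * yy
    ridge = np.sin(2 * np.pi * coord / spec.stripe_period)

    # Smooth field: heavily low-passed white noise; after sigma = n/8
    # smoothing its spectrum is confined to centered indices <~ 2, i.e.
    # inside the inner square of the default band. Rescaled to the ridge's
    # RMS contrast so the mixture's total contrast is roughly constant.
    smooth = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8, mode="wrap")
    smooth = smooth / smooth.std() * ridge.std()

    lam = spec.effacement
    texture = (1 - lam) * ridge + lam * smooth
    z = spec.offset + spec.amplitude * texture
    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, size=z.shape)
    return GrayImage(np.clip(z, 0.0, None))


def _sample_axial_vonmises(rng: np.random.Generator, mode: float, kappa: float, size: int) -> np.ndarray:
    """Axial orientations: von Mises on the doubled-angle circle.

    Rods are undirected, so orientations live on a 180-degree circle;
    sampling 2*theta from a von Mises and halving respects that topology.
    kappa = 0 reduces to the uniform law on [0, pi).
    """
    doubled = rng.vonmises(0.0, kappa, size=size) if kappa > 0 else rng.uniform(-np.pi, np.pi, size=size)
    return mode + doubled / 2.0


def make_rod_field(spec: RodFieldSpec) -> GrayImage:
    """Render a seeded field of soft-edged rods.

    Each rod is an additive segment with a Gaussian cross-section of
    width ``rod_width`` and a hard cap at half its sampled length; rod
    lengths are normal around ``rod_length_mean`` (sd 20%, floor 1 px).
    """
    if spec.rod_length_mean < 1:
        raise ValueError("rod_length_mean must be >= 1 px")
    if spec.n < 8:
        raise ValueError("rod field requires n >= 8")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    z = np.full((n, n), float(spec.background))
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    if spec.n_rods > 0:
        centers = rng.uniform(0, n, size=(spec.n_rods, 2))
        angles = _sample_axial_vonmises(rng, spec.orientation_mode, spec.orientation_kappa, spec.n_rods)
        lengths = np.clip(
            rng.normal(spec.rod_length_mean, 0.2 * spec.rod_length_mean, spec.n_rods),
            1.0,
            None,
        )
        for (cx, cy), theta, length in zip(centers, angles, lengths):
            dx, dy = xx - cx, yy - cy
            t = dx * np.cos(theta) + dy * np.sin(theta)       # along the rod
            d = -dx * np.sin(theta) + dy * np.cos(theta)      # across the rod
            profile = np.exp(-0.5 * (d / spec.rod_width) ** 2)
            profile[np.abs(t) > length / 2.0] = 0.0
            z += spec.rod_intensity * profile
    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, size=z.shape)
    return GrayImage(np.clip(z, 0.0, None))


def make_membrane_trace(spec: MembraneTraceSpec) -> TraceProfile:
    """Positive 1-D trace ``base * exp(g)`` with smoothed Gaussian ``g``."""
    if spec.base_intensity <= 0:
        raise ValueError("base_intensity must be positive")
    if spec.irregularity < 0:
        raise ValueError("irregularity must be nonnegative")
    if spec.irregularity == 0:
        return TraceProfile(np.full(spec.length, float(spec.base_intensity)))
    rng = np.random.default_rng(spec.seed)
    g = gaussian_filter1d(rng.standard_normal(spec.length), spec.smoothing_scale, mode="wrap")
    g = (g - g.mean()) / g.std() * spec.irregularity
    return TraceProfile(spec.base_intensity * np.exp(g))


def make_ring_phantom(n: int = 128, period: float = 12.0, offset: float = 1.0, amplitude: float = 0.4) -> GrayImage:
    """Concentric-ring (isotropic) texture: equal power at every
    orientation, the rotation-symmetric control for anisotropy metrics."""
    if n < 8:
        raise ValueError("ring phantom requires n >= 8")
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - c, yy - c)
    z = offset + amplitude * np.sin(2 * np.pi * r / period)
    return GrayImage(np.clip(z, 0.0, None))
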
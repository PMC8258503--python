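import numpy as np
import pytest

from simquant import GrayImage, PlaneWaveSpec, make_plane_wave


@pytest.fixture(scope="session")
def wave_04() -> GrayImage:
    """The steep demonstration sine z = sin(0.4x + 0.4y), 128x128."""
    return make_plane_wave(PlaneWaveSpec(omega_x=0.4, omega_y=0.4, offset=0.0, amplitude=1.0))


@pytest.fixture(scope="session")
def wave_005() -> GrayImage:
    """The shallow demonstration sine z = sin(0.05x + 0.05y), 128x128."""
    return make_plane_wave(PlaneWaveSpec(omega_x=0.05, omega_y=0.05, offset=0.0, amplitude=1.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def naive_dft2(pixels: np.ndarray) -> np.ndarray:
    """O(N^4) direct DFT, centered layout — the independent oracle."""
    n = pixels.shape[0]
    idx = np.arange(n)
    freqs = idx - n // 2
    out = np.zeros((n, n), dtype=complex)
    for a, fv in enumerate(freqs):
        for b, fu in enumerate(freqs):
            phase = np.exp(-2j * np.pi * (np.outer(idx * fv, np.ones(n)) + np.outer(np.ones(n), idx * fu)) / n)
            out[a, b] = np.sum(pixels * phase)
    return out


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
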
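"""Which spectral region carries which periodicity?

Two 128x128 plane waves — a steep one (0.4 rad/px, mimicking fine periodic
foot processes) and a shallow one (0.05 rad/px, mimicking the coarse primary
process) — are transformed, band-filtered and reconstructed. The steep wave
lives inside the concentric-square annulus (side fractions 1/4 to 1/16); the
shallow wave lives in its complement. The plane-wave fitter then recovers
each printed frequency from the image alone.
"""

import numpy as np

from simquant import (
    FOOT_PROCESS_BAND,
    fit_plane_wave,
    forward_spectrum,
    make_plane_wave,
    reconstruct_from_band,
)
from simquant.phantoms import PlaneWaveSpec

for omega in (0.4, 0.05):
    img = make_plane_wave(PlaneWaveSpec(omega_x=omega, omega_y=omega))
    spec = forward_spectrum(img)
    in_band = reconstruct_from_band(spec, FOOT_PROCESS_BAND)
    out_band = reconstruct_from_band(spec, FOOT_PROCESS_BAND, complement=True)
    corr = lambda a: np.corrcoef(a.pixels.ravel(), img.pixels.ravel())[0, 1]
    fit = fit_plane_wave(img)
    print(f"wave omega = {omega:.2f} rad/px")
    print(f"  correlation with annulus reconstruction:    {corr(in_band):+.3f}")
    print(f"  correlation with complement reconstruction: {corr(out_band):+.3f}")
    print(f"  recovered frequency: omega_x = {fit.omega_x:.6f}, omega_y = {fit.omega_y:.6f}")

print(
    "\nA correlation near +1 marks the region that carries the wave's"
    "\nperiodicity; the fitted frequencies reproduce the generating values."
)
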
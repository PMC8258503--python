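"""Basement-membrane irregularity from a traced polyline.

A synthetic micrograph is built whose row 40 carries a membrane-like
stripe with a controlled intensity modulation; the stripe is traced with
a polyline, linearized into a 180-sample profile, and summarized by the
coefficient of variation. Generated 1-D trace phantoms at two
irregularity levels are compared the same way.
"""

import numpy as np

from simquant import GrayImage, PolylineROI, extract_trace, trace_cv
from simquant.phantoms import MembraneTraceSpec, make_membrane_trace

# build an image containing a horizontal membrane with 10% sinusoidal ripple
n = 200
yy, xx = np.mgrid[0:64, 0:n].astype(float)
membrane_profile = 100.0 * (1.0 + 0.1 * np.sin(2 * np.pi * xx / 9.0))
img = GrayImage(membrane_profile * np.exp(-0.5 * ((yy - 40.0) / 1.5) ** 2) + 1.0)

trace = extract_trace(img, PolylineROI([(5.0, 40.0), (190.0, 40.0)]))
stats = trace_cv(trace)
print(f"traced membrane: mean {stats.mean:.1f}, sd {stats.sd:.2f}, CV {stats.cv:.4f}")

for sigma in (0.05, 0.4):
    cvs = [
        trace_cv(make_membrane_trace(MembraneTraceSpec(irregularity=sigma, seed=s))).cv
        for s in range(10)
    ]
    print(f"trace phantom irregularity {sigma:.2f}: median CV {np.median(cvs):.3f}")

print("\nCV rises with the irregularity of the membrane signal; a smooth,")
print("evenly stained membrane has CV near the ripple amplitude alone.")
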
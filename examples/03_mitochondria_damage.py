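"""Mitochondrial damage index: tube-like vs fragmented rod fields.

Aligned long rods emulate healthy tubular mitochondria (anisotropic
texture, elongated spectral radar chart, low damage index); short
uniformly oriented rods emulate fragmented mitochondria (isotropic
texture, circular radar chart, damage index near 1). Ten phantoms per
condition are scored and the groups compared by Mann-Whitney U.
"""

import numpy as np

from simquant import damage_batch, mann_whitney
from simquant.phantoms import RodFieldSpec, make_rod_field

aligned = [make_rod_field(RodFieldSpec(orientation_kappa=100.0, seed=s)) for s in range(10)]
fragmented = [
    make_rod_field(RodFieldSpec(orientation_kappa=0.0, rod_length_mean=3.0, n_rods=300, seed=s))
    for s in range(10)
]

df = damage_batch(aligned + fragmented, subjects=["tubular"] * 10 + ["fragmented"] * 10)
rois = df[df["kind"] == "roi"]
a = rois[rois["subject"] == "tubular"]["damage_index"]
b = rois[rois["subject"] == "fragmented"]["damage_index"]
res = mann_whitney(b, a)

print(df[df["kind"] == "subject_mean"][["subject", "damage_index"]].to_string(index=False))
print(f"\nmedian damage index: tubular {a.median():.3f}, fragmented {b.median():.3f}")
print(f"Mann-Whitney U = {res.u_statistic:.0f}, two-sided p = {res.p_two_sided:.2e} ({res.method})")
print("\nA damage index near 1 means no preferred spectral direction —")
print("the fragmented texture; intact tube fields score well below 1.")
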
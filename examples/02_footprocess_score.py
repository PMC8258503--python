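"""Foot-process integrity score across an effacement series.

Phantom ROIs are generated with the effacement parameter lambda swept from
0 (crisp periodic ridges, healthy) to 0.9 (mostly smooth low-frequency
field, effaced). The band-power score — the fraction of spectral magnitude
inside the (1/4, 1/16) concentric-square annulus — should fall
monotonically as lambda grows.
"""

import numpy as np

from simquant import band_power_score, spearman_rho
from simquant.phantoms import FootProcessPhantomSpec, make_foot_process_phantom

lams = np.arange(0.0, 1.0, 0.1)
all_l, all_s = [], []
print("lambda   median score (10 seeds)")
for lam in lams:
    scores = [
        band_power_score(
            make_foot_process_phantom(FootProcessPhantomSpec(effacement=float(lam), seed=s))
        ).score_normalized
        for s in range(10)
    ]
    all_l += [float(lam)] * len(scores)
    all_s += scores
    print(f"  {lam:.1f}        {np.median(scores):.3f}")

rho = spearman_rho(all_l, all_s)
print(f"\nSpearman rho(lambda, score) = {rho:.3f}")
print("A strongly negative rank correlation: the score tracks the loss of")
print("foot-process periodicity, mirroring its clinical anticorrelation with proteinuria.")
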
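"""Analytic phase boundary between clan endogamy and dual organization.

Dual organization halves mating rivalry but pays a small cooperation
cost ~ d_c(1 - exp(-alpha mu^2))/2 from the mutation-scale misalignment
of mate clans, weighted by the sustenance probabilities p_C, p_D.  The
critical pressure ratio is d_m/d_c = 1 - exp(-alpha mu^2)
+ (2/d_c) log(p_C/p_D): a constant ratio for large d_c, a constant d_m
offset for small d_c.
"""

import numpy as np

from kinsim import AnalyticParams, boundary_curve, dual_beats_endogamy, threshold_ratio

ap = AnalyticParams(alpha=1.0, mu=0.1, p_C=0.9, p_D=0.7, d_c=1.0, d_m=0.5)
wins, endo, dual = dual_beats_endogamy(ap)
print(f"growth weights at d_c=1, d_m=0.5: endogamy {endo:.4f}, dual {dual:.4f}"
      f" -> dual favoured: {wins}")
print(f"critical d_m/d_c at d_c=1: {threshold_ratio(ap):.4f}")

curve = boundary_curve(ap, np.linspace(0.5, 50, 6))
print(curve.round(4).to_string(index=False))
print("ratio ->", 1 - np.exp(-ap.alpha * ap.mu**2),
      "as d_c grows (large-d_c asymptote)")
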
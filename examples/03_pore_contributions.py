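"""Which pores deliver the calcium that arrives at the far probe?

Pores are queued along the arc between the firing channel C (cytosolic
side, slow D=2) and the probe P_N (nucleosolic side, fast D=15).  Each
pore's pulses are accumulated at the probe up to the probe's peak time and
normalised, giving signed per-pore contribution fractions: pores near C
inject most of the calcium, while pores near the probe — where the inner
surface is transiently richer than the outer — take calcium back out and
show up negative.
"""

import numpy as np

import nefire as nf

res = nf.pore_contribution_decomposition(48, D_outer=2.0, D_inner=15.0)

print(f"probe peak at t = {res.t_peak:.2f} s; fractions sum to "
      f"{res.fractions.sum():.6f}; {int((res.fractions < 0).sum())} of "
      f"{len(res.fractions)} pores are net-negative\n")
print("distance from C (um)   contribution fraction")
for k in range(0, 48, 6):
    print(f"{res.distances_to_source[k]:20.2f}   {res.fractions[k]:+.4f}")
print(f"{'(nearest to probe)':>20}   {res.fractions[-1]:+.4f}")
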
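"""What a single channel firing can and cannot do, straight from the kernel.

No simulation here: the point-source kernel answers two questions in closed
form — how far a single release can trigger a neighbour (the propagation
condition), and how long a channel stays refractory while its own calcium
decays (the refractory period).
"""

import numpy as np

import nefire as nf

release = nf.ReleaseAmount(sigma_mol=2.0e-20)  # per-firing release
threshold = nf.FiringThreshold(c_th=0.0425, alpha=0.15)

print("surface      D      refractory tau_R   max trigger distance")
for side, D in (("inner", 5.0), ("outer", 20.0)):
    surface = nf.Surface(side, D=D, k_s=1.0)
    tau = nf.refractory_period(surface, release, threshold)
    # largest neighbour distance at which the kernel peak still reaches c_th
    reach = max(
        (dr for dr in np.arange(0.1, 15.0, 0.01)
         if nf.propagation_condition_closed_form(dr, surface, release, threshold)),
        default=0.0,
    )
    print(f"{side:>7} {D:>7.1f}   {tau:>12.2f} s   {reach:>13.2f} um")

# the numeric and closed-form peak agree to rounding error
surface = nf.Surface("outer", 20.0, 1.0)
ok, t_star, peak = nf.propagation_condition_numeric(3.0, surface, release, threshold)
closed = nf.propagation_peak_closed_form(3.0, surface, release)
print(f"\npeak at 3 um: numeric {peak:.6f} uM* at t*={t_star:.3f} s, "
      f"closed form {closed:.6f} uM*, can trigger: {ok}")
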
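"""Compose cerebellar, basal-ganglia and cortical gains into the total
subjective-time gain across interval durations.

Cerebellar weight dominates sub-second intervals, basal-ganglia weight
supra-second ones (crossover at 1 s by default), with a cortical bump at
intermediate timescales.  The comparator correction (strength g) pushes the
total gain back toward 1 when the cerebellar gain is veridical.
"""

from cdt import (
    ComparatorSpec,
    ComponentGains,
    crossover_duration,
    total_gain_multiplicative,
    weights_at,
)

print("tau (s)   w_cbl   w_bg    w_ctx")
for tau in (0.1, 0.5, 1.0, 2.0, 10.0):
    w = weights_at(tau)
    print(f"{tau:7.1f}  {w[0]:.3f}   {w[1]:.3f}   {w[2]:.3f}")
print(f"CBL/BG crossover: {crossover_duration():.6f} s")

# a dilated cortico-basal-ganglia state with a veridical cerebellum
gains = ComponentGains(kappa_cbl=1.0, kappa_bg=1.4, kappa_ctx=1.2)
w = weights_at(2.0)
for g in (0.0, 0.5, 1.0):
    k = total_gain_multiplicative(gains, w, ComparatorSpec(g=g))
    print(f"comparator g = {g:.1f}: total kappa = {k:.4f}")
print("g = 1 restores kappa = 1 exactly: the comparator fully corrects the "
      "cortico-striatal dilation.")
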
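"""Closed-form steady state: from kinetic constants to coupling strength.

Given the inter-cell diffusion rate D, efflux rate k_out and nonspecific
influx k_in, the steady-state tracer profile decays exponentially with
coupling distance; the decay constant lambda = sqrt(k_out/D) summarizes how
far tracer spreads, and S = exp(-lambda) is the fraction of probe-cell
tracer found in the directly coupled cells.
"""

import numpy as np

import couplekit as ck

params = ck.ModelParams(D=25.0, k_out=1.0, k_in=0.25, C_solution=40.0, C0=100.0)

print(f"background C_bg = {params.C_bg:.1f} a.u. "
      "(influx/efflux balance far from the probe)")
print(f"decay constant lambda = {params.lam:.3f} per hop")
print(f"coupling strength S = {ck.coupling_strength(params.lam):.3f} "
      "(fraction of probe tracer in shell 1)")

profile = ck.steady_state_profile(params, np.arange(7))
print("\nshell  concentration (a.u.)")
for x, c in zip(profile.x, profile.C):
    print(f"{int(x):5d}  {c:8.2f}")
print("\nEach shell holds exp(-lambda) of the previous shell's excess over "
      "background; by shell 6 the profile is nearly back at C_bg.")

# the exact discrete chain decays slightly differently per hop
r = ck.decay_ratio_discrete(params.k_out, params.D)
print(f"\nexact discrete shell ratio r = {r:.4f} "
      f"(continuum exp(-lambda) = {np.exp(-params.lam):.4f})")
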
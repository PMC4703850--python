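"""Estimate lambda and S from noisy per-cell intensity profiles.

Generates intensity tables the way the assay produces them (one probe cell
plus six cells per shell, 10% multiplicative noise), fits the normalized
exponential decay, and shows how pooling probes tightens the estimate.
"""

import numpy as np

import couplekit as ck

lam_true = 0.7
bundle = ck.generate_profile_table(ck.DEFAULT_PARAMS, lam_true,
                                   noise_cv=0.1, n_probes=10, seed=42)
print(f"true lambda = {lam_true}, true S = {bundle.S_true:.3f}, "
      f"background fraction b = {bundle.bg_frac}")

print("\nper-probe fits:")
fits = [ck.fit_decay(p) for p in bundle.profiles]
for p, f in zip(bundle.profiles, fits):
    print(f"  {p.probe_id}: lambda = {f.lam:.3f} +/- {f.se_lam:.3f}, "
          f"S = {f.S:.3f}, bg = {f.bg_frac:.3f}")

pooled = ck.fit_decay(ck.pool_profiles(bundle.profiles))
print(f"\npooled over 10 probes: lambda = {pooled.lam:.4f}, S = {pooled.S:.4f}")
print("Pooling shell observations across probes averages the noise before "
      "the fit; the pooled lambda sits much closer to truth than any single "
      "probe's.")
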
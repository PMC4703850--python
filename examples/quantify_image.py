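"""Measure coupling strength from a rendered two-channel scene.

Renders a synthetic mosaic (tracer channel, probe-marker channel, label
mask) with realistic microscope noise, then runs the image pipeline: find
probe cells, take each probe's six nearest cells as the directly coupled
set, and compute the background-adjusted neighbor ratio S.
"""

import math

import couplekit as ck

lam_true = 0.7
scene = ck.generate_scene(lam_true, noise=ck.NoiseSpec(seed=7))
print(f"scene: {scene.scene.tracer_channel.shape} px, "
      f"{scene.lattice.n_cells} cells, probes at {scene.probe_ids}")
print(f"ground truth: lambda = {lam_true}, S = {math.exp(-lam_true):.4f}\n")

for m in ck.quantify_scene(scene.scene):
    s = ck.neighbor_ratio_strength(m)
    flags = f"  [{';'.join(m.flags)}]" if m.flags else ""
    print(f"probe {m.probe_id}: I0 = {m.I0:6.1f}, mean(I1) = "
          f"{sum(m.I1) / len(m.I1):6.1f}, I_bg = {m.I_bg:5.1f} "
          f"-> S = {s.S:.4f}{flags}")

print("\nEach probe's S is the neighbor excess over background relative to "
      "the probe excess; values cluster tightly around exp(-lambda).")
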
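# couplekit

Quantify gap-junction (electrical) coupling strength from the spread of a
fluorescent tracer through a network of coupled cells.

In a dye-coupling assay, a sparse set of "probe" cells is loaded with a
gap-junction-permeable tracer (e.g. a fluorophore-coupled dipeptide imported
by a transporter expressed only in those cells). The tracer diffuses into
neighboring cells through gap junctions, leaks back out of every cell, and
enters all cells nonspecifically from the bath at a low rate. couplekit turns
the resulting fluorescence patterns into a calibrated measure of coupling
strength. It is written for experimentalists analyzing such assays (in cell
monolayers or in tissue such as the retinal horizontal-cell mosaic) and for
anyone validating the estimators on fully synthetic data.

## Model

Cells are indexed by coupling distance *x* (hops) from the probe cell.
Per-cell tracer concentration obeys

```
dC_i/dt = D Σ_{j∈nbr(i)} (C_j − C_i) − k_out C_i + k_in C_solution
```

with inter-cell diffusion rate *D*, efflux rate *k_out* and nonspecific
influx *k_in* from bath concentration *C_solution* (all rates per hour).
At steady state the profile is an exponential decay over a background:

```
C(x) = (C0 − C_bg) e^(−λx) + C_bg,   λ = √(k_out / D),   C_bg = k_in C_solution / k_out
```

The **coupling strength** `S = e^(−λ)` is the fraction of the probe cell's
tracer excess found in the directly coupled cells. couplekit estimates it
two ways:

* **profile fit** — nonlinear least squares of the normalized intensity
  `I(x)/I0 = (1 − b) e^(−λx) + b` with background fraction `b = I_bg/I0`;
* **neighbor ratio** — for mosaics, `S = (mean(I1) − I_bg) / (I0 − I_bg)`
  with `I1` the intensities of the probe's six nearest marker-positive cells.

The package also contains the time-dependent simulator (graph-Laplacian ODE
on arbitrary cell lattices, with Hill-type blocker attenuation of *D*), an
image-quantification pipeline (label-mask region measurement, probe
detection, six-nearest-neighbor search, background estimation), permutation
tests for group comparisons, and synthetic-data generators (jittered
hexagonal mosaics, noisy profile tables, rendered two-channel scenes,
experiment-design scenario suites) with full ground truth.

## Worked example

```python
import couplekit as ck

scene = ck.generate_scene(0.7, noise=ck.NoiseSpec(seed=7))   # truth: λ = 0.7
for m in ck.quantify_scene(scene.scene):
    print(m.probe_id, round(ck.neighbor_ratio_strength(m).S, 4))
```

prints

```
26 0.4972
32 0.4961
308 0.4964
372 0.4967
```

four probe cells whose measured coupling strength clusters tightly around
the ground truth `e^(−0.7) = 0.4966`: the pipeline recovers the generative
coupling strength from a rendered, noisy image to well under 1%. The
`examples/` directory has one short script per capability (closed-form
model, simulation to steady state, profile fitting, image quantification,
blocker dose response, light-window group comparison); each prints its
numbers with a line on what they mean. A thin CLI wraps the same functions:
`couplekit {simulate,fit,quantify,compare,synth} --help`.

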
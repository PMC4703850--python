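# Methods

## Model

Tracer transport is compartmental: each cell is one well-mixed compartment,
and cells are nodes of a lattice whose edges are gap-junctional contacts.
For cell *i* with neighbor set nbr(*i*),

    dC_i/dt = D Σ_{j∈nbr(i)} (C_j − C_i) − k_out·C_i + k_in·C_solution .

* **D** (per hour) — inter-cell exchange rate; the product of gap-junction
  permeability and contact geometry, in cell-index units. Position *x*
  counts coupling hops, never micrometers: the assay's readout is per-shell
  intensity, and shells are defined by hops.
* **k_out** (per hour) — first-order efflux (e.g. export by multidrug
  transporters).
* **k_in** (per hour) and **C_solution** (a.u.) — slow nonspecific entry
  from the bath, which sets the far-field background
  C_bg = k_in·C_solution/k_out.
* **Probe loading** — either a Dirichlet clamp at C0 (fixed-C0 mode, the
  default; all closed forms are conditioned on the measured probe
  intensity) or a constant uptake rate U (loading-rate mode, for studying
  the approach to steady state). Whether probe cells also lose tracer at
  k_out during loading is unresolved experimentally; fixed-C0 mode makes
  the question moot at steady state, and loading-rate mode includes the
  efflux term.

At steady state on a deep lattice, C(x) = (C0 − C_bg)e^(−λx) + C_bg with
λ = √(k_out/D), and the coupling strength S = e^(−λ) is the shell-to-shell
ratio of the excess over background. On a discrete 1D chain the exact
shell ratio is the root r ∈ (0, 1] of r² − (2 + k_out/D)r + 1 = 0;
−ln r → λ as k_out/D → 0. The continuum λ is the canonical definition
throughout; r is exposed (`decay_ratio_discrete`) as the exact oracle that
the simulator and the estimators are tested against. The distinction is
only visible at strong decay (at λ = 1, e^(−λ) = 0.368 vs r = 0.382).

## Simulation and steady state

The ODE system is linear and stiff for large D; integration uses BDF with
the analytic sparse Jacobian, rtol 1e−8 / atol 1e−10. The exact steady
state is also available as a direct sparse solve (`solve_steady_state`),
with probe rows replaced by Dirichlet identity rows in fixed-C0 mode.

Steady state is declared when the maximum per-cell relative change drops
below 1%/h (configurable). At the packaged retina defaults (below), a
tracer-free start converges at ≈ 3.5–4.8 h of simulated incubation,
consistent with assays where 4 h and 6 h profiles are indistinguishable.

Blockers act by attenuating D through a Hill curve
D′ = D/(1 + (dose/ic50)^hill), leaving k_out and k_in untouched — the
pharmacology targets the junctional channels, not general membrane
transport. Packaged parameters (MFA: ic50 5 µM, hill 3; CBX: ic50 1.25 µM,
hill 3) place "coupling nearly abolished" (S < 0.05) at 40 µM MFA and
10 µM CBX under the default kinetics.

## Estimators

**Profile fit.** Intensities are assumed proportional to concentration.
The fit is on shell means (mean intensity at each distinct x — matching
the one-value-per-shell structure of fitted-curve figures), normalized to
the probe intensity I0, with model (1 − b)e^(−λx) + b, bounds λ ≥ 0 and
0 ≤ b < 1. By default b is a free parameter (the background is estimated
as the fitted asymptote); it can instead be fixed from a measured I_bg.
Optimization is bounded least squares from starts λ ∈ {0, 0.1, 1, 3}
(parameter tolerance 1e−12); ties in RSS resolve to the smaller λ, which
pins the flat-profile degeneracy (a flat profile fits λ = 0 with any b,
and equally well with b → 1 and any λ) to the physically meaningful
answer S = 1. A profile that is flat *at the measured background*
(I0 ≈ I_bg) raises an unidentifiability error instead of returning a
number. Standard errors come from the Gauss–Newton covariance at the
optimum. Normalization makes the result invariant to intensity rescaling.

**Neighbor ratio.** For mosaic data, S = (mean(I1) − I_bg)/(I0 − I_bg)
over the six nearest marker-positive cells. Noise can push the ratio
outside [0, 1]; such values are clipped and flagged rather than discarded,
preserving sample size while enabling sensitivity checks.

**Group comparison.** A two-sided permutation test on the difference of
group means: exhaustively enumerated (exact) whenever the number of
relabelings fits within the permutation budget, Monte-Carlo with the
add-one correction otherwise. Chosen because it is assumption-free and
exact at the small group sizes typical of per-probe measurements.

## Image pipeline

The pipeline consumes a tracer channel, a probe-marker channel and an
integer label mask; segmentation is deliberately outside the critical path
(cells in the source assays are identified by immunostaining, and any
external segmenter's mask can be supplied; a threshold-plus-watershed
fallback exists for convenience only). Pixels are 0-based row-major;
centroids are area centroids in µm; distances are Euclidean in the image
plane.

Probe detection thresholds per-cell marker means with an exact
(sample-based) Otsu split — histogram-based Otsu fails here because a few
hundred near-identical background means collapse into one bin — guarded by
a sparsity requirement (< 20% of cells in the high class, probes being
sparse by design; a single-cell high class is always accepted). Background
is the median tracer intensity over non-cell pixels at least 2 px from any
cell region (dilation excludes bleed halos); a far-cells alternative
(mean over cells ≥ 4 typical spacings from every probe) is provided.
Probes whose six-neighbor sets overlap another probe's are flagged and
should be excluded from group statistics; probes encountered among the six
nearest cells are skipped, replaced by the next nearest, and flagged.

## Synthetic data

The generators emulate the study conditions end to end, and every
generator is a pure function of its spec including the seed.

* **Mosaic** — hexagonal grid of pitch 25 µm with Gaussian positional
  jitter (SD 5% of pitch), adjacency within 1.5× pitch, ~1% probe cells
  drawn from interior cells (full six-neighbor ring — in tissue the mosaic
  extends far beyond the imaged field, so a probe always has a complete
  coupled ring) and rejected within 4 hops of one another. Under jitter
  the realized nearest-neighbor distance sits ≈ 8% below the pitch: it is
  the minimum over six near-equal distances, an order-statistic effect.
* **Profile tables** — I(x) = [(1 − b)e^(−λx) + b]·I0·(1 + ε),
  ε ~ N(0, CV²) with CV 10% by default, one probe observation at x = 0 and
  six cells per shell for six shells; truncation at zero.
* **Scenes** — cells painted as filled disks (radius 0.35× spacing) on a
  diffuse pedestal at the model's C_bg (nonspecific tissue fluorescence,
  so the image-background estimate measures the same quantity the
  estimator subtracts), then Gaussian PSF blur (σ 0.75 µm), Poisson shot
  noise (50 photons per a.u.), Gaussian read noise (1 a.u.) and a constant
  camera offset (5 a.u.) at 0.5 µm/px. The label mask is exact pre-noise
  truth; overlapping disks resolve to the nearest centroid and are
  flagged.
* **Scenarios** — `blocker_sweep` (doses 0/5/10/20/40 µM MFA acting on D);
  `bright_vs_dim` (λ 1.2 vs 0.3 — light adaptation weakens horizontal-cell
  coupling); `window_intact` (both regions at λ 0.7: local illumination
  equalizes across an intact retina) and `window_cut` (IN 1.2, OUT 0.3:
  cutting isolates the adaptation). The window scenarios encode observed
  outcome patterns as generative truth; they do not model the retinal
  signaling that produces them. No quantitative λ is established for these
  conditions; 1.2/0.3/0.7 are illustrative defaults.

**Default kinetics** (D 25/h, k_out 1/h, k_in 0.25/h, C_solution 40 a.u.,
C0 100 a.u.): chosen so the background fraction is 0.1, baseline coupling
is strong (λ 0.2, S 0.82), and the approach to steady state lands near
ln(1/0.01)/k_out ≈ 4.6 h, in the 2–6 h window the assay design assumes.

What the generators do **not** emulate: photobleaching, z-stacks and
projection choices, blood-vessel and glial background structures, spectral
bleed-through, segmentation errors (masks are exact), and spatial
correlation of noise beyond the PSF. Passing tests therefore demonstrate
estimator correctness under the stated noise model, not robustness to
every artifact of real confocal data.

## Problem sizes and numerical choices

Validation runs use desk-scale problems: 130-cell chains (checking the
first 60 cells, where a reflecting far boundary has no influence — the
infinite-chain oracle is only valid away from the chain end, where the
no-flux boundary doubles the tail excess), a 900-cell regular hex mosaic
with a central probe for geometry checks, 21 rendered ~400-cell scenes for
the end-to-end study, 500 replicates of 30 pooled probes for the bias
study, and 9999 permutations (or exhaustive enumeration) for p-values.

## Known limitations

* λ and S are per hop; converting to physical distance requires the mosaic
  geometry and is deliberately out of scope, as is separating k_out from D
  (the steady-state estimator identifies only their ratio).
* On 2D lattices the steady state is not exactly exponential in hop count
  (the discrete analog of a Bessel-function decay): the neighbor ratio and
  the profile fit agree within 5% for λ ≳ 0.3 but diverge (~9% at λ = 0.2)
  for weaker decay. The 1D chain does not have this issue.
* The hex cross-estimator and scene studies use a single central-probe or
  sparse-probe geometry; heavily overlapping probe neighborhoods are
  flagged, not corrected.
* The blocker Hill parameters are calibration targets, not measured
  pharmacology; only the monotone dose–response structure is meaningful.
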
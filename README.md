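# ribofret

Analysis toolkit for three-color single-molecule FRET studies of ribosomal
5′ domain assembly, together with the SHAPE footprinting normalization and
the dynamical-network trajectory reanalysis that accompany such studies.

## The scientific problem

During 30S ribosome biogenesis the 16S 5′ domain binds the primary assembly
proteins S4, S17 and S20 before the secondary protein S16 can join. In
three-color smFRET experiments the RNA helix h3 is labeled with Cy7, protein
S4 with Cy5, and the incoming protein (S16, S17 or S20) with Cy3; alternating
532/633 nm excitation (50 ms per frame) probes all three pairwise distances.
The h3 helix exchanges between a **docked** conformation (high Cy5→Cy7 FRET,
*E* ≈ 0.61) and a **flipped** intermediate (low FRET), and protein binding
shifts this equilibrium. This package provides, as tested reusable code:

- **`simulate`** — generators for every input the pipeline consumes:
  fluorescence traces with two-state Markov kinetics, binding/unbinding,
  photobleaching, leakage, detection efficiencies and shot noise; SHAPE
  peak-area tables with planted protections; node trajectories with a
  planted correlation structure. All seed-deterministic, with ground truth.
- **`fret`** — background/leakage/detection corrections and a closed-form
  photon-conservation model for the three pairwise efficiencies:
  under donor excitation `F3 = N(1−E35−E37)`, `F5 = N·E35(1−E57)`,
  `F7 = N(E37 + E35·E57)` with `N = F3+F5+F7`; under red excitation
  `E57 = F7/(F7 + γ57·F5)`.
- **`selection`** — 1:1:1 stoichiometry filtering via single-step
  photobleach detection (binary-segmentation changepoints), site-specific
  binding filters, two-state threshold idealization (*E* < 0.35 → flipped),
  and least-squares double-Gaussian fits of pooled FRET histograms.
- **`kinetics`** — binding-moment detection from the total intensity rise
  (three-frame smoothing, iterated midpoint threshold), bound-lifetime
  estimation, post-synchronized FRET population maps, low-FRET time courses,
  and the τ_pre/τ_post dwell analysis of the state occupied at binding.
- **`shape`** — SHAPE reactivity normalization (background subtraction,
  scaling so the 92–97 percentile band averages 100, a 2.5 reactivity
  floor) and classification of ±protein log₁₀ reactivity ratios into
  protection categories.
- **`network`** — dynamical networks from coarse-grained trajectories:
  contact edges (< 4.5 Å for > 75% of frames), generalized (Gaussian
  mutual-information) correlations *C*ᵢⱼ ∈ [0,1], edge weights
  *d* = −log|*C*ᵢⱼ|, closeness centers, shortest paths, center-of-mass
  distances and between-condition correlation changes.

Packaged fixture schemes (`fig1_s4`, `fig3_s20_20nM`, `fig3_no_s20`,
`fig4`) encode the observed study conditions — state efficiencies
0.61/0.33, bound lifetimes of 15 s (with S20) and 3 s (without), and the
post-binding docked-lifetime increase of 1.5× with flipped-lifetime halving.

## Worked example

```python
from ribofret import workflows

fit, e = workflows.pooled_histogram_fit("fig1_s4", min_frames=5000, seed=2)
print(f"mu_low = {fit.mu_low:.3f}  mu_high = {fit.mu_high:.3f}  frac_low = {fit.frac_low:.3f}")

mean, sem, n = workflows.binding_lifetime("fig3_s20_20nM", 300, seed=11)
print(f"bound lifetime (+S20): {mean:.1f} +/- {sem:.1f} s  (n = {n})")

res = workflows.postsync_experiment(n_traces=800, seed=1)
d = res["docked"]
print(f"docked dwell: tau_pre = {d['mean_pre_s']:.2f} s, tau_post = {d['mean_post_s']:.2f} s")
```

prints

```
mu_low = 0.332  mu_high = 0.611  frac_low = 0.412
bound lifetime (+S20): 14.6 +/- 0.9 s  (n = 297)
docked dwell: tau_pre = 4.82 s, tau_post = 7.06 s
```

The double-Gaussian fit recovers the planted docked/flipped efficiencies
(0.61/0.33) and their populations; the detected binding events average to
the 15 s bound lifetime planted for the S20-containing complexes; and after
the binding moment the docked dwell is ~50% longer than before it,
quantifying how protein binding stabilizes the native conformation.

A `ribofret` command-line interface exposes the same pipeline
(`ribofret simulate / select / histogram / binding / sync / dwell / shape /
network`); see `ribofret --help`.

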
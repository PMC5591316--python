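# Methods

This note records the models, estimators and numerical choices behind
`ribofret`, and what the synthetic-data tests do and do not demonstrate.

## Three-color efficiency model

All efficiencies derive from a photon-conservation forward model.  One
donor (Cy3) excitation produces `N` absorbed photons that exit through
three channels with pairwise efficiencies `E35`, `E37` (direct transfer)
and `E57` (acceptor-to-acceptor cascade):

```
F3 = N (1 − E35 − E37)
F5 = N · E35 (1 − E57)
F7 = N (E37 + E35 · E57)
```

so `N = F3 + F5 + F7` is conserved across conformational states.  The model
inverts in closed form (`E35 = F5/((1−E57)N)`, `E37 = F7/N − E35·E57`) and
round-trips to machine precision over the full grid of physical
efficiencies, which the tests assert.  Red excitation probes the
acceptor pair directly: `E57 = F7/(F7 + γ57 F5)`.

Instrument effects are applied in a fixed order and undone in the same
order: background subtraction → inverse spectral leakage (a 3×3 mixing
matrix) → Cy7 detection rescaling (Cy7 is detected less efficiently;
default relative factor 0.6).  Efficiencies are reported unclipped with
validity flags; frames with non-positive denominators or `E57 ≈ 1`
(indeterminate cascade) are flagged, never truncated, so the noise
structure survives into histogram fitting.  Histograms span [−0.2, 1.2]
with 40 bins by default, clipping outliers into edge bins so the total
count is conserved.

## Trace simulation

Conformational exchange is a two-state continuous-time Markov chain
(docked/flipped) sampled exactly by competing exponential clocks and
discretized at frame midpoints (50 ms frames; even frames green, odd red).
Protein binding is a pseudo-first-order clock (optionally state-dependent,
and gated by an injection dead time `t_inject`, as in a flow experiment);
binding switches the exchange rates from `rates_pre` to `rates_post`,
unbinding switches them back.  Photobleaching is one irreversible
exponential step per dye — matching the single-step selection criterion —
with the Cy3 clock starting at its first appearance.  Expected counts pass
through per-dye detection factors, the leakage matrix and additive
background; noise is Poisson by default (photon statistics; a Gaussian
option exists for speed).  The full provenance from parameters to data is
kept in a `GroundTruth` record (state segments, binding/bleach times), used
only by tests — every estimator runs blind.

### Fixture schemes

The packaged fixtures encode *observed* quantities of the assembly system,
not microscopic constants (which are unpublished):

| fixture | encodes | key values |
|---|---|---|
| `fig1_s4` | equilibrium S4-only complex | E states 0.61/0.33, ~40% flipped |
| `fig3_s20_20nM` | S16 injection, +S20 | mean bound dwell 15 s |
| `fig3_no_s20` | S16 injection, −S20 | mean bound dwell 3 s |
| `fig4` | post-synchronized S16 binding | docked dwell ×1.5, flipped ×0.5 after binding |

Free choices, made once: exchange rates give second-scale dwells (docked
5 s, flipped 3.3 s before binding in `fig4`), long relative to the 0.1 s
frame pair, consistent with the visibly resolvable transitions in this kind
of data; brightness 200–1000 photons/frame so the two states are separated
by many noise SDs; background 20 counts/channel; leakage of a few percent
into redder channels.  `fig4` sets dissociation slow (k_off = 0.002 s⁻¹)
because observed bound lifetimes are bleach-limited underestimates and the
pre/post dwell contrast requires the post-binding rates to persist over the
dwell being measured; its S20-containing complexes use the upshifted
low-FRET value 0.27.

## Estimators

**Step detection** is recursive binary segmentation minimizing the
piecewise-constant least-squares cost; steps below `sensitivity` (default
3) × the robust noise SD (median absolute successive difference scaled to
SD) are suppressed, and the reported frame is the first frame after the
change.  Under a 15:1 step-to-noise ratio it localizes steps within ±2
frames in >95% of trials.

**Stoichiometry filtering** demands, per dye, one terminal down-step to
background and at most one arrival up-step.  Dye presence uses: ch3 under
green excitation (Cy3), the total red signal (Cy5 — nearly
state-invariant), and ch7 under red excitation (Cy7).  Only the Cy3 channel
additionally counts intermediate plateau steps (its direct-excitation
intensity is stoichiometry-proportional; the acceptor channels fluctuate
with the FRET state and are judged on presence only).

**Binding detection** smooths the total green-excitation intensity with a
centered three-frame moving average, seeds a changepoint at the largest
up-step, sets the threshold midway between the mean levels of the flanking
segments (the unbound baseline and the bound plateau — not the whole
remainder of the trace, which may contain the post-dissociation baseline),
and iterates threshold/first-crossing to a fixed point (≤10 rounds).  The
result is invariant to constant offsets.  Bound intervals are the
above-threshold runs; runs shorter than 3 frame pairs are discarded as
nonproductive spikes.  An interval reaching the record end is censored; the
default lifetime estimator averages *all* detected dwells (censored ones at
their observed length), which systematically underestimates long lifetimes —
the uncensored-only estimator is available.

**Idealization** thresholds `E57` at 0.35 (flipped below), with runs
shorter than `min_dwell_frames` merged into the flanking state (shortest
run first).  The default `min_dwell_frames = 2` suppresses shot-noise
chatter in generic use.  The τ_pre/τ_post workflow uses
`min_dwell_frames = 1`: at fixture SNR the states are >4 noise SDs apart so
chatter is negligible, while merging would blank genuine short excursions
and inflate the dwells of the flanking state (a bias the planted-truth
fixtures expose directly).

**Double-Gaussian fits** run on binned counts (lmfit least squares),
initialized at the two most separated local maxima (quartile fallback).
Components are ordered by mean; `frac_low` is the low component's area
share.  If the fitted means are closer than the larger sigma the two
components are unresolved and the fit collapses to a single Gaussian,
reported with `collapsed=True` — this makes the degenerate single-population
case well-defined instead of an arbitrary area split.

**τ_pre/τ_post**: for the state occupied at the detected binding moment,
τ_pre is the time since entering it and τ_post the time until leaving it.
Record-truncated dwells are flagged and excluded from means.  With
time-homogeneous kinetics the straddling dwell is length-biased: τ_pre and
τ_post each average one full mean dwell (memorylessness), so their sum is
~2× it — the null-fixture test checks exactly this inspection-paradox
identity.  Residual estimator biases at the defaults are ≲2%: sub-frame
excursions are invisible (slightly lengthening flanking dwells) and the
detected binding frame lags the true one by ~half a frame pair.

## SHAPE normalization

Per condition: net = modified − background lane (negatives to 0); scale so
the mean of the 92–97 percentile band equals 100 (percentile rank by sorted
position on a 0–100 scale, band inclusive; ordinal ranking keeps the band
populated under ties, whose equal values leave the band mean unchanged);
floor reactivities strictly below 2.5 at 2.5 (guaranteeing finite log
ratios).  The ±protein classification uses fixed log₁₀-ratio bins —
strong protection [−1.5, −1], moderate (−1, −0.5], moderate exposure
[0.5, 1], otherwise unchanged; values beyond the outer edges are clamped to
the nearest class and flagged.  Fixed bins are used rather than an
unsupervised clustering because the categories are defined by these ranges.
The synthetic generator plants log ratios on the *net* signal above an
independently drawn background (as background subtraction assumes) and
places planted nucleotides well above the reactivity floor, since log
ratios are only quantifiable where the unprotected signal clears the
baseline — true of real footprinting data as well.

## Dynamical networks

Nodes are coarse-grained centers (amino acid, nucleobase, sugar) with
masses; contacts use node-position distances (the inputs are node
trajectories; a heavy-atom mode would require full coordinates).  An edge
requires distance < 4.5 Å in strictly more than 75% of frames.  The
generalized correlation is the Gaussian mutual-information form: from the
6×6 joint covariance of two 3D displacement vectors,
`MI = ½ ln(det Σᵢᵢ det Σⱼⱼ / det Σ)` and `C = sqrt(1 − exp(−2·MI/3))`,
which maps to [0,1] and equals the per-coordinate correlation for the
generator's planted Gaussian motions (a |Pearson| fallback is available;
the estimator used is recorded in the output).  Edge weights are
`d = −log|C|` (natural log — the base uniformly rescales weights and cannot
change shortest paths); `C = 0` gives an infinite weight and the edge is
excluded from path computations.  Central nodes minimize the sum of
shortest-path distances over the queried subset (closeness; ties to the
lowest id), and shortest paths use Dijkstra with lexicographic tie-breaking,
validated against brute-force enumeration on small graphs.

## What the synthetic data does and does not show

The generators emulate the statistical structure the estimators rely on:
Markovian two-state exchange, exponential binding/bleaching, Poisson
counts, linear spectral mixing, log-normal peak areas, Gaussian node
motions.  They omit dye blinking and triplet states, FRET-dependent
photobleaching, diffusion/flow artifacts during injection, baseline drift,
electropherogram alignment errors, and anharmonic/multi-well trajectory
dynamics.  Passing tests therefore demonstrate correctness of the
measurement pipeline under the stated model and calibrated recovery of
planted parameters — not robustness to every artifact of real microscope or
capillary data.

## Problem sizes

Test and reproduction runs use: 300 traces per lifetime condition (the
event count the dwell tolerance of 2 s.e. is defined on), 800–12000 traces
for the post-synchronized analysis (the percent-change estimator has
~1/√n·140% relative spread per event), ≥5000 pooled frames for histogram
fits, 10⁴ frames for correlation recovery, and 200 random ≤8-node graphs
for the path oracle.
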
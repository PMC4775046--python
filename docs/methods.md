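# Methods

This note records the models implemented in `rvimap`, their
assumptions, the numerical choices, and what the desk-scale test
scenarios do and do not demonstrate.

## Cell model

Membrane dynamics are the ten Tusscher–Panfilov 2006 human ventricular
model, epicardial parameter set (the transmural subtype is a
configuration option; endo and M variants change the transient-outward
gating and the default g_Ks/g_to). Integration uses Rush–Larsen updates
for the eleven voltage-dependent gates, forward Euler for the calcium
subsystem, Na⁺/K⁺ concentrations and the membrane potential, with
dt = 0.02 ms for single-cell work (halving dt changes the measured APD
by < 1 ms; the convergence test is in the suite).

Two performance devices, both verified not to move APD or CV beyond
0.1%-level effects:

- every voltage-dependent rate and current coefficient is pre-tabulated
  on a 0.05 mV grid and linearly interpolated, with each grid row
  holding all 28 coefficients so one lookup touches two contiguous rows;
- the four Nernst reversal potentials are recomputed from the
  concentrations once per millisecond rather than every step (they
  drift on the scale of beats), and the Ca²⁺-subspace gate's
  exponential relaxation factor uses its second-order expansion
  (dt/τ ≤ 0.025).

### Regional parameter sets

The package's baseline "normal myocardium" cell sets g_Ks = 0.75 nS/pF
absolute (replacing the model default), the value that yields an APD of
roughly 250 ms under the package's pacing convention; this is also the
proximal half of the 2D sheet. The distal half uses g_Ks = 0.2 nS/pF
(≈ 300 ms). Border zone scales the baseline's g_Kr to 20%, g_Ks to 30%
and g_Na to 38% (≈ 330 ms APD) — the electrical remodelling that gives
infarct border zones their long refractoriness. SCAR and LESION carry
no cell model at all.

### Pacing convention

APDs are measured on the final beat after 10 pre-pacing beats at a
cycle length of **500 ms**, as the interval between the upward −20 mV
crossing (activation) and the subsequent downward −70 mV crossing
(repolarisation, ≈ 90% repolarised), linearly interpolated between
samples. The 500 ms S1 cycle length is the package's pacing convention
throughout (it reproduces the 250/300/330 ms regional APD triple that
defines the study conditions; at 600 ms the distal and border-zone
variants run 15–25 ms longer). The S1 train in tissue is 2 beats by
default in the test scenarios: tissue is initialised from each region's
single-cell paced limit cycle, so the propagated beat converges within
two cycles. Stimuli are 2 ms, 52 pA/pF transmembrane current (about
twice diastolic threshold).

## Tissue model

Monodomain reaction–diffusion on structured grids:

    dV/dt = div(D grad V) − I_ion,   D = sigma / (beta * Cm)

with isotropic conductivity σ, surface-to-volume ratio β = 1400 cm⁻¹
and Cm = 1 µF/cm² (σ = 0.1 S/m gives D = 0.0714 mm²/ms and a plane-wave
CV of 0.45 m/s at 200 µm spacing). Spatial discretisation is the
5-point (2D) / 7-point (3D) finite-difference Laplacian with
harmonic-mean face diffusivities, pre-computed per face; no-flux
boundaries. SCAR and LESION nodes have D = 0 and are skipped by the
ionic update, so they act as internal no-flux boundaries. Operator
splitting per step: diffusion update, then the pointwise ionic update.
The solver refuses to run when the explicit-diffusion CFL bound is
violated, and aborts with the failing time on numerical blow-up
(|V| > 200 mV).

Region conductivities: the sheet uses σ = 0.1 S/m; the cuboid scenarios
use σ = 0.05 S/m — slower conduction that keeps the reentrant pathway's
timing inside the small domain — exposed as a configuration field.
Border zone gets σ × 0.55² so that its
CV is 55% of healthy CV (CV ∝ √σ; the calibration is verified in the
suite on a fine strip), reproducing the prescribed 45% CV reduction
that stands in for tortuous zig-zag conduction.

Time step: dt = 0.05 ms default; the heavy sweep scenarios use
dt = 0.1 ms, which changes CV by +1.3% and APD by −0.8% relative to
dt = 0.02 ms — immaterial for the induction and localisation phenomena
studied. Spatial steps: 200 µm for 2D (the reference discretisation),
312.5–500 µm for the 3D cuboid (see "Problem sizes").

### Markers and events

The solver streams threshold-crossing events (first/subsequent upward
−20 mV crossings, downward −70 mV crossings, linearly interpolated
within the step) into fixed-capacity per-node buffers instead of
storing V histories; decimated snapshots are available for small runs
and the two extraction paths agree to 10⁻⁹ ms on identical runs. The S2
marker map takes each node's *first* activation at/after the S2
stimulus and the first repolarisation after that activation;
re-activations during reentry are deliberately excluded (the map
describes the premature beat). Sites never activated by S2 are invalid
and excluded downstream; a site with activation but no repolarisation
in the record keeps its AT and may donate it to RVI pairs but never
provides an RT.

### Outcome classification

An S1S2 episode is classified from the post-S2 activation events:

- **UDB_REENTRY** — at least `min_reentry_nodes` (5) conducting nodes
  activate a second time without further stimulation. Successive
  crossings closer than a 60 ms dead time are merged first: cardiac
  tissue is absolutely refractory on that scale, so faster
  double-crossings are electrotonic notches near a block line, not
  re-excitation (without the dead time, such notches at the cuboid's
  isthmus mouth masquerade as reentry).
- **BDB** — no re-activation, but some adjacent conducting node pair
  either differs in S2 activation time by more than `block_jump_ms`
  (25 ms; an order of magnitude above any physiological neighbour
  delay at these spacings) or has exactly one member never activated:
  a line-of-block segment existed and the episode died out.
- **NO_BLOCK** — every node activated exactly once with no such pair.
- **UNDETERMINED** — no capture, or activity still ongoing within
  30 ms of the end of the record.

The thresholds are configuration (`OutcomeConfig`); the defaults were
set from the phenomenology of the 2D scenarios, where no-block cases
show < 8 ms neighbour jumps and block cases > 38 ms.

## RVI computation

For every valid site *i* with a repolarisation time, all sites *j*
with AT_j strictly greater than AT_i and |x_j − x_i| ≤ r_s (exact
Euclidean metric; simultaneous activations contribute nothing) add
RT_i − AT_j at the pair midpoint. Midpoints are accumulated on a
regular lattice — spacing equal to the marker-site pitch unless
overridden — and each bin reports the mean of its contributions; empty
bins are masked, and bin centres sit at half-offsets so a lone
neighbouring-site pair's bin is centred on the pair midpoint. Surface
mode restricts both *i* and *j* to the declared recording surface
(z = 0 for the built-in geometries), volume mode uses all sites.
Neighbour search uses a k-d tree with chunked enumeration; equality
with the O(n²) all-pairs implementation is oracle-tested.

Summary statistics: RVI_min (minimum bin mean) and RVI_%<50ms
(percentage of unmasked bins below 50 ms). Electrode subsampling keeps
the site nearest each node of a regular lattice of the requested pitch
(no interpolation). Ablation targets are connected components
(26-connectivity on the bin lattice) of bins below 25 ms.

Two structural properties, both tested: adding a constant to every AT
and RT leaves the map unchanged (time-origin invariance), and adding a
constant to every RT shifts every bin by exactly that constant — the
RVI is a relative metric, which is why moving the RT threshold from
−70 to −60 mV (a near-uniform shift, see below) does not change which
region is flagged.

## Scar generation and geometry

The 2D sheet is a square grid (default 5 × 5 cm at 200 µm; the test
scenarios use the half-scale 2.5 cm sheet at the same spacing), upper
half proximal, lower half distal. The cuboid (2 × 2 × 1 cm) contains
two ellipsoidal necrotic regions with semi-axes 4 × 2 × 2.5 mm and
centres 7 mm apart along y, leaving a 3 mm conducting isthmus labelled
border zone (the corridor between the inner-facing ellipsoid surfaces,
clipped to their x–z elliptical cross-section). A depth parameter
translates both centres along +z; at depth 0 the upper ellipsoid halves
are clipped by the recording surface, and from 3.0 mm the scar is
wholly intramural. Membership is tested at node centres — at 200–500 µm
spacing, boundary aliasing is negligible against 4–8 mm features.

Synthetic scar anatomies on arbitrary meshes follow the seed-point
recipe: draw n seed points uniformly from a candidate region (a single
recorded integer seed makes every anatomy reproducible), compute each
node's minimal geodesic distance *d* to any seed by Dijkstra on the
element-edge graph with Euclidean edge lengths, then label scar where
d < 5000 µm and border zone where 5000 ≤ d < 7000 µm. Geodesic (not
Euclidean) distance is used since the algorithm is defined on a mesh.

## Ablation

Lesions are insulating spheres (default radius 3.5 mm, the middle of
the clinical 3–4 mm range) grown from the surface projection of target
centroids, relabelling all conducting tissue inside; scar is untouched
and overlaps union. In a wall thicker than the radius a sphere is not
transmural, so a full-wall cylindrical shape is available — lesion
geometry is known to matter for success and is deliberately
configurable. When one low-RVI region exceeds a lesion footprint, a
greedy cover places each next lesion at the bin covering the most
still-uncovered target bins. Re-induction repeats the identical S1S2
protocol on the ablated model; prevention means the outcome is no
longer UDB_REENTRY.

## Analytic line-of-block fields

`rvimap.synthetic` builds S2-like marker maps with no PDE solve: AT is
the geodesic travel time from a pacing origin on an 8-neighbour
sampling lattice whose edges cannot cross a horizontal block segment,
distal edges are slowed by a factor (default 5) standing in for
premature-wave conduction into barely-recovered tissue, and
RT = AT + region APD. `arrhythmogenic_scenario` couples the block
length to the excess of the distal APD over the coupling interval
(0.8 mm per ms) — the fixture's encoding of how a larger APD gradient
lengthens the line of block. What the fixture does *not* emulate:
restitution, electrotonic smoothing of repolarisation, and wavefront
curvature; those behaviours are exercised only by the monodomain runs.
Its purpose is to make the RVI pipeline testable in milliseconds with
closed-form-checkable geodesics (the suite cross-checks against an
independent graph implementation).

## Problem sizes and desk-scale choices

The shipped test scenarios are sized for a single CPU core:

- 2D induction sweeps: half-scale 2.5 cm sheet at 200 µm (126² nodes),
  2 S1 at 500 ms + S2, dt 0.1 ms, ~30 s per episode. On this sheet at
  CI 300 ms the bi-directional-block → reentry transition sits at a
  distal APD of 309 ms (bracketed at 2 ms resolution), with BDB at
  307 ms; along the CI axis at the default distal cell the ordering
  no-block (≥ 312 ms) → BDB (311 ms) → reentry (≤ 310 ms) appears, the
  BDB window being only ~1–2 ms wide at this scale (the detour around
  a half-length block line is short, so once substantial block forms,
  the proximal side has usually recovered by wavefront return).
- 3D cuboid: 500 µm spacing (41 × 41 × 21) for the scar-depth series
  and 312.5 µm (65 × 65 × 33) for the induction/ablation pair, where
  the premature wave must block at the isthmus mouth, wait out the
  border zone's recovery at the far end, and break back into proximal
  tissue — a source–sink-limited event that needs the finer grid and a
  280 ms coupling interval at these parameters.

## Known limitations

- **Wholly intramural scars.** For cuboid scar depths ≥ 3.0 mm the
  surface RVI map at the affordable grids shows only a ~23 ms
  activation drag and single-digit APD modulation above the scar —
  not enough to push any surface bin below 50 ms. The mechanism that
  produces a strong surface signature (functional block of the thin
  healthy layer over the scar through source–sink loading by the
  refractory isthmus beneath) is resolution-sensitive and does not
  switch on at 312.5–500 µm; the corresponding depth-series assertions
  fail at those depths and are left failing rather than weakened.
- **Search-radius dependence of RVI_min.** On the desk-scale maps the
  map minimum is V-shaped in r_s: growing the radius from 2.5 to 5 mm
  first admits deeper-detour cross-block pairs (lowering the minimum)
  and only beyond ~5 mm does bin dilution raise it monotonically. A
  monotone rise over the whole 2.5–25 mm range would require the
  cross-block pairs to dominate the smallest-radius bins already,
  which needs a longer line of block than these scaled scenarios
  produce. RVI_%<50ms grows monotonically with r_s in all scenarios.
- Structured grids only for the solver (the scar generator also
  handles unstructured meshes); isotropic conductivity, no fibre
  architecture, monodomain only.
- The outcome classifier is rule-based on activation events; exotic
  episodes (e.g. sustained micro-reentry confined to a few nodes)
  are guarded against by the node-count floor but not analysed
  further.
- Reentry in the cuboid at this scale is a single re-excitation loop
  confined mostly to the isthmus/border zone rather than a long-lived
  macroscopic circuit; the classifier treats any genuine repeated
  activation as reentry, which is the property the ablation loop
  tests.
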
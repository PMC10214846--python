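# Methods

This note records the models behind `organostack`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Working fluids and environment

All internal computation is in SI; interfaces that face the bench accept
mm, µl and µl/h.  Defaults, all configurable through `Liquid` and
`Environment`:

| quantity | default | note |
|---|---|---|
| gravity *g* | 9.81 m/s² | standard value |
| FC40 density | 1855 kg/m³ | ≈1.86× water; FC40 is only ever quoted as "~1.8× denser", so the exact value is a configurable choice |
| medium density | 998 kg/m³ | DMEM + 10% FBS at 25 °C; 1000 is equally defensible and supported |
| medium viscosity | 0.89 mPa·s | water-like |
| interfacial tension γ (medium:FC40) | 23 mN/m | measured value for DMEM + 10% FBS under FC40 |
| dish height | 13 mm | maximum FC40 fill of a 60 mm dish |

## Pressure balances and the flow-direction criterion

Caps are ideal spherical caps pinned at the opening's inner edge;
contact-angle hysteresis is ignored.  For a pinned cap the geometry is
fully determined by base radius *a* and height *h*: `R = (a²+h²)/2h`,
`θ = 2·atan(h/a)`, `V = πh(3a²+h²)/6`.  Cap heights above the opening
diameter are rejected (such a cap would have detached).

The head-difference term uses Δρ = ρ_FC40 − ρ_medium by default: for
stacks fully submerged in FC40, raising the medium column by d*h* replaces
dense FC40 with lighter medium, so the effective driving density is the
difference.  Published balance curves for such systems are sometimes drawn
with the bare medium density instead; `flow_direction` and
`boundary_delta_h` accept either convention (`density_convention=
"difference" | "medium"`), and neither is asserted to be the only correct
reading — the guaranteed-direction conclusions at the shipped example
geometries hold under both.

`worst_case` mode answers "is the direction guaranteed?": for each
candidate direction the opposing cap is taken at its 90° Laplace maximum
(`2γ/(ID/2)`) and the assisting cap flat.  A margin above the 0.1 Pa
indeterminacy tolerance fixes the direction; otherwise the result is
indeterminate, with a symmetric mid-estimate reported so that swapping the
stacks exactly negates the returned pressure.

Budding and gap stability are force-balance heuristics, not derived
results: a cap buds when buoyancy `Δρ·g·V` exceeds the maximum pinning
force `γπ·ID`, giving `V* = γπ·ID/(Δρg)` (~43 µl for a 5 mm opening — past
the 32.7 µl hemisphere, so budding requires over-filling past 90°); an
exposed medium column spanning a gap is classified by the dimensionless
ratio `Δρ·g·ID·gap/(4γ)` with thresholds 0.7 and 1.3, calibrated so that
at default parameters 1 mm gaps are stable, 2 mm marginal and 4 mm
unstable, matching bench experience with spacer stacks.

## Darcy networks

Modules are lumped 1-D Darcy elements, `R_hyd = µL/(kA)`; circuits are
solved by sparse nodal analysis with fixed-pressure and fixed-inflow
boundaries, and mass balance at every interior node is asserted to 1e-9
of the largest edge flow after each solve.  This is deliberately an
approximation: fluid walls morph during flow and a faithful treatment
would need continuum boundary conditions; within the lumped picture only
ratios, directions and conservation properties are trustworthy, because
no authoritative permeabilities exist for filter papers, agarose fills or
dilute Geltrex — the shipped values are order-of-magnitude placeholders
and are labelled as such.  Bypass paths (gaps between modules, seepage up
stack sides) are explicit user-declared edges; nothing is inferred from
geometry.  The wanted/wasteful partition divides boundary throughflow by
the `wanted` edge flags and is exact whenever the flagged edges form a cut
of the circuit (the usual module-plus-bypass topology).

## Cap dynamics

`series_to_flow` smooths heights with a 3-point moving average by default
(measured cap heights carry pixel-scale noise; disable with
`smoothing_window=1`), converts to volumes, and differentiates with
central differences — exact on series whose volume declines linearly.

`simulate_feeding` advances cap volumes with an explicit fixed step
(default 10 s) — at each step the stack nodes enter the network as
fixed-pressure boundaries at potential `−Δρ·g·h_stack + 2γ sin θ/a`
(cap self-weight neglected, as is conventional at mm scale).  Three
numerical details:

- **Drained caps.**  A cap at zero volume cannot supply more than its
  external feed; such stacks switch to fixed-inflow boundaries (a small
  complementarity loop), which reproduces the physical flow-limited
  steady state without the integrator chasing an empty cap.
- **Adaptive halving.**  A step that would drive a volume negative is
  halved, down to `step·2⁻²⁰`, then an error is raised.
- **Budding.**  When a cap volume crosses `V*` it is reset to the 90°
  hemisphere volume and the excess logged as a bud.  The residual-cap
  state after budding is not observable in practice; the hemisphere reset
  is this package's documented heuristic.  Under constant inflow *Q* the
  stationary budding period is therefore `(V* − V_hemisphere)/Q`, which
  the simulation reproduces to <1% at the default step.

The volume budget (inputs = Δcaps + buds + withdrawals) closes to machine
precision by construction and is checked against a 0.1% tolerance.

## Colony scoring

**Detection.**  Background (paper texture, flare) is estimated by a
decimated large-kernel median filter (250 µm default, large relative to a
colony) and subtracted.  The detection copy is denoised with a 1-px
Gaussian; the mask is thresholded at 0.25 of the image maximum, closed
with a 3×3 element, and 8-connected components are labelled.  Each focus
is then re-measured at 0.25 of its *own* peak: a projected sphere
thresholded at fraction *q* of its peak keeps the disc of radius
`R√(1−q²)`, so the measured area is corrected by `1/(1−q²)`, making the
area→volume estimate unbiased under the chord-projection model (recovered
volumes are within ~4% on clean synthetic fields).  Two safeguards deal
with real-image pathologies: components whose peak is below 15 robust
standard deviations of the residual background are rejected (surviving
texture extremes reach ~10σ; even a dim single cell exceeds ~25σ), and
detections whose equivalent discs overlap are fused (a colony split into
two lobes by a dark fiber is one biological object).  The minimum area
defaults to one 10 µm-radius cell footprint.

**Profiles.**  The longest axis is the major axis of the focus's
intensity-weighted second moments, with ties broken toward the image
x-axis; 1-px-wide scans along it and its orthogonal pass through the
weighted centroid, span the component's extent, are sampled bilinearly,
smoothed with a 3-sample moving average (single-pixel samples are
shot-noise limited), and normalized to peak = 100, length = 100.

**Necrosis rule.**  A scan has a *valley* if any sample strictly inside
the middle two-thirds (positions 16.7–83.3, endpoints excluded) falls
below 37% of the reference peak; valleys in both scans → *possibly
necrotic*, exactly one → *single-valley (fiber)*, none → *no valley*.  The
37% threshold is the chord-model center intensity of a sphere whose
central 25% of volume is dark, **relative to the fully fluorescent
sphere's peak 2R**.  A scan normalized to its own peak references the rim
maximum instead, which for a cored sphere is below 2R, so self-
normalization inflates the apparent center value (a 25% core reads ~48%
of its own rim peak).  Both references are implemented:
`reference="self"` applies the conventional rule verbatim;
`reference="sphere"` rescales to the implied full-sphere peak, estimated
as the maximum of `I/√(1−u²)` over the scan interior (|u| ≤ 0.9) — valid
because cores and fiber shadows only ever depress samples.  The sphere
reference places the decision boundary exactly at f = 0.25 on analytic
profiles and is what the synthetic benchmark uses; the discrepancy between
the two conventions is documented here rather than resolved.

**Growth.**  `τ = Δt·ln 2 / ln(V̄₁/V̄₀)` on cohort means; infinite when
the means are equal.  Cohorts are cross-sectional (a paper is stained and
discarded at each timepoint), which the generator mirrors.

## Synthetic data

Generators are pure functions of their arguments and seed (one
`numpy.random.default_rng` per call; identical calls are bit-identical).
Every artifact ships its ground truth so pipeline stages are tested as
estimator-versus-truth recoveries.

- **Cap series**: volume integration of a prescribed flow, inverted to
  heights (Cardano solution of the cap cubic), Gaussian height noise
  (default scenario: 10 µl/h, 2-min sampling, 20 µm noise).
- **Colony fields**: colonies are chord-length projections of uniformly
  fluorescent spheres; dark cores remove the central `f` of the volume;
  paper texture is two octaves (40 and 160 µm) of smoothed noise at 15%
  multiplicative amplitude on a background of 5 a.u.; halos are a 3 µm
  Gaussian blur; shot noise is Poisson at 1 a.u./photon.  Texture, halo
  and noise amplitudes are this package's parameterizations of features
  visible in real stained-paper images — invented, not measured.  A
  colony "growing around a fiber" is modelled as a sphere shadowed by an
  opaque band through its center (relative half-width 0.2–0.4 of the
  colony radius, attenuation 0.66–0.72): the scan across the fiber then
  shows a central valley while the scan along it is uniformly attenuated
  and keeps a central peak — reproducing the observed one-valley fiber
  phenomenology.  Seeding density scenarios draw Poisson counts from
  cells/ml × field volume (10⁵/ml over a 340 µm thickness gives the
  familiar ~110 cells per 1.1 µl).
- **Growth cohorts**: `V(t) = V₀·2^(t/τ)·ε` with ε lognormal, unit mean,
  CV 0.3 by default, drawn independently per colony *and* per observation
  day (different individuals are measured each day).
- **Circuits**: templates transcribe the standard bench geometries
  (OD 10/ID 5/1 mm washers; four 8×8×3 mm agarose blocks, 768 µl total; a
  four-input cross feeding three 340 µm papers over a spacer with a
  6×6 mm hole); `randomize=True` jitters dimensions ±20% for property
  tests.

What passing tests on these synthetics does **not** show: performance on
real micrographs with out-of-focus flare, creped-paper thickness
variation (±2×), fused or non-spherical colonies, dye-penetration
artifacts, or any absolute flow prediction (placeholder permeabilities).
The classifier benchmark (50 cored colonies at f = 0.4, 50 viable, fibers
on 30%, fixed seed) achieves sensitivity and specificity ≥ 0.9 under the
sphere reference; that is a statement about the model's internal
consistency, not about clinical-grade necrosis detection.

## Problem sizes

Default test and acceptance runs use desk-scale problems: ≤ 11-node
networks, ~1200×1200 px synthetic fields, 20-colony cohorts, and feeding
simulations of ≤ 12 simulated hours at a 5–20 s step.  These sizes were
chosen as the smallest that exercise every code path and keep the full
suite comfortably interactive.
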
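# Methods

## The model

Brain interstitial space (ISS) — the fluid-filled gap system between
the membranes of neurons and glia — behaves, for small-molecule
transport, like the pore space of an unconsolidated porous medium with
porosity φ ≈ 0.2 and measured tortuosity τ ≈ 1.6.  `sheetvoid`
implements three periodic lattice models of this medium built from
cubic "cells" (cross-sections of neuropil processes, not cell bodies)
of half-width *a*, separated by fluid **sheets** of half-width *w*
(adjacent faces sit 2*w* apart), optionally carved with **voids** of
width *b*:

* **uniform** — plain cubic lattice, no voids;
* **CCV** (corner cubic void) — a cube of side *b* removed from each of
  the 8 corners of the cell;
* **ETV** (edge tunnel void) — square tunnels of cross-section *b* × *b*
  along all 12 edges, joined by the 8 corner cubes.

Each cell plus its half-sheets tiles space as a bounding cube of
half-width *p* = *a* + *w*.  Within one bounding cube the ISS volume is
the sheet volume *V*ₛ = 8*p*³ − 8*a*³ plus the void volume *V*ᵥ (8*b*³
for CCV; 8(3*a* − 2*b*)*b*² for ETV).  Two dimensionless numbers
control transport:

* porosity φ = (*V*ₛ + *V*ᵥ)/*V*ₚ, and
* the void-to-sheet ratio Ω = *V*ᵥ/*V*ₛ.

Voids act as dead-space microdomains: a molecule that wanders into a
local expansion is more likely to hit its walls than to find the narrow
sheet connecting onward, so voids raise the geometrical tortuosity
τ_g = √(D/D*) above the zero-void value without changing φ much.  The
closed-form calculus connecting (φ, w, a, b, Ω) lives in
`sheetvoid.relations`; all relations were re-derived and are enforced
as round-trip identities in the test suite (to 1e−10).

A note on the ETV void volume: the form V_v = 8(3a − 2b)b² is the one
consistent with the tunnel bookkeeping (12 tunnels of volume
2(a − b)b² plus 8 corner cubes b³) and with the ETV porosity formula;
the package uses it throughout, and the block decomposition of the cell
(below) verifies it exactly.

## Zero-void anchor

For the uniform lattice, high-precision Monte Carlo gives the corrected
relation

    τ_g = sqrt((3 − φ)/2) + 0.07 φ (1 − φ),

with the φ → 0 limit √(3/2) ≈ 1.2247.  Because that limit falls well
short of 1.6 (and of 1.333 = 1.6/1.2 when a viscous tortuosity
component of 1.2 is factored out), uniform sheets alone cannot explain
measured brain tortuosity; this anchor is also the Ω = 0 point of every
structure–transport fit.

## Geometry engine

A cell is stored once, in its local frame, as a 3×3×3 block grid with
per-axis breakpoints (−a, −(a−b), a−b, a).  A block is void when all
three of its indices are outer (CCV corner) or at least two are (ETV
corner or edge).  Everything else follows from this decomposition:

* point classification folds a global coordinate by the lattice period
  2*p* into the local frame and reads the block mask (O(1) per query,
  memory independent of ensemble size);
* the mesh exporter emits exactly the block faces whose neighbour is
  not solid, so exported OBJ surfaces are watertight and their
  divergence-theorem volume equals the analytic solid volume to 1e−9;
* the walker's ray tracer knows that solid boundaries only lie on the
  break planes.

The ensemble is centred on a lattice **vertex**, not a cell centre:
cell centres sit at odd multiples of *p*, so the origin is the cavity
where the corner voids of 8 neighbouring cells and three crossing
sheets meet — the release site of every simulation.  The origin itself
classifies as sheet (sheets coat every void), with the 8 voids starting
one sheet-width away along the diagonals.

## Random-walk simulator

Molecules perform fixed-step Brownian motion: per-axis Gaussian
increments of variance 2 D Δt.  The free diffusivity D is 1.11×10⁻⁵
cm²/s (TMA at 37 °C) or 7.71×10⁻⁶ cm²/s when the viscous component 1.2
is folded in; internally lengths are µm, times s, so cm²/s values are
multiplied by 10⁸ at the configuration boundary.  The time step must
keep the mean radial step l̄_r = √(4 D Δt/π) at most 2w/4 (Δt = 20 ns
gives l̄_r ≈ 4.4 nm against sheets of 40 nm).  Gaussian-increment
sampling is an explicit modelling choice; the simulator it emulates
pins only the mean radial displacement formula, and the steady-state
tortuosity is insensitive to the step-length distribution once steps
are much smaller than every geometric feature — the zero-void lattice
check against the corrected closed-form relation bounds any residual
bias.

Each step segment is reflected specularly off solid faces: candidate
crossings of the (folded) break planes are enumerated along the
segment, the segment is classified piecewise between crossings (the
solid/ISS label can only change on a plane), and the first sub-interval
that would be solid triggers a mirror reflection at its entry plane,
iterating until the step is consumed (cap 32 bounces; a capped step is
discarded and counted, which never occurred in the validation runs).
For a flat wall this reproduces reflected Brownian motion exactly; only
multi-face corner events within a single step are approximate.
Reflection preserves path length to 1e−12.

The outer ensemble boundary is *not* reflecting: any molecule leaving
the bounds aborts the run with a containment error, and the ensemble
must be sized so this cannot happen (32³–64³ cells; enlarging the
lattice costs nothing because geometry is folded, only the bound check
changes).  Periodic wrap-around is deliberately not offered.

Randomness comes from numpy's PCG64 generator seeded by the run config;
increments are drawn in chunks and consumed by a numba-compiled kernel
(~10⁷ particle-steps per second per core).  A run is fully determined
by its seed; re-running a config reproduces its time-course CSV
byte-for-byte.

## Reduction to tortuosity

At output times t the simulator records ⟨r²⟩ over molecules, from which
D*(t) = ⟨r²⟩/6t and τ_g(t) = √(D/D*).  The time course shows an early
peak (molecules trapped by the first wall encounters), then decays to a
plateau; only the plateau value is a tortuosity.  The plateau onset is
detected as the earliest time, after the peak, where the log–log slope
|d ln τ²/d ln t| fitted over a trailing half-decade window (clipped to
the end of the run, minimum 5 points and 0.15 decades) stays below
0.01; τ_g is then averaged from the onset to the end of the run.  The
original analysis chose the onset by inspection; the slope rule is a
reproducible automation of that judgement.

Because ⟨r²⟩/6t is cumulative, it approaches the plateau like
1 + c/t: validation runs of the φ = 0.2 reference geometries show the
reported τ_g settling within ~1% of its long-time value when the run
lasts ~2–3× the onset time, which is the accuracy the desk-scale
protocol targets.  Coordinate histograms at the plateau match an
independently generated Gaussian of variance 2 D* t (R² per the
1 − (‖resid‖/‖Y − mean Y‖)² definition), confirming D* is a classic
diffusivity.

## Structure–transport fits and inversion

Steady-state τ_g² is fitted against Ω by ordinary least squares:
linear for CCV at normal porosities (φ ≤ 0.4), cubic for CCV at high
porosities (0.6–0.9), quartic for ETV — fixed orders, not selected by
information criteria.  Inversion for a target tortuosity takes the
closed-form solution (linear) or the smallest non-negative real
polynomial root within the fitted Ω range (+5% margin for printed
rounding); a target with no admissible root raises a "tortuosity
unreachable" error — the ETV family genuinely cannot reach τ_g = 1.6,
only the viscous-case 1.333.  Geometry follows from Ω via the scale
factors A = a/w and B = b/a, which are independent of w; tables for
w ∈ {10, 20, 40} nm are generated from a single inversion.

## Asleep/awake analysis

Porosity in mouse cortex rises from φ_w = 0.141 (awake) to φ_s = 0.234
(asleep) at roughly constant measured tortuosity (τ = 1.55 is adopted;
1.292 in the viscous variant).  Within the linear CCV regime a single
simulated trial point per state — (Ω = 4.0, τ = 2.013) asleep,
(Ω = 3.0, τ = 1.981) awake — plus the zero-void anchor from the
corrected lattice relation fixes each state's line τ² = τ₀² + mΩ.  The
slopes are computed from these two points (the published slope values
0.657/0.829 are not reproducible from the published inputs at the last
digit, but the published Ω solutions are, so the pipeline recomputes
slopes rather than accepting them).  Solving each line at the shared
target τ gives the state Ω, hence (A, B) and geometry per sheet width;
a final row chooses the awake sheet width w = p_ref/(1 + A_w) that
keeps the bounding cube identical to the asleep reference — the
constant-brain-volume scenario.

## Problem sizes and what the tests show

The validation protocol is deliberately desk-scale: 2000–2500 molecules
(25 000 in the `full` preset), Δt = 20 ns, durations of 6 ms for the
φ = 0.2 geometries and 24 ms for the large asleep-state trial cell,
32³–64³ cells.  At these sizes the plateau τ_g carries ~0.5–1%
stochastic-plus-transient uncertainty, which is why simulation
reproductions are asserted at ±0.03/±0.05 absolute and the re-estimated
linear slope at ±10% (from three simulated points rather than the
original 26).  The full fitted coefficient tables would need 50+ runs
at 25 000 molecules each and are out of scope for the default suite.

Synthetic data used by the tests (exact polynomial curves, Gaussian
clouds) exercise the reduction and fitting code paths with known
answers; they do not emulate tissue heterogeneity, molecule–matrix
interactions, or cell-size dispersion, so passing tests demonstrate
fidelity to the idealised lattice models, not to real cortex.

## Numerical choices

* Cubic/quartic inversions use companion-matrix roots
  (`numpy.polynomial`); the ETV width equation is solved by bracketed
  Brent iteration on (0, a), where monotonicity guarantees uniqueness.
* Tiny negative values arising from cancellation at the uniform-lattice
  limit (Ω, the CCV brace term, linear-inversion roots) are clamped to
  zero below 1e−9–1e−12; genuinely negative values raise typed errors.
* Reflection hits snap the molecule exactly onto the face plane before
  the remaining sub-step continues, keeping the classifier away from
  ambiguous boundary states; sub-intervals shorter than 1e−14 of a step
  are skipped as degenerate.
* All analytic functions validate domains and raise typed exceptions
  (`DomainError`, `GeometryError`, `NoVoidSolutionError`, ...) rather
  than returning NaN.

## Known limitations

* The cumulative D* estimator biases τ_g slightly high at finite run
  length (about +0.5–1% at 2–3× the plateau onset); runs must be
  extended, not re-windowed, to reduce it.
* Corner events (two reflections closer than a step) are resolved as
  sequential mirror reflections, which is not exactly corner-reflected
  Brownian motion; the effect is below the stochastic noise at the
  mandated step sizes.
* Only mono-disperse cubic cells are modelled; truncated octahedra,
  random polyhedra and missing-cell (lacunar) variants are out of
  scope, as are advection, binding, and absorbing boundaries.
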
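# Methods

This note records the model assumptions, numerical choices and synthetic
study conditions behind `urchindrift`, in the order the pipeline runs.

## Velocity fields and interpolation

A `VelocityField` holds u/v (optionally w) on a regular lon × lat × depth
× time grid with a static land mask.  Conventions, fixed once and used
everywhere: horizontal coordinates in degrees; depth in metres, positive
down, starting at the surface; w in m/s, positive up (so depth evolves as
−w); time in seconds since the field's epoch.  Files that store an
elevation-style depth axis (negative up) or a w flagged `positive: down`
are normalised on read.  Coordinates must be strictly increasing; a file
with a reversed latitude axis is rejected rather than silently sorted.

Interpolation is tri-linear in space and linear in time.  Near the coast,
land nodes contribute zero velocity and the trilinear weights are
renormalised over the water nodes of the enclosing cell; a cell whose
eight spatial corners are all land interpolates to (0, 0, 0).  The
renormalisation prevents the artificial near-shore slow-down that plain
trilinear interpolation against zero-filled land values would produce.
Exactness properties (node identity, linear-field reproduction, bounds by
cell extremes) are asserted in the test suite.

Daily reanalysis snapshots are interpolated linearly in time; no sub-daily
structure (e.g. tides) is represented — a known limitation for island
flows.

## The transport model

Larvae are passive: no swimming, no vertical migration, no mortality, no
growth.  Motion is dx/dt = u, dy/dt = v, dz/dt = w, integrated by
classical RK4 with velocity evaluated at t, t+dt/2, t+dt/2, t+dt.  The
integration state is (lon, lat, depth); at every stage evaluation the
horizontal velocities are converted from m/s to deg/s using Earth radius
6371 km and cos(latitude) for longitude.  This per-evaluation conversion
is adequate at island scale (tens of km); it is not a general-purpose
geodesic integrator.

Numerics: dt = 120 s, 122-day drift per particle, snapshots every 6 h on
a global clock anchored at the first release (so snapshots are synoptic,
usable for density maps, rather than per-particle age-aligned).  The
integrator's order is verified by self-convergence on solid-body rotation
(error ratio ~16 on dt halving against a dt = 7.5 s reference; the
reference cancels the small cos-lat model bias that would otherwise
contaminate the measurement), and constant-field steps are exact.

Boundary handling: a particle whose landing cell has no water corner
beaches, frozen at its last water position (absorbing — the conservative
choice; the alternative of reflecting boundaries would keep counts higher
but invents a physical process).  A particle leaving the grid in any RK4
stage exits, frozen at its last in-domain position.  Survivors finish at
their 122-day age.  All terminal states are absorbing, and particle count
is conserved at every snapshot by construction.

Releases: 6000 particles/day for 92 consecutive days (552,000 total) at
uniform random depth in 0–80 m, placed uniformly at random over the union
of the six zones (rejection sampling); an equal-count-per-zone mode is
available because uniform-over-union weights zones by area, which changes
per-zone source contributions.  Sampling uses one seeded generator with
deterministic per-day batch draws: reproducible bit-for-bit given the
seed, though the draw order is batch-wise rather than strictly
particle-by-particle.  Time is seconds on the field clock; a calendar
start (June 1, spanning the June–August spawning peak) is a configuration
concern, mapped through the field's epoch attribute.

## Zones and recruitment

The six coastal zones RC_A…RC_F serve as both release areas and
recruitment targets.  Since the real polygons are unpublished, the default
geometry is synthetic: six 60°-bearing annular sectors, clockwise from
north, between the shore of a circular island (radius 8 km) and 8 km
offshore.  User polygons load from GeoJSON for real applications.
Point-in-zone queries resolve boundary points to the lowest id among the
touching zones — arbitrary but deterministic, making the assignment a
partition.

A particle recruits to the zone containing it at the **first** snapshot
whose age lies in [110, 120] days (115 ± 5: pod formation within ~100
days plus ~5 days of settlement).  The window is age-based (per-particle,
days since that particle's release), not calendar-based; first-contact
resolves multiple in-window presences deterministically.  Particles
beached or exited are excluded from the snapshot on.  No depth screening
is applied at recruitment (an optional maximum-recruitment-depth exists,
off by default).

Indices: the connectivity matrix counts release zone × recruitment zone;
retention is its diagonal.  `retention_fraction` uses *released* as the
denominator (recruited anywhere / released); source contributions and
sink proportions are row and column shares of all recruits.  Percentages
are reported to two decimals, halves rounding up.  The matrix always
stores the diagonal; reports may include or exclude it.

## Depth strata

Bathymetric strata 0–50, 50–100, 100–150, 150–200 m are half-open
[lower, upper), so the printed touching bounds never overlap; depths of
200 m or more fall outside all strata.

## Count models for bycatch

One record per trap haul: year (2015–2022), fishing-season month
(October–May, 8 levels), zone, depth stratum, lobster size class (large /
small, split at 107.5 mm carapace length), and the urchin count.  Design
matrices use treatment coding with the first declared level as reference
(2015, October, RC_A, 0–50 m, large); published coefficient values from
other codings are comparable only up to reparameterisation.

Families: Poisson; NB2 (variance λ + λ²/φ; larger φ means closer to
Poisson); and their zero-inflated versions with a constant structural-zero
probability π (intercept-only zero part — no covariates are specified for
it).  The ZINB per-record likelihood is
log[π + (1−π)·NB(0; λᵢ, φ)] for zeros and log[(1−π)·NB(yᵢ; λᵢ, φ)]
otherwise.  It reduces to plain NB at π = 0 and approaches ZIP as
φ → ∞; both reductions and the normalisation over the count support are
verified numerically in the tests, and the full fit is cross-checked
against an independent implementation (statsmodels, whose α is 1/φ).

Fitting: maximum likelihood over θ = (β, log φ, logit π) with analytic
gradients and L-BFGS-B (gradient tolerance 1e-6), from a deterministic
start — β from a Newton Poisson warm start, log φ = 0, logit π from the
empirical excess-zero fraction clipped to [0.02, 0.90].  On
non-convergence the optimizer restarts once from a fixed-seed jittered
start; the fit is returned either way with its convergence flag.
Degenerate (empty) design columns raise a warning naming the column.

Model selection: AIC = 2·df − 2·logL, df counting coefficients plus φ
and π where present; ties break toward fewer parameters.  The default
candidate set is the simple ladder m1–m5 (one factor each, in the order
year, month, zone, depth, size) and the cumulative ladder M1–M5 adding
factors in that order; the full cumulative model carries
1+7+7+5+3+1 = 24 coefficients plus φ and π = 26 parameters.  Zero
inflation is refit per candidate.  An overdispersion diagnostic (Pearson
χ²/df under the fitted family's mean–variance relation) accompanies the
ladder.

## Synthetic study conditions

**Flow.**  Scenario fields compose a uniform background current, a
Rankine recirculation cell over the island, optional drifting eddies, and
optional white noise; w is absent (zero), and the land mask is carved
from the island circle.  Rankine vortices (solid-body core, 1/r far
field) were chosen over Gaussian eddies for their closed-form tangential
profile, testable exactly.  The Southern-Hemisphere convention is fixed
in one constant: anticyclonic = counterclockwise = positive vertical
curl.  Away from the core rim the generated flow is divergence-free to
< 1e-6 s⁻¹ on the grid.

**The retention preset** realises the closed-recirculation regime: vortex
core radius 30 km (solid-body across the whole 8–16 km zone ring), peak
speed 0.3 m/s, background drift 0.02 m/s eastward, no noise, on a
1/48° grid spanning ±0.5° around the island.  Inside a solid-body core a
background flow U merely displaces the rotation centre by U/Ω (2 km at
these values), so orbits stay closed and most larvae remain in the ring
through the recruitment window; losses occur where displaced orbits graze
the island and beach.  This geometry argument fixes the preset's
behaviour: retention well above 50%, stable across release seeds, and
strictly decreasing as the background flow grows (doubling U doubles the
orbit displacement and roughly doubles the beaching ring).  Measured
values: 87–88% retention across seeds, falling to 66–68% with doubled
background flow.

**Trap hauls.**  Predictors are drawn uniformly over their level sets;
counts are ZINB with λᵢ = exp(Xᵢβ).  Default truth: intercept 0.3; year
effects rising from 0 to 2.2 (the post-2018 surge); small month
seasonality (±0.2); zone effects ±0.4; depth effects falling to −1.6 in
the deepest stratum; small-lobster effect +0.15; φ = 1.2; π = 0.35 —
chosen once to mirror the qualitative structure of the observed series
(sharp year effect, shallow-biased depth profile, weak positive
small-size association, ~58% zeros).  Generator moments match the
analytic mean (1−π)λ and zero probability π + (1−π)(φ/(φ+μ))^φ on large
samples.

**What the synthetic conditions do not emulate**: real bathymetry,
ENSO-scale interannual variability, sub-mesoscale turbulence, tidal
currents, larval behaviour (pluteus-arm buoyancy, swimming, vertical
migration), temperature-dependent mortality, and spatial autocorrelation
or effort structure in the trap data.  Passing tests therefore establish
the correctness of the machinery (integration, bookkeeping, likelihoods,
selection) and the qualitative circulation–retention mechanism, not
quantitative predictions for the real archipelago.

## Problem sizes

The test suite and the acceptance script run the release scaled to 100
particles/day × 10 days (1000 particles; the production schedule ×0.002)
with full production numerics (120-s step, 122-day drift, 6-h snapshots),
and the ZINB recovery study at n = 10,000 records × 50 replicates in the
suite (10 in the script).  The production schedule itself is exercised
for release bookkeeping only.

## Known limitations

Single-level (depth-independent) synthetic flows mean vertical shear is
untested against an oracle; the degree-space integrator accumulates a
small cos-lat bias over very long drifts at high latitude; rejection
sampling is inefficient for zone unions much smaller than their bounding
box; and the ZINB zero part is intercept-only by design.
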
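# Methods

`lagoonconnect` models lagoon-scale larval dispersal and source–sink
connectivity of a bottom-dwelling broadcast spawner (the black-lip pearl
oyster *Pinctada margaritifera* is the motivating species) in a deep
atoll lagoon, and decomposes the variability of connectivity across the
physical and biological factors that drive it. This note documents the
model components, their assumptions, the tunable parameters, and the
design decisions taken where the design was genuinely open.

## The idealized lagoon

The domain generator builds a radially symmetric saucer basin
`d(r) = d_max (1 − (r/R)^p)` on a regular square grid. `R` is adjusted
so the rasterized wet area matches the requested surface (default
142 km²) and `p` so the discrete mean wet depth matches the requested
mean (default 41 m, maximum 70 m); both land within a fraction of a
percent. The vertical is discretized into sigma layers (default 8 at
desk scale; 23 mirrors a field-scale configuration) whose interfaces are
tightened near surface and bottom with the monotone map
`s − c·sin(2πs)/(2π)` (tightening `c = 0.7`).

Openings are carved into the rim at configurable azimuths: one pass
(sill 11 m, north-west) and hoa spillway fields (sill 0.3 m, southern
and north-western rim), matching the geomorphology of deep Tuamotu
lagoons where hoa make up about 5 % of a 77 km rim. Real bathymetric
complexity (pinnacles, honeycomb cells) is reduced to optional seeded
pinnacle perturbations; nothing downstream depends on it.

Spawning/destination sectors partition the ≥ 5 m part of the lagoon into
k = 12 patches by planar k-means (10 restarts, fixed seed) on cell
centroids — on a convex basin this yields contiguous, similar-area
sectors (max/min area ratio ≤ 2 in tests). Wet cells shallower than 5 m
form a single "shallow" compartment (destination only, labelled B);
the open ocean is the 14th destination (O).

Broodstock maps: the natural (wild) stock uses a density-by-depth table
from the Takapoto atoll survey of Zanini & Salvat (2000) — 1 / 3.6 /
5.2 / 8.2 oysters per 100 m² in the 0–10 / 10–20 / 20–30 / 30–40 m
bins and 2.5 beyond 40 m, bins left-closed right-open — and emits
larvae from the bottom sigma layer. The reared stock sits on synthetic
rectangular concession patches biased to the western half (seeded), at
the legal ceiling of 12,000 oysters/ha, emitting between 5 and 10 m
(longline depth).

## Synthetic winds and regime classification

The wind generator draws a gap-free daily (u, v) series from a sticky
Markov mixture over regime specifications (mean/SD of speed and of
meteorological direction, monthly occurrence weights). The stay
probability `1 − 1/persistence_days` (default 10 d) makes 30-day windows
regime-dominated, which is what the downstream classification presumes.
Directions are degrees the wind comes *from*, clockwise from north
(`u = −|W| sin θ, v = −|W| cos θ`), so easterly trades sit near 90°.
The default regime specifications transcribe the published 12-regime
Ahe climatology (1979–2011 ERA-Interim-derived), with monthly weights
concentrated in each regime's season; direction SDs are capped at 45°
in the generator because the two largest published SDs (91.4°, 66.2°)
describe within-cluster circular scatter, not a sampling distribution a
normal draw should imitate.

Classification follows the climatology procedure: 30-day windows with
20-day overlap (a 1979–2011 daily record gives exactly 1203), wind
stress `τ = ρ_a Cd |W| (u, v)` with ρ_a = 1.2 kg m⁻³ and Cd = 0.0016
(constant Cd makes the scaling homothetic, so it cannot affect the
clustering — asserted as a test invariant), 15 two-day sub-means per
window, PCA on the mean-centred but *not* variance-scaled 30-vectors
(absolute variability is the signal), and PAM k-medoids (k = 12) on the
scores. The number of retained components is the smallest reaching 95 %
of variance by default (`variance_kept = 1` reproduces full-space
clustering; distances are then preserved exactly, also a test). PAM is
implemented deterministically (greedy BUILD, steepest-descent SWAP);
plain seeded k-means is available as an option. Each regime is
represented by the member sequence closest to the cluster barycentre
(ties → earliest start date, a case that never arises in practice).

Occurrence probability is 100 × members/total (rounded half-up to one
decimal in the summary table); wind statistics pool the member windows'
days, with circular direction means and Yamartino SDs. Season labels:
a regime is winter (Jun–Oct) or summer (Nov–May) when its occurrence
mass in those months exceeds 50 % *and* is at least 1.15× the season's
calendar share, otherwise transition. The enrichment condition is
needed because the 7-month summer window holds 58 % of a uniform
regime's mass by construction; without it no regime could ever be
"transition".

## Circulation

A full primitive-equation hydrodynamic model is out of scope; the
circulation provider is a parametric stand-in reproducing the features
that matter for lagoon-scale dispersal, with externally computed fields
ingestible through NetCDF.

* **Double gyre.** A corner streamfunction (zero on and next to land,
  envelope following normalized depth) with an anticlockwise northern
  cell and a weaker clockwise southern cell (factor 0.5) under easterly
  wind. Face transports are streamfunction differences, so the discrete
  divergence vanishes identically and no flow crosses the closed rim.
  Amplitude scales linearly with wind-stress magnitude and is calibrated
  to a peak depth-averaged speed of 0.05 m/s at the 7 m/s reference
  wind (observed residuals are ~5 cm/s). The geographic (not
  wind-relative) cell asymmetry keeps the field exactly odd under wind
  reversal.
* **Vertical shear.** A cosine-in-sigma anomaly (downwind surface,
  upwind return at depth), discretely de-meaned with sigma weights so
  each column's depth-integrated transport is unchanged; amplitude
  `shear_fraction` (default 0.5) of the gyre peak speed, scaling with
  stress.
* **Ocean exchange.** Wave-driven inflow over the hoa balanced by
  outflow through the pass, both ∝ stress magnitude (default 270 m³/s
  at 7 m/s — the idealized volume then turns over on the order of
  hundreds of days, the right order for a deep, nearly closed lagoon).
  The through-flow is closed inside the lagoon by a discrete potential
  flow (weighted graph Laplacian with hoa sources and a pass sink,
  factorized once per grid), so continuity holds exactly at every cell.
* **Vertical velocity** is diagnosed from continuity, integrating layer
  divergences up from the bottom; the surface residual is zero to
  round-off by construction.

`e_flushing_time` releases a uniform passive tracer and reports the
first time the volume-mean concentration falls below 1/e, flagging runs
that do not decay within the horizon. On a well-mixed box with outflow
Q it reproduces the analytic V/Q within a few percent (test).

## Larval transport

Larval distribution is an Eulerian grid of concentrations, one field
per spawning site, advanced by a strictly conservative finite-volume
scheme:

* horizontal: first-order upwind advection on the face volume fluxes
  plus explicit Fickian diffusion (Kh, default 1 m² s⁻¹), sub-stepped
  to a CFL limit of 0.9;
* vertical: water motion, diel swimming and diffusion (Kz, default
  1e-3 m² s⁻¹) are solved implicitly per column (backward-Euler
  flux-form tridiagonal, an M-matrix). This is unconditionally stable,
  positivity-preserving and exactly conservative; it is what makes the
  centimetre-thick sigma layers of the 0.3 m hoa cells tractable,
  where explicit vertical diffusion would force ~5 s substeps;
* ocean exchange: outflow removes mass at the cell concentration;
  inflow re-injects it at the concentration of a well-mixed virtual
  ocean reservoir (default volume 10× the lagoon), implementing larval
  remobilization through the pass and hoa;
* the shallow (< 5 m) compartment is ordinary wet space: mass entering
  it counts toward the shallow-loss tally but remains transportable
  back to adjacent deep cells.

Because every term is a flux between two stores, the per-source budget
(lagoon + shallow + ocean = release) closes to round-off at every step;
the acceptance suite asserts < 1e-10 relative on the standard grid and
< 1e-12 in closed basins. The whole one-step operator is linear, which
the tests exploit: on a 5×5×3 grid the operator is assembled column by
column from unit releases and multi-day runs are checked against its
matrix powers to 1e-9.

Diel vertical migration is `w = α cos(2π t / 24)` with t in hours past
local midnight: upward at night, downward in the day, zero crossings at
a fixed tropical 06:00/18:00, zero 24-h mean. The peak speed α defaults
to 1e-3 m/s (configurable; the source literature leaves the numeric
value to a companion reference). Behavior is vertical only; larvae are
horizontally passive, with no growth, mortality or stage dependence.

Release scenarios: *potential* seeds every sector uniformly at 100
larvae/ha of sector surface in a chosen depth band (5–10 m or bottom —
the release-level factor); *natural*/*reared* seed proportionally to
the spawner maps in the stock's own band. Snapshots are taken at
pelagic larval durations of 15, 20, 25 and 30 days.

## Connectivity and variance decomposition

Potential connectivity `P_sd = Q_sd / Q_s` tallies each destination's
full water column at snapshot time; B takes the shallow mass and O the
ocean reservoir, so each source row sums to exactly 1 (closed
accounting; asserted to 1e-6 in every run and exactly in the uniform
mixing oracle, where `P_sd = V_d/V_total`). Realistic connectivity is
the row-wise product `L_sd = P_sd · W_s` — a theoretic larval number
depending only on adult stock, since fecundity and mortality are not
modelled. Cumulated source/sink scores are sector-block row/column sums
standardized as z-scores; B and O are excluded from rankings.
Coefficients of variation across a factor's levels are 100·SD/mean per
cell. SD convention: sample SD (n−1) throughout, configurable to
population SD. Seasonal profiles sum the natural and reared L, cumulate
by destination, average regimes within each season, and z-score across
destinations.

The scenario grid is the balanced full factorial — release level (2) ×
swim (2) × wind regime (12) × PLD (4) × site (12) × destination (14).
Potential probabilities are arcsine-√ transformed, realistic numbers
Box-Cox transformed (λ = 0.3; zeros offset by the smallest positive
observed value, a case that occurs when sectors hold no concessions).
On a balanced grid the factorial contrast subspaces are orthogonal, so
each term's sum of squares is computed directly from marginal cell
means by inclusion-exclusion (sequential = partial SS); %Var =
100·SS/SS_total, residual completing the budget, F/p reported against
the residual. This direct computation is exact and orders of magnitude
faster than a 32k × 4k regression design matrix; it is cross-checked
against statsmodels' sequential `anova_lm` on a small grid.

## What the synthetic data do and do not show

The synthetic generators emulate the *structure* of the study system —
saucer morphology, trade-wind regime mixture with seasonal weighting,
depth-structured wild stock and concession-clustered reared stock — at
desk scale (500 m cells, 8 layers, a parametric two-gyre flow). They do
not emulate real bathymetric complexity, tides/waves, stratification,
observed concession cadastres, or the actual ERA-Interim record, and
the idealized circulation is not a hydrodynamic hindcast. Passing tests
therefore certify the *machinery* (conservation, oracle equivalence,
statistical identities, planted-structure recovery) and the in-paper
arithmetic (sequence counts, stock totals, occurrence percentages),
not a quantitative reproduction of field-scale connectivity values;
quantities like mean intra-lagoon P or ocean export are expected to be
of the same order as published field-scale results, not equal to them.

## Numerical choices and degenerate inputs

* CFL 0.9 on horizontal terms; dt default 6 h (3 h in the pipeline),
  sub-stepped automatically; steps never cross a flow-slab boundary.
* Negative concentrations beyond 1e-9 relative raise a scheme error;
  sub-round-off negatives are clipped.
* Zero-variance PCA input, k > n clustering, empty clusters, zero-SD
  z-scores, zero-mean CV cells, unbalanced ANOVA grids, zero-release
  connectivity rows: all raise or flag (NaN) explicitly rather than
  propagating garbage.
* Release bands outside a shallow column are clipped to the bottom
  layer with a warning.
* Determinism: every stochastic component takes an explicit seed; the
  pipeline manifest records all derived seeds and output checksums, and
  reruns are bit-identical (tested).

## Problem sizes

Defaults used by the test suite and the acceptance script: ~31×31
cells of 500 m, 8 sigma layers, 12 sources; a 30-day dispersal run
takes well under a second, the full 2×2×12 treatment grid with four
PLD snapshots a few minutes including classification of a 33-year
synthetic wind record (1203 sequences, PAM on ~30 components).

## Known limitations

* The circulation is parametric; absolute connectivity values inherit
  its idealizations. Real flow fields can be supplied via
  `read_flow_netcdf` (face fluxes, or cell-centred velocities that are
  validated for non-divergence).
* First-order upwind advection is numerically diffusive; it was chosen
  for monotonicity and exact conservation, which the oracle tests
  require. Horizontal resolution, not scheme order, is the main lever.
* The ocean reservoir is a single well-mixed box; re-entry
  concentrations ignore along-rim structure.
* PAM is O(k n²) per SWAP pass with a dense distance matrix — fine for
  ~1200 sequences, not for hundreds of thousands.
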
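# lagoonconnect

Larval dispersal and source–sink connectivity modelling for atoll
lagoons.

Pearl-oyster aquaculture in French Polynesia depends entirely on
collecting wild spat, so farmers need to know where larvae spawned in a
lagoon end up after their 15–30 day pelagic phase — and how sensitive
that answer is to wind, release depth, larval behavior and duration.
`lagoonconnect` is a desk-scale toolbox for that question: it builds an
idealized deep atoll lagoon (a ~142 km² saucer with a pass and shallow
*hoa* spillways), classifies multi-year daily winds into recurrent
30-day regimes, drives an Eulerian larval transport model with a diel
vertical-migration sub-model, and assembles connectivity matrices with
a factorial variance decomposition. It is aimed at coastal modellers
and shellfish-management scientists who want a testable, fully seeded
implementation of the whole chain — from wind climatology to ANOVA —
that also ingests externally computed flow fields.

## The model in brief

* **Wind regimes.** Daily winds are cut into 30-day sequences
  (20-day overlap), transformed to wind stress
  `τ = ρ_a·C_d·|W|·(u, v)` (C_d = 0.0016), summarized into 15 two-day
  means, embedded by non-standardized PCA, and clustered with PAM
  (k-medoids, k = 12). Each regime is the real sequence closest to its
  cluster barycentre, with occurrence probabilities and a
  winter/summer/transition season label.
* **Transport.** Larval concentration per spawning site obeys an
  advection–diffusion equation on sigma layers, forced by a
  streamfunction-based double-gyre circulation with surface-downwind /
  deep-return shear and stress-scaled pass/hoa exchange. Vertical
  swimming is `w = α·cos(2πt/24)` — up at night, down in the day. The
  finite-volume scheme (upwind horizontal, implicit vertical) conserves
  every source's mass budget to round-off.
* **Connectivity.** Potential connectivity `P_sd = Q_sd / Q_s` is the
  probability of reaching destination *d* from site *s* at snapshot
  time (destinations: 12 sectors + shallow "B" + ocean "O"; rows sum
  to 1). Realistic connectivity `L_sd = P_sd·W_s` weights rows by
  spawner counts (natural depth-structured stock, or reared stock at
  12,000 oysters/ha of concession).
* **Variance decomposition.** Over the balanced factor grid — release
  level (2) × swim (2) × wind regime (12) × PLD {15, 20, 25, 30} ×
  site (12) × destination (14) — arcsine-√ (P) or Box-Cox λ = 0.3 (L)
  transformed responses are decomposed into exact per-term %Var by
  balanced factorial ANOVA.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
from lagoonconnect import (
    build_idealized_lagoon, partition_sectors, generate_wind_series,
    WindRegimeClassifier, flow_for_sequence, run_dispersal,
    potential_connectivity, ReleaseSpec, SwimmingParams,
)
from lagoonconnect.circulation import CirculationModel
from lagoonconnect.datasets import ahe_regime_specs

grid = build_idealized_lagoon(area_km2=142.0, mean_depth_m=41.0,
                              max_depth_m=70.0, n_sigma=8, dx_m=500.0)
sectors = partition_sectors(grid, k=12, seed=0)
print(f"lagoon: {grid.wet_area / 1e6:.1f} km^2, mean depth "
      f"{grid.mean_depth:.1f} m, volume {grid.volume / 1e9:.2f}e9 m^3")

wind = generate_wind_series("1999-01-01", "2008-12-31",
                            ahe_regime_specs(), seed=7)
res = WindRegimeClassifier(wind, k=4, seed=0).fit()
print(res.summary()[["start_date", "n_sequences", "probability_pct",
                     "speed_mean", "direction_mean", "season"]])

model = CirculationModel(grid)
flow = flow_for_sequence(grid, res.regimes[0].reference, model=model)
snaps = run_dispersal(grid, sectors, flow,
                      ReleaseSpec("potential", band=(5, 10)),
                      SwimmingParams(alpha=1e-3), pld_days=[20],
                      dt=6 * 3600.0)
P = potential_connectivity(snaps[20], sectors)
print(f"mean intra-lagoon P_sd: {100 * P.intra_lagoon().values.mean():.1f} %")
print(f"ocean export: {100 * P.values['O'].mean():.1f} %, "
      f"shallow loss: {100 * P.values['B'].mean():.2f} %")
print(f"row-sum closure error: {abs(P.row_sums() - 1).max():.2e}")
```

prints

```
lagoon: 142.2 km^2, mean depth 41.0 m, volume 5.83e9 m^3
       start_date  n_sequences  probability_pct  speed_mean  direction_mean      season
regime
1        10/12/06          155             42.7         5.7            89.9  transition
2        15/02/00           77             21.2         6.7            94.0      winter
3        14/04/04           58             16.0         4.5            79.0      summer
4        29/06/03           73             20.1         5.5            86.9  transition
mean intra-lagoon P_sd: 7.9 %
ocean export: 5.1 %, shallow loss: 0.12 %
row-sum closure error: 2.78e-15
```

The domain generator hits the requested area and mean depth within a
fraction of a percent (the resulting volume, 5.8×10⁹ m³, matches the
field estimate for a lagoon of this morphology). The regime table shows
occurrence probabilities summing to 100 %, easterly mean directions and
season labels from each regime's monthly occurrence mass. After 20 days
of dispersal under the first regime's reference wind sequence, about
7.9 % of a site's larvae sit in an average destination sector, ~5 % has
been exported through the pass, and ~0.1 % sits in the shallow rim
compartment; the closure error shows the mass accounting is exact.

## Command line

```bash
lagoon-connect wind --start 1999-01-01 --end 2008-12-31 --seed 7 --out wind.csv
lagoon-connect regimes --wind wind.csv --k 12 --seed 0 --out regimes.csv
lagoon-connect run --config config.yaml     # full pipeline + manifest
```

`lagoon-connect run` executes domain → wind → regimes → circulation →
dispersal → connectivity → ANOVA from a single YAML file, writing CSVs,
NetCDF grids and a `manifest.json` with seeds and output checksums;
reruns with the same configuration are bit-identical.

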
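# urchindrift

Biophysical larval-dispersal and bycatch-abundance modelling for island
sea-urchin populations.

## The problem

The long-spined sea urchin *Centrostephanus sylviae* has surged around the
Robinson Crusoe and Santa Clara islands (Juan Fernández Archipelago), where
it turns up as bycatch in the *Jasus frontalis* lobster-trap fishery.  Two
questions drive the analysis this package supports:

1. **Where do the larvae go?**  The species spends ~4 months as
   meroplankton.  Whether larvae released around the islands are retained
   locally — and which coastal zones act as sources or sinks — is a
   question of ocean circulation, answered here with an individual-based
   Lagrangian transport model (IBM) on gridded velocity fields.
2. **What explains adult bycatch rates?**  Urchin counts per trap haul are
   overdispersed and zero-heavy.  The package fits Poisson, zero-inflated
   Poisson, negative-binomial and zero-inflated negative-binomial (ZINB)
   GLMs over year, month, zone, depth stratum and lobster size class, and
   ranks them by AIC.

Both stages are exercisable entirely at desk scale through synthetic
generators: an idealized island circulation (background flow + Rankine
recirculation cell + optional drifting eddies) and a ZINB trap-haul
simulator with known ground truth.

## The models

**Transport.**  Passive larvae follow the flow,

dx/dt = u, dy/dt = v, dz/dt = w,

integrated with classical fourth-order Runge–Kutta
(y_{n+1} = y_n + (k₁ + 2k₂ + 2k₃ + k₄)/6) at a 120-s step for 122 days,
with positions recorded every 6 h.  Velocities are interpolated
tri-linearly in (lon, lat, depth) and linearly in time; land nodes are
excluded by weight renormalisation.  The production release is 6000
particles/day for 92 days (552,000 total) at 0–80 m depth across six
coastal zones RC_A…RC_F.  A larva *recruits* to the zone containing it at
its first snapshot aged 110–120 days (115 ± 5); the 6×6 release × recruit
matrix carries retention on its diagonal, and its row/column shares give
source contributions and sink proportions.

**Abundance.**  Counts Y per haul follow a mixture: a structural zero with
probability π, otherwise NB2 with mean λ = exp(Xβ) and variance
λ + λ²/φ.  Fitting is by maximum likelihood (analytic gradients,
quasi-Newton, deterministic Poisson warm start); candidate predictor sets
form a simple ladder m1–m5 (one factor each) and a cumulative ladder M1–M5
(year; +month; +zone; +depth; +size), compared by AIC = 2·df − 2·logL.

## Worked example

```bash
cd analysis
python 01_make_field.py   # idealized circulation -> results/pipeline_run/
python 02_run_ibm.py      # 1000 larvae x 122 days of drift
python 03_connectivity.py # recruitment window -> matrix + indices
python 04_fit_abundance.py# ZINB ladder on synthetic trap hauls
```

Stage 2 and 3 print, for the closed-recirculation preset at seed 1:

```
released 1000 particles; 525 snapshots on the 6-h clock
final fates: {'active': 0, 'beached': 141, 'exited': 0, 'finished': 859}
recruits in the 110-120 d window: 859 of 1000 released
retention (share of released recruited anywhere): 85.9%
top source zone: RC_C (20.02% of recruits contributed)
top sink zone: RC_C (20.14% of recruits received)
```

Read: with closed anticyclonic streamlines around the island, 86% of
larvae are still inside the zone ring when the settlement window opens;
the 14% loss is beaching where the background drift displaces orbits onto
the shore.  Stage 4 prints the AIC ladder; on data generated from the full
model, the full model M5 (26 parameters: 24 coefficients + φ + π) ranks
first and recovers φ ≈ 1.16 and π ≈ 0.35 (truth 1.2 / 0.35).

The same pipeline runs from the shell (`urchindrift make-field | run-ibm |
connectivity | fit-abundance | run-all`, each taking a YAML config, an
output directory and a seed), and accepts real inputs: CMEMS-style NetCDF
velocity fields and GeoJSON zone polygons.

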
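# sealhab

Winter habitat-use and fishery-overlap modelling for satellite-tracked
female Antarctic fur seals (*Arctocephalus gazella*).

During the May–September krill-fishing season, post-breeding female fur
seals from South Georgia disperse to feed, mostly on Antarctic krill —
the same resource the commercial fishery targets. Quantifying where the
seals are likely to be, and how much of the fleet's activity and catch
falls inside that predicted habitat, is the basis for managing the
interaction. `sealhab` implements that analysis end to end as a Python
library for movement ecologists and fishery scientists:

1. **Telemetry QC** — ARGOS location tables are deduplicated, clipped to
   the winter season, stripped of invalid (class Z) fixes, passed through
   an iterative speed–distance–angle filter (10 m/s speed limit;
   out-and-back spikes with internal angle < 15°/25° at step lengths
   > 2.5/5 km), cleared of on-land positions, and split at gaps > 3 days.
2. **State-space regularization** — each track segment is fitted with a
   continuous-time correlated random walk (integrated Ornstein–Uhlenbeck
   velocity: dv = −βv dt + σ dW) via an exact Kalman filter over the
   irregular uplink times; an RTS smoother emits positions every 3 h.
3. **Habitat model** — smoothed positions become presences; three
   pseudo-absences per presence are drawn uniformly over a model domain
   bounded by front and ice-extent lines; a binomial GAM with shrinkage
   cubic regression splines (k = 4) links presence to depth, slope,
   aspect, colony distance and monthly SST/chlorophyll/wind-curl fields.
   Covariates are screened for collinearity (|r| > 0.7, higher-VIF member
   removed) and selected by forward stepwise search on aggregate AUC
   under month-blocked cross-validation (train on one month, test on the
   rest).
4. **Prediction and overlap** — the selected model predicts a probability
   surface over the domain (colony distance substituted with distance to
   the nearest of all colonies); masks at > 0.50 and > 0.95 probability
   are intersected with krill-haul records to give the fishery footprint
   (km²), the catch taken inside each mask, and both as percentages.

Because the original telemetry and catch data are restricted, the package
includes a first-class synthetic study system (`sealhab.synthetic`): a
gridded environment with an island, shelf and offshore rises; seals moving
by a biased correlated random walk with a *known* habitat preference;
ARGOS corruption with class-dependent error and planted artefacts; and a
shelf-break fishing fleet. Every pipeline stage is tested against this
ground truth or against closed-form oracles.

## Worked example

```python
import pandas as pd
import sealhab as sh

world = sh.default_world(seed=0)                       # synthetic study system
tracks = sh.simulate_seal_tracks(world, 6, duration_days=150, seed=1)
em = sh.ArgosErrorModel(spike_rate=0.02)               # ARGOS corruption
obs = pd.concat([sh.argosify(t, em, seed=20 + i) for i, t in enumerate(tracks)])

segments, log = sh.clean_tracks(obs, world.stack)      # QC
regularized = sh.regularize_segments(segments)         # CTCRW -> 3-h steps
domain = sh.build_domain(world.front_line, world.ice_line, world.stack)
table = sh.build_dataset(regularized, domain, world.stack, world.colonies, seed=7)

kept, _ = sh.screen_collinearity(table)
trace = sh.forward_stepwise(table, [c for c in ("CDIST", "DEPTH", "SST",
                                                "CHL", "CURL") if c in kept])
print(trace.selected, round(trace.cv.auc, 3))
```

prints (seed 0):

```
['CDIST', 'DEPTH'] 0.848
```

i.e. stepwise selection under month-blocked CV recovers exactly the two
covariates the synthetic seals were given (attraction to the colony,
preference for shallow water) with an aggregate cross-validated AUC of
0.85, and rejects the three no-signal dynamic covariates. Continuing,

```python
model = sh.fit_binomial_gam(table, trace.selected)
surface = sh.predict_surface(model, world.stack, world.colonies, domain)
m50 = sh.threshold_mask(surface, 0.50)
hauls = sh.simulate_fishery(world, 300, seed=11)
print(sh.overlap_summary(m50, hauls, domain))
```

reports the > 50 %-probability habitat area, the fishery footprint inside
it and the share of the catch taken there — the numbers a manager would
compare across years. The `examples/` directory holds one short script per
capability (synthetic world, track cleaning, CTCRW fitting, habitat model,
fishery overlap, deployment summaries), each printing the numbers it
computes and what they mean.

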
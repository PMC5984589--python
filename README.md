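# sms — spatial multi-sensor biologging for free-ranging livestock

`sms` turns raw animal-borne sensor logs — 40 Hz tri-axial acceleration (g),
tri-axial magnetometry, tag temperature, plus ~1-per-minute GPS fixes — into
spatially explicit behaviour: what a grazing animal did every second, where it
did it, how fast it was feeding, and how those quantities relate to landscape
layers (vegetation class, elevation, slope, predation risk, intra-specific
competition). It targets extensive rangeland systems (the motivating case is
Merino sheep on Patagonian paddocks), where behaviour must be inferred
remotely and placed on heterogeneous terrain.

The pipeline has four stages, each usable on its own:

1. **Signal features** (`sms.signal_features`). Raw acceleration **a** is split
   into a static (postural) component **s** — a centred 2 s running mean — and
   a dynamic component **d** = **a** − **s**. From these:
   head pitch θ = atan2(s_y, √(s_x² + s_z²)); VeDBA = ‖**d**‖₂ (a standard
   proxy for movement energy expenditure); windowed activity counts; and a
   tilt-compensated compass heading from the magnetometer.
2. **Behaviour classification** (`sms.behaviour_classify`). Per-behaviour
   *threshold trees*: for each behaviour (grazing, resting–ruminating, search,
   vigilance, fast walk) the labelled training data define an allowed interval
   per feature (default the [0.025, 0.975] quantiles). Each 1 Hz block is
   assigned the first behaviour, in a fixed evaluation order, whose envelopes
   all contain it; unmatched blocks stay *unclassified*. Bites (vegetation
   clipping during grazing) are local peaks in |dynamic heave| above a trained
   threshold, head down, ≥ 0.25 s apart — giving a per-second bite rate
   (≤ 4 s⁻¹).
3. **Dead reckoning** (`sms.dead_reckoning`). Positions are integrated from
   heading h and a VeDBA-calibrated speed v:
   x_{k+1} = x_k + v_k Δt sin h_k, y_{k+1} = y_k + v_k Δt cos h_k,
   then corrected against GPS fixes either by the conventional linear
   distribution of each inter-fix closure error, or by an anchored
   linear-Gaussian smoother (random-walk offset state, Kalman + RTS) that
   returns a posterior mean path *and* a per-point uncertainty σ.
4. **Landscape fusion** (`sms.landscape`). The corrected 1 Hz track is joined
   with behaviour, bite rate, VeDBA and temperature and annotated with raster
   values, then summarised: grazing-intensity maps (bites per cell), vigilance
   rate by risk/competition level, VeDBA by slope bin, cumulative bite and
   vigilance curves, hourly temperature profiles.

A fully ground-truthed synthetic deployment generator
(`sms.synthetic_data`) emulates all input kinds — behaviour sequence, sensor
signals, true path, GPS, rasters, focal-observation labels — so the entire
pipeline is testable end to end with known truth.

## Worked example

Simulate 12 h of a sheep's day, train on half the labelled intervals,
classify the rest, reconstruct and correct the path, and fuse with the
landscape:

```python
import numpy as np
from sms import SimConfig, simulate_deployment, evaluate, activity_budget
from sms.pipeline import classify_deployment, reconstruct_track
from sms.landscape import annotate, grazing_intensity

dep = simulate_deployment(SimConfig(duration_s=43200, seed=42))
features, blocks, trees, behaviours, train, validate, events = \
    classify_deployment(dep, seed=42)
print(evaluate(behaviours, validate).summary())
track = reconstruct_track(features, dep.gps, method="melding")
annot = annotate(track, behaviours, blocks, list(dep.rasters.values()))
imap = grazing_intensity(annot, dep.rasters["vegetation"])
```

This prints

```
overall proportion correct: 0.846
  grazing      84.2 %
  resting      83.5 %
  search       85.7 %
  vigilance    89.3 %
  fast_walk    85.8 %
```

and the downstream products give, for this deployment: a classified activity
budget of 0.379 grazing / 0.251 resting / 0.294 search / 0.018 vigilance /
0.058 fast walk over classified seconds (the generator's truth is
0.36/0.25/0.31/0.02/0.06); a mean bite rate while grazing of 1.23 s⁻¹
(generated at 1.22 s⁻¹); 16 053 bites mapped onto the vegetation grid from
17 025 detected events; a corrected path whose median error against the true
path is 19.2 m with a mean reported σ of 7.5 m; and tag temperatures spanning
9.9–21.1 °C over the half day. Per-behaviour accuracy means the percentage of
held-out labelled seconds assigned to the observed behaviour; unclassified
seconds count as misses.

The same chain is scriptable from a shell:

```sh
sms simulate --seed 42 --duration 43200 --out dep/
sms fit-trees dep/sensors.csv dep/labels.csv --out trees.yaml --seed 42
sms classify dep/sensors.csv trees.yaml --labels dep/labels.csv --out pred.csv
sms evaluate pred.csv dep/labels.csv
sms deadreckon dep/sensors.csv dep/gps.csv --method melding --out track.csv
sms annotate track.csv pred.csv dep/sensors.csv --raster dep/vegetation.asc \
    --raster dep/slope.asc --raster dep/risk.asc --out annot.csv
sms summarize annot.csv --product intensity --template dep/vegetation.asc \
    --out intensity.asc
```

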
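# divecorrect

Current-corrected swimming velocities and piecewise-constant-heading
segmentation for satellite-tracked diving animals.

## The problem

The ground track of a migrating sea turtle mixes two signals: what the
animal actively swims and what the ocean does to it.  The standard
correction subtracts the *surface* current at each daily position, but a
diving animal does not drift with the surface — it drifts with the
currents of the layers it actually occupies.  Where the water column is
vertically sheared (for example where a monsoon current reverses
direction below ~40 m), the surface approximation can misstate the
encountered current by the full magnitude of the flow, and with it the
inferred swimming speed and heading.

`divecorrect` implements the three-dimensional correction.  Writing
**V**g for ground velocity, **V**s for swimming velocity and **V**c for
the encountered current,

    Vs(t) = Vg(t) − Vc(x(t), d(t), t)

with the encountered current estimated from the daily time-at-depth
(TAD) distribution over the 30 upper layers of an operational ocean
model (lower bounds 0–318.1 m):

    Vc[TAD] = Σₙ TADₙ · Vcₙ

Both the surface variant (**V**s⁰) and the TAD variant (**V**s[TAD])
are carried through the pipeline, and their disagreement is summarised
by the relative error ε = ‖Vs[TAD] − Vs⁰‖ / ‖Vs[TAD]‖.

Downstream, the swimming velocity is integrated into the
*current-corrected track* — the movement of the animal in a motionless
ocean — and the daily heading series θ(t) is segmented into
constant-heading legs by Gaussian-kernel binary segmentation with an
elbow rule on the cost curve.  Segments with circular RMSE below 30°
are treated as directed navigation legs; the heading changes Δθ between
successive valid legs are the animal's course corrections.  This is the
machinery needed to ask whether an open-ocean migrant navigates by
"map and compass": long straight compass legs separated by a small
number of corrections.

Because the full analysis needs gridded ocean-model currents that are
too heavy to ship, the package includes a first-class synthetic
generator (`divecorrect.synthetic`): layered current fields with
controllable vertical shear and eddies, bathymetry with a shelf, and
simulated diving turtles with known headings, speed and dive mixture —
so every stage is testable against ground truth.

## Worked example

Simulate a two-leg migrant (30 days at 10°, 30 days at 50°, 0.5 m/s,
diving half above / half below the 40 m reversal of a ±0.3 m/s sheared
ocean) and fit the model:

```python
import numpy as np
from divecorrect import CurrentCorrection
from divecorrect.synthetic import (OceanSpec, ShearSpec, TurtleSpec,
                                   make_ocean, simulate_turtle)

ocean, bathy = make_ocean(
    OceanSpec(lon_min=45, lon_max=75, lat_min=-25, lat_max=12,
              grid_step_deg=1.0, n_days=62,
              shear=ShearSpec(u_above=0.3, u_below=-0.3)),
    seed=0)
w = np.zeros(30); w[9] = 0.5; w[19] = 0.5          # 50/50 dive mixture
spec = TurtleSpec(start_lon=55.0, start_lat=-18.0,
                  legs=[(10.0, 30), (50.0, 30)], swim_speed=0.5,
                  tad_weights=w, heading_noise_sd_deg=5.0,
                  animal_id="demo", seed=42)
track, depths, truth = simulate_turtle(spec, ocean)
res = CurrentCorrection(track, depths, ocean, bathy).fit()
print(res.summary())
```

prints

```
Current-corrected swimming-velocity analysis
====================================================
animal:            demo
days analysed:     61
Vs[TAD] coverage:  98.4%
||Vs[tad]||:  mean 0.500  sd 0.000  max 0.500 m/s  (>0.8 m/s: 0.0%)
||Vs[surface]||:  mean 0.432  sd 0.106  max 0.576 m/s  (>0.8 m/s: 0.0%)
breakpoints:       1 at days [30]
  segment 0: days 0-29  theta 10.1 deg  RMSE 3.8 deg  [valid]  S(tad/surf/real) 1.00/1.00/1.00
  segment 1: days 30-59  theta 50.6 deg  RMSE 4.0 deg  [valid]  S(tad/surf/real) 1.00/0.99/1.00
```

The TAD correction recovers the commanded 0.5 m/s exactly and finds the
course correction on the right day with the right leg headings, while
the surface-only estimate is biased (mean 0.432 m/s, spurious
variability) because it subtracts a current the diving animal never
fully experienced.

The same pipeline is available from the shell:

```
divecorrect simulate --config sim.yaml --seed 1 --out simdir/
divecorrect run --tracks simdir/tracks.csv --depths simdir/depths.csv \
                --currents simdir/ocean.nc --bathy simdir/bathy.nc --out rundir/
```

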
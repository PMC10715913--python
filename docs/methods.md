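# Methods

## Model

The daily ground velocity of a tracked animal is decomposed as
Vg = Vs + Vc: active swimming plus passive drift.  The package's
central assumption is that over a 24 h window the drift experienced by
a diving animal is the occupancy-weighted average of the horizontal
currents of the depth layers it visited,

    Vc[TAD] = Σₙ TADₙ · Vcₙ ,   n = 0 … 29,

where TADₙ is the day's normalised time-at-depth histogram on the 30
upper layers of a 1/12° operational ocean model (layer bounds
0–318.1 m) and Vcₙ is the layer-n current interpolated at the daily
midpoint position.  The surface-only variant Vc⁰ (layer 0) is carried
in parallel as the classical approximation; their disagreement is the
relative error ε = ‖Vs[TAD] − Vs⁰‖/‖Vs[TAD]‖, with 10% used as the
benchmark separating regions where the surface approximation is
acceptable from regions of significant vertical shear.

The analysis operates entirely in a daily frame: raw fixes are
interpolated at 00:00/12:00/24:00 UTC, ground velocity is the geodesic
displacement between the bracketing midnights divided by 86 400 s, and
the daily current field (centred 12:00 UTC) is used for the whole day
with no temporal interpolation.

## Pipeline stages and the parameters that matter

- **Daily interpolation** (`preprocess`): time-linear great-circle
  interpolation between bracketing fixes; no extrapolation.  This is a
  deterministic regularisation; state-space smoothing of Argos errors
  is deliberately out of scope — pre-smoothed daily positions can be
  ingested directly.
- **TAD histograms** (`tad`): bin 0 holds the surface (0 m exactly);
  bin n holds depths in (bₙ₋₁, bₙ]; deeper records clamp into bin 29
  with a counter.  A day is *valid* with ≥ 16% of the nominal 288
  five-minute records, i.e. ≥ 47 records (ceiling).  The
  `subsample_validation` utility reproduces the thinning study behind
  that criterion (total-variation distance by default; the metric is
  pluggable because the original similarity measure is not fixed).
- **Currents** (`currents`): inverse-distance weighting over the four
  surrounding grid nodes, default power p = 2 (the conventional
  choice; the source method states only "IDW").  Distances are local
  metres (cos-latitude scaling); queries within 1 m of a node return
  the node value; land-masked nodes are dropped with weight
  renormalisation; a fully masked neighbourhood, an invalid TAD or a
  masked positively-weighted layer make the day a gap.
- **Gap policy and corrected tracks** (`corrected`): leading/trailing
  gap days are trimmed; a track is rejected if an interior gap exceeds
  48 h (a gap of exactly 48 h is retained — "longer than" read
  strictly) or if more than 20% of days are gaps.  Remaining gaps are
  filled by linear interpolation of the *current* between valid
  neighbours, re-deriving Vs = Vg − Vc; the wording of the original
  rule is ambiguous between interpolating the current and the swimming
  velocity, so the alternative (direct Vs interpolation) is available
  via `gap_fill_mode="vs"`.  Integration uses daily Euler steps in the
  local equirectangular metric; the path-length invariant (Σ‖Vs‖·86 400
  within 0.5%) bounds the metric error.
- **Segmentation** (`segmentation`): headings are embedded as unit
  vectors (cos θ, sin θ) before kernel evaluation, making the detector
  wrap-safe; at the small within-leg dispersions of interest the
  embedded metric is equivalent to the angular one.  The Gaussian
  kernel bandwidth comes from the median heuristic
  (γ = 1/median‖xᵢ−xⱼ‖²).  Breakpoints are found by greedy binary
  segmentation with nested solutions, leftmost tie-breaking,
  `min_segment_len_days = 5` and `max_nbkps = 10` (guards against
  degenerate splits on 100–300-day series; the source caps nothing
  explicitly but reports ≤ 4 breakpoints per track).  Cost(0) is the
  unsegmented cost, and the number of breakpoints is the elbow
  argmaxₙ [Cost(n−1) − Cost(n)]; the rule cannot return zero
  breakpoints, so a flat curve yields n = 1 with a warning.  Segment
  validity: circular RMSE < 30°, the threshold separating directed
  swimming from foraging-like meandering.  Breakpoints flanking
  invalid segments are retained; Δθ is computed between successive
  valid segments, wrapped to (−180°, 180°].
- **Metrics** (`metrics`): straightness S = net geodesic displacement /
  summed daily geodesic path (the index is referenced without a
  formula in the source; this is the standard movement-ecology
  definition); speed summaries report the share of days above
  0.8 m/s (implausible for juvenile loggerheads); paired comparisons
  across track variants use two-sided paired t-tests on the same
  segments, without multiple-testing correction.

Geodesic quantities (distances, azimuths, destinations) use Vincenty's
formulae on WGS-84, validated against an independent reference
implementation; inner-loop propagation uses the local equirectangular
metric, whose error at 5-minute and daily step sizes is far below the
other uncertainties.

## The synthetic generator

`synthetic.make_ocean` builds daily layered current fields on a regular
grid from a scenario: a uniform background, an optional two-layer shear
(flow reversing across a stated depth, optionally confined to a
latitude band — the signature of monsoon-driven vertical shear), and
stationary axisymmetric eddies applied to all layers; bathymetry is
deep (4000 m) with an optional rectangular shelf.
`synthetic.simulate_turtle` advances a migrant in 5-minute steps: each
step it occupies a depth bin drawn from its dive mixture and moves with
(swim vector + current at that depth); headings are constant within a
leg up to a daily compass noise.  Defaults mirror the study system:
0.5 m/s swimming speed, ±0.3 m/s shear reversing at 40 m, a 50/50 dive
mixture straddling the reversal, 288 five-minute depth records per day.
The generator records per-day ground truth (headings, swim vector,
time-averaged encountered current, positions, breakpoint days), and
`degrade_observations` adds zero-mean position noise, independent
record thinning and block gaps.

What it does *not* emulate: ocean dynamics (no eddy evolution or
continuity), Argos location-class error structure, behavioural state
switching, tides or Stokes drift.  Passing recovery tests therefore
demonstrate the correctness of the estimation machinery under the
stated observation model, not robustness to every failure mode of real
telemetry.

## Reference experiments and problem sizes

The reproduction script and acceptance tests use three experiment
designs chosen to keep a full run under a minute on one core:

- *Recovery*: 20 replicates of two-leg migrants (32-day legs, heading
  change 20–60°, daily heading noise sd 8°, 0.5 m/s, 50/50 mixture) in
  a spatially uniform ±0.3 m/s sheared ocean on a 2° grid.  Scored on
  exact breakpoint-count recovery, ±3-day timing, 5° heading and
  0.05 m/s speed tolerances.
- *Shear discrimination*: one 40-day northward migrant crossing from a
  vertically uniform region into a sheared band (1° grid); daily ε is
  compared inside and outside the band with a 1.5° margin excluding
  band-edge grid cells.
- *Straightening*: one 50-day straight swimmer with a 70/30 mixture
  crossing an eddy (radius 150 km, 0.3 m/s) and the sheared band,
  establishing S(X_TAD) ≥ S(X₀) ≥ S(X_g).

Numerical choices worth knowing: ε is undefined (excluded, not
infinite) when ‖Vs[TAD]‖ ≤ 0.01 m/s; zero-speed days inherit the
previous day's heading; circular means returning an angle numerically
equal to 360° are mapped to 0°; elbow ties resolve to the smallest n;
duration statistics use the sample (n−1) standard deviation; longitudes
are kept in [−180°, 180°) with inputs on [0°, 360°) remapped at read
time.

## Limitations

The interpolator is not a state-space filter, so Argos error is not
modelled — on real data the daily positions should come from a
smoothing step or from deposited daily-interpolated files.  The
corrected track is a kinematic fiction (no re-advection through the
time-varying field).  Simulation samples currents at the nearest grid
node while the analysis interpolates; on the piecewise-uniform
synthetic fields the two coincide, which is what makes exact recovery
checks possible, but it means grid-scale gradients are not exercised.
The per-track straightness ordering is only guaranteed where the
encountered current actually bends the track: with perfectly
cancelling shear and no eddies the real track is already straight.
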
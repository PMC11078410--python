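# Methods

## Problem setting

A small fleet of autonomous underwater vehicles maps chlorophyll-a
fluorescence (CF, µg/L) inside a rectangular operational volume during a
bloom. CF is strictly positive, right-skewed ("hot spots"), and organised
into patches with a subsurface maximum. Each vehicle must decide, on board
and with only the data it has seen or received, where to sample next; the
fleet can only communicate through 340-byte satellite short-burst-data
(SBD) messages relayed by a shore hub when a vehicle surfaces.

## The on-board field model

Measurements y are modelled through their logs. With
z_S = ln y_S − m_GP and m_GP = mean(ln y_S), the centred log field is a
zero-mean Gaussian process with anisotropic squared-exponential covariance

    k(s, s′) = σ_c² exp(−½ Σ_d ((s_d − s′_d)/M_d)²)

over s = (x, y, z, τ). Predictions use the standard GP posterior with the
nugget σ_n² on the training diagonal only; reported predictive variance is
that of the latent field (the nugget is excluded — it would add a constant
and carry no spatial information for planning). Log-space predictions are
mapped back to the measurement scale with the exact log-normal moments
ŷ = exp(f̄ + v/2), Σ_y² = ŷ²(eᵛ − 1), which makes the predictive variance
scale with the predicted mean — the property the planner exploits to seek
both maxima and uncertainty.

Implementation notes:

* The training covariance K_{S,S} + σ_n²I depends only on the (fixed)
  training space-time coordinates, so `fit()` Cholesky-factorises it once;
  the evaluation time τ_now enters only the cross-covariance K_{*,S},
  rebuilt per prediction. This is algebraically identical to re-evaluating
  the full system each call, at a fraction of the cost.
* m_GP is recomputed from the current training set at every refit, so the
  prior mean tracks the data the vehicle actually holds.
* Non-positive readings are clipped to a configurable floor
  (default 0.01 µg/L) before the log — real fluorometers emit zeros.
* Exact duplicate (location, time) rows are merged by averaging before the
  solve to protect conditioning; an empty training set predicts the prior
  (m_GP = 0, variance σ_c²) with a warning.
* σ_c and σ_n are standard deviations of z. A config switch
  (`sigma_values_are: variance`) reinterprets configured values as
  variances for users whose records follow the other convention.

Default hyperparameters (field scale): M = (600, 600, 3) m, M_τ = 10000 s,
σ_c = 1.6, σ_n = 0.7. De-correlation lengths should be chosen relative to
the grid cell size and the operational-area extent; see "Scaled-down
experiment" below for how they are rescaled on a smaller volume.

## Grid segmentation and data exchange

Raw >1 Hz sensor streams are segmented onto a shared n_x × n_y × n_z grid:
a cell receiving new measurements is overwritten with the mean value and
mean time of the *new* batch only (temporal de-correlation makes superseded
values irrelevant), untouched cells keep their data, and the model trains
on one point per occupied cell (cell centre, cell timestamp). This bounds
the GP's sample size by the grid size and gives every agent the same
vocabulary of cell numbers for communication.

Wire format: a 10-byte header (message id, vehicle id, two float32
coordinates) followed by fixed-width records of n_c quantized channel
bytes, a UInt16 cell number and a quantized UInt8 time; record size
n_d = 3 + n_c, at most ⌊320/n_d⌋ records per message (340-byte SBD limit
minus 20 bytes of driver overhead), all fields big-endian. Channel values
are quantized linearly in ln(value) over a configured range (default
0.01–100 µg/L), giving uniform relative precision (~1.8 % per step) on a
log-normal quantity; time is quantized in whole minutes since the mission
epoch, saturating at 255. Quantization round-trip error is bounded by half
a step on the log scale.

The operator hub keeps, per reporting vehicle, the newest record per cell
and the vehicle's last surface fix. A reply to a surfacing vehicle carries
the other vehicles' positions (as plain numbers — the fleet is small) and
their cell records not yet delivered to that vehicle, newest first, within
the same record budget; delivery is tracked per (recipient, reporter, cell,
time code) so nothing is re-sent endlessly. Repeated exchange rounds make
all on-board grids converge to identical codes for all reported cells.

## Planner

Pilot survey: vehicle n_v of N_v crosses the volume at
x = V_x(2 n_v + 1)/(2 N_v) from y = 0 to y = V_y, undulating between the
surface and the maximum depth (default: two full down-up cycles per
crossing), seeding the model at all depths. Adaptive phase: from the
current position, 3 n_θ candidates (n_θ = 8 headings by default, radius r =
one horizontal cell extent, depth offsets ±one vertical cell extent) are
screened against the volume and scored with

    U(x) = k_μ ŷ(x) + k_σ Σ_y²(x) − Σ_{k≠v} (k_l / d_k(x))²,

point-evaluated at the candidate's 3D position at the current time. The
separation term uses horizontal distance only (the volume is far wider than
deep) and is normalised so that k_l is the standoff radius at which the
penalty per neighbour equals 1; a candidate exactly on top of a neighbour
scores −∞. Exact ties break to the lowest candidate index, making the
planner deterministic. Stale fleet positions are used as-is by default
(an optional maximum age drops them).

## Synthetic bloom fields

The generator produces strictly positive fields whose log values combine:

1. a deterministic vertical profile with a Gaussian subsurface maximum
   (default depth 30 m, width 15 m);
2. an anisotropic Gaussian random field (spectral smoothing of white noise;
   default squared-exponential lengths 300 m horizontal, 15 m vertical);
3. a configurable number of discrete Gaussian patches (default 2) near the
   subsurface maximum.

The sum is standardised to a target log mean and sd (defaults ln 2 and 1.6,
the model's process scale), so values are approximately log-normal by
construction, with coherent patches several grid cells across. Sensing adds
multiplicative noise exp(ε), ε ~ N(0, σ_n²), the form consistent with the
model's log-space nugget.

What the generator does *not* emulate: advection and temporal evolution of
the bloom (fields are static by default, as in the convergence experiments),
fine-scale variability below the generator grid (~25 m), NPQ-type
depth-dependent sensor bias, and navigational drift. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
fleet-size behaviour, not performance on a dynamic ocean.

## Mission simulator

Per tick (default 10 s) each vehicle advances toward its waypoint at its
nominal speed (drawn once per mission from 1.0–1.5 m/s) and takes one noisy
sample while submerged. On waypoint arrival the buffer is segmented, the
model refitted, and the next waypoint chosen. Every exchange period
(default 600 s) the vehicle surfaces — instantaneously; no travel time is
charged, and the logged surface position is its (x, y) at depth 0 — sends
its unsent cell records (newest first, truncated to the record budget, the
rest kept queued), and merges the hub's reply into its grid (newer time
wins per cell) and fleet state. All randomness flows from one seed through
named substreams, so identical (seed, config) reproduce byte-identical
logs.

Model quality is scored at every exchange and at mission end as the RMSE
between the on-board posterior at all grid-cell centres and the truth
field. The primary scale is the log scale (f̄_* against ln truth): the
nugget σ_n is a log-space, unitless quantity, so "RMSE converges to the
nugget sd" is only meaningful there. A linear-scale (µg/L) RMSE of ŷ
against truth is also reported. The fleet value is the mean over vehicles;
"terminal" means each vehicle's last snapshot.

## Scaled-down experiment

The convergence experiment sized for a workstation (and used by
`scripts/acceptance.py` and the acceptance tests):

* volume 1000 × 1000 × 50 m, grid 10 × 10 × 5 (100 × 100 × 10 m cells);
* M = (400, 400, 6) m, M_τ = 10000 s: horizontal lengths scaled with the
  volume extent (600 × 1000/1500), vertical with the cell height
  (3 × 10/5). Keeping the field-scale M_z = 3 m against 10 m cells would
  decouple the depth layers entirely: candidate variance pins at the prior,
  the utility degenerates to e^{2f̄}-weighted hotspot-parking, and the
  fleet stops exploring. De-correlation lengths are operator inputs tied to
  the grid and area, so they rescale with them;
* σ_c = 1.6, σ_n = 0.7; k_μ = k_σ = 1, k_l = 300 m; tick 10 s, exchange
  period 600 s;
* mission duration 2400 s — the single-vehicle convergence time of the
  full-scale study (6000–7000 s on a 3000 m volume) scaled by the volume
  ratio — by which time the 4-vehicle RMSE curve has plateaued;
* 10 replicate (field, mission) seed pairs per estimate; the median
  terminal fleet log-RMSE is the headline number.

Under these conditions the median terminal RMSE decreases monotonically
with fleet size, with the largest gain from one to two vehicles, and the
four-vehicle fleet converges to the nugget floor (≈0.7, the simulation's
irreducible noise level).

## Geostatistical validation

The empirical semivariogram γ(h) = mean of ½(z_i − z_j)² over pairs binned
by *horizontal* lag (default 100 m bins to 2000 m, optional seeded
subsampling) is fitted with the spherical model by least squares weighted
by per-bin pair counts. Vertical structure has far shorter scales and gets
its own variogram if needed; time is ignored for missions much shorter than
M_τ. A pure-nugget outcome (partial sill ≈ 0) flags the range as
unidentifiable instead of reporting a meaningless number. Empty lag bins
are reported as missing, never interpolated.

Distribution best-fit ranks log-normal, gamma, beta, Burr XII and normal
candidates, each fitted by maximum likelihood (location pinned at zero for
the positive-support families; the beta candidate is fitted on values
rescaled to (0, 1) with the Jacobian folded into its likelihood). SSE is
computed between each candidate's bin-averaged density (CDF increment over
bin width — the quantity a density-normalised histogram bar estimates) and
a 50-bin histogram; AIC = 2k − 2 ln L with k the free parameters. The
report is sorted by SSE with AIC alongside: Burr XII, with an extra shape
parameter, can tie a log-normal arbitrarily closely in SSE, and AIC is the
tie-breaker that accounts for it.

## Numerical choices and degenerate inputs

* GP solves use Cholesky factorisation; a non-positive-definite system
  (after the nugget) raises rather than silently regularising.
* Posterior variances are clipped to [0, σ_c²] to absorb last-digit
  round-off.
* Grid cells are half-open [lo, hi) with the last cell closed, so the far
  volume faces map to valid cells; the linear index is x-fastest
  (id = i_x + n_x(i_y + n_y i_z)) and is part of the wire protocol.
* Out-of-volume measurements are dropped with a counted warning (GPS
  jitter makes them routine), never errors; out-of-volume prediction
  queries are flagged, not dropped.
* The spherical variogram fit starts from (first-bin γ, max γ − first-bin
  γ, half the max lag) with non-negativity bounds; non-convergence raises
  with diagnostics.

## Known limitations

* The planner is myopic (one waypoint ahead); no receding-horizon search,
  obstacle avoidance or vehicle dynamics.
* No hyperparameter estimation: M, σ_c, σ_n are operator inputs; the
  variogram tools inform the choice but nothing is fitted automatically.
* Static truth fields in the convergence experiments likely flatter the
  accuracy achievable on a dynamic bloom.
* The flat-earth projection is adequate for volumes up to a few km across,
  not for basin-scale domains.
* Cell averaging of multiplicatively noisy values carries the usual
  log-normal mean bias (e^{σ_n²/2} in expectation at high sample counts);
  it is part of the method as specified (cells store arithmetic means) and
  is visible as a small positive bias in reconstructed log fields.
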
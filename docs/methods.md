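# Methods

## Problem setting

Cells carried by capillary-driven flow through parallel microchannels move
hundreds of pixels between consecutive video frames, look alike, and share
a common but time-varying bulk velocity. Tracking-by-detection under these
conditions fails for generic trackers built on small-displacement or
appearance assumptions. FloCyT exploits the two structural priors the chip
geometry provides: motion is strongly aligned with the channel axis, and
all cells ride the same bulk flow.

The package tracks *centroids only*: the input is a per-frame list of
`(x, y)` detections in pixels, with the image x axis pointing downstream.
No images are consumed (an optional rasterizer exists for visual QC).

## Tracking model

### State estimation

Each track carries a 4-state linear Kalman filter, `[x, y, vx, vy]`
(pixels, pixels/frame), with a constant-velocity transition (one frame per
step), direct position observation, and white-acceleration process noise.

Defaults, all exposed in `KalmanConfig`:

| parameter | default | units | rationale |
|---|---|---|---|
| `measurement_noise_scale` | 100 | px² | detection jitter of order 5–10 px per axis |
| `process_noise_scale` | 625 | px²/frame⁴ | acceleration scale σ_a = 25 px/frame² |
| `initial_position_var` | 100 | px² | one measurement's worth of uncertainty |
| `initial_velocity_var` | 10⁴ | (px/frame)² | the seed velocity is approximate; let the first detections dominate |

The process-noise scale is the one genuinely load-bearing choice, pinched
between two failure modes. It must be of the order of the largest
sustained acceleration in the flow: cells that transiently stop and
restart decelerate at up to ~100 px/frame² at the fast end of the velocity
grid, and a stiffer filter (σ_a below ~15 px/frame²) lags such ramps by
more than the backward association gate, after which the track is lost and
the identity fragments on every frame of the stop. But a more reactive
filter (σ_a of 50+) tracks the detection noise itself, and in slow dense
flow — where overtaking cells sit within a noise width of each other for
several consecutive frames — noisy predictions are what swap identities.
σ_a = 25 px/frame² is the smallest headroom that follows the ramps,
maximizing smoothing in the noise-limited regime.

### Anisotropic gated association

A predicted track position `p` and a detection `d` are a feasible pair iff

    -s_bk <= d_x - p_x <= s_fr   and   |d_y - p_y| <= s_ort

(closed intervals; a `flow_direction: -x` flag flips the parallel
component's sign for right-to-left flow). Feasible pairs cost their
Euclidean distance; infeasible pairs are excluded. The benchmark gates are
`s_fr=600, s_bk=200, s_ort=100` px. The minimum-cost maximal matching is
solved with the Hungarian algorithm; because standard solvers reject
infinities, infeasible entries carry a finite sentinel larger than the
total cost of any feasible matching, and sentinel pairs are discarded from
the solution, which simultaneously maximizes the number of feasible
matches. Cost ties resolve by the solver's deterministic row order.

### Bulk-flow initialization

The global velocity `v_g` is the mode of the smoothed 2D histogram of all
cross-frame centroid displacements `b_n - a_m` (full m×n cross product)
pooled over the first `n_frame_pairs` consecutive frame pairs (benchmark:
15 pairs, Gaussian kernel σ = 10 bins, 5 px bins). True bulk motion piles
coincident vectors into one bin; the spurious cross-pair vectors scatter.
Numerical details:

- Histogram bounds default to the association gates plus margin
  (flow axis: −s_bk−100 … s_fr+100; orthogonal: ±(s_ort+50)), keeping the
  search physically plausible and the histogram small.
- The histogram carries 3σ guard-band bins outside the configured bounds:
  smoothing runs on the extended array and the argmax is taken on the
  cropped core, so peaks near the bounds are not attenuated (zero-padded
  smoothing would bias the mode inward; kernel renormalization would bias
  it outward).
- Argmax ties resolve to the lowest flow-axis bin, then the lowest
  orthogonal bin — determinism over physical preference; ties essentially
  never occur on real counts.
- σ is interpreted in bins. Smoothing cost is bounded by the histogram
  size, not the number of displacement vectors.
- Empty frames skip their pairs; fewer available pairs than requested are
  used with a warning.
- Optionally (`refresh_v_g`), `v_g` is re-estimated every `n_frame_pairs`
  frames over a sliding window; default off, since the staged blend below
  takes over quickly anyway.

### Track lifecycle

Per frame, in order: predict every track; build the gated cost matrix;
assign; correct matched tracks (miss counters reset); increment miss
counters of unmatched tracks; delete tracks unmatched for more than
`max_missed_frames` (default 3) or whose *predicted* flow-axis position
left the ROI while unmatched (a track that matched a detection inside the
ROI survives — deleting on prediction alone would kill live cells at the
ROI edge); create a track for every unmatched detection inside the ROI.

New tracks are seeded with the staged blend

    v0 = alpha * v_l + (1 - alpha) * v_g,    0 <= alpha <= 1,

where `v_l` is the component-wise median of the Kalman velocities of
tracks at least 2 frames old. `alpha` is 0 until the active-track count
reaches `alpha_activation_tracks` (default 10), then jumps to its
configured value (default 0.7), so initialization adapts to temporal flow
variation once enough local evidence exists. Tracks are emitted from
birth; with ground-truth centroids as detections there are no false
positives to suppress with a tentative period.

Hypothesis trajectories record the **associated detection coordinates** on
matched frames; coasted frames emit nothing. This is the usual
tracking-by-detection output convention and makes scoring with a small
match radius exact.

### Per-channel variant

`track_per_channel` clusters detection y coordinates with 1D K-Means
(k = number of channels, fixed seeding), routes every detection to the
nearest band centre, and runs an independent tracker per band with
disjoint id ranges, suppressing cross-channel association. Clustering
pools the whole sequence by default: flow start-up is sparse, and a short
initial window can miss lanes entirely (a configurable window, extended to
at least 10 detections per channel, is available). With fewer pooled
detections than channels the variant refuses and plain tracking should be
used. On tilted recordings the y-only clustering mis-assigns lanes; the
variant assumes axis-aligned channels and does not try to detect tilt.

## Synthetic flow simulator

The generator emulates the benchmark's study conditions: 1500 frames at
30 fps, 1080×1920 px, 15 horizontal channels, and a per-dataset grid
(presets A–L) of base-velocity ranges `[v_min, v_max]`, total initialized
cells, and throughput (cells/s). Per-frame displacements of cell *i*:

    dx_i(t) = m(t) vx_i(t) + eta_x,    eta_x ~ N(0, 5²) px
    dy_i(t) = vy_i(t) + eta_y,         eta_y ~ N(0, 0.5²) px
    m(t)    = 1 + 0.15 cos(2 pi t / N)

Choices where the conditions are stated only qualitatively:

- **Base velocity**: truncated normal on `[v_min, v_max]`, mean at the
  interval midpoint, σ = (v_max−v_min)/6 — the interval read as the ±3σ
  effective support of the stated normal, so truncation clips ~0.3% of
  mass and the distribution stays genuinely normal-shaped.
- **Arrivals**: Poisson per frame at rate throughput/30, thinned once the
  configured cell total is initialized (the grid's totals equal
  throughput × 50 s, so the budget runs out at the end of the run). Entry
  x is jittered in `[0, v_base)` — a sub-frame arrival time — and the
  channel is uniform random. Cells leave when the centroid passes the
  right edge.
- **Stop-and-go** (default 5% of cells, one event each): linear
  deceleration to zero over 5 frames, a stationary hold of uniform 5–20
  frames, linear re-acceleration over 10 frames. An instantaneous halt
  would be a step discontinuity in velocity; an obstruction develops over
  finite contact time, and the ramp is what makes the event a *hard but
  fair* test of the filter rather than an unconditional identity loss.
- **Lateral motion**: constant per-cell `|vy| <= 0.5` px/frame, position
  clamped to the cell's channel band (geometric confinement); channel
  pitch 72 px, cell radii uniform 8–12 px, so cell diameter ≈ inner
  channel width.
- The RNG consumes an identical stream regardless of the noise scales, so
  runs at different σ share the same sampled cells for a fixed seed.

What the generator does **not** model — and what passing benchmarks
therefore cannot show: cell deformation and biomechanics, optics and
detection (tracking consumes exact ground-truth centroids, so detector
misses, merges and localization bias are absent), channel tilt, collisions
(fast cells pass through slow ones; overtakes are *harder* than reality in
one way — coincident centroids — and easier in another — no contact
dynamics), and the long-term monotone decay of real capillary flow beyond
the single cosine modulation period.

## Evaluation

CLEAR-MOT with Euclidean centroid distances and a 1 px match radius
(detections are exact ground-truth centroids, so correspondence is exact;
the radius is exposed for future detector noise). Per-frame
correspondence keeps the previous frame's pairings while both parties are
present within the radius, then matches the residual by minimum total
distance. Reported: MOTA `1−(FP+FN+IDSW)/n_gt`; IDSW (change of a ground
truth's matched hypothesis id relative to its most recent match); IDF1
under the optimal global one-to-one identity pairing (maximum co-located
frames, solved as an assignment problem); MT (identities matched in
≥ 80% of their frames, inclusive). Tests cross-check all four against an
independent literal-definition reference implementation that uses
brute-force per-frame matching and networkx max-weight matching.

## Known limitations

- Identity through *birth-time crossings* is unrecoverable in principle:
  when two cells enter the same lane within a frame of each other, both
  tracks are seeded with the same blended velocity, and if the true paths
  cross between two samples, crossed and uncrossed interpretations are
  both consistent with the detections. This is the dominant residual
  switch source in noiseless runs (a few tens of switches per ~2000 cells
  at benchmark densities) and bounds attainable IDSW away from zero.
- Under detection noise, *multi-frame near-coincidences* are noise-limited:
  two slow cells overtaking (or a cell passing through a stopped one —
  the simulator has no collision handling) can stay within ~2 noise widths
  of each other for several frames, and the position-only Euclidean cost
  then carries little identity information. This dominates residual
  switches in the slowest, densest benchmark preset.
- Fixed gates assume the velocity scale is known; the adaptive-gate
  variant (gates from the current velocity estimate) is a recognized
  extension and is not implemented.
- Axis-aligned flow is assumed throughout; tilted channels need
  pre-rotation upstream of the tracker.

## Problem sizes used in tests

The acceptance-level benchmark runs all twelve presets at full scale
(1500 frames, up to 5000 cells). Unit and property tests run the same
physics on shortened runs (60–400 frames) chosen so every mechanism they
probe (spawning, stop events, lane clustering, noise scaling) is well
represented while the whole suite stays fast.
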
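# Methods

## Models

### Baseline tracker

Tracking-by-detection with an 8-dimensional linear Kalman state per
track, `(xc, yc, w, h, dxc, dyc, dw, dh)` — box centre, size and their
per-frame rates — under a constant-velocity transition (Δt = 1 frame).
Process and measurement noise are diagonal and scaled by box height
(position std = h/20, velocity std = h/160 per frame), the standard
SORT-family heuristic; both carry a configurable multiplier.

Association is two-stage. Detections are split by confidence:
*high* (s > τ, default τ = 0.50), *low* (η < s ≤ τ, default η = 0.10);
scores at or below η are discarded. The boundary score s = τ goes to
the low group. Stage 1 matches confirmed + lost tracks to the high
group by minimising Σ(1 − IoU) with `scipy.optimize.linear_sum_assignment`;
matched pairs below the stage's minimum IoU (0.30) are undone. Stage 2
matches the remaining confirmed/lost tracks to the low group the same
way. Tentative (not yet confirmed) tracks see only the high-confidence
leftovers of stage 1 — new tracks start only from unmatched
high-confidence detections, and an unmatched tentative track is deleted
immediately, which keeps one-frame false positives from ever being
emitted. Confirmed tracks that miss a frame become *lost* but keep
predicting; after `max_lost = 30` further unmatched frames they are
deleted. Confirmed pairs with mutual IoU > 0.85 are treated as
duplicates and the younger (higher-id) one is deleted. Only confirmed
tracks matched in the current frame are emitted, so the output contains
no extrapolated boxes.

The lifecycle constants (`n_init = 3`, `max_lost = 30`, duplicate IoU
0.85) follow common SORT-family practice; all are configurable. Lost
tracks take part in stage-1 association. Camera-motion compensation is
omitted — the microscope stage is static.

### Heading-aware EKF

State `(x, y, v, θ)`: position (px), scalar speed (px/frame), heading
(radians in (−π, π]). Motion model (unicycle map):

    x ← x + v Δt cos θ
    y ← y + v Δt sin θ
    v ← v,  θ ← θ

with analytic Jacobian

    [1  0  Δt cos θ   −v Δt sin θ]
    [0  1  Δt sin θ   +v Δt cos θ]
    [0  0  1           0         ]
    [0  0  0           1         ]

Only position is observed (H selects the first two components), so
R is 2 × 2 even though Q is 4 × 4: Q = α σ_q² I₄, R = β σ_r² I₂ with
σ_q = σ_r = 1 px and α = β = 1 by default — the operating point at
which the tracking metrics are flattest under the α, β ∈ {0.5, 1, 2}
sensitivity grid. The gain is computed by solving the innovation
system rather than forming an explicit inverse; a singular innovation
covariance raises instead of propagating NaNs. After each update the
polar velocity is canonicalised — if ‖(v cos θ, v sin θ)‖ > 1e−4 then
θ ← atan2(v sin θ, v cos θ) and v ← |v|, which flips a negative speed
into a π-rotated heading without changing the velocity vector — θ is
wrapped to (−π, π] and P is re-symmetrised as (P + Pᵀ)/2.

A new identity's filter starts at the first detection with v = 0,
θ = 0 and a diagonal P (position var 10 px², speed var 25, heading var
π²): speed and heading are unobservable from one detection, so they
start vague and converge over the next few updates. These
initialisation variances are configurable.

**Velocity-only ablation variant.** The `velocity_only` state mode
implements the [x, y, v] ablation: θ is removed from the estimated
state (zero process noise, Jacobian columns coupling position to θ
zeroed, zero initial θ variance) and is instead carried forward from
the displacement direction of successive *filtered* positions. The
prediction still follows the carried heading, but heading error is no
longer reduced by the filter — which is exactly the degradation the
ablation measures.

### Identity reassignment

The layer maintains: an alias table baseline-id → final-id, one EKF
per final id, and a lost registry (final id → EKF + last frame seen).
Per frame, for each baseline output:

1. Known baseline id → its final id (if the final id had been retired
   to the lost registry because the baseline coasted through a short
   gap itself, it is restored silently — not counted as a merge).
2. Unknown baseline id → every lost EKF is rolled forward to the
   current frame (one predict per elapsed frame, so positional
   uncertainty grows with the gap) and the candidate with minimum
   Euclidean distance to the detection centroid is revived **iff**
   that distance is under the gate; ties break to the lower final id.
   Otherwise a fresh final id is minted.
3. The resolved identity's EKF runs one predict + update with the box
   centroid. Box size passes through from the baseline unfiltered.

After the frame, identities not emitted move to the lost registry;
entries older than `max_lost = 30` frames are pruned permanently along
with their aliases (an identity absent exactly `max_lost` frames is
still revivable; one frame more and it is gone). When a lost identity
is revived through a *new* baseline id, aliases it held from before
the loss are dropped: otherwise the baseline could later resurrect the
old alias and the same final id would be live under two baseline
tracks at once. A final id emitted twice in one frame is impossible by
construction and asserted.

The gate defaults to a fixed δ = 30 px — the middle of the {15, 30,
45} px sensitivity range, at which identity recovery and false
reassignment balance. A `covariance_scaled` mode is provided
(gate = c·√(P₀₀ + P₁₁)) for an uncertainty-driven gate; it is not the
default because the fixed-pixel form is what the sensitivity analysis
characterises. Matching is greedy per detection in detection order, as
in the layer's algorithmic statement; a frame-global optimal variant
is out of scope. With δ = 0 the layer never merges and reproduces the
baseline's id structure exactly.

### Evaluation metrics

CLEAR-MOT with temporal continuity: per frame, surviving previous
correspondences with IoU ≥ 0.5 are kept, the remainder matched by
optimal IoU assignment at the same threshold. MOTA = 1 − (FN + FP +
IDSW)/|GT boxes|; an id switch is counted when a ground-truth object's
matched prediction id differs from the one it was last matched to.
MOTP is reported as the mean (1 − IoU) over matches — a dimensionless
distance in [0, 1], matching how values like 0.467 are conventionally
tabulated. Identity metrics (IDF1/IDP/IDR) use one global bipartite
matching between gt and predicted trajectories minimising misses plus
false positives under exclusive assignment, with dummy rows/columns so
unmatched trajectories pay their full length; IDTP is the summed
per-frame overlap of matched pairs. The 0.5 IoU threshold for both
families is standard MOT practice and configurable. Track duration
counts frames of actual presence (gaps excluded). Empty ground truth
is an error, never a NaN.

These metrics are implemented in-package on numpy/scipy and verified
against hand-computed scenes and exhaustive enumeration oracles in the
test suite.

### Motility parameters

VCL = Σᵢ ‖pᵢ₊₁ − pᵢ‖ / T, VSL = ‖p_end − p_start‖ / T,
LIN = VSL/VCL ∈ [0, 1], with T the first-to-last-frame duration in
seconds. The reciprocal VCL/VSL is reported alongside because some
published CASA summaries tabulate the ratio in that orientation (their
"LIN" column exceeds 1 and numerically equals VCL/VSL); emitting both,
clearly labelled, lets either convention be checked. For tracks with
gaps, VCL sums only hops between consecutive frames by default —
bridging a gap with a straight hop would count unobserved path —
while VSL and T always span the first and last observed points;
`bridge_gaps=True` restores the literal all-hops sum. LIN is reported
as missing when VCL = 0.

## Synthetic data

The simulator generates what the method assumes and what its failure
modes need: curvilinear swimmers in a 640 × 480 px field at 50 fps.
Per object: speed ~ Normal(3, 1) px/frame truncated at 0, fixed over
the track; heading follows a random walk with per-frame increments
Normal(0, turn_rate_sd) (default 0.15 rad/frame; a constant-turn
component is available for filter-consistency tests); position follows
the unicycle map and reflects at the frame edges (heading mirrored),
so every identity exists in every frame and any measured overcount is
the tracker's fault alone. Boxes are fixed 15 × 15 px.

Degradation deletes or perturbs, never moves in time: independent
per-frame dropouts (default 5%), contiguous burst dropouts emulating
occlusion (start probability 1%/frame, length 3–10), explicit forced
occlusion windows for controlled experiments, isotropic Gaussian
centroid jitter (1 px), and a confidence mixture (15% of detections
drawn from [0.15, 0.50], the rest from [0.60, 0.99]) exercising the
two-stage association. All randomness flows from one seeded generator;
equal seeds give byte-identical files.

Named regimes: `low` (10 objects), `medium` (35), `high` (65 — the
crowded 60–70-per-frame band, with heavier dropout and turning),
`high_turn` (30 objects, 0.30 rad/frame turning, 2 px jitter — the
heading-ablation stress case), and `gap_test` (5 objects, clean
detections except four forced occlusion windows, three short enough to
recover and one of 36 frames, longer than the 30-frame lost buffer and
hence deliberately unrecoverable).

What the simulator does **not** reproduce: real detector behaviour
(correlated misses, size jitter, false positives from debris), head
oscillation around the flagellar axis, cells entering/leaving the
field, and appearance information of any kind. Passing tests therefore
demonstrate the identity-management mechanics under the stated motion
and dropout model, not end-to-end performance on clinical video.

## Numerical choices

- Assignment: `scipy.optimize.linear_sum_assignment`; optimality is
  cross-checked against exhaustive permutation search up to 6 × 6.
- Kalman gains via `np.linalg.solve` on the innovation system; both
  filters re-symmetrise the posterior covariance.
- The 8-dim filter floors box width/height at 1e−6 px after update.
- Boxes serialise at 6 significant digits; readers accept any decimal.
- Frame indices are 1-based; downsampling keeps frames with
  (frame − 1) mod k = 0 and renumbers from 1.
- Filter-consistency testing uses a constant-turn trajectory (3
  px/frame, 0.05 rad/frame, 300 frames, 2 px measurement noise); the
  filter there runs with σ_r = 2 (the known noise level) and
  σ_q = 0.5, reflecting the nearly deterministic motion.

## Problem sizes

Scenario-level experiments use 150-frame sequences (3 s at 50 fps):
5 objects (gap_test) to 65 (high density), with directional
comparisons aggregated over 20 seeds. These sizes give stable
directional statistics — the EKF layer's improvements hold in ≥ 15/20
seeds — while each run stays in the seconds range.

## Known limitations

- Reassignment is greedy per detection; two simultaneous reappearances
  near one lost prediction are resolved in detection order, not
  jointly.
- A revived identity can be wrong in dense fields — the gate is purely
  positional; there is no appearance cue to veto a merge, and a wrong
  merge shows up as an id switch in evaluation.
- During a gap the EKF extrapolates a straight ray at the heading held
  at loss time; a cell that turns sharply while occluded lands outside
  the gate and gets a new id (by design — the alternative is false
  merges).
- MOTA can go slightly negative on pathological inputs (FP + FN + IDSW
  exceeding the gt box count); this is inherent to the metric.
- The baseline's Kalman noise heuristics assume box size roughly
  tracks object scale; with the simulator's fixed 15 px boxes this is
  benign, but real detectors with volatile box sizes may need the
  noise multipliers retuned.
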
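# Methods

## Overview

`runvalue` attaches a goal-probability value to high-intensity runs in
football tracking data. The pipeline has four stages:

1. **Tracking data model** — long-format per-frame positions of 22 players
   and the ball at 25 Hz, possession intervals with binary goal outcomes,
   and a 25→5 Hz downsampling convention.
2. **Frame features** — a 22-dimensional vector per in-possession 5 Hz
   frame describing ball geometry and both teams' shape, motion and pitch
   control.
3. **Value model** — a gradient-boosted binary classifier estimating the
   probability that the possessing team scores before the possession ends,
   trained on possession outcomes propagated to every frame.
4. **Run valuation** — detection of sustained >5.5 m/s runs at 25 Hz,
   per-run movement metrics, and the value accrued per run: the mean
   smoothed frame value over the run minus the value at its first frame.

A synthetic match generator with logged ground truth stands in for
proprietary tracking feeds; it defines the study conditions under which the
pipeline is tested.

## Conventions

* Coordinates in metres, origin at the pitch centre; x runs goal-to-goal in
  [−52.5, 52.5], y in [−34, 34] on the default 105 × 68 m pitch. Each team
  has one attack direction (±x) per period, stored on the `Pitch`.
* Frame indices are 0-based and global within a match; intervals are closed
  on both ends.
* Downsampling keeps frames whose global index is ≡ 0 (mod 5). The grid is
  anchored at frame 0 for the whole match, so the number of retained frames
  inside a run depends on its alignment: a 122-frame run starting on frame
  1 retains 24 grid frames, while an aligned start would retain 25.
* Possessions never overlap; dead balls always split possessions, and
  frames between possessions belong to neither team.

## Frame features

Two overall features — ball distance and angle to the attacked goal — plus
ten per side (in-possession first): centroid x/y, ball-centroid distance
(total and along x), players strictly between the ball line and the goal
line, convex-hull area, mean 1 s and 5 s displacements, mean unsigned
angular displacement between consecutive 1 s movement vectors, and
pitch-control area. Column order is frozen in `FEATURE_NAMES`.

Choices a reader should know about:

* **Angle to goal** is measured against the *goal line*: the reference
  direction is the goal-line unit vector pointing from the goal centre
  toward the ball's half of the pitch. This is the only geometry that
  yields 90° for a ball at the pitch centre and 180° at the corner flag
  simultaneously; the angle lives in [π/2, π], with the tie at y = 0
  resolved to π/2.
* **Goalkeeper handling**: centroids, hulls and the displacement features
  use outfield players only; the beyond-ball count includes goalkeepers.
* Every frame is **oriented** so the possessing team attacks +x
  (coordinates are point-reflected through the pitch centre when needed),
  which makes the features invariant to reflecting the pitch together with
  swapping attack directions.
* **Pitch control** is a deliberately simple, deterministic model: each
  player projects an isotropic Gaussian influence (σ = 6 m) centred at
  position + velocity·τ (τ = 0.5 s, velocities by finite differences on
  the 5 Hz grid); each grid cell (1 m nominal; the batch pipeline uses 2 m
  for speed) goes to the team with the larger summed influence, ties split
  half-half, so the two areas sum exactly to the pitch area.
* **Masking, not zero-filling**: frames whose trailing 5 s history is
  incomplete (or whose hull is degenerate, fewer than 3 distinct outfield
  positions) are masked and dropped from training and prediction. Zero
  movement vectors contribute an angular displacement of 0.

## Value model

An xgboost binary classifier Θ maps the feature vector X_f of frame f to
V_f(p) = P(possessing team scores before possession p ends). Every 5 Hz
frame inside a possession inherits the possession's outcome G_p ∈ {0, 1} as
its label; dead-ball frames are unlabelled.

* **Hyperparameters** are drawn by random search (default 50 draws over
  tree depth 2–8, learning rate 0.03–0.3 log-uniform, 50–300 trees, row and
  column subsampling 0.6–1.0, minimum child weight 1–64 log-uniform) and
  scored by grouped cross-validated log-loss with *matches* as groups, so
  no match contributes to both training and validation. The best setting is
  refit on all training matches. Everything is deterministic given a seed.
* **No class re-weighting** despite goals being rare: the run value formula
  consumes the probabilities directly, so calibration is worth more than
  balanced accuracy.
* **Smoothing**: independent per-frame predictions show single-frame blips,
  so each prediction is replaced by the mean of itself and its immediate
  neighbours. The window never crosses a possession boundary; edge frames
  average the neighbours that exist. A weighted (1, 2, 1)/4 window is
  available via the `weights` argument; the uniform mean is the default.
* The same model output serves both perspectives: for out-of-possession
  analyses the number is read as *opponent* value accrued.

## Run detection and valuation

* **Speed** is the magnitude of the per-axis least-squares slope through
  the five 25 Hz frames centred on the current frame; the first and last
  two frames of any contiguous segment are undefined. For exactly linear
  motion the estimate is exact; on a 10 m-radius circle at 5 m/s the
  0.16 s window bias is below 0.01 m/s.
* **Runs** are maximal intervals with speed strictly above 5.5 m/s on
  every 25 Hz frame, kept when they span at least 25 frames (1 s). A
  single frame at or below the threshold terminates a run; dips are never
  bridged. Both knobs are arguments.
* **Acceleration** is the backward difference of speed on the 5 Hz grid
  (no extra smoothing; the 25 Hz data enter through the speed estimate).
  Runs report max |a|.
* **Tortuosity** is 1 − (straight-line displacement / path length) over
  the trailing 3 s window on the 5 Hz grid, in [0, 1); it is 0 when the
  path is shorter than 0.5 m (the ratio is undefined at zero path length,
  and the guard is irrelevant at run speeds) and undefined until 3 s of
  history exist. Runs report the maximum.
* **Phases**: a run crossing a possession change is split into maximal
  constant-phase segments (own team / opponent / neither in possession),
  each analysed separately; neither-segments carry no value. Each phase is
  valued with *its own* first grid frame as the reference V(f₁), keeping
  split segments self-contained.
* **Buckets**: negative (V < 0), positive-negligible (0 ≤ V < 0.014) and
  high (V ≥ 0.014). The default 0.014 cut-off is the 95th percentile of
  in-possession run values in the reference season; an empirical-percentile
  derivation (linear interpolation) is provided for new data.
* **Concurrency** counts teammate run *instances* overlapping a run by at
  least one 25 Hz frame — two separate runs by the same teammate count
  twice — so the count can exceed the number of teammates.

## Synthetic match generator

The generator emulates the statistical structure the method relies on, with
ground truth for every downstream stage. Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| duration | 600 s, one period | desk-scale stand-in for a match; long enough that a 150-match study carries ~10⁲ goal possessions |
| frame rate | 25 Hz | matches optical tracking feeds |
| movement noise scale | 1.5 m/s | typical non-sprint speed; non-sprint speed hard-capped at 3× this |
| sprint rate | 0.6 events·player⁻¹·min⁻¹ | ≈ 1322.5 runs per match / 22 players / 90 min |
| sprint target speed | U(5.0, 9.4) m/s | straddles the 5.5 m/s threshold so detection is non-trivial |
| sprint duration | lognormal(μ=0.4, σ=0.6) s, clipped to [0.7, 10] | mode ≈ 1 s, heavy right tail; 1–2 s runs dominate |
| curved-sprint fraction | 0.25, ω ∈ (0.25, 0.7) rad/s | exercises tortuosity |
| possession length | scale 12 s, end hazard growing with age (τ = 15 s), mean ≈ 8 s | real possession lengths are short and not heavy-tailed |
| dead-ball share / gap | 0.4 of non-goal ends; Exp(4 s) gaps | possessions split on dead balls; gaps have possession = none |
| goal hazard | logistic(−1.6 − 0.30·d) per tick | distance-only, monotone; ~1% of possessions score |
| line-height drift | OU, sd 8 m, τ 30 s per team | teams vary block height independently of the ball |
| attack push / defence retreat | 8 m / 4 m anchor shift | possession ebb and flow |
| penetrating passes | p = 0.10 per retarget (0.5 follow-up), depth N(8, 4), lateral N(0, 12) | final-third entries that dwell, as real attacks do |

Players follow mean-reverting (OU-style) velocity noise around formation
anchors (4-3-3) that shift with the ball and with possession; sprints
override the noise with a ramp–plateau–decay constant-heading profile whose
plateau is logged as ground truth. The ball chases pass targets on the
possessing team, preferring advanced players.

**Latent goal fires.** Each second of possession a goal may "fire" with the
distance hazard, but fires only set the possession's outcome — they do not
end it; the possession runs to its natural turnover/dead-ball end. This
makes possession lengths independent of the outcome and makes the logged
per-tick generative probability — 1 − Π(1 − h_k) over the possession's
remaining ticks — *exactly* calibrated against the recorded outcomes, which
is what the reliability checks test against. The cost is that play
continues for a few seconds after a "goal" inside its possession; the label
semantics (binary outcome per possession) are unaffected.

**What the generator does not emulate**: tactical structure (offside,
set pieces, substitutions, marking), ball flight height, realistic pass
kinematics, scoreline effects, player heterogeneity. Passing tests on this
generator therefore demonstrates that the *pipeline machinery* recovers
known ground truth — injected sprints, a monotone distance signal,
calibrated probabilities — not that the fitted model would transfer to
real tracking data.

## Problem sizes and numerical choices

* The synthetic study uses 150 matches of 600 s (fixed seed), split 120
  train / 30 held out; features use a 2 m pitch-control grid in batch runs.
  These are the package's desk-scale choices; all constants are arguments.
* The library default for the random search is 50 draws with 3 folds; the
  batch study tunes with 8 draws and 2 grouped folds, which is where the
  CV curve flattens at this data size.
* Calibration is assessed with grouped out-of-fold predictions at the
  selected hyperparameters (every frame predicted by a model that never saw
  its match) binned into deciles; the slope is the n-weighted least-squares
  slope of empirical frequency on mean predicted probability.
* Feature-importance stability is assessed by re-tuning on random 60-match
  subsets under different seeds and ranking normalised gain.
* Ties and degenerate inputs: pitch-control ties split half-half; hulls
  with < 3 distinct points are flagged, not computed; zero-length movement
  vectors contribute zero angular displacement; a ball exactly at the goal
  centre has angle π/2.

## Known limitations

* Value attribution is at team level: every concurrent run during a
  high-value spell receives the full team value; the method cannot assign
  individual causal credit.
* The 5.5 m/s threshold is uniform, not individualised.
* Feature history windows do not straddle period boundaries only because
  synthetic matches are single-period; multi-period data should be split
  per period before feature building.
* The empirical high-value threshold (95th percentile) is sensitive to the
  value model's scale on small studies; the reference constant 0.014 is the
  default.
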
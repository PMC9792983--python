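# Methods

`gaitmat` analyzes pressure-walkway recordings of quadrupedal walking:
it segments limb prints into strike boxes, applies exclusion rules,
computes the standard spatiotemporal stride-cycle parameters, and
compares them across parkinsonian severity states with a mixed linear
model. Because no public recordings exist for this kind of apparatus,
the package ships a synthetic gait generator with exact ground truth;
every downstream stage is validated against it.

## Recording model

A recording is a stack of pressure grids (kPa) sampled at a fixed frame
rate from a mat of square resistive sensels. The default `paper_mat`
geometry is a 1.95 m x 0.45 m walkway at 4 sensels/cm² (5 mm pitch,
390 x 90 sensels) digitized at 30 frames/s. The sensel grid is the
authority for the active area; a vendor-quoted sensel count that
disagrees with `n_rows x n_cols` is treated as metadata.

Force aggregation converts pressure to kilogram-force:
`F = sum(p_i · 1000 · pitch²) / g0` with `g0 = 9.80665 m/s²`; sensel
area is `pitch²` (square tiling). Weight calibration rescales a
recording so the mean whole-mat force over a quiet-standing window
equals the subject's weight; the scale factor is kept in metadata.

The on-disk `.pwm` dialect is UTF-8 text (header `key = value` lines,
then one `FRAME index timestamp` block per sample with `n_rows` rows of
`n_cols` pressures at 6 significant digits). The simulator quantizes
its pressures to the same 6 significant digits, so write → read is
bit-exact on everything it produces and files are diffable.

## Synthetic gait generator

The generator emulates a ~11 kgf primate (macaque-sized) crossing the
walkway in a lateral-sequence walk: limb cycle offsets LH 0, LF 0.25,
RH 0.5, RF 0.75 of a stride cycle, so each hind contact is followed a
quarter cycle later by the ipsilateral forelimb.

**Scheduling.** Stride-to-stride variation is drawn at the *body* level:
one cycle duration `T_k ~ N(T0, sqrt(sd_stance² + sd_swing²))` and one
cycle advance `L_k ~ N(L0, sd_length)` per stride, shared by all four
limbs. Each limb draws its own stance time
`stance ~ N(st0, sd_stance)` (truncated positive); swing time is the
cycle remainder `T_k − stance`, so stride = stance + swing holds exactly
in the ground truth. Per-limb stride lengths add a small jitter
(0.2 x `sd_length`) around `L_k`. Rationale: all four limbs ride one
trunk, so most stride-to-stride variation is common mode; fully
independent per-limb draws would let limb trajectories drift into one
another and produce spatially merged prints, which a walking animal
does not do. For the same reason `L_k` is truncated below at
`front_hind_spacing + print_length + 0.02 m` — a walker does not step
onto its own ipsilateral forelimb print.

**Placement.** Hind prints of cycle k sit at
`x = phase_hind · L0 + Σ L_j`; the ipsilateral front print of the same
cycle sits exactly `front_hind_spacing` ahead of it, making the
interlimb length (toe-to-toe ipsilateral distance) equal the spacing by
construction. Left/right prints sit `lateral_offset` either side of
the mat midline (sides defined relative to the travel direction). The
whole pass is centered on the mat; spans that do not fit raise a
configuration error.

**Rasterization.** Each stance paints an elliptical print
(`print_length x print_width`) whose per-frame total force follows a
double-peaked stance profile (loading and push-off peaks, mid-stance
valley, floor of 0.25 so contact pressure never vanishes inside the
stance). The center of pressure migrates from 20% to 80% of the print
length, heel to toe. Per-limb force is normalized to
`subject_weight / (4 · duty_factor)`, so whole-mat force averaged over
a stride cycle approximates the subject's weight (quasi-static
support; verified to 10% in tests). A frame shows contact when its
sampling interval overlaps the stance interval, which makes detected
stance durations unbiased against truth (quantization error is
symmetric around zero).

**Defaults** (naive state): stride length 0.50 m (sd 0.02), stance
0.55 s (sd 0.015), swing 0.275 s (sd 0.015) — duty factor 2/3, cadence
~291 steps/min over four limbs, speed ~0.6 m/s; spacing 0.25 m, prints
7 x 4 cm, weight 11 kgf. These are plausible magnitudes for a 10–12 kg
quadruped on a 1.95 m mat; they are free parameters of the simulator,
and only their ordering across severity states carries meaning.

**Severity presets** scale the baseline multiplicatively:

| state    | stance/swing time | stride length | all sds |
|----------|------------------:|--------------:|--------:|
| naive    | 1.00              | 1.00          | 1.0     |
| mild     | 1.15              | 1.00          | 1.3     |
| moderate | 1.35              | 0.95          | 1.8     |
| severe   | 1.75              | 0.80          | 2.5     |

Construction asserts the directional ladder: times lengthen (cadence
and speed fall) monotonically, variability never decreases, and stride
length is materially reduced only in the severe state. The severe
swing-time variance is 2.5² ≈ 6.3x the naive one. The severe
stride-length scale is 0.80 so the severe cycle length (0.40 m) stays
clear of the print-collision bound (0.34 m).

**Artifacts.** `inject_noise_blips` adds single-sensel events of 1–2
frames at locations that are never active (with a 4-sensel safety
margin, so blips cannot merge with prints or each other under
gap-tolerant segmentation). `truncate_end_prints` emulates a subject
stepping partly off the walkway: the spatially first and last prints
are translated to their nearest mat end and clipped by the boundary
until the on-mat area falls below the requested fraction of the full
print; ground truth marks them partial. Only end prints may be
truncated.

**Cohorts.** `simulate_cohort` nests passes in sessions in states, with
multiplicative session-level offsets (relative sd 0.02 by default) on
the stance/swing/stride means. `rasterize=False` skips the pressure
movie and returns ground truth only — the fast path for statistical
studies that operate at the parameter level.

## Footfall detection

Active voxels (pressure > 0 by default, matching "first and last
instance of non-zero data"; threshold configurable) are grouped by
gap-tolerant connected components in the (row, col, frame) volume: two
voxels connect when both spatial indices differ by at most
`spatial_gap_tolerance + 1` and frames by at most
`temporal_gap_tolerance + 1` (defaults 1 and 1, bridging single-sensel
or single-frame dropouts inside one physical print). The labeling is
implemented by sparse shifted-coordinate intersection plus union-find,
so its adjacency is *exactly* the stated neighborhood; tests verify
equality with an exhaustive flood-fill oracle on random volumes.

Each component yields a strike box: spatial bounding rectangle,
first/last frame of non-zero pressure, per-frame force profile (kgf)
over the rectangle, and ever-active sensel count (area).

**Exclusion rules.**
*Noise:* boxes spanning ≤ 2 frames (< ~67 ms at 30 frames/s) are
momentary events or incomplete stances and are removed. The boundary is
inclusive: a 2-frame box is removed, a 3-frame box retained.
*Partial end prints:* a box is removed only if it lies within
`end_zone_length` (default 0.15 m) of either mat end *and* its area is
below `partial_fraction` (default 0.75) of the median area of boxes
outside the end zones. The conjunction keeps full prints near the ends
and small prints mid-mat. "Size" is interpreted as area; the reference
is the per-pass median because prints of one subject are near-constant
in size. Both filters are idempotent and log every removal.

**Direction** is the sign of the least-squares slope of box centroid
column against first frame; heel/toe edges are then normalized so the
heel is the trailing edge. **Left/right** comes from the sign of the
centroid residual about the fitted midline trajectory, relative to the
travel direction (so mirroring the mat swaps labels, as anatomy
requires). **Front/hind** uses the temporal structure of each side's
track: same-side inter-onset gaps alternate short (hind → ipsilateral
front, the quarter-cycle offset) and long (front → next hind); the box
closing a short gap is the front. Alternation propagates labels even
when an end print was filtered out; sides without a usable alternation
stay `unassigned`.

**Pass validity** requires all four limb labels, no inter-onset
interval longer than `max_dwell` (default 1.0 s — stopping/hesitation),
and monotone progression along the travel direction with at most one
print length of backtrack. Progression is checked per limb track when
labels exist: the interleaved footfall order legitimately steps
backward *between* limbs (by up to ~`(2·spacing − stride)/2`), which is
not locomotor backtracking.

## Gait parameters

For consecutive boxes of one limb, with heel/toe edges d1/d2 of the
first box, heel edge d3 of the next, and times t1 (first contact), t2
(last contact), t3 (next first contact):

    stance length = d2 − d1   stance time = t2 − t1
    swing  length = d3 − d2   swing  time = t3 − t2
    stride length = d3 − d1   stride time = t3 − t1
    stride speed  = stride length / stride time

Additivity (stride = stance + swing) is exact by construction.
Positions are measured along the travel axis (signed by direction), so
mirrored passes give identical values. Stride speed is defined as
stride length over stride time — the only dimensionally consistent
per-stride speed.

Pass-level, over all retained boxes regardless of limb: `dN` spans the
first box's heel edge to the last box's toe edge; `tN` spans the first
to the last instance of non-zero pressure; cadence is
`n_stances / tN · 60` (all-limb steps/min) and gait speed `dN / tN`.
Values are stored at full precision; the reporting layer rounds cadence
half-up to an integer and speeds to two decimals (10 stances / 2.25 s /
1.90 m → 267 steps/min and 0.84 m/s).

Interlimb length is the distance between the leading (toe) edges of an
ipsilateral front/hind pair — "digits" and "leading edges" name the
same edge; each front box pairs with the same-side hind box nearest in
onset time.

The tidy parameter table has one row per (subject, state, session,
pass, limb, stride, parameter) with a front/hind `limb_group` column;
cadence and gait speed enter at pass level (`limb = "all"`).

## Statistics

`fit_state_model` fits a linear mixed model with state as fixed effect
(cell-means coding) and session — unique within state, hence nested —
as a random intercept, by REML (statsmodels `MixedLM`). Least-square
means are the fixed-effect level means; a session variance estimated at
the zero boundary is accepted as a boundary solution, not a failure.
Pairwise contrasts use the fixed-effect covariance; with more than two
levels p-values are Tukey-adjusted via the studentized-range
distribution (`q = |t|·√2`), which reduces to the ordinary t test at
two levels, so the adjusted p can never undercut the unadjusted one.
Contrast and CI degrees of freedom are `n_sessions − k` (the level at
which a between-session factor varies), falling back to `N − k` for
nearly unreplicated designs. `fit_baseline_subject_model` applies the
same machinery to naive-state data with subject as the factor.

Effect sizes follow Cohen's d reconstructed from least-square means and
standard errors: `s_i = se_i·√n_i`, pooled for unequal sample sizes;
|d| < 0.35 is small, 0.35–0.65 (inclusive) medium, > 0.65 large. The
reconstruction is isolated in `cohens_d_unequal` so an alternative
reading can be substituted.

`levene_hov` is the classic mean-centered Levene test (median centering
optional). One caveat the simulator makes explicit: swing times of the
four limbs within one stride cycle share the body cycle time and are
therefore correlated; feeding all of them to an iid test inflates its
size well above the nominal level. Variance studies therefore subsample
one swing value per stride cycle.

Recovery studies of the mixed model use cohorts with zero session-level
variance; with only a handful of sessions and real session variance no
mean ± 2·SE band is a 95% band, so coverage checks would conflate
estimator calibration with design limitations.

## Numerical choices and problem sizes

- Detection threshold: strictly positive pressure; gap tolerances 1
  sensel / 1 frame; all configurable.
- Seeds: every stochastic routine takes an explicit seed;
  `simulate_cohort` fans a root seed out through `SeedSequence` spawns,
  so runs are reproducible pass-by-pass and identical seeds give
  byte-identical `.pwm` files.
- The acceptance studies use 60–100 passes per state for full-pipeline
  parameter recovery, 200 replicates of n = 100 for Levene rates, and
  100 replicates of a 3-state x 4-session x 10-pass cohort for LS-mean
  coverage — sizes at which the Monte-Carlo error of the reported rates
  is a few percent.

## What the simulator does and does not show

Passing tests demonstrate that the pipeline recovers the parameters and
group-level contrasts of data whose generative structure matches the
simulator: clean elliptical prints, steady straight-line walking,
Gaussian parameter variation, isolated noise events, boundary-clipped
end prints. Real recordings add effects the simulator deliberately
omits: sensel drift and hysteresis, partially overlapping prints,
turning, hesitation and festination, within-print pressure asymmetry,
and non-Gaussian stride variation. Results on synthetic data bound what
the pipeline can do under its own assumptions; they do not certify
performance on hardware data. The severity presets reproduce the
*direction* of published group differences, not any subject's
magnitudes, which are not publicly available.

## Known limitations

- Overlapping prints are not separated beyond connected components; the
  simulator spaces prints so this situation does not arise in tests.
- Front/hind chaining relies on the short/long gap alternation of a
  lateral-sequence walk; pacing or trotting gaits would defeat it.
- The Cohen's d reconstruction from SE is one defensible reading of an
  under-specified convention.
- `validate_pass` detects stopping via inter-onset gaps; a subject
  creeping forward arbitrarily slowly but steadily is not flagged.
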
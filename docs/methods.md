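# Methods

## Measurement model

All angles are full 3-D included angles at a vertex joint,
θ = arccos(V_d·V_p / (|V_d||V_p|)), computed directly on camera-space
joint positions. The frontal/sagittal-plane vocabulary ("abduction in
the frontal plane", "flexion in the sagittal plane") is treated as a
description of the movement being performed, not as a projection step:
the two-vector formula contains no projection, and none is applied by
default. A `project_plane` flag on `joint_angle`/`angle_series` projects
both segment vectors onto the frontal or sagittal plane for sensitivity
analysis only.

Conventions that the sensor ecosystem leaves ambiguous, fixed here and
isolated so they can be flipped:

* **Coordinate frame** — x to the camera's left (the participant's right
  when facing the camera), y up, z from camera toward participant,
  origin at the sensor. Only `kinarom.skeleton.MIRROR_AXIS` and the
  simulator template encode this.
* **Elbow convention** — included angle, 180° = straight arm. Anatomical
  flexion would be 180° − θ.
* **"Hand"** in the segment triples means the `Hand*` joints proper, not
  `Wrist` or `HandTip` (configurable via `SegmentDefinition`).
* **Adduction triple** (Hand, Shoulder, Hip) is hand-referenced, which is
  anatomically unusual; it is kept verbatim as the system's operating
  definition and flagged as configurable.
* The cosine is clamped to [−1, 1] before arccos. Note arccos is
  √ε-conditioned near 0°/180°, so identity-pose round trips are exact to
  ~1e-6° rather than 1e-12°.

Frames in which any required joint is `not_tracked` (or missing) are
excluded from the series with a per-frame reason rather than silently
interpolated: a dot-product angle on missing joints is meaningless.

## Session reduction (AROM)

A session is nominally 30 frames at 30 Hz of one movement. The series is
smoothed with a centred running median (default window 5, shrinking at
the edges; window 1 disables smoothing), and

* **AROM** = maximum of the smoothed series,
* **mean, SD** = mean and sample SD (n−1) of the smoothed series.

The reduction from 30 samples to a single session value is a genuine
design choice: max-of-smoothed-median captures the active limit while a
single flying-pixel spike cannot inflate it (a spike must survive ≥3 of
5 frames to move the median). The mean is emitted alongside because
group-level comparisons of held poses are more naturally made on means;
`PipelineConfig.compare_on` selects which statistic feeds the cohort
comparisons (default `mean`). One consequence to be aware of: median
smoothing trims the endpoint of a strictly rising ramp by up to half a
window, so peak-chasing use cases should set `window=1`.

Accuracy against a goniometer-set reference is reported as absolute
error (half-up to 3 decimals) and relative error in percent of the
reference (truncated to 2 decimals). Truncation, not rounding, is the
convention of the printed validation tables this package reproduces;
computations use decimal arithmetic so printed-table reproduction is
exact rather than float-approximate.

## Simulator

`pose_to_skeleton` builds a fully tracked 25-joint frame from a seated
template plus two prescribed angles. The upper arm is the hip→shoulder
direction rotated by the abduction angle within the frontal plane
(lateral raise); the forearm+hand segment is the upper-arm direction
tilted toward the participant's front by (180° − elbow included angle).
Both constructions preserve the prescribed included angles *exactly* for
any template proportions, which is what makes the zero-noise round trip
(< 1e-6°) a meaningful cross-validation of simulator and measurement
pipeline rather than a tautology: the two sides use independent
geometric constructions (rotation matrices vs dot products).

Default anthropometry is child-scale — upper arm 0.28 m, forearm+hand
0.30 m, shoulder-to-hip drop 0.40 m, shoulder half-width 0.18 m — and
configurable; no published segment lengths existed to adopt.

**Noise.** Sensor noise was characterised at the angle level: six
calibrated presets ({1, 2, 3} m × {7, 73} lx) each carry the observed
mean and SD of a re-measured 90° arm (e.g. 2 m/73 lx → 91.65 ± 2.06°,
i.e. bias +1.65°, SD 2.06°; 2 m is the recommended operating distance).
Per frame the simulator draws `nominal + bias + N(0, sd)` for each
prescribed angle — an in-plane angular perturbation — rebuilds the
skeleton, then optionally adds isotropic positional jitter
(N(0, 0.003 m) per joint axis) to exercise the positional pipeline.
Preset lookups return **zero** positional jitter by default: the preset
SD already characterises the *total* noise at the angle level, and
jitter on top would double-count it (~+1° angular SD at these segment
lengths), breaking the calibration self-consistency property. Clipping
the noisy angles to [0, 180] is a no-op at the calibrated noise scales.

**Cohorts.** `simulate_cohort` draws per-participant true limits from
group-level distributions (abduction: control 108.51 ± 19.67° vs
hemiparesis 81.60 ± 26.94°; elbow flexion included angle: 100.85 ± 37.88
vs 116.15 ± 44.09°; assessment totals 65 ± 1 vs 56 ± 10), simulates each
trial as a 30-frame *held pose* at the participant's limit under the
2 m/73 lx preset, and generates a manual item sheet whose subtotal
matches the participant's target total minus the nominal 6 automated
points. Trials are held poses, not reach ramps, because the elbow is
measured as an included angle: a flexion trial that started extended
would have its session maximum pinned at ~180° and erase the flexion
signal. Ground-truth angles and targets are retained on each record for
recovery tests.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: occlusion and limb self-crossing, skeleton-
fitting failures that displace joints coherently rather than as angular
noise, soft-tissue and clothing artefacts, distance-dependent jitter
correlation, tremor spectra, and any illumination mechanism (the presets
are an empirical lookup, deliberately not a model). Conclusions about
real sensor performance rest on the empirical preset values, not on the
simulation.

## FMA scoring

The 33-item motor catalogue (sections A-I … A-V, B, C, D; 0/1/2 each;
total 0–66) fixes three automated items in section A-II — shoulder
abduction, elbow flexion, elbow extension, the movements a skeleton
stream can actually resolve — and leaves 30 items manual. Automated
scoring applies `2 if AROM ≥ full else 1 if AROM ≥ partial else 0` with
defaults abduction 150/90°, elbow flexion 130/60°, elbow extension
160/120° (included angle). These cutoffs are configuration, not
measurement: no published angle→ordinal mapping exists, so the defaults
sit at clinically typical full/partial active ranges and are overridable
per deployment. The elbow-extension item is scored from the flexion
trial's session maximum, which *is* the extension-side reach of that
recording.

Capacity bands come in three schemes because the published descriptions
disagree: the front-panel scheme (0–22, 23–31, 32–47, 53–66) leaves
48–52 unbanded; the cohort-share scheme (31–47, 47–52, 52–66) has
overlapping endpoints. The default `hybrid` scheme — [0,23) none,
[23,31) low, [31,47) limited, [47,52) notable, [52,67) total — is the
unique half-open partition consistent with both, and is the one that
reproduces the published 78 % "total performance" share for the
hemiparesis cohort (14/18). Both alternatives remain available
(`interface` returns `unclassified` in its gap; `discussion` resolves
overlaps top-down).

## Statistics

Group summaries are mean ± sample SD (n−1), rounded half-up to the
table's decimals. The rank-sum test pools both samples, assigns
mid-ranks to ties, and either

* **exact**: enumerates all C(nx+ny, nx) assignments of the pooled ranks
  (automatic for nx+ny ≤ 16, i.e. ≤ 12 870 assignments);
  p = 2·min(P(R ≤ r_obs), P(R ≥ r_obs)) capped at 1; or
* **normal_approx**: tie-corrected variance with continuity correction
  (scipy's asymptotic Mann–Whitney), the standard recipe at n = 18+18.

The approximation's accuracy is asymmetric: in the rejection-relevant
tail (exact p ≤ 0.1, nx,ny ≥ 4) it tracks the exact p within 0.02, while
mid-distribution (p ≈ 0.5) it is conservative by substantially more at
small n — it cannot flip a verdict there, but "within 0.02 everywhere"
would be a false claim and is not asserted. Classification shares round
percents half-up to integers (77.78 % → 78 %), so shares can sum to
100 ± 1.

Two published statistics are knowingly not reproduced and not chased:
the control-group age SD prints as 2.54 but computes to 2.55 from the
characteristics table (only the mean is asserted), and the FMA group
comparison prints p = 0.0004 where every standard rank-sum variant on
the published totals gives 0.00013–0.00018 (the published value was
presumably computed on sensor-scored totals that were never printed);
the package asserts H₀ rejection and agreement with an independent
implementation instead.

## Problem sizes and determinism

Every stochastic path takes an explicit integer seed (numpy Generator);
identical seeds give bitwise-identical streams, cohorts and reports. The
self-consistency acceptance check uses 1000 replicate 30-frame sessions
per calibrated preset (30 000 draws each, Monte-Carlo error on the mean
≈ 0.04°); unit tests use smaller replicate counts (40–60 sessions) with
correspondingly wider 4σ Monte-Carlo bands. The exact-test property
checks stay at nx+ny ≤ 10 (≤ 252 assignments per case) against an
independent brute-force enumerator that computes U by pairwise
comparison rather than rank sums.

## Known limitations

* Shoulder rotation, pronation/supination and wrist angles are out of
  scope — the 25-joint stream cannot express them; those FMA items stay
  manual by design.
* The AROM statistic is a maximum, so it is monotone under appended
  frames and upward-biased by ~+1.5 smoothed-noise SDs for a held pose;
  comparisons default to the session mean for this reason.
* The A-II angle cutoffs and the automated-item identities are
  configuration choices; deployments should calibrate them against local
  clinical practice before scores are interpreted.
* One printed bench row (right shoulder, 60° target) was published from
  an unrounded mean and cannot be reproduced exactly from the printed
  mean; it is flagged in `kinarom.reference` and tested with a one-digit
  tolerance.
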
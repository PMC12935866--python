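# Methods

## The quantity being estimated

For one subject, the analysis input is an S × T × 3 array of COM velocity
(mm/s): S heel-strike-to-heel-strike gait cycles, each time-normalized to T
points spanning 0–100% of the cycle, over the AP/ML/VT axes (x = AP
+forward, y = ML +left, z = VT +up, treadmill/belt frame). At each cycle
point the unbiased (S−1) sample covariance Σₜ (mm²/s²) of the S velocity
vectors summarizes stride-to-stride variability. Derived quantities:

- directional SD waveforms: square roots of diag Σₜ (mm/s);
- variability ellipsoid: semi-axes k·√λᵢ from the eigendecomposition of Σₜ,
  volume V(t) = (4/3)πk³√det Σₜ (mm³/s³);
- subject summary: cycle means of V(t) and of the three SD waveforms, and
  the *total variability* = sum of the three cycle-mean SDs;
- the gait tube: the stride-mean velocity trajectory with each ellipsoid
  projected into the local Frenet–Serret normal plane, cross-sections
  smoothed over the cycle.

k is the SD-scaling constant of the ellipsoid. The default k = 1 (a
one-standard-deviation ellipsoid) is an inference from unit consistency —
with k = 1 the product of realistic directional SDs (tens of mm/s)
reproduces the magnitude of reported volumes (~10⁵–10⁶ mm³/s³), whereas a
95%-confidence χ² scaling would inflate volumes ~22-fold. It is exposed as
a parameter everywhere.

## Signal preparation

Raw inputs are five pelvis-marker trajectories (SACR, LASI, RASI, LPSI,
RPSI; mm; 60 Hz) and a vertical GRF channel (N). The chain is:

1. **Filtering** — zero-phase (forward–backward) 4th-order Butterworth
   low-pass, cutoff 6 Hz, applied to positions. Filtering and
   marker-averaging are linear and commute, so the implementation filters
   the COM average once. Both settings are configurable; 6 Hz/4th order is
   standard gait-kinematics practice.
2. **COM** — frame-wise arithmetic mean of the five pelvis markers. Marker
   gaps ≤ 5 frames are filled linearly; longer gaps invalidate the cycles
   they touch (dropped and logged, never interpolated away).
3. **Velocity** — central differences (second-order one-sided at the ends),
   mm/s.
4. **Heel strikes** — first sample at/above a 20 N vertical-GRF threshold
   on each upward crossing, with a refractory interval (default 0.4 × the
   median inter-event interval) to suppress within-stance re-crossings.
5. **Segmentation** — each cycle spans its two bounding heel strikes
   inclusive, resampled by cubic interpolation onto T = 101 points
   (0, 1, …, 100%), endpoints preserved exactly. Cycles outside 0.5–1.5 ×
   the median cycle duration are dropped and logged.

T = 101 and right-limb events are conventions, both configurable.

## Frenet frames and the tube

The tangent is the normalized derivative of the (lightly smoothed) mean
velocity trajectory; the normal is the tangent-orthogonal component of the
tangent derivative; the binormal completes the right-handed triad. Points
whose curvature component is below 1e−6 (in turning-angle-per-step units,
or relative to the curve's maximum) are flagged degenerate and inherit the
nearest non-degenerate normal, re-orthogonalized locally; a perfectly
straight trajectory receives a constant fallback frame. Successive normals
are sign-aligned to prevent frame flips. Orthonormality holds to 1e−8
everywhere by construction and is asserted in tests.

Cross-sections are the 2×2 marginal covariances P Σₜ Pᵀ (P = normal/binormal
rows). Ellipsoids always come from the *unsmoothed* covariance; the
temporal smoothing that makes the tube continuous is a centered circular
moving average (window in % of cycle, default 5%) applied to the projected
2×2 covariances and, before differentiation, to the mean trajectory. The
circular boundary encodes that 0% and 100% are the same event.

## Group statistics

- **Scalar metrics**: two-sided Wilcoxon rank-sum per metric (exact
  enumeration when n₁+n₂ ≤ 12 without ties, otherwise the normal
  approximation with midrank-tie and continuity corrections). No
  multiplicity correction across the five metrics, matching field practice
  for this analysis.
- **Waveform SPM**: point-wise pooled-variance two-sample t (Welch
  optional); the null distribution of max |t| over the cycle comes from
  group-label permutations — full enumeration when C(N, n₁) ≤ n_perm
  (deterministic, seed-free), otherwise n_perm random relabelings always
  including the identity. The critical threshold is the (1−α) quantile;
  each suprathreshold cluster gets p = the fraction of permutations whose
  max |t| reaches the cluster's max. Per-phase results take the minimum p
  over clusters overlapping the phase (1.0 if none). Permutation rather
  than random-field theory keeps the inference assumption-light and exactly
  testable; defaults α = 0.05, n_perm = 10 000, seed recorded.
- **Coordination**: per-group Pearson r between per-subject cycle-mean
  volume and total variability (one point per subject — the only reading
  consistent with n−3 Fisher denominators), p from t = r√(n−2)/√(1−r²);
  groups compared by Fisher r-to-z with a two-sided normal p.

## The synthetic generator

`generate_trial` simulates a walker whose COM velocity is a periodic
template plus phase-dependent noise, then renders it as five rigidly
offset pelvis markers (only the common origin moves, so COM-averaging is
exact by construction) and a stance-shaped GRF pulse train whose rising
edges are the ground-truth heel strikes (instantaneous onset at 0.35 ×
body weight, so threshold detection is exact).

Templates (belt frame, belt speed kept as metadata): VT is two-lobed (one
oscillation per step), ML one-lobed (one sway per stride), AP a zero-mean
biphasic fluctuation; amplitudes 180/100/120 mm/s give a closed velocity
loop with non-degenerate curvature. Stride durations jitter with CV 0.02.

Noise: per stride and axis, a smooth perturbation from a periodic Fourier
basis (3 harmonics) with standard-normal coefficients correlated across
axes (default correlation 0.2/0.15/0.1); the 1/√J normalization makes the
across-stride variance exactly 1 at every phase. Successive strides are
joined by a constant-power cos/sin smoothstep crossfade over the last 10%
of the cycle, keeping the noise C¹-continuous at heel strikes (a hard
switch would be smeared by the low-pass filter and visibly depress the
recovered SD near 0%/100%). The noise velocity is this unit process times
the SD envelope, so the generated phase-dependent directional SD *equals*
the envelope by construction — the basis of all recovery tests. The top
noise harmonic (≈2.5 Hz at a 1.2 s stride) stays below the 6 Hz analysis
cutoff.

Envelopes are raised cosines with exact cycle means; the presets use the
reported cycle-mean directional SDs (control 75.07/51.58/93.60 mm/s
AP/ML/VT; PAD 49.99/39.70/40.29) with the VT modulation peaking at 15% of
the cycle, so the control-vs-PAD contrast is largest during weight
acceptance. Stride period 1.2 s (control) / 1.3 s (PAD), stance fraction
0.62/0.65, body weight 750 N, belt speed 0.68/0.56 m/s (exposed, not
load-bearing). Cohorts draw per-subject lognormal envelope factors
(CV 0.15 per axis) and per-subject seeds deterministically from the cohort
seed.

**What the generator does not emulate**: real pelvis-marker soft-tissue
artifact, non-Gaussian or autocorrelated-beyond-one-stride variability,
asymmetry between limbs, GRF double-hump morphology and force-plate noise,
speed drift, and — importantly — the decoupling of volume from total
variability seen in impaired gait (per-subject scale factors make the two
strongly correlated in *both* synthetic groups). Passing tests therefore
validate the estimator and its statistics, not any clinical claim.

## Problem sizes and numerical choices

- Validation runs use S = 90 strides/subject (typical recording length);
  recovery tests use S = 500 with a 3-standard-error tolerance
  (SE of an SD ≈ σ/√(2(S−1))); the 100-replicate group-direction check
  runs the full pipeline at cohort sizes 132/52 with 40 strides/subject —
  a direction-of-effect property at cohort level, insensitive to S.
- SPM null calibration: 1000 replicate null cohorts (10 + 10 subjects,
  T = 101, 500 permutations); the family-wise false-positive rate must sit
  within 3 Monte-Carlo SEs of α = 0.05.
- Eigenvalues within −1e−8·scale of zero are clamped to 0; matrices more
  indefinite, asymmetric matrices, and non-orthonormal frames raise.
- Suprathreshold clusters use a strict > threshold comparison so the exact
  null (identical groups, t ≡ 0) yields no clusters.
- All randomness flows from explicit seeds; a full study re-run with the
  same config is bit-identical.

## Known limitations

- Single-limb cycle definition only; no bilateral merging or toe-off
  detection.
- CSV ingest only (mm or m auto-detected/overridable); no C3D reader.
- The Frenet normal is undefined where curvature vanishes; the propagation
  rule keeps frames orthonormal but their in-plane orientation there is a
  convention.
- Phase-level SPM p-values inherit the resolution 1/n_perm of the
  permutation null.
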
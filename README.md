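# gaittube

Continuous, phase-dependent analysis of walking stability from center-of-mass
(COM) velocity variability — the "gait tube" framework — with the group
statistics used to compare a healthy control cohort against a cohort with
impaired gait (e.g. peripheral artery disease, PAD).

Event-based stability metrics (margin of stability at heel strike) only see
discrete instants of the gait cycle. This package instead treats
stride-to-stride variability of 3D COM velocity as a continuous function of
the normalized gait cycle: at every cycle percentage *t* the S stride
velocity vectors give a 3×3 sample covariance **Σ**(t) over the
anteroposterior (AP), mediolateral (ML) and vertical (VT) axes, whose
eigendecomposition defines a variability ellipsoid with semi-axes
k·√λᵢ (mm/s) and volume

&nbsp;&nbsp;&nbsp;&nbsp;V(t) = (4/3)·π·k³·√det **Σ**(t)   (mm³/s³,  k = 1 by default)

Projecting these ellipsoids onto the Frenet–Serret normal planes of the mean
velocity trajectory and smoothing over the cycle yields a 3D "tube" whose
local thickness shows when, within the cycle, the walker is variable.

Group comparisons:

- **Scalar metrics** (cycle-mean ellipsoid volume, per-axis velocity SDs and
  their sum, the total variability) — Wilcoxon rank-sum tests.
- **Waveforms** (ellipsoid volume vs cycle %) — nonparametric 1D statistical
  parametric mapping (SPM): a point-wise two-sample t waveform with
  family-wise control from the permutation distribution of the maximum |t|,
  aggregated over the eight clinical gait phases (Initial Contact 0–2%,
  Loading Response 2–12%, …, Terminal Swing 87–100%).
- **Coordination** — Pearson correlation between ellipsoid volume and total
  variability within each group, compared across groups by Fisher's r-to-z:
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

Because no raw recordings ship with the package, a synthetic treadmill-trial
generator (`gaittube.synthetic`) produces pelvis-marker trajectories and a
vertical ground-reaction-force channel with *known* phase-dependent
directional variability, so the entire pipeline is validated by parameter
recovery. The `control` preset has large vertical variability (cycle-mean VT
SD 93.60 mm/s), the `pad` preset suppressed variability (40.29 mm/s), with
the group contrast peaking during weight acceptance (~10–20% of the cycle).

## Worked example

```python
import gaittube as gt

trial   = gt.generate_trial(gt.control_profile(), n_strides=90, seed=1)
strides = gt.strides_from_trial(trial.markers, trial.vgrf)  # (90, 101, 3)
summary = gt.subject_summary(strides, k=1.0)
print(f"AP/ML/VT SD: {summary.var_ap:.1f} {summary.var_ml:.1f} "
      f"{summary.var_vt:.1f} mm/s")
print(f"total variability: {summary.total_variability:.1f} mm/s")
print(f"mean ellipsoid volume: {summary.mean_ellipsoid_volume:.3g} mm^3/s^3")
```

prints

```
AP/ML/VT SD: 73.7 51.9 93.0 mm/s
total variability: 218.6 mm/s
mean ellipsoid volume: 1.47e+06 mm^3/s^3
```

i.e. the analysis recovers the control preset's generating SDs
(75.07 / 51.58 / 93.60 mm/s) within sampling error at 90 strides, and the
cycle-mean one-SD ellipsoid volume is of order (4/3)π·75·52·94 ≈ 1.5×10⁶.

The same from the shell:

```bash
gts simulate --profile control --subjects 1 --strides 90 --seed 1 --out trials
gts analyze --trial trials/subject_000 --out subject.json
gts report               # full two-cohort study with default config
gts plot --study-dir gts_out
```

`gts report` writes `summaries.csv`, `phase_table.csv`, `fig2.csv` (group
volume waveforms ± SD, control-minus-PAD difference, significance mask),
`spm.json`, `comparison.json`, tube geometry CSVs and a markdown report; on
the default synthetic cohorts every gait phase is flagged significant and
control exceeds PAD in volume and VT SD.

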
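"""Synthetic treadmill gait generator.

Produces pelvis-marker trajectories (SACR, LASI, RASI, LPSI, RPSI, mm, 60 Hz)
and a vertical ground-reaction-force channel whose rising edges define the
true heel strikes, for a walker whose COM velocity follows a periodic
template plus stride-to-stride correlated Gaussian variability.

The noise model is the key design element: each stride draws an independent
smooth zero-mean perturbation per axis from a low-order periodic Fourier
basis whose normalization makes the stride-to-stride variance exactly 1 at
every phase point; successive strides are joined by a constant-power
(cos/sin-weighted) crossfade over the last fraction of the cycle, which
keeps the process continuously differentiable across heel strikes while
preserving the exact unit variance.  The phase-dependent SD envelope of the
generated COM velocity therefore equals ``sd_envelopes`` by construction,
and the stride-level correlation between axes equals
``inter_axis_correlation``.  Because the noise is smooth, continuous and
band-limited below the analysis filter cutoff, the downstream pipeline can
recover the generator parameters — which is how the whole analysis is
validated.

Two presets emulate the study cohorts: a control-like walker with large
vertical (VT) velocity variability and a PAD-like walker with suppressed VT
variability, the group contrast peaking during weight acceptance
(~10-20% of the gait cycle).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from gaittube.signal_prep import ForceSignal, MarkerFrameSeries

__all__ = [
    "GaitProfile",
    "TrialTruth",
    "SyntheticTrial",
    "MARKER_OFFSETS_MM",
    "control_profile",
    "pad_profile",
    "profile_from_name",
    "generate_trial",
    "generate_cohort",
]

#: Rigid offsets of the five pelvis markers from the pelvis origin (mm),
#: axis convention x = AP (+forward), y = ML (+left), z = VT (+up).
MARKER_OFFSETS_MM: dict[str, tuple[float, float, float]] = {
    "SACR": (-130.0, 0.0, 20.0),
    "LASI": (90.0, 120.0, 0.0),
    "RASI": (90.0, -120.0, 0.0),
    "LPSI": (-110.0, 45.0, 10.0),
    "RPSI": (-110.0, -45.0, 10.0),
}

_PELVIS_ORIGIN_MM = np.array([0.0, 0.0, 950.0])

#: Margin simulated before the first and after the last heel strike (s), so
#: zero-phase filtering of the first/last stride sees real data on both sides.
_PAD_S = 0.3


def _phase_grid(n: int) -> NDArray[np.float64]:
    return np.linspace(0.0, 1.0, n, endpoint=False)


def default_velocity_templates(
    ap_amplitude: float = 120.0,
    ml_amplitude: float = 100.0,
    vt_amplitude: float = 180.0,
    n_points: int = 201,
) -> NDArray[np.float64]:
    """Periodic mean COM-velocity templates over one gait cycle (mm/s).

    AP: zero-mean biphasic fluctuation about the belt frame (belt speed is
    NOT added; it is carried in trial metadata).  ML: one-lobed alternating
    waveform (one lateral sway per stride).  VT: two-lobed waveform (one
    vertical oscillation per step, two per stride).  The three axes trace a
    closed loop in velocity state space with non-vanishing curvature, which
    keeps the Frenet frames of the mean trajectory well defined.
    """
    phi = _phase_grid(n_points)
    ap = ap_amplitude * (0.7 * np.cos(4 * np.pi * phi + 0.6) + 0.3 * np.cos(2 * np.pi * phi))
    ml = ml_amplitude * np.sin(2 * np.pi * phi)
    vt = vt_amplitude * np.sin(4 * np.pi * phi)
    return np.column_stack([ap, ml, vt])


def cosine_sd_envelopes(
    cycle_means: tuple[float, float, float],
    depths: tuple[float, float, float] = (0.30, 0.25, 0.45),
    peaks: tuple[float, float, float] = (0.50, 0.30, 0.15),
    n_points: int = 201,
) -> NDArray[np.float64]:
    """Raised-cosine SD envelopes with exact cycle means (mm/s).

    ``env_a(phi) = mean_a * (1 + depth_a * cos(2*pi*(phi - peak_a)))``; the
    cosine integrates to zero over the cycle so the cycle mean equals
    ``cycle_means[a]`` exactly.  The default VT peak at 15% of the cycle puts
    the largest vertical variability — and hence the largest group contrast
    between presets — in the weight-acceptance region of the cycle.
    """
    phi = _phase_grid(n_points)
    cols = []
    for m, d, p in zip(cycle_means, depths, peaks):
        if not 0.0 <= d < 1.0:
            raise ValueError(f"envelope depth must be in [0, 1), got {d}")
        cols.append(m * (1.0 + d * np.cos(2 * np.pi * (phi - p))))
    return np.column_stack(cols)


@dataclass
class GaitProfile:
    """Statistical description of one walker (or one group preset).

    Parameters
    ----------
    stride_period : float
        Mean duration of a full gait cycle (s).
    belt_speed : float
        Treadmill belt speed (m/s); metadata only, AP velocity is expressed
        in the belt (lab) frame.
    stance_fraction : float
        Fraction of the cycle the foot is loaded, in (0, 1).
    mean_velocity_waveforms : ndarray, shape (P, 3)
        Periodic per-axis COM-velocity templates (mm/s) sampled on a uniform
        phase grid over [0, 1); order AP, ML, VT.
    sd_envelopes : ndarray, shape (P, 3)
        Non-negative phase-dependent stride-to-stride SD of COM velocity
        (mm/s), same grid and axis order.
    inter_axis_correlation : ndarray, shape (3, 3)
        Correlation of the stride-level noise between axes; symmetric, unit
        diagonal, positive semidefinite.
    subject_heterogeneity_cv : float
        Coefficient of variation of the lognormal per-subject, per-axis
        factor applied to the SD envelopes when generating a cohort.
    body_weight : float
        Body weight (N); sets the vertical GRF plateau.
    sample_rate : float
        Common sampling rate of markers and GRF (Hz).
    stride_time_cv : float
        Coefficient of variation of stride duration (natural timing jitter).
    noise_harmonics : int
        Number of Fourier harmonics in the per-stride noise basis; the top
        harmonic (in Hz, ``noise_harmonics / stride_period``) must stay well
        below the analysis low-pass cutoff for the variability to survive
        filtering.
    crossfade_fraction : float
        Fraction of the cycle over which successive strides' noise draws are
        crossfaded with constant power, making the noise continuous at heel
        strikes.
    """

    stride_period: float = 1.2
    belt_speed: float = 0.68
    stance_fraction: float = 0.62
    mean_velocity_waveforms: NDArray[np.float64] = field(default_factory=default_velocity_templates)
    sd_envelopes: NDArray[np.float64] = field(
        default_factory=lambda: cosine_sd_envelopes((75.07, 51.58, 93.60))
    )
    inter_axis_correlation: NDArray[np.float64] = field(
        default_factory=lambda: np.array(
            [[1.0, 0.20, 0.10], [0.20, 1.0, 0.15], [0.10, 0.15, 1.0]]
        )
    )
    subject_heterogeneity_cv: float = 0.15
    body_weight: float = 750.0
    sample_rate: float = 60.0
    stride_time_cv: float = 0.02
    noise_harmonics: int = 3
    crossfade_fraction: float = 0.10
    name: str = "custom"

    def __post_init__(self) -> None:
        self.mean_velocity_waveforms = np.asarray(self.mean_velocity_waveforms, dtype=float)
        self.sd_envelopes = np.asarray(self.sd_envelopes, dtype=float)
        self.inter_axis_correlation = np.asarray(self.inter_axis_correlation, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.stride_period > 0:
            raise ValueError(f"invalid profile: stride_period must be > 0, got {self.stride_period}")
        if not self.sample_rate > 0:
            raise ValueError(f"invalid profile: sample_rate must be > 0, got {self.sample_rate}")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError(
                f"invalid profile: stance_fraction must be in (0, 1), got {self.stance_fraction}"
            )
        if self.mean_velocity_waveforms.ndim != 2 or self.mean_velocity_waveforms.shape[1] != 3:
            raise ValueError("mean_velocity_waveforms must have shape (P, 3)")
        if self.sd_envelopes.ndim != 2 or self.sd_envelopes.shape[1] != 3:
            raise ValueError("sd_envelopes must have shape (P, 3)")
        if np.any(self.sd_envelopes < 0):
            raise ValueError("sd_envelopes must be non-negative everywhere")
        R = self.inter_axis_correlation
        if R.shape != (3, 3) or not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("inter_axis_correlation must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("inter_axis_correlation must have a unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("inter_axis_correlation must be positive semidefinite")
        if self.subject_heterogeneity_cv < 0:
            raise ValueError("subject_heterogeneity_cv must be >= 0")
        if self.noise_harmonics < 1:
            raise ValueError("noise_harmonics must be >= 1")
        if not 0 < self.crossfade_fraction < 0.5:
            raise ValueError(
                f"crossfade_fraction must be in (0, 0.5), got {self.crossfade_fraction}"
            )


def control_profile(**overrides) -> GaitProfile:
    """Control-like preset: large VT variability (cycle-mean SD 93.60 mm/s)."""
    params = dict(
        stride_period=1.2,
        belt_speed=0.68,
        stance_fraction=0.62,
        sd_envelopes=cosine_sd_envelopes((75.07, 51.58, 93.60)),
        name="control",
    )
    params.update(overrides)
    return GaitProfile(**params)


def pad_profile(**overrides) -> GaitProfile:
    """PAD-like preset: suppressed VT variability (cycle-mean SD 40.29 mm/s)."""
    params = dict(
        stride_period=1.3,
        belt_speed=0.56,
        stance_fraction=0.65,
        sd_envelopes=cosine_sd_envelopes((49.99, 39.70, 40.29)),
        name="pad",
    )
    params.update(overrides)
    return GaitProfile(**params)


def profile_from_name(name: str, **overrides) -> GaitProfile:
    presets = {"control": control_profile, "pad": pad_profile}
    try:
        return presets[name](**overrides)
    except KeyError:
        raise ValueError(f"unknown profile preset {name!r}; expected one of {sorted(presets)}")


@dataclass
class TrialTruth:
    """Ground truth recorded alongside a synthetic trial (for recovery tests)."""

    profile: GaitProfile
    seed: int
    heel_strike_times: NDArray[np.float64]  # (n_strides + 1,) s
    heel_strike_indices: NDArray[np.int64]  # (n_strides + 1,) sample indices
    stride_periods: NDArray[np.float64]  # realized durations, strides 0..n
    noise_coefficients: NDArray[np.float64]  # (n_strides + 3, 2J, 3), strides -1..n+1
    subject_scale: NDArray[np.float64] = field(default_factory=lambda: np.ones(3))


@dataclass
class SyntheticTrial:
    markers: MarkerFrameSeries
    vgrf: ForceSignal
    truth: TrialTruth
    seed: int


def _periodic_interp(table: NDArray, phase: NDArray) -> NDArray:
    """Linear interpolation of a (P, 3) table periodic on phase in [0, 1)."""
    P = table.shape[0]
    x = (phase % 1.0) * P
    i0 = np.floor(x).astype(np.intp) % P
    i1 = (i0 + 1) % P
    w = (x - np.floor(x))[:, None]
    return table[i0] * (1.0 - w) + table[i1] * w


def _noise_basis(phase: NDArray, n_harmonics: int) -> NDArray:
    """(N, 2J) periodic Fourier basis, unit variance under i.i.d. N(0,1)
    coefficients: Var[sum_j (a_j cos + b_j sin)/sqrt(J)] = sum_j (cos^2 +
    sin^2)/J = 1 exactly, at every phase point."""
    j = np.arange(1, n_harmonics + 1)
    ang = 2 * np.pi * phase[:, None] * j[None, :]
    return np.concatenate([np.cos(ang), np.sin(ang)], axis=1) / np.sqrt(n_harmonics)


def generate_trial(profile: GaitProfile, n_strides: int = 90, seed: int = 0) -> SyntheticTrial:
    """Simulate one treadmill trial with ``n_strides`` complete gait cycles.

    The trial contains ``n_strides + 1`` heel strikes (stance pulses), so the
    cycle from each heel strike to the next is complete; a short margin is
    simulated before the first and after the last heel strike.
    """
    profile.validate()
    if n_strides < 2:
        raise ValueError(f"n_strides must be >= 2, got {n_strides}")
    rng = np.random.default_rng(seed)
    rate = profile.sample_rate
    n = int(n_strides)

    # Realized stride durations for strides 0..n (stride n pads the tail).
    jitter = np.clip(rng.standard_normal(n + 1), -3.0, 3.0)
    periods = profile.stride_period * (1.0 + profile.stride_time_cv * jitter)

    events = _PAD_S + np.concatenate([[0.0], np.cumsum(periods[:n])])  # c_0..c_n
    duration = events[-1] + _PAD_S
    t = np.arange(int(np.floor(duration * rate)) + 1) / rate

    # Stride membership: sample i belongs to stride k iff c_k <= t_i < c_{k+1};
    # idx = -1 before the first heel strike, n after the last.
    idx = np.searchsorted(events, t, side="right") - 1
    k = np.clip(idx, 0, n)
    per = np.where(idx < 0, periods[0], periods[k])
    start = np.where(idx < 0, events[0] - periods[0], events[k])
    phase = (t - start) / per

    # Correlated smooth noise: an independent coefficient block per stride
    # (-1..n+1), with a constant-power crossfade into the next stride's draw
    # over the last crossfade_fraction of each cycle.  cos^2 + sin^2 = 1 with
    # independent draws keeps the variance exactly 1 at every phase, while
    # the smoothstep weight makes the noise C^1-continuous at heel strikes.
    J = profile.noise_harmonics
    L = np.linalg.cholesky(profile.inter_axis_correlation + 1e-12 * np.eye(3))
    coef = rng.standard_normal((n + 3, 2 * J, 3)) @ L.T
    basis = _noise_basis(phase, J)
    z_own = np.einsum("sm,sma->sa", basis, coef[idx + 1])
    z_next = np.einsum("sm,sma->sa", basis, coef[idx + 2])
    delta = profile.crossfade_fraction
    u = np.clip((phase - (1.0 - delta)) / delta, 0.0, 1.0)
    w = 0.5 * np.pi * (3.0 * u**2 - 2.0 * u**3)  # smoothstep, zero-slope ends
    z = np.cos(w)[:, None] * z_own + np.sin(w)[:, None] * z_next

    velocity = _periodic_interp(profile.mean_velocity_waveforms, phase)
    velocity = velocity + _periodic_interp(profile.sd_envelopes, phase) * z

    # Pelvis origin position: integrate velocity (mm/s -> mm).
    dt = 1.0 / rate
    pos = np.empty_like(velocity)
    pos[0] = 0.0
    np.cumsum(0.5 * (velocity[1:] + velocity[:-1]) * dt, axis=0, out=pos[1:])
    pos += _PELVIS_ORIGIN_MM

    positions = {
        name: pos + np.asarray(off) for name, off in MARKER_OFFSETS_MM.items()
    }
    markers = MarkerFrameSeries(rate=rate, positions=positions, axis_convention="AP-ML-VT")

    # Vertical GRF: zero in swing, near-body-weight pulse in stance, with an
    # instantaneous rise at heel strike so the threshold crossing is sharp.
    u = (t - events[k]) / (profile.stance_fraction * periods[k])
    in_stance = (idx >= 0) & (u >= 0.0) & (u <= 1.0)
    fz = np.where(
        in_stance,
        profile.body_weight * (0.35 + 0.80 * np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2),
        0.0,
    )
    vgrf = ForceSignal(rate=rate, fz=fz)

    hs_idx = np.searchsorted(t, events, side="left")
    truth = TrialTruth(
        profile=profile,
        seed=seed,
        heel_strike_times=events,
        heel_strike_indices=hs_idx.astype(np.int64),
        stride_periods=periods,
        noise_coefficients=coef,
    )
    return SyntheticTrial(markers=markers, vgrf=vgrf, truth=truth, seed=seed)


def generate_cohort(
    profile: GaitProfile,
    n_subjects: int,
    seed: int = 0,
    n_strides: int = 90,
) -> list[SyntheticTrial]:
    """Simulate a cohort: per-subject SD envelopes jittered by a lognormal
    factor with CV ``profile.subject_heterogeneity_cv`` (independently per
    axis), per-subject seeds derived deterministically from ``seed``."""
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    rng = np.random.default_rng(seed)

    subject_seeds: list[int] = []
    seen = set()
    while len(subject_seeds) < n_subjects:
        s = int(rng.integers(0, 2**31 - 1))
        if s not in seen:
            seen.add(s)
            subject_seeds.append(s)

    cv = profile.subject_heterogeneity_cv
    sigma = np.sqrt(np.log1p(cv**2))  # lognormal with mean 1, CV = cv
    trials = []
    for s in subject_seeds:
        scale = np.exp(sigma * rng.standard_normal(3) - 0.5 * sigma**2)
        subject_profile = dataclasses.replace(
            profile, sd_envelopes=profile.sd_envelopes * scale
        )
        trial = generate_trial(subject_profile, n_strides=n_strides, seed=s)
        trial.truth.subject_scale = scale
        trials.append(trial)
    return trials
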
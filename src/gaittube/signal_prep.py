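"""From raw marker + GRF streams to time-normalized COM-velocity strides.

The processing chain is: zero-phase low-pass filtering of marker positions,
COM as the frame-wise mean of the five pelvis markers, central-difference
differentiation to COM velocity, heel-strike detection from the vertical GRF
threshold crossings, and segmentation of each heel-strike-to-heel-strike
cycle onto a fixed grid of T points spanning 0-100% of the gait cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

logger = logging.getLogger(__name__)

__all__ = [
    "PELVIS_MARKERS",
    "AXES",
    "MarkerFrameSeries",
    "ForceSignal",
    "ComTrajectory",
    "StrideSet",
    "com_from_pelvis",
    "lowpass",
    "differentiate",
    "detect_heel_strikes",
    "segment_and_normalize",
    "strides_from_trial",
]

#: The five pelvis markers whose average approximates the COM position.
PELVIS_MARKERS: tuple[str, ...] = ("SACR", "LASI", "RASI", "LPSI", "RPSI")

#: Axis order used throughout: anteroposterior, mediolateral, vertical.
AXES: tuple[str, str, str] = ("AP", "ML", "VT")

#: Marker gaps up to this many frames are filled linearly; longer gaps
#: invalidate the gait cycles they fall in.
MAX_GAP_FILL_FRAMES = 5


@dataclass
class MarkerFrameSeries:
    """Synchronized 3D marker trajectories (mm)."""

    rate: float
    positions: dict[str, NDArray[np.float64]]
    axis_convention: str = "AP-ML-VT"

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        lengths = {v.shape[0] for v in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError(f"markers have mismatched lengths: {sorted(lengths)}")
        for name, v in self.positions.items():
            if v.ndim != 2 or v.shape[1] != 3:
                raise ValueError(f"marker {name!r} must have shape (N, 3), got {v.shape}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]


@dataclass
class ForceSignal:
    """Vertical ground reaction force (N)."""

    rate: float
    fz: NDArray[np.float64]

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        self.fz = np.asarray(self.fz, dtype=float)
        if not np.all(np.isfinite(self.fz)):
            raise ValueError("fz must be finite everywhere")


@dataclass
class ComTrajectory:
    """COM position (mm) and, once differentiated, velocity (mm/s)."""

    rate: float
    position: NDArray[np.float64]
    velocity: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)
            if self.velocity.shape != self.position.shape:
                raise ValueError("velocity and position must have the same shape")


@dataclass
class StrideSet:
    """S strides x T normalized points x 3 axes of COM velocity (mm/s)."""

    values: NDArray[np.float64]
    stride_times: NDArray[np.float64]  # heel-strike timestamps, length S + 1
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"values must have shape (S, T, 3), got {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError(f"a StrideSet needs at least 2 strides, got {self.values.shape[0]}")

    @property
    def n_strides(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    @property
    def percent_grid(self) -> NDArray[np.float64]:
        return np.linspace(0.0, 100.0, self.n_points)


def _fill_short_gaps(pos: NDArray, max_gap: int = MAX_GAP_FILL_FRAMES) -> NDArray:
    """Linearly fill NaN runs of length <= max_gap; longer runs stay NaN."""
    out = pos.copy()
    bad = ~np.isfinite(out).all(axis=1)
    if not bad.any():
        return out
    # identify contiguous NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    idx = np.arange(pos.shape[0], dtype=float)
    for s, e in zip(edges[::2], edges[1::2]):  # run is [s, e)
        if e - s <= max_gap and s > 0 and e < pos.shape[0]:
            for a in range(3):
                out[s:e, a] = np.interp(idx[s:e], [s - 1, e], [out[s - 1, a], out[e, a]])
    return out


def com_from_pelvis(
    markers: MarkerFrameSeries, max_gap_frames: int = MAX_GAP_FILL_FRAMES
) -> ComTrajectory:
    """COM position as the frame-wise arithmetic mean of the pelvis markers.

    Short marker dropouts (<= ``max_gap_frames``) are filled linearly; frames
    inside longer gaps remain NaN and invalidate their gait cycles during
    segmentation.
    """
    missing = [m for m in PELVIS_MARKERS if m not in markers.positions]
    if missing:
        raise KeyError(f"missing pelvis marker(s): {', '.join(missing)}")
    stack = np.stack(
        [_fill_short_gaps(markers.positions[m], max_gap_frames) for m in PELVIS_MARKERS]
    )
    return ComTrajectory(rate=markers.rate, position=stack.mean(axis=0))


def lowpass(
    x: NDArray, cutoff: float, rate: float, order: int = 4
) -> NDArray[np.float64]:
    """Zero-phase Butterworth low-pass filter (applied forward and backward).

    NaN samples are temporarily bridged by linear interpolation so the filter
    stays finite, then restored to NaN, keeping long-gap frames invalid.
    """
    x = np.asarray(x, dtype=float)
    nyquist = rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must be in (0, {nyquist}) Hz, got {cutoff}")
    flat = x.reshape(x.shape[0], -1)
    nan_rows = ~np.isfinite(flat).all(axis=1)
    if nan_rows.any():
        flat = flat.copy()
        good = np.flatnonzero(~nan_rows)
        if good.size == 0:
            raise ValueError("signal is entirely non-finite")
        for c in range(flat.shape[1]):
            flat[nan_rows, c] = np.interp(np.flatnonzero(nan_rows), good, flat[good, c])
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, flat, axis=0)
    if nan_rows.any():
        y[nan_rows] = np.nan
    return y.reshape(x.shape)


def differentiate(position: NDArray, rate: float) -> NDArray[np.float64]:
    """Velocity by central differences (second-order one-sided at the ends)."""
    position = np.asarray(position, dtype=float)
    if position.shape[0] < 3:
        raise ValueError(f"need at least 3 samples to differentiate, got {position.shape[0]}")
    return np.gradient(position, axis=0, edge_order=2) * rate


def detect_heel_strikes(
    vgrf: ForceSignal,
    threshold: float = 20.0,
    refractory_s: float | None = None,
) -> NDArray[np.int64]:
    """Heel strikes as upward crossings of a vertical-GRF threshold.

    Each returned index is the first sample at/above ``threshold``.  Events
    closer together than the refractory interval are discarded (keeping the
    earlier one); when ``refractory_s`` is None it defaults to 0.4 times the
    median inter-event interval, which suppresses re-crossings from force
    oscillations within one stance phase.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    above = vgrf.fz >= threshold
    rising = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if rising.size <= 1:
        return rising.astype(np.int64)
    if refractory_s is None:
        refractory = 0.4 * float(np.median(np.diff(rising))) / vgrf.rate
    else:
        refractory = refractory_s
    min_gap = refractory * vgrf.rate
    kept = [int(rising[0])]
    for r in rising[1:]:
        if r - kept[-1] >= min_gap:
            kept.append(int(r))
    return np.asarray(kept, dtype=np.int64)


def segment_and_normalize(
    com: ComTrajectory,
    events: NDArray[np.int64],
    T: int = 101,
    duration_bounds: tuple[float, float] = (0.5, 1.5),
    interpolation: str = "cubic",
) -> StrideSet:
    """Cut heel-strike-to-heel-strike cycles and resample each to T points.

    Each cycle spans its two bounding heel strikes inclusive, mapped onto T
    evenly spaced points covering 0-100% of the cycle (endpoints preserved
    exactly).  Cycles whose duration falls outside ``duration_bounds`` times
    the trial's median cycle duration, or which contain non-finite velocity
    samples (unfilled marker gaps), are dropped and logged.
    """
    if com.velocity is None:
        raise ValueError("ComTrajectory has no velocity; differentiate it first")
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    events = np.asarray(events, dtype=np.int64)
    if events.size < 3:
        raise ValueError(
            f"need at least 3 heel strikes (2 complete cycles), got {events.size}"
        )
    durations = np.diff(events)
    median_dur = float(np.median(durations))
    lo, hi = duration_bounds
    grid = np.linspace(0.0, 1.0, T)

    kept, dropped = [], []
    for i, (e0, e1) in enumerate(zip(events[:-1], events[1:])):
        if not lo * median_dur <= (e1 - e0) <= hi * median_dur:
            dropped.append((i, f"duration {e1 - e0} samples outside "
                               f"[{lo:g}, {hi:g}] x median {median_dur:g}"))
            continue
        if not np.all(np.isfinite(com.velocity[e0 : e1 + 1])):
            dropped.append((i, "non-finite velocity samples (marker gap)"))
            continue
        kept.append(i)

    all_finite = np.all(np.isfinite(com.velocity))
    if interpolation == "cubic" and all_finite and kept:
        # fast path: one global natural cubic spline through every sample,
        # evaluated at each kept cycle's normalized query times (integer
        # sample points are interpolated exactly, so endpoints are preserved)
        spline = CubicSpline(np.arange(com.velocity.shape[0], dtype=float), com.velocity)
        e0 = events[kept]
        queries = e0[:, None] + grid[None, :] * (events[np.asarray(kept) + 1] - e0)[:, None]
        strides = list(spline(queries.ravel()).reshape(len(kept), T, 3))
    else:
        strides = []
        for i in kept:
            seg = com.velocity[events[i] : events[i + 1] + 1]
            x = np.linspace(0.0, 1.0, seg.shape[0])
            kind = interpolation if seg.shape[0] >= 4 else "linear"
            strides.append(interp1d(x, seg, kind=kind, axis=0, assume_sorted=True)(grid))
    for i, reason in dropped:
        logger.info("dropped cycle %d: %s", i, reason)
    if len(strides) < 2:
        raise ValueError(
            f"insufficient data: only {len(strides)} valid cycles after filtering"
        )
    times = events / com.rate
    return StrideSet(values=np.stack(strides), stride_times=times, dropped=dropped)


def strides_from_trial(
    markers: MarkerFrameSeries,
    vgrf: ForceSignal,
    T: int = 101,
    cutoff_hz: float = 6.0,
    filter_order: int = 4,
    threshold_n: float = 20.0,
) -> StrideSet:
    """Full per-subject chain: filter -> COM -> velocity -> events -> strides."""
    com = com_from_pelvis(markers)
    pos = lowpass(com.position, cutoff_hz, markers.rate, order=filter_order)
    vel = differentiate(pos, markers.rate)
    com = ComTrajectory(rate=markers.rate, position=pos, velocity=vel)
    events = detect_heel_strikes(vgrf, threshold=threshold_n)
    return segment_and_normalize(com, events, T=T)
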
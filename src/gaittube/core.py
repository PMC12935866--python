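"""Gait-tube geometry: phase-dependent covariance, ellipsoids, Frenet frames.

At every normalized time point t the S stride velocity vectors give a 3x3
sample covariance Sigma_t (mm^2/s^2).  Its eigendecomposition defines the
variability ellipsoid: semi-axis i equals k * sqrt(lambda_i) (mm/s) and the
volume is (4/3) * pi * k^3 * sqrt(det Sigma_t) (mm^3/s^3), with k the
SD-scaling constant (k = 1: one-standard-deviation ellipsoid).  The tube is
the mean velocity trajectory with these ellipsoids projected onto the
Frenet-Serret normal planes and smoothed over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

from gaittube.signal_prep import StrideSet

__all__ = [
    "CovarianceSeries",
    "Ellipsoid",
    "EllipsoidSeries",
    "Ellipse2D",
    "FrenetFrameSeries",
    "GaitTube",
    "SubjectSummary",
    "stride_covariance",
    "ellipsoid_from_covariance",
    "ellipsoid_series",
    "directional_variability",
    "subject_summary",
    "frenet_frames",
    "project_covariance_to_plane",
    "smooth_waveform",
    "build_gait_tube",
    "group_mean_waveforms",
]

#: Relative threshold below which a curvature component counts as degenerate.
DEGENERATE_CURVATURE_RTOL = 1e-6


@dataclass
class CovarianceSeries:
    """Per-phase-point 3x3 COM-velocity covariance (mm^2/s^2)."""

    Sigma: NDArray[np.float64]  # (T, 3, 3)
    n_strides: int

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.ndim != 3 or self.Sigma.shape[1:] != (3, 3):
            raise ValueError(f"Sigma must have shape (T, 3, 3), got {self.Sigma.shape}")


@dataclass
class Ellipsoid:
    semi_axes: NDArray[np.float64]  # (3,) mm/s, sorted descending
    orientation: NDArray[np.float64]  # (3, 3), columns = eigenvectors, det +1
    volume: float  # mm^3/s^3
    k: float = 1.0


@dataclass
class EllipsoidSeries:
    semi_axes: NDArray[np.float64]  # (T, 3), sorted descending per point
    orientations: NDArray[np.float64]  # (T, 3, 3)
    volume: NDArray[np.float64]  # (T,)
    k: float = 1.0


@dataclass
class Ellipse2D:
    """Cross-section ellipse in a local (normal, binormal) plane."""

    semi_axes: NDArray[np.float64]  # (2,) mm/s, sorted descending
    angle: float  # radians of the major axis from the normal direction

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass
class FrenetFrameSeries:
    tangent: NDArray[np.float64]  # (T, 3) unit vectors
    normal: NDArray[np.float64]
    binormal: NDArray[np.float64]
    degenerate_flags: NDArray[np.bool_]


@dataclass
class GaitTube:
    mean_trajectory: NDArray[np.float64]  # (T, 3) mm/s
    frames: FrenetFrameSeries
    cross_sections: list[Ellipse2D]
    smoothing_window: float  # % of cycle
    k: float = 1.0

    @property
    def cross_section_areas(self) -> NDArray[np.float64]:
        return np.array([e.area for e in self.cross_sections])


@dataclass
class SubjectSummary:
    """Cycle-averaged gait-tube metrics for one subject."""

    mean_ellipsoid_volume: float  # mm^3/s^3
    var_ap: float  # mm/s, cycle-mean AP velocity SD
    var_ml: float
    var_vt: float
    total_variability: float  # var_ap + var_ml + var_vt
    volume_waveform: NDArray[np.float64] = field(repr=False)  # (T,)
    sd_waveforms: NDArray[np.float64] = field(repr=False)  # (T, 3)
    n_strides: int = 0

    def metrics(self) -> dict[str, float]:
        return {
            "mean_ellipsoid_volume": self.mean_ellipsoid_volume,
            "var_ap": self.var_ap,
            "var_ml": self.var_ml,
            "var_vt": self.var_vt,
            "total_variability": self.total_variability,
        }


def stride_covariance(strides: StrideSet) -> CovarianceSeries:
    """Unbiased (S-1 denominator) sample covariance at every phase point."""
    X = strides.values
    S = X.shape[0]
    if S < 2:
        raise ValueError(f"need at least 2 strides, got {S}")
    D = X - X.mean(axis=0, keepdims=True)
    Sigma = np.einsum("sti,stj->tij", D, D) / (S - 1)
    return CovarianceSeries(Sigma=Sigma, n_strides=S)


def _check_covariance(Sigma: NDArray, tol: float) -> NDArray:
    Sigma = np.asarray(Sigma, dtype=float)
    scale = max(float(np.abs(Sigma).max()), 1.0)
    if not np.allclose(Sigma, np.swapaxes(Sigma, -1, -2), atol=tol * scale):
        raise ValueError("covariance matrix is not symmetric")
    return 0.5 * (Sigma + np.swapaxes(Sigma, -1, -2))


def ellipsoid_from_covariance(Sigma: NDArray, k: float = 1.0, tol: float = 1e-8) -> Ellipsoid:
    """Variability ellipsoid of one covariance matrix.

    Semi-axis i = k * sqrt(eigenvalue i); volume = (4/3) pi k^3 sqrt(det).
    Small negative eigenvalues (>= -tol * scale) are clamped to zero;
    anything more indefinite raises.
    """
    Sigma = _check_covariance(Sigma, tol)
    eigval, eigvec = np.linalg.eigh(Sigma)
    scale = max(float(np.abs(eigval).max()), 1.0)
    if eigval.min() < -tol * scale:
        raise ValueError(f"covariance is indefinite (min eigenvalue {eigval.min():g})")
    eigval = np.clip(eigval, 0.0, None)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.linalg.det(eigvec) < 0:
        eigvec = eigvec.copy()
        eigvec[:, -1] *= -1
    volume = (4.0 / 3.0) * np.pi * k**3 * float(np.sqrt(np.prod(eigval)))
    return Ellipsoid(semi_axes=k * np.sqrt(eigval), orientation=eigvec, volume=volume, k=k)


def ellipsoid_series(cov: CovarianceSeries, k: float = 1.0, tol: float = 1e-8) -> EllipsoidSeries:
    """Vectorized ellipsoid decomposition of a whole covariance series."""
    Sigma = _check_covariance(cov.Sigma, tol)
    eigval, eigvec = np.linalg.eigh(Sigma)
    scale = np.maximum(np.abs(eigval).max(axis=1), 1.0)
    if (eigval.min(axis=1) < -tol * scale).any():
        raise ValueError("covariance series contains an indefinite matrix")
    eigval = np.clip(eigval, 0.0, None)
    # eigh returns ascending eigenvalues; flip to descending
    eigval = eigval[:, ::-1]
    eigvec = eigvec[:, :, ::-1]
    neg = np.linalg.det(eigvec) < 0
    eigvec[neg, :, -1] *= -1
    volume = (4.0 / 3.0) * np.pi * k**3 * np.sqrt(np.prod(eigval, axis=1))
    return EllipsoidSeries(
        semi_axes=k * np.sqrt(eigval), orientations=eigvec, volume=volume, k=k
    )


def directional_variability(strides: StrideSet) -> NDArray[np.float64]:
    """Per-axis stride-to-stride SD waveform, shape (T, 3) in AP/ML/VT order.

    Equals the square roots of the covariance-series diagonal.
    """
    Sigma = stride_covariance(strides).Sigma
    return np.sqrt(np.diagonal(Sigma, axis1=1, axis2=2))


def subject_summary(strides: StrideSet, k: float = 1.0) -> SubjectSummary:
    """Cycle-averaged volume and directional SDs for one subject."""
    cov = stride_covariance(strides)
    ell = ellipsoid_series(cov, k=k)
    sd = np.sqrt(np.diagonal(cov.Sigma, axis1=1, axis2=2))
    means = sd.mean(axis=0)
    return SubjectSummary(
        mean_ellipsoid_volume=float(ell.volume.mean()),
        var_ap=float(means[0]),
        var_ml=float(means[1]),
        var_vt=float(means[2]),
        total_variability=float(means.sum()),
        volume_waveform=ell.volume,
        sd_waveforms=sd,
        n_strides=strides.n_strides,
    )


def _unit(v: NDArray, axis: int = -1) -> tuple[NDArray, NDArray]:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return np.divide(v, n, out=np.zeros_like(v), where=n > 0), n.squeeze(axis)


def frenet_frames(mean_trajectory: NDArray, degeneracy_rtol: float = DEGENERATE_CURVATURE_RTOL) -> FrenetFrameSeries:
    """Frenet-Serret frames along a T x 3 trajectory.

    tangent = normalized first derivative; normal = normalized component of
    the tangent derivative orthogonal to the tangent; binormal = tangent x
    normal.  Points where the curvature component nearly vanishes are flagged
    degenerate and inherit the normal direction of the nearest non-degenerate
    point (re-orthogonalized against the local tangent); a fully straight
    trajectory gets a constant fallback frame.  Successive normals are
    sign-aligned to avoid frame flips.
    """
    P = np.asarray(mean_trajectory, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"mean_trajectory must have shape (T, 3), got {P.shape}")
    if P.shape[0] < 5:
        raise ValueError(f"need at least 5 points, got {P.shape[0]}")
    d1 = np.gradient(P, axis=0, edge_order=2)
    tangent, speed = _unit(d1)
    if np.any(speed <= 0):
        raise ValueError("trajectory has zero-length derivative (repeated points)")
    dT = np.gradient(tangent, axis=0, edge_order=2)
    curv = dT - np.sum(dT * tangent, axis=1, keepdims=True) * tangent
    curv_norm = np.linalg.norm(curv, axis=1)
    # the tangent is a unit vector, so curv_norm is a turning angle per step;
    # flag both absolute float-noise curvature and curvature negligible
    # relative to the curve's own maximum
    ref = float(curv_norm.max())
    degenerate = curv_norm <= max(degeneracy_rtol * ref, degeneracy_rtol)

    T = P.shape[0]
    normal = np.zeros_like(tangent)
    good = np.flatnonzero(~degenerate)
    if good.size:
        normal[good] = curv[good] / curv_norm[good, None]
        # propagate the nearest non-degenerate normal into degenerate runs
        for i in np.flatnonzero(degenerate):
            j = good[np.argmin(np.abs(good - i))]
            normal[i] = normal[j]
    else:
        # straight line: any direction not parallel to the tangent works
        seed = np.eye(3)[np.argmin(np.abs(tangent[0]))]
        normal[:] = seed
    # re-orthogonalize against the local tangent and enforce sign continuity
    normal -= np.sum(normal * tangent, axis=1, keepdims=True) * tangent
    normal, _ = _unit(normal)
    for i in range(1, T):
        if np.dot(normal[i], normal[i - 1]) < 0:
            normal[i] *= -1
    binormal = np.cross(tangent, normal)
    return FrenetFrameSeries(
        tangent=tangent, normal=normal, binormal=binormal, degenerate_flags=degenerate
    )


def _check_orthonormal(frame: NDArray, tol: float = 1e-8) -> NDArray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (3, 3):
        raise ValueError(f"frame must be a 3x3 matrix of rows (t, n, b), got {frame.shape}")
    if not np.allclose(frame @ frame.T, np.eye(3), atol=tol):
        raise ValueError("frame is not orthonormal")
    return frame


def _ellipse_from_cov2(C: NDArray, k: float) -> Ellipse2D:
    eigval, eigvec = np.linalg.eigh(0.5 * (C + C.T))
    eigval = np.clip(eigval, 0.0, None)
    major = eigvec[:, 1]
    return Ellipse2D(
        semi_axes=k * np.sqrt(eigval[::-1]),
        angle=float(np.arctan2(major[1], major[0])),
    )


def project_covariance_to_plane(Sigma: NDArray, frame: NDArray, k: float = 1.0) -> Ellipse2D:
    """Project a 3x3 covariance into the (normal, binormal) plane of a frame.

    ``frame`` is the 3x3 orthonormal matrix with rows (tangent, normal,
    binormal).  The marginal covariance is P Sigma P^T with P the (normal,
    binormal) rows; the returned ellipse uses the same k-scaling as the 3D
    ellipsoids.
    """
    frame = _check_orthonormal(frame)
    Sigma = _check_covariance(Sigma, 1e-8)
    P = frame[1:, :]
    return _ellipse_from_cov2(P @ Sigma @ P.T, k)


def smooth_waveform(series: NDArray, window: float) -> NDArray[np.float64]:
    """Centered circular moving average over the gait cycle.

    ``window`` is in percent of the cycle; the kernel width in samples is
    round(window / 100 * T), at least 1 (window 0 is the identity).  The
    circular (cycle-periodic) boundary reflects that 0% and 100% of the gait
    cycle are the same event.
    """
    series = np.asarray(series, dtype=float)
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    if window > 100:
        raise ValueError(f"window must be <= 100% of the cycle, got {window}")
    n = series.shape[0]
    w = max(1, int(round(window / 100.0 * n)))
    if w == 1:
        return series.copy()
    return ndimage.uniform_filter1d(series, size=w, axis=0, mode="wrap")


def build_gait_tube(strides: StrideSet, k: float = 1.0, window: float = 5.0) -> GaitTube:
    """Mean velocity trajectory + smoothed Frenet-plane cross sections.

    The ellipsoids come from the unsmoothed per-point covariance; smoothing
    is applied (a) to the mean trajectory before Frenet differentiation, to
    avoid noise-driven frame flips, and (b) to the projected 2x2 cross-section
    covariances, which is the temporal smoothing that makes the tube
    continuous.
    """
    mean_traj = strides.values.mean(axis=0)
    frames = frenet_frames(smooth_waveform(mean_traj, window))
    Sigma = stride_covariance(strides).Sigma
    Pmat = np.stack([frames.normal, frames.binormal], axis=1)  # (T, 2, 3)
    cov2 = np.einsum("tij,tjk,tlk->til", Pmat, Sigma, Pmat)
    cov2 = smooth_waveform(cov2.reshape(cov2.shape[0], 4), window).reshape(cov2.shape)
    sections = [_ellipse_from_cov2(C, k) for C in cov2]
    return GaitTube(
        mean_trajectory=mean_traj,
        frames=frames,
        cross_sections=sections,
        smoothing_window=window,
        k=k,
    )


def group_mean_waveforms(subject_waveforms: list[NDArray] | NDArray) -> tuple[NDArray, NDArray]:
    """Point-wise grand mean and across-subject SD of per-subject waveforms.

    Accepts a list (or stacked array) of equally shaped T-vectors or T x 3
    arrays; returns (mean, sd) of the same shape.  SD uses the n-1
    denominator and is zero for a single subject.
    """
    arrs = [np.asarray(w, dtype=float) for w in subject_waveforms]
    if not arrs:
        raise ValueError("need at least one subject waveform")
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"subject waveforms have mismatched shapes: {sorted(shapes)}")
    X = np.stack(arrs)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros_like(mean)
    return mean, sd
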
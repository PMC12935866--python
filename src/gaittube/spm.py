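"""Phase-resolved group comparison of gait waveforms (permutation SPM).

A point-wise two-sample t statistic is computed along the normalized gait
cycle and family-wise error across the whole 0-100% cycle is controlled
nonparametrically: group labels are permuted (full enumeration when
feasible, otherwise random permutations always including the identity), the
null distribution of the maximum |t| over the cycle sets the critical
threshold at the 1 - alpha quantile, and each suprathreshold cluster
receives the fraction of permutations whose maximum |t| reaches the
cluster's own maximum.  Results are then aggregated over the eight named
clinical gait phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from itertools import combinations
import warnings

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "GaitPhase",
    "PhaseDefinition",
    "DEFAULT_PHASES",
    "Cluster",
    "SPMResult",
    "spm_two_sample",
    "phase_aggregate",
    "difference_waveform",
]


@dataclass(frozen=True)
class GaitPhase:
    name: str
    start: float  # % of gait cycle
    end: float


@dataclass
class PhaseDefinition:
    """Ordered clinical gait phases; contiguous and covering 0-100%."""

    phases: tuple[GaitPhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("at least one phase is required")
        if self.phases[0].start != 0.0 or self.phases[-1].end != 100.0:
            raise ValueError("phases must cover 0-100% of the gait cycle")
        for a, b in zip(self.phases[:-1], self.phases[1:]):
            if a.end != b.start:
                raise ValueError(
                    f"phases must be contiguous: {a.name} ends at {a.end}, "
                    f"{b.name} starts at {b.start}"
                )
        for p in self.phases:
            if not p.end > p.start:
                raise ValueError(f"phase {p.name} has non-positive extent")

    def __iter__(self):
        return iter(self.phases)

    def names(self) -> list[str]:
        return [p.name for p in self.phases]


#: The eight clinical gait phases as percent ranges of the cycle.
DEFAULT_PHASES = PhaseDefinition(
    (
        GaitPhase("Initial Contact", 0.0, 2.0),
        GaitPhase("Loading Response", 2.0, 12.0),
        GaitPhase("Mid Stance", 12.0, 31.0),
        GaitPhase("Terminal Stance", 31.0, 50.0),
        GaitPhase("Pre-Swing", 50.0, 62.0),
        GaitPhase("Initial Swing", 62.0, 75.0),
        GaitPhase("Mid Swing", 75.0, 87.0),
        GaitPhase("Terminal Swing", 87.0, 100.0),
    )
)


@dataclass
class Cluster:
    start_pct: float
    end_pct: float
    start_idx: int
    end_idx: int  # inclusive
    max_t: float
    p: float


@dataclass
class SPMResult:
    t_waveform: NDArray[np.float64]
    critical_threshold: float
    clusters: list[Cluster]
    per_phase: dict[str, tuple[bool, float]]
    n_permutations: int
    seed: int | None
    alpha: float
    full_enumeration: bool = False
    percent_grid: NDArray[np.float64] = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "t_waveform": self.t_waveform.tolist(),
            "critical_threshold": self.critical_threshold,
            "clusters": [
                {
                    "start_pct": c.start_pct,
                    "end_pct": c.end_pct,
                    "max_t": c.max_t,
                    "p": c.p,
                }
                for c in self.clusters
            ],
            "per_phase": {
                name: {"significant": bool(sig), "p": p}
                for name, (sig, p) in self.per_phase.items()
            },
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alpha": self.alpha,
            "full_enumeration": self.full_enumeration,
        }


def _pooled_t(sumA, sumsqA, sumT, sumsqT, nA, nB, equal_var=True):
    """Two-sample t from group-A sums and total sums, vectorized over rows."""
    sumB = sumT - sumA
    sumsqB = sumsqT - sumsqA
    meanA, meanB = sumA / nA, sumB / nB
    ssA = sumsqA - nA * meanA**2
    ssB = sumsqB - nB * meanB**2
    if equal_var:
        sp2 = (ssA + ssB) / (nA + nB - 2)
        denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    else:
        denom = np.sqrt(ssA / (nA * (nA - 1)) + ssB / (nB * (nB - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (meanA - meanB) / denom
    return np.where(denom > 0, t, 0.0)


def spm_two_sample(
    waveA: NDArray,
    waveB: NDArray,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = 0,
    phases: PhaseDefinition = DEFAULT_PHASES,
    equal_var: bool = True,
) -> SPMResult:
    """Permutation SPM comparison of two groups of waveforms.

    Parameters
    ----------
    waveA, waveB : ndarray, shape (NA, T) and (NB, T)
        Per-subject waveforms on a common normalized-cycle grid.
    alpha : float
        Family-wise significance level.
    n_perm : int
        Number of permutations.  When the number of distinct group
        relabelings C(NA+NB, NA) is <= n_perm the null is enumerated exactly
        (and the result is deterministic, independent of ``seed``); otherwise
        ``n_perm`` random relabelings are used, the first being the identity.
    """
    A = np.atleast_2d(np.asarray(waveA, dtype=float))
    B = np.atleast_2d(np.asarray(waveB, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"waveform lengths differ: {A.shape[1]} vs {B.shape[1]}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse", stacklevel=2)
    nA, nB = A.shape[0], B.shape[0]
    N = nA + nB
    T = A.shape[1]
    X = np.vstack([A, B])
    X2 = X * X
    sumT, sumsqT = X.sum(axis=0), X2.sum(axis=0)

    n_exact = comb(N, nA)
    full = n_exact <= n_perm
    if full:
        sel = np.zeros((n_exact, N), dtype=bool)
        for r, ix in enumerate(combinations(range(N), nA)):
            sel[r, list(ix)] = True
        # put the identity labeling first for readability
        ident = np.zeros(N, dtype=bool)
        ident[:nA] = True
        first = int(np.flatnonzero((sel == ident).all(axis=1))[0])
        sel[[0, first]] = sel[[first, 0]]
        P = n_exact
    else:
        rng = np.random.default_rng(seed)
        sel = np.zeros((n_perm, N), dtype=bool)
        sel[0, :nA] = True  # identity
        for r in range(1, n_perm):
            sel[r, rng.permutation(N)[:nA]] = True
        P = n_perm

    M = sel.astype(float)
    t_all = _pooled_t(M @ X, M @ X2, sumT, sumsqT, nA, nB, equal_var)
    t_obs = t_all[0]
    maxs = np.abs(t_all).max(axis=1)
    threshold = float(np.quantile(maxs, 1.0 - alpha, method="higher"))

    pct = np.linspace(0.0, 100.0, T)
    clusters: list[Cluster] = []
    supra = np.abs(t_obs) > threshold
    if supra.any():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], supra.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):  # run [s, e)
            cmax = float(np.abs(t_obs[s:e]).max())
            p = float(np.mean(maxs >= cmax))
            clusters.append(
                Cluster(
                    start_pct=float(pct[s]),
                    end_pct=float(pct[e - 1]),
                    start_idx=int(s),
                    end_idx=int(e - 1),
                    max_t=cmax,
                    p=p,
                )
            )

    per_phase = _per_phase(clusters, phases, alpha)
    return SPMResult(
        t_waveform=t_obs,
        critical_threshold=threshold,
        clusters=clusters,
        per_phase=per_phase,
        n_permutations=P,
        seed=None if full else seed,
        alpha=alpha,
        full_enumeration=full,
        percent_grid=pct,
    )


def _overlaps(c: Cluster, ph: GaitPhase) -> bool:
    return c.start_pct <= ph.end and c.end_pct >= ph.start


def _per_phase(
    clusters: list[Cluster], phases: PhaseDefinition, alpha: float
) -> dict[str, tuple[bool, float]]:
    out: dict[str, tuple[bool, float]] = {}
    for ph in phases:
        ps = [c.p for c in clusters if _overlaps(c, ph)]
        sig = any(c.p <= alpha for c in clusters if _overlaps(c, ph))
        out[ph.name] = (sig, min(ps) if ps else 1.0)
    return out


def phase_aggregate(result: SPMResult, phases: PhaseDefinition = DEFAULT_PHASES):
    """Per-phase significance table as a pandas DataFrame.

    One row per phase; p is the minimum cluster p among clusters overlapping
    the phase range (1.0 when no cluster overlaps); a phase is significant
    when an overlapping cluster has p <= alpha.
    """
    import pandas as pd

    per_phase = _per_phase(result.clusters, phases, result.alpha)
    rows = [
        {
            "phase": ph.name,
            "start_pct": ph.start,
            "end_pct": ph.end,
            "significant": per_phase[ph.name][0],
            "p": per_phase[ph.name][1],
        }
        for ph in phases
    ]
    return pd.DataFrame(rows)


def difference_waveform(groupA_mean: NDArray, groupB_mean: NDArray) -> NDArray[np.float64]:
    """Point-wise A - B difference of two group-mean waveforms."""
    a = np.asarray(groupA_mean, dtype=float)
    b = np.asarray(groupB_mean, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"waveform shapes differ: {a.shape} vs {b.shape}")
    return a - b
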